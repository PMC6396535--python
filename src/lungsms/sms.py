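"""Volume correction and the Standard Mass Score (SMS).

The corrected percentile density moves a subject's recalibrated PD15 to the
density that would have been measured at the predicted CT-volume, assuming
the sponge-model power law with empirical exponent S:

    rho_cor = rho_cal · (V_CT,pred / V_CT) ** S

S = −1 is the strict sponge model (lung mass ρ·V conserved over the
respiratory cycle); the default S = −1.1 is the empirically steeper slope
that best reproduces paired inspiratory/expiratory densitometry.

The SMS is the Z-score of the corrected density against the normative
density law, evaluated at the subject's predicted CT-volume:

    SMS = [log(rho_cor) − (α + β·log(V_CT,pred))] / σ

SMS 0 means exactly the predicted normal lung tissue mass; values in
(−2, 2) are within the normal range; below −2 abnormal tissue loss, above
+2 abnormally increased mass.  Severe emphysema produces scores many
standard deviations below zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .densitometry import (
    REGIONS,
    LungMask,
    RegionPartition,
    compute_volume,
    partition_regions,
    percentile_density,
    segment_lungs,
)
from .errors import DegenerateInputError, DomainError, LungSMSError
from .io import CTVolume, SubjectRecord
from .normative import NormativeModel
from .recalibration import ReferenceSamples, recalibrate, sample_references
from .reference_equations import predicted_tlc

#: the four regional involvement patterns that dominate in basal-first
#: (alpha-1 antitrypsin deficiency type) emphysema
CANONICAL_PATTERNS = ("none", "basal", "central+basal", "apical+central+basal")

#: fixed canonical ordering of all eight patterns (A, C, B flags)
PATTERN_ORDER = ("none", "apical", "central", "basal", "apical+central",
                 "apical+basal", "central+basal", "apical+central+basal")


def volume_correct(rho_cal: float, v_ct: float, v_ct_pred: float,
                   slope_s: float = -1.1) -> float:
    """Sponge-model volume correction of a recalibrated density (g/L)."""
    if rho_cal <= 0 or v_ct <= 0 or v_ct_pred <= 0:
        raise DomainError(
            f"volume correction needs positive density and volumes, got "
            f"rho_cal={rho_cal}, v_ct={v_ct}, v_ct_pred={v_ct_pred}"
        )
    if slope_s >= 0:
        raise DomainError(f"slope S must be negative, got {slope_s}")
    return float(rho_cal * (v_ct_pred / v_ct) ** slope_s)


def standard_mass_score(rho_cor: float, v_ct_pred: float,
                        model: NormativeModel, scope: str = "global") -> float:
    """Z-score of a corrected density against the normative law."""
    if rho_cor <= 0 or v_ct_pred <= 0:
        raise DomainError("SMS needs positive corrected density and volume")
    law = model.law(scope)
    if law.sigma == 0:
        raise DegenerateInputError(
            f"normative σ is zero for scope {scope!r}; Z-score undefined")
    log = model.log
    return float((log(rho_cor) - law.predict_log_density(log(v_ct_pred)))
                 / law.sigma)


def classify(sms: float) -> str:
    """Band classification of one SMS value (±2 normal range)."""
    if sms < -2.0:
        return "abnormal_low"
    if sms > 2.0:
        return "abnormal_high"
    return "normal"


@dataclass
class SMSResult:
    """Full audit trail of one subject's standardized densitometry."""

    subject_id: str
    rho_cal: float                      # recalibrated PD15, g/L
    v_ct: float                         # observed CT-volume, L
    tlc_pred: float                     # predicted TLC, L
    v_ct_pred: float                    # predicted CT-volume, L
    rho_cor: float                      # volume-corrected PD15, g/L
    sms_global: float
    sms_regional: dict = field(default_factory=dict)
    regional_detail: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classification:
            self.classification = {"global": classify(self.sms_global),
                                   **{r: classify(s)
                                      for r, s in self.sms_regional.items()}}

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "rho_cal_gl": self.rho_cal, "v_ct_l": self.v_ct,
            "tlc_pred_l": self.tlc_pred, "v_ct_pred_l": self.v_ct_pred,
            "rho_cor_gl": self.rho_cor, "sms_global": self.sms_global,
            "sms_regional": dict(self.sms_regional),
            "regional_detail": self.regional_detail,
            "classification": dict(self.classification),
            "audit": self.audit,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [
            f"Standard Mass Score report — subject {self.subject_id}",
            f"  recalibrated PD15 : {self.rho_cal:8.2f} g/L",
            f"  CT-volume         : {self.v_ct:8.2f} L",
            f"  predicted TLC     : {self.tlc_pred:8.2f} L",
            f"  predicted CT-vol  : {self.v_ct_pred:8.2f} L",
            f"  corrected PD15    : {self.rho_cor:8.2f} g/L",
            f"  SMS (global)      : {self.sms_global:8.2f}  "
            f"[{self.classification['global']}]",
        ]
        for region in REGIONS:
            if region in self.sms_regional:
                lines.append(
                    f"  SMS ({region:<7})     : {self.sms_regional[region]:8.2f}  "
                    f"[{self.classification[region]}]")
        return "\n".join(lines)


def score_record(subject_id: str, gender: str, height: float, v_ct: float,
                 pd15: float, model: NormativeModel,
                 regional: Optional[Mapping[str, tuple[float, float]]] = None,
                 tlc_coefficients: Optional[Mapping] = None) -> SMSResult:
    """Score a subject from tabular measurements (no image needed).

    ``regional`` maps region name to ``(v_ct_region, pd15_region)``.
    """
    tlc = predicted_tlc(gender, height, tlc_coefficients)
    v_pred = model.predicted_v_ct(gender, tlc, "global")
    rho_cor = volume_correct(pd15, v_ct, v_pred, model.slope_s)
    sms_g = standard_mass_score(rho_cor, v_pred, model, "global")
    sms_r, detail = {}, {}
    if regional:
        for region, (v_r, d_r) in regional.items():
            v_pred_r = model.predicted_v_ct(gender, tlc, region)
            rho_cor_r = volume_correct(d_r, v_r, v_pred_r, model.slope_s)
            sms_r[region] = standard_mass_score(rho_cor_r, v_pred_r, model, region)
            detail[region] = {"v_ct_l": v_r, "pd15_gl": d_r,
                              "v_ct_pred_l": v_pred_r, "rho_cor_gl": rho_cor_r}
    return SMSResult(
        subject_id=subject_id, rho_cal=float(pd15), v_ct=float(v_ct),
        tlc_pred=tlc, v_ct_pred=v_pred, rho_cor=rho_cor, sms_global=sms_g,
        sms_regional=sms_r, regional_detail=detail,
        audit={"slope_s": model.slope_s, "log_base": model.log_base,
               "path": "tabular"},
    )


def _stage(name: str):
    """Decorator-free stage annotation: re-raise with the stage name noted."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LungSMSError):
                exc.add_note(f"stage: {name}")
            return False

    return _Ctx()


def score_subject(volume: CTVolume, subject: SubjectRecord,
                  model: NormativeModel,
                  refs: Optional[ReferenceSamples] = None,
                  threshold: float = -380.0,
                  air_roi=None, aorta_roi=None,
                  fractional_partitions: bool = True) -> SMSResult:
    """Full imaging pipeline: segment → partition → recalibrate → PD15 → SMS.

    Every intermediate value is retained in the result's audit trail.  When
    ``refs`` is None the references are sampled from the volume (explicit
    ROIs if given, otherwise the automatic phantom-convention placement).
    """
    with _stage("segmentation"):
        mask = segment_lungs(volume, threshold=threshold)
        v_ct = compute_volume(mask)
    with _stage("partitioning"):
        partition = partition_regions(mask, fractional=fractional_partitions)
    with _stage("reference sampling"):
        if refs is None:
            refs = sample_references(volume, air_roi=air_roi, aorta_roi=aorta_roi)
    with _stage("recalibration"):
        densities = recalibrate(volume.voxels[mask.membership], refs)
    with _stage("densitometry"):
        pd15 = percentile_density(densities, 0.15)
        regional: dict[str, tuple[float, float]] = {}
        region_volumes = partition.region_volumes
        has_regional = all(r in model.regional_laws for r in REGIONS)
        if has_regional:
            for region in REGIONS:
                rmask = partition.region_mask(region) & mask.membership
                d_r = recalibrate(volume.voxels[rmask], refs)
                regional[region] = (region_volumes[region],
                                    percentile_density(d_r, 0.15))
    with _stage("scoring"):
        result = score_record(
            subject_id=subject.subject_id, gender=subject.gender,
            height=subject.height, v_ct=v_ct, pd15=pd15, model=model,
            regional=regional or None,
        )
    result.audit.update({
        "path": "imaging", "threshold_hu": threshold,
        "references": refs.to_dict(),
        "partition_volumes_l": [float(v) for v in partition.partition_volumes],
        "fractional_partitions": partition.fractional_slices,
        "n_lung_voxels": int(mask.membership.sum()),
        "source_id": volume.source_id,
    })
    return result


@dataclass
class PatternClassification:
    flags: tuple[bool, bool, bool]     # below-normal for (apical, central, basal)
    name: str
    canonical: bool


def classify_pattern(result: SMSResult | Mapping[str, float] | tuple,
                     ) -> PatternClassification:
    """Regional involvement pattern: below-normal flags per region.

    A region is involved iff its SMS < −2.  The four patterns consistent
    with basal-first progression (none; basal; central+basal; all three)
    are flagged canonical; the other four combinations are non-canonical.
    """
    if isinstance(result, SMSResult):
        scores = result.sms_regional
    elif isinstance(result, Mapping):
        scores = result
    else:
        scores = dict(zip(REGIONS, result))
    missing = [r for r in REGIONS if r not in scores or scores[r] is None
               or (isinstance(scores[r], float) and math.isnan(scores[r]))]
    if missing:
        raise DegenerateInputError(f"missing regional SMS for {missing}")
    flags = tuple(bool(scores[r] < -2.0) for r in REGIONS)
    involved = [r for r, f in zip(REGIONS, flags) if f]
    name = "+".join(involved) if involved else "none"
    return PatternClassification(flags=flags, name=name,
                                 canonical=name in CANONICAL_PATTERNS)
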