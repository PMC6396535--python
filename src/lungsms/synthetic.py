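"""Synthetic phantoms and cohorts with exact ground truth.

Two generation tiers share one parameter vocabulary:

* cheap tabular cohorts (heights, volumes, percentile densities and, for
  patient cohorts, true Standard Mass Scores and coupled D_LCO values) for
  the statistics modules, and
* full voxel phantoms (body, two ellipsoidal lungs, trachea entering from
  the superior border, descending-aorta cylinder, exterior air) for the
  imaging modules.

The core contract is inverse construction: densities are written through
the normalization equations backwards (Z-score → corrected density →
observed density at the generated volume), so running the analysis pipeline
on generated data returns the generating parameters up to voxelization and
sampling noise.  Disease severity is modelled directly in SMS space with a
basal → central → apical progression; emphysema microstructure and scanner
noise are deliberately not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import REGIONS, LungMask, partition_regions, percentile_density
from .errors import SyntheticSpecError
from .io import CTVolume
from .normative import DensityLaw, NormativeModel, VolumeTranslation
from .recalibration import BLOOD_DENSITY_GL, ReferenceSamples
from .reference_equations import predicted_tlc

# ---------------------------------------------------------------------------
# cohort specifications
# ---------------------------------------------------------------------------

#: regional share of total CT-volume: 3, 3 and 4 of the ten retained twelfths
REGION_FRACTIONS = {"apical": 3 / 12, "central": 3 / 12, "basal": 4 / 12}


@dataclass
class DiseaseSpec:
    """Basal-first emphysema severity model, parameterized in SMS space."""

    severity_median: float = 12.0     # median tissue-loss burden, SMS units
    severity_sdlog: float = 1.0       # lognormal shape of the burden
    severity_cap: float = 45.0        # PD15 cannot fall below a few g/L
    central_lag: float = 5.0          # burden before the central region joins
    apical_lag: float = 10.0          # burden before the apical region joins
    region_noise_sd: float = 0.8
    global_weights: tuple[float, float, float] = (0.25, 0.25, 0.5)
    global_noise_sd: float = 0.3
    dlco_mean: float = 55.0           # %pred marginal, Table-1-like
    dlco_sd: float = 19.0
    dlco_r2: float = 0.25             # true SMS–D_LCO coupling
    dlco_range: tuple[float, float] = (5.0, 140.0)
    inspiration_mean: float = 1.05    # patients tend to hyperinflate
    inspiration_sd: float = 0.08
    inspiration_range: tuple[float, float] = (0.85, 1.30)

    def __post_init__(self) -> None:
        if not (0.0 <= self.dlco_r2 <= 1.0):
            raise SyntheticSpecError(
                f"infeasible SMS–D_LCO coupling R² = {self.dlco_r2}")


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort (log10 density law)."""

    seed: int
    n_subjects: int = 76
    male_fraction: float = 52 / 76
    height_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.76, "female": 1.63})
    height_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.07, "female": 0.06})
    alpha: float = 2.50               # log10 g/L at log10 V = 0
    beta: float = -0.70               # across-subject size slope
    sigma: float = 0.025              # residual SD, log10
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.40, "female": 0.40})
    delta: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.95, "female": 0.95})
    volume_noise_sd: float = 0.10     # L, around the translation line
    inspiration_mean: float = 1.00    # controls are scanned at full inspiration
    inspiration_sd: float = 0.08
    inspiration_range: tuple[float, float] = (0.75, 1.25)
    slope_s: float = -1.1
    age_range: tuple[float, float] = (26.0, 78.0)
    smoking_probs: Mapping[str, float] = field(
        default_factory=lambda: {"never": 0.447, "ex": 0.342, "current": 0.211})
    disease: Optional[DiseaseSpec] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticSpecError("a seed is mandatory for reproducibility")
        if self.n_subjects < 2:
            raise SyntheticSpecError("need at least two subjects")
        if self.sigma < 0:
            raise SyntheticSpecError("sigma must be non-negative")

    # -- the generating model, as a ready-made results object ----------------
    def truth_model(self, regional: bool = True) -> NormativeModel:
        """The exact generating parameters packaged as a NormativeModel."""
        nan = float("nan")

        def law(alpha: float) -> DensityLaw:
            return DensityLaw(alpha=alpha, beta=self.beta, sigma=self.sigma,
                              se_alpha=nan, se_beta=nan, se_sigma=nan, n=0)

        def trans(scale: float) -> dict[str, VolumeTranslation]:
            return {g: VolumeTranslation(
                gamma=scale * self.gamma[g], delta=scale * self.delta[g],
                se_gamma=nan, se_delta=nan, n=0) for g in ("male", "female")}

        regional_laws, translations = {}, {"global": trans(1.0)}
        if regional:
            for region, frac in REGION_FRACTIONS.items():
                regional_laws[region] = law(self.alpha - self.beta * math.log10(frac))
                translations[region] = trans(frac)
        return NormativeModel(
            global_law=law(self.alpha), translations=translations,
            regional_laws=regional_laws, slope_s=self.slope_s, log_base="10",
            n_subjects=0, provenance=f"synthetic truth (seed {self.seed})",
        )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _demographics(spec: CohortSpec, rng: np.random.Generator,
                  prefix: str) -> pd.DataFrame:
    n = spec.n_subjects
    n_male = int(round(n * spec.male_fraction))
    genders = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(genders)
    heights = np.array([
        float(np.clip(rng.normal(spec.height_mean[g], spec.height_sd[g]),
                      1.40, 2.10))
        for g in genders
    ])
    ages = rng.uniform(*spec.age_range, size=n).round(0)
    smoking = rng.choice(list(spec.smoking_probs),
                         p=np.array(list(spec.smoking_probs.values()))
                         / sum(spec.smoking_probs.values()), size=n)
    return pd.DataFrame({
        "subject_id": [f"{prefix}-{i:03d}" for i in range(n)],
        "gender": genders, "height": heights, "age": ages,
        "smoking_status": smoking,
    })


def _volumes(spec: CohortSpec, df: pd.DataFrame, rng: np.random.Generator,
             insp_mean: float, insp_sd: float,
             insp_range: tuple[float, float]) -> pd.DataFrame:
    tlc = np.array([predicted_tlc(g, h)
                    for g, h in zip(df["gender"], df["height"])])
    gamma = np.array([spec.gamma[g] for g in df["gender"]])
    delta = np.array([spec.delta[g] for g in df["gender"]])
    v_pred_true = gamma + delta * tlc
    v_full = v_pred_true + rng.normal(0.0, spec.volume_noise_sd, len(df))
    f = _truncnorm(rng, insp_mean, insp_sd, *insp_range, size=len(df))
    out = df.copy()
    out["_tlc_pred"] = tlc
    out["_v_pred_true"] = v_pred_true
    out["v_ct"] = v_full * f
    return out


def _densities_from_sms(spec: CohortSpec, df: pd.DataFrame,
                        sms_by_scope: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Invert the normalization: write PD15 columns realizing given scores."""
    out = df.copy()
    v_pred = df["_v_pred_true"].to_numpy()
    sponge = (df["v_ct"].to_numpy() / v_pred) ** spec.slope_s
    for scope, sms in sms_by_scope.items():
        if scope == "global":
            alpha, col = spec.alpha, "pd15"
            v_p, ratio = v_pred, sponge
        else:
            frac = REGION_FRACTIONS[scope]
            alpha, col = spec.alpha - spec.beta * math.log10(frac), f"pd15_{scope}"
            v_p, ratio = frac * v_pred, sponge
            out[f"v_ct_{scope}"] = frac * df["v_ct"].to_numpy()
        rho_cor = 10.0 ** (alpha + spec.beta * np.log10(v_p) + spec.sigma * sms)
        out[col] = rho_cor * ratio
    return out


def generate_normative_cohort(spec: CohortSpec) -> pd.DataFrame:
    """A healthy cohort following the generating density law exactly.

    Per subject: height by gender, predicted TLC via the shipped reference
    equations, CT-volume ``(γ + δ·TLC_pred + ε_V)·f`` with inspiration
    fraction ``f``, and densities written through the sponge model so the
    corrected density obeys ``log10 ρ_cor = α + β log10 V_pred + N(0, σ)``
    globally and per region.
    """
    if spec.disease is not None:
        raise SyntheticSpecError("normative cohorts must not carry a disease model")
    rng = np.random.default_rng(spec.seed)
    df = _demographics(spec, rng, "norm")
    df = _volumes(spec, df, rng, spec.inspiration_mean, spec.inspiration_sd,
                  spec.inspiration_range)
    n = len(df)
    # scope-wise residuals are independent standard draws; the inversion
    # scales them by σ
    sms = {"global": rng.standard_normal(n)}
    for region in REGIONS:
        sms[region] = rng.standard_normal(n)
    df = _densities_from_sms(spec, df, sms)
    return df.drop(columns=["_tlc_pred", "_v_pred_true"])


def generate_patient_cohort(spec: CohortSpec,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """An emphysema cohort with known per-subject SMS and coupled D_LCO.

    A lognormal tissue-loss burden drives the basal region one-for-one;
    the central and apical regions join after the configured lags
    (basal → central → apical progression).  Densities are back-computed
    through the normalization equations so the tabular pipeline recovers
    the true scores exactly.  Returns ``(cohort, truth)`` where ``truth``
    holds the generating scores, burden and D_LCO.
    """
    disease = spec.disease
    if disease is None:
        raise SyntheticSpecError("patient cohorts require a disease model")
    rng = np.random.default_rng(spec.seed)
    df = _demographics(spec, rng, "aatd")
    df = _volumes(spec, df, rng, disease.inspiration_mean,
                  disease.inspiration_sd, disease.inspiration_range)
    n = len(df)

    burden = np.minimum(
        rng.lognormal(math.log(disease.severity_median),
                      disease.severity_sdlog, n),
        disease.severity_cap)
    eta = rng.normal(0.0, disease.region_noise_sd, (3, n))
    sms_apical = -np.maximum(0.0, burden - disease.apical_lag) + eta[0]
    sms_central = -np.maximum(0.0, burden - disease.central_lag) + eta[1]
    sms_basal = -burden + eta[2]
    w_a, w_c, w_b = disease.global_weights
    sms_global = (w_a * sms_apical + w_c * sms_central + w_b * sms_basal
                  + rng.normal(0.0, disease.global_noise_sd, n))

    df = _densities_from_sms(spec, df, {
        "global": sms_global, "apical": sms_apical,
        "central": sms_central, "basal": sms_basal,
    })

    z = (sms_global - sms_global.mean()) / sms_global.std(ddof=0)
    noise = rng.standard_normal(n)
    dlco = disease.dlco_mean + disease.dlco_sd * (
        math.sqrt(disease.dlco_r2) * z
        + math.sqrt(1.0 - disease.dlco_r2) * noise)
    df["dlco_pct_pred"] = np.clip(dlco, *disease.dlco_range)

    truth = pd.DataFrame({
        "subject_id": df["subject_id"], "burden": burden,
        "sms_global": sms_global, "sms_apical": sms_apical,
        "sms_central": sms_central, "sms_basal": sms_basal,
        "dlco_pct_pred": df["dlco_pct_pred"],
    })
    return df.drop(columns=["_tlc_pred", "_v_pred_true"]), truth


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

@dataclass
class ModelTargets:
    """Derive the phantom's density targets by inverting a normative model."""

    model: NormativeModel
    gender: str
    height: float
    sms_global: float = 0.0
    sms_regional: Optional[Mapping[str, float]] = None


@dataclass
class PhantomSpec:
    """Geometry and density targets of a voxel phantom."""

    seed: int
    lung_volume_target: float = 5.5       # L
    pd15_target: float = 90.0             # g/L on the recalibrated scale
    density_spread: float = 15.0          # g/L SD of the voxel distribution
    regional_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"apical": 0.0, "central": 0.0, "basal": 0.0})
    inspiration_fraction: float = 1.0
    body_hu: float = 40.0
    air_hu: float = -990.0
    aorta_hu: float = 45.0
    trachea_hu: float = -995.0
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (3.2, 3.0, 3.0)
    sponge_exponent: float = -1.1
    sponge_reference: Optional[tuple[float, float]] = None   # (V_ref L, PD15_ref)
    model_targets: Optional[ModelTargets] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticSpecError("a seed is mandatory for reproducibility")
        if self.pd15_target <= 0:
            raise SyntheticSpecError("pd15_target must be positive")
        if not (0.3 < self.inspiration_fraction <= 1.2):
            raise SyntheticSpecError(
                f"inspiration fraction {self.inspiration_fraction} outside (0.3, 1.2]")


@dataclass
class PhantomTruth:
    """Everything downstream modules compute, emitted by construction."""

    lung_mask: np.ndarray
    trachea_mask: np.ndarray
    region_labels: np.ndarray
    v_ct_l: float
    region_volumes_l: dict
    pd15_gl: float
    regional_pd15_gl: dict
    references: ReferenceSamples
    spec: PhantomSpec


def _ellipsoid(zc, yc, xc, az, ay, ax, zz, yy, xx):
    return (((zz - zc) / az) ** 2 + ((yy - yc) / ay) ** 2
            + ((xx - xc) / ax) ** 2) <= 1.0


def _density_to_hu(rho: np.ndarray, air_hu: float, aorta_hu: float) -> np.ndarray:
    return air_hu + rho * (aorta_hu - air_hu) / BLOOD_DENSITY_GL


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build a thoracic phantom realizing the requested volume and PD15.

    The exterior is air, the body an elliptic cylinder of soft tissue, the
    lungs two ellipsoids whose joint voxel volume approximates the target,
    the trachea an air column entering from the superior border and the
    descending aorta a blood-density cylinder at the conventional
    left-posterior position.  Lung voxel densities are drawn around the
    target with the requested spread and shifted so the nearest-rank PD15
    matches the target per region; HU values are the inverse of the
    air/blood recalibration, so the analysis pipeline recovers the targets.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1, n2 = spec.grid_shape
    s0, s1, s2 = spec.spacing
    e0, e1, e2 = n0 * s0, n1 * s1, n2 * s2

    v_target_l = spec.lung_volume_target * spec.inspiration_fraction
    v_target_mm3 = v_target_l * 1e6
    # semi-axis aspect (craniocaudal : anteroposterior : left-right)
    kz, ky, kx = 1.9, 1.0, 0.9
    r = (v_target_mm3 / (2 * (4.0 / 3.0) * math.pi * kz * ky * kx)) ** (1.0 / 3.0)
    az, ay, ax = kz * r, ky * r, kx * r

    lung_top = 0.16 * e0
    gap = 14.0
    if lung_top + 2 * az > 0.95 * e0:
        raise SyntheticSpecError(
            f"lung target volume {v_target_l:.2f} L exceeds the craniocaudal "
            "grid capacity")
    body_ay, body_ax = ay + 16.0, 2 * ax + gap + 14.0
    if body_ay > 0.42 * e1 or body_ax > 0.46 * e2:
        raise SyntheticSpecError(
            f"lung target volume {v_target_l:.2f} L exceeds the in-plane "
            "grid capacity")

    zz = ((np.arange(n0) + 0.5) * s0)[:, None, None]
    yy = ((np.arange(n1) + 0.5) * s1)[None, :, None]
    xx = ((np.arange(n2) + 0.5) * s2)[None, None, :]

    def lungs_at(scale: float) -> np.ndarray:
        azs, ays, axs = az * scale, ay * scale, ax * scale
        cz, cy = lung_top + azs, e1 / 2.0
        off = axs + gap
        left = _ellipsoid(cz, cy, e2 / 2.0 + off, azs, ays, axs, zz, yy, xx)
        right = _ellipsoid(cz, cy, e2 / 2.0 - off, azs, ays, axs, zz, yy, xx)
        return left | right

    voxvol = s0 * s1 * s2
    lung = lungs_at(1.0)
    scale = (v_target_mm3 / (lung.sum() * voxvol)) ** (1.0 / 3.0)
    lung = lungs_at(scale)
    v_actual_l = lung.sum() * voxvol * 1e-6

    # squarish (superellipse) torso cross-section, plus a guaranteed soft-
    # tissue shell around the lungs so they never touch exterior air
    body = (((yy - e1 / 2.0) / body_ay) ** 4
            + ((xx - e2 / 2.0) / body_ax) ** 4 <= 1.0) \
        & (zz <= 0.97 * e0)
    body = np.broadcast_to(body, (n0, n1, n2)).copy()
    from scipy import ndimage as _ndi
    body |= _ndi.binary_dilation(lung, iterations=4)

    trachea = (((yy - 0.47 * e1) ** 2 + (xx - e2 / 2.0) ** 2) <= 5.5 ** 2) \
        & (zz <= lung_top - 6.0)
    trachea = np.broadcast_to(trachea, (n0, n1, n2)) & body
    from .recalibration import AUTO_AORTA_AP_FRACTION, AUTO_AORTA_LR_OFFSET_MM
    aorta = (((yy - AUTO_AORTA_AP_FRACTION * e1) ** 2
              + (xx - (e2 / 2.0 + AUTO_AORTA_LR_OFFSET_MM)) ** 2) <= 7.0 ** 2) \
        & (zz >= 0.25 * e0) & (zz <= 0.80 * e0)
    aorta = np.broadcast_to(aorta, (n0, n1, n2)) & body
    if (trachea & lung).any() or (aorta & lung).any():
        raise SyntheticSpecError(
            "phantom geometry infeasible: airway or aorta intersects the lungs")

    # partition the ground-truth mask for regional bookkeeping
    mask = LungMask(lung, trachea, spec.spacing)
    partition = partition_regions(mask)

    # density targets, per region, on the recalibrated scale
    if spec.model_targets is not None:
        mt = spec.model_targets
        model = mt.model
        tlc = predicted_tlc(mt.gender, mt.height)
        v_pred = model.predicted_v_ct(mt.gender, tlc, "global")
        base = math.e if model.log_base == "e" else 10.0
        law = model.law("global")
        rho_cor = base ** (law.alpha + law.beta * (math.log(v_pred)
                                                   / math.log(base))
                           + law.sigma * mt.sms_global)
        targets = {"global": rho_cor * (v_actual_l / v_pred) ** model.slope_s}
        region_volumes = partition.region_volumes
        for region in REGIONS:
            sms_r = (mt.sms_regional or {}).get(region, mt.sms_global)
            law_r = model.law(region) if region in model.regional_laws else law
            v_pred_r = (model.predicted_v_ct(mt.gender, tlc, region)
                        if region in model.translations else
                        REGION_FRACTIONS[region] * v_pred)
            rho_r = base ** (law_r.alpha
                             + law_r.beta * (math.log(v_pred_r) / math.log(base))
                             + law_r.sigma * sms_r)
            targets[region] = rho_r * (region_volumes[region] / v_pred_r) \
                ** model.slope_s
    else:
        v_ref, pd15_ref = spec.sponge_reference or (spec.lung_volume_target,
                                                    spec.pd15_target)
        pd15_eff = pd15_ref * (v_actual_l / v_ref) ** spec.sponge_exponent
        targets = {"global": pd15_eff}
        for region in REGIONS:
            targets[region] = pd15_eff + spec.regional_offsets.get(region, 0.0)

    # draw voxel densities and pin each region's nearest-rank PD15
    densities = np.zeros(int(lung.sum()))
    part_of_lung = partition.partition_index[lung]
    groups = {"apical": (1, 2, 3, 4), "central": (5, 6, 7),
              "basal": (8, 9, 10, 11, 12)}
    for region, parts in groups.items():
        sel = np.isin(part_of_lung, parts)
        eps = rng.normal(0.0, spec.density_spread, int(sel.sum()))
        densities[sel] = eps - percentile_density(eps, 0.15) + targets[region]

    hu = np.full(spec.grid_shape, spec.air_hu, dtype=np.float32)
    hu[body] = spec.body_hu
    hu[lung] = _density_to_hu(densities, spec.air_hu, spec.aorta_hu)
    hu[trachea] = spec.trachea_hu
    hu[aorta] = spec.aorta_hu

    volume = CTVolume(hu, spec.spacing,
                      source_id=f"phantom(seed={spec.seed})")
    refs = ReferenceSamples(
        air_mean=spec.air_hu, blood_mean=spec.aorta_hu,
        air_n=int((~body & ~lung).sum()), blood_n=int(aorta.sum()),
        sample_locations={"air": "ground truth", "aorta": "ground truth"},
    )
    regional_pd15 = {
        region: percentile_density(densities[
            partition.region_label[lung] == code])
        for region, code in (("apical", 1), ("central", 2), ("basal", 3))
    }
    truth = PhantomTruth(
        lung_mask=lung, trachea_mask=trachea,
        region_labels=partition.region_label,
        v_ct_l=v_actual_l, region_volumes_l=partition.region_volumes,
        pd15_gl=percentile_density(densities),
        regional_pd15_gl=regional_pd15,
        references=refs, spec=spec,
    )
    return volume, truth


def phantom_for_subject(model: NormativeModel, gender: str, height: float,
                        seed: int, sms_global: float = 0.0,
                        sms_regional: Optional[Mapping[str, float]] = None,
                        inspiration_fraction: float = 1.0,
                        **overrides) -> PhantomSpec:
    """A PhantomSpec whose densities realize given SMS values for a subject."""
    tlc = predicted_tlc(gender, height)
    v_pred = model.predicted_v_ct(gender, tlc, "global")
    return PhantomSpec(
        seed=seed,
        lung_volume_target=v_pred,
        inspiration_fraction=inspiration_fraction,
        model_targets=ModelTargets(model=model, gender=gender, height=height,
                                   sms_global=sms_global,
                                   sms_regional=sms_regional),
        **overrides,
    )
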