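"""Volumetric and tabular input/output with explicit unit conventions.

All attenuation values are Hounsfield units (HU), densities g/L, volumes
liters and heights meters everywhere inside the package; this module is the
only place where unit conversion happens.

Volumes are normalized on read to a fixed anatomical axis convention:

* axis 0 — craniocaudal, index 0 at the lung apex (superior);
* axis 1 — anteroposterior, index 0 anterior;
* axis 2 — left-right, index 0 at the anatomical left.

Regional partitioning and automatic reference-ROI placement rely on this
convention, so it is enforced here rather than downstream.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortRowError,
    FormatError,
    MetadataError,
    ModelVersionError,
    PlausibilityWarning,
    SchemaError,
)

#: axcodes (direction of increasing index) realising the internal convention
_CANONICAL_AXCODES = ("I", "P", "R")

_AXIS_ROLES = {0: "craniocaudal", 1: "anteroposterior", 2: "left-right"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A calibrated CT attenuation grid in the canonical axis order.

    Parameters
    ----------
    voxels
        3-D array of attenuation values in HU (float32).
    spacing
        Per-axis voxel size in mm, ordered like the axes.
    source_id
        Free-text provenance (file path, phantom seed, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""
    axis_roles: Mapping[int, str] = field(default_factory=lambda: dict(_AXIS_ROLES))
    superior_direction: str = "index 0 of axis 0"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MetadataError("CTVolume requires a 3-D voxel grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(
                f"all three voxel spacings must be strictly positive, got {self.spacing}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise MetadataError("voxel values must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view along each axis in mm."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))

    def write_nifti(self, path: os.PathLike | str) -> None:
        """Write the volume as NIfTI, preserving the canonical orientation."""
        import nibabel as nib

        s0, s1, s2 = self.spacing
        # canonical axes map to RAS world: axis0 -> -S, axis1 -> -A, axis2 -> +R
        affine = np.array(
            [
                [0.0, 0.0, s2, 0.0],
                [0.0, -s1, 0.0, 0.0],
                [-s0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        img = nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), affine)
        nib.save(img, os.fspath(path))


_GENDER_ALIASES = {
    "m": "male", "male": "male", "man": "male", "1": "male",
    "f": "female", "female": "female", "woman": "female", "2": "female",
}

_SMOKING_ALIASES = {
    "never": "never", "non": "never", "nonsmoker": "never", "0": "never",
    "ex": "ex", "former": "ex", "past": "ex",
    "current": "current", "smoker": "current", "yes": "current",
}


def normalize_gender(value: object) -> str:
    key = str(value).strip().lower()
    if key not in _GENDER_ALIASES:
        raise SchemaError(f"unrecognized gender value {value!r}")
    return _GENDER_ALIASES[key]


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics of one subject; heights in meters."""

    subject_id: str
    gender: str
    height: float
    age: Optional[float] = None
    smoking_status: Optional[str] = None
    dlco_pct_pred: Optional[float] = None
    fev1_pct_pred: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", normalize_gender(self.gender))
        if not (1.0 < float(self.height) < 2.5):
            raise SchemaError(
                f"subject {self.subject_id}: height {self.height} m outside (1.0, 2.5)"
            )
        if self.smoking_status is not None:
            key = str(self.smoking_status).strip().lower()
            if key not in _SMOKING_ALIASES:
                raise SchemaError(
                    f"subject {self.subject_id}: unrecognized smoking status "
                    f"{self.smoking_status!r}"
                )
            object.__setattr__(self, "smoking_status", _SMOKING_ALIASES[key])


# ---------------------------------------------------------------------------
# volume reading
# ---------------------------------------------------------------------------

def _canonicalize(data: np.ndarray, affine_ras: np.ndarray,
                  source_id: str) -> CTVolume:
    """Reorient an (i, j, k) array with a RAS affine to the internal axes."""
    import nibabel as nib
    from nibabel import orientations as nio

    ornt = nio.io_orientation(affine_ras)
    if np.any(np.isnan(ornt)):
        raise MetadataError(f"{source_id}: orientation matrix is degenerate")
    target = nio.axcodes2ornt(_CANONICAL_AXCODES)
    transform = nio.ornt_transform(ornt, target)
    data = nio.apply_orientation(data, transform)
    # spacing: column norms of the affine, permuted to the new axis order
    zooms = np.sqrt((affine_ras[:3, :3] ** 2).sum(axis=0))
    spacing = tuple(float(zooms[int(transform[a, 0])]) for a in range(3))
    return CTVolume(np.asarray(data, dtype=np.float32), spacing, source_id=source_id)


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"{path}: missing or non-positive voxel spacing")
    return _canonicalize(data, img.affine, str(path))


def _read_sitk(path: Path) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(os.fspath(path))
    if img.GetDimension() != 3:
        raise MetadataError(f"{path}: expected a 3-D volume")
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise MetadataError(f"{path}: missing or non-positive voxel spacing")
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    # SimpleITK works in LPS; nibabel conventions are RAS
    lps_affine = np.eye(4)
    lps_affine[:3, :3] = direction @ np.diag(spacing)
    lps_affine[:3, 3] = origin
    ras_affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps_affine
    # GetArrayFromImage returns (k, j, i); transpose to (i, j, k)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return _canonicalize(data, ras_affine, str(path))


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and not p.name.startswith(".")
    )
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(os.fspath(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{path}: no readable DICOM image files")

    first = slices[0]
    for attr in ("PixelSpacing", "ImagePositionPatient", "ImageOrientationPatient"):
        if getattr(first, attr, None) is None:
            raise MetadataError(f"{path}: DICOM series is missing {attr}")

    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda ds: float(np.dot(normal, ds.ImagePositionPatient)))

    positions = np.array([np.dot(normal, s.ImagePositionPatient) for s in slices])
    if len(slices) < 2:
        raise MetadataError(f"{path}: need at least two slices to infer slice spacing")
    steps = np.diff(positions)
    if np.ptp(steps) > 0.01 * abs(np.mean(steps)) + 1e-6:
        warnings.warn("non-uniform DICOM slice spacing; using the mean step",
                      PlausibilityWarning, stacklevel=3)
    dz = float(abs(np.mean(steps)))
    if dz <= 0:
        raise MetadataError(f"{path}: degenerate slice spacing")
    dr, dc = (float(v) for v in first.PixelSpacing)

    stack = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        stack.append(arr * slope + intercept)
    vol = np.stack(stack, axis=-1)  # (row, col, slice)

    # voxel index (r, c, s) -> LPS world; rows advance along col_dir
    lps_affine = np.eye(4)
    lps_affine[:3, 0] = col_dir * dr
    lps_affine[:3, 1] = row_dir * dc
    lps_affine[:3, 2] = normal * dz * np.sign(np.mean(steps))
    lps_affine[:3, 3] = np.asarray(first.ImagePositionPatient, dtype=float)
    ras_affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps_affine
    return _canonicalize(vol, ras_affine, str(path))


def read_volume(path: os.PathLike | str,
                format_hint: Optional[str] = None) -> CTVolume:
    """Read a CT volume from DICOM directory, NIfTI, MetaImage or NRRD.

    Returns a :class:`CTVolume` in HU (DICOM rescale slope/intercept applied)
    with spacing in mm, reoriented to the internal anatomical convention.

    Raises
    ------
    FormatError
        If the path does not exist or no reader accepts it.
    MetadataError
        If spacing or orientation metadata is missing.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{p}: no such file or directory")
    hint = (format_hint or "").lower()
    try:
        if p.is_dir() or hint == "dicom":
            return _read_dicom_dir(p)
        name = p.name.lower()
        if hint in ("nifti", "nii") or name.endswith((".nii", ".nii.gz")):
            return _read_nifti(p)
        if hint in ("metaimage", "mha", "mhd", "nrrd") or name.endswith(
                (".mha", ".mhd", ".nrrd")):
            return _read_sitk(p)
    except (MetadataError, FormatError):
        raise
    except Exception as exc:  # unreadable content
        raise FormatError(f"{p}: could not be read ({exc})") from exc
    raise FormatError(f"{p}: unrecognized volume format")


def write_label_map(labels: np.ndarray, spacing: Sequence[float],
                    path: os.PathLike | str) -> None:
    """Write an integer label map (region codes) as NIfTI."""
    vol = CTVolume(np.zeros_like(labels, dtype=np.float32), tuple(spacing))
    vol.voxels = labels.astype(np.float32)
    vol.write_nifti(path)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: default header aliases, lower-cased; the supplementary-table layout is not
#: fixed, so callers may extend or override this mapping.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "subject_id": ("subject_id", "subject", "id", "case", "patient"),
    "gender": ("gender", "sex"),
    "height": ("height", "height_m", "body_height", "length"),
    "age": ("age", "age_years"),
    "smoking_status": ("smoking_status", "smoking", "smoker"),
    "v_ct": ("v_ct", "volume", "ct_volume", "lung_volume", "volume_l", "ctvol"),
    "pd15": ("pd15", "perc15", "pd15_gl", "percentile_density", "density"),
    "dlco_pct_pred": ("dlco_pct_pred", "dlco", "dlco_pct", "dlco_pred"),
    "fev1_pct_pred": ("fev1_pct_pred", "fev1", "fev1_pct", "fev1_pred"),
    "v_ct_apical": ("v_ct_apical", "volume_apical"),
    "v_ct_central": ("v_ct_central", "volume_central"),
    "v_ct_basal": ("v_ct_basal", "volume_basal"),
    "pd15_apical": ("pd15_apical", "perc15_apical"),
    "pd15_central": ("pd15_central", "perc15_central"),
    "pd15_basal": ("pd15_basal", "perc15_basal"),
}

_MANDATORY = ("gender", "height", "v_ct", "pd15")
_NUMERIC = (
    "height", "age", "v_ct", "pd15", "dlco_pct_pred", "fev1_pct_pred",
    "v_ct_apical", "v_ct_central", "v_ct_basal",
    "pd15_apical", "pd15_central", "pd15_basal",
)


def read_cohort_frame(path: os.PathLike | str,
                      column_aliases: Optional[Mapping[str, Iterable[str]]] = None,
                      ) -> pd.DataFrame:
    """Read a cohort CSV/XLSX into a DataFrame with canonical column names.

    Mandatory columns (under any configured alias): gender, height, v_ct,
    pd15.  Heights looking like centimetres (> 3) are converted to meters
    with a warning; volumes outside 1–12 L and densities outside 0–300 g/L
    raise plausibility warnings but are kept.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"{p}: no such file")
    try:
        if p.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(p)
        else:
            raw = pd.read_csv(p)
    except Exception as exc:
        raise SchemaError(f"{p}: unreadable cohort table ({exc})") from exc
    if raw.empty or raw.shape[1] == 0:
        raise SchemaError(f"{p}: cohort table is empty")

    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        for canon, names in column_aliases.items():
            aliases[canon] = tuple(str(n).lower() for n in names)

    lower = {str(c).strip().lower(): c for c in raw.columns}
    mapping: dict[str, str] = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[canon] = lower[name]
                break
    missing = [c for c in _MANDATORY if c not in mapping]
    if missing:
        raise SchemaError(
            f"{p}: missing mandatory column(s) {missing}; expected one of "
            + "; ".join(f"{c}: {aliases[c]}" for c in missing)
        )

    out = pd.DataFrame(index=raw.index)
    for canon, col in mapping.items():
        out[canon] = raw[col]
    if "subject_id" not in out:
        out["subject_id"] = [f"subject-{i}" for i in range(len(out))]
    out["subject_id"] = out["subject_id"].astype(str)
    out["gender"] = [normalize_gender(g) for g in out["gender"]]
    if "smoking_status" in out:
        out["smoking_status"] = [
            None if pd.isna(s) else _SMOKING_ALIASES.get(str(s).strip().lower(), None)
            for s in out["smoking_status"]
        ]

    for canon in _NUMERIC:
        if canon not in out:
            continue
        parsed = pd.to_numeric(out[canon], errors="coerce")
        bad = parsed.isna() & out[canon].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortRowError(idx, f"unparseable value {out[canon].iloc[idx]!r} "
                                      f"in column {canon!r}")
        out[canon] = parsed.astype(float)

    cm_like = out["height"] > 3.0
    if cm_like.any():
        warnings.warn(f"{int(cm_like.sum())} height value(s) look like cm; "
                      "converted to meters", PlausibilityWarning, stacklevel=2)
        out.loc[cm_like, "height"] = out.loc[cm_like, "height"] / 100.0

    v = out["v_ct"]
    if ((v < 1.0) | (v > 12.0)).any():
        warnings.warn("CT-volume value(s) outside the plausible 1–12 L range",
                      PlausibilityWarning, stacklevel=2)
    d = out["pd15"]
    if ((d < 0.0) | (d > 300.0)).any():
        warnings.warn("PD15 value(s) outside the plausible 0–300 g/L range",
                      PlausibilityWarning, stacklevel=2)
    return out.reset_index(drop=True)


def read_cohort_table(path: os.PathLike | str,
                      column_aliases: Optional[Mapping[str, Iterable[str]]] = None,
                      ) -> list[tuple[SubjectRecord, float, float]]:
    """Read a cohort table as (SubjectRecord, CT-volume L, PD15 g/L) tuples."""
    df = read_cohort_frame(path, column_aliases)
    out = []
    for i, row in df.iterrows():
        rec = SubjectRecord(
            subject_id=row["subject_id"],
            gender=row["gender"],
            height=float(row["height"]),
            age=None if "age" not in row or pd.isna(row.get("age")) else float(row["age"]),
            smoking_status=row.get("smoking_status"),
            dlco_pct_pred=None if pd.isna(row.get("dlco_pct_pred", np.nan))
            else float(row["dlco_pct_pred"]),
            fev1_pct_pred=None if pd.isna(row.get("fev1_pct_pred", np.nan))
            else float(row["fev1_pct_pred"]),
        )
        out.append((rec, float(row["v_ct"]), float(row["pd15"])))
    return out


# ---------------------------------------------------------------------------
# normative model persistence
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = "1"


def write_model(model, path: os.PathLike | str) -> None:
    """Persist a fitted :class:`~lungsms.normative.NormativeModel` as JSON."""
    payload = model.to_dict()
    payload["schema_version"] = MODEL_SCHEMA_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_model(path: os.PathLike | str):
    """Read a persisted normative model; inverse of :func:`write_model`."""
    from .normative import NormativeModel

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.pop("schema_version", None)
    if version != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"{path}: unknown normative-model schema version {version!r} "
            f"(this build reads version {MODEL_SCHEMA_VERSION!r})"
        )
    return NormativeModel.from_dict(payload)
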