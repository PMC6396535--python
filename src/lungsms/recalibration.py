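"""Internal recalibration of HU values to physical density (g/L).

Scanner drift and inter-manufacturer differences shift the HU scale even
after routine air/water calibration.  The internal recalibration measures
two reference materials inside each scan — air outside the patient (above
the sternum) and blood in the descending aorta — and applies the affine map
fixed by anchoring air to 0 g/L and blood to 1050 g/L:

    rho_cal(v) = 1050 · (v − air_mean) / (blood_mean − air_mean)

With nominal references (air −1000 HU, blood +50 HU) this reduces to
rho = HU + 1000.  Values below measured air map to negative densities and
are deliberately retained: clipping would bias the 15th percentile in
near-air emphysematous lungs.

The map is invariant under any global affine distortion of the HU values
provided the references are re-sampled from the distorted scan — which is
precisely the drift-immunity the method exists for.

Automatic ROI placement is best-effort and aimed at the package's phantom
geometry (air: anterior exterior band; aorta: a small cylinder at the
conventional left-posterior paravertebral position).  Clinical use should
pass explicit ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import (
    DegenerateInputError,
    ReferenceInversionError,
    SamplingError,
)
from .io import CTVolume

#: density assigned to the blood reference after rescaling
BLOOD_DENSITY_GL = 1050.0

#: phantom-convention automatic aorta ROI: offsets are fractions of the
#: in-plane field of view; the x offset is mm left of the midline.
AUTO_AORTA_AP_FRACTION = 0.68
AUTO_AORTA_LR_OFFSET_MM = -10.0
AUTO_AORTA_RADIUS_MM = 4.0

#: automatic air ROI: anterior exterior band, central in the other two axes
AUTO_AIR_AP_FRACTION = 0.08


@dataclass(frozen=True)
class SphereROI:
    """Sphere in mm coordinates of the canonical axes (z, y, x from origin)."""
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class CylinderROI:
    """Axis-aligned (craniocaudal) cylinder in mm coordinates."""
    center_mm: tuple[float, float]      # (anteroposterior, left-right)
    radius_mm: float
    z_range_mm: tuple[float, float]


ROI = Union[SphereROI, CylinderROI, np.ndarray]


@dataclass
class ReferenceSamples:
    """Measured air and blood reference values for one scan."""

    air_mean: float
    blood_mean: float
    air_n: int
    blood_n: int
    sample_locations: dict = field(default_factory=dict)

    def validate(self, min_count: int = 100) -> "ReferenceSamples":
        if self.air_n < min_count or self.blood_n < min_count:
            raise SamplingError(
                f"reference ROI too small: air n={self.air_n}, "
                f"blood n={self.blood_n}, minimum {min_count}"
            )
        if not self.air_mean < self.blood_mean:
            raise ReferenceInversionError(
                f"air reference ({self.air_mean} HU) must be darker than the "
                f"blood reference ({self.blood_mean} HU)"
            )
        return self

    def to_dict(self) -> dict:
        return {
            "air_mean_hu": self.air_mean, "blood_mean_hu": self.blood_mean,
            "air_n": self.air_n, "blood_n": self.blood_n,
            "blood_density_gl": BLOOD_DENSITY_GL,
            "sample_locations": self.sample_locations,
        }


def roi_mask(volume: CTVolume, roi: ROI) -> np.ndarray:
    """Boolean voxel mask for a sphere/cylinder ROI (or a mask passthrough)."""
    if isinstance(roi, np.ndarray):
        if roi.shape != volume.shape:
            raise SamplingError("ROI mask shape does not match the volume")
        return roi.astype(bool)
    s0, s1, s2 = volume.spacing
    n0, n1, n2 = volume.shape
    z = (np.arange(n0) + 0.5) * s0
    y = (np.arange(n1) + 0.5) * s1
    x = (np.arange(n2) + 0.5) * s2
    if isinstance(roi, SphereROI):
        cz, cy, cx = roi.center_mm
        d2 = ((z - cz)[:, None, None] ** 2 + (y - cy)[None, :, None] ** 2
              + (x - cx)[None, None, :] ** 2)
        return d2 <= roi.radius_mm ** 2
    if isinstance(roi, CylinderROI):
        cy, cx = roi.center_mm
        in_plane = ((y - cy)[:, None] ** 2 + (x - cx)[None, :] ** 2
                    <= roi.radius_mm ** 2)
        in_z = (z >= roi.z_range_mm[0]) & (z <= roi.z_range_mm[1])
        return in_z[:, None, None] & in_plane[None, :, :]
    raise SamplingError(f"unsupported ROI type {type(roi)!r}")


def default_air_roi(volume: CTVolume) -> np.ndarray:
    """Anterior exterior band: air outside the body, above the sternum."""
    n0, n1, n2 = volume.shape
    mask = np.zeros(volume.shape, dtype=bool)
    mask[n0 // 3:2 * n0 // 3,
         1:max(2, int(n1 * AUTO_AIR_AP_FRACTION)),
         n2 // 3:2 * n2 // 3] = True
    return mask


def default_aorta_roi(volume: CTVolume) -> CylinderROI:
    """Conventional descending-aorta position used by the phantom geometry."""
    ext0, ext1, ext2 = volume.extent_mm()
    return CylinderROI(
        center_mm=(AUTO_AORTA_AP_FRACTION * ext1,
                   ext2 / 2.0 + AUTO_AORTA_LR_OFFSET_MM),
        radius_mm=AUTO_AORTA_RADIUS_MM,
        z_range_mm=(0.40 * ext0, 0.60 * ext0),
    )


def sample_references(volume: CTVolume,
                      air_roi: Optional[ROI] = None,
                      aorta_roi: Optional[ROI] = None,
                      min_count: int = 100) -> ReferenceSamples:
    """Measure the air and blood reference means for one scan.

    Explicit ROIs take precedence; with ``None`` the phantom-convention
    automatic placement is used.

    Raises
    ------
    SamplingError
        If an ROI is empty or holds fewer than ``min_count`` voxels.
    ReferenceInversionError
        If the air mean is not below the blood mean (swapped ROIs, ...).
    """
    air_desc, aorta_desc = "explicit", "explicit"
    if air_roi is None:
        air_roi, air_desc = default_air_roi(volume), "auto anterior exterior band"
    if aorta_roi is None:
        aorta_roi, aorta_desc = default_aorta_roi(volume), "auto descending aorta"

    air_mask = roi_mask(volume, air_roi)
    blood_mask = roi_mask(volume, aorta_roi)
    air_n, blood_n = int(air_mask.sum()), int(blood_mask.sum())
    if air_n == 0 or blood_n == 0:
        raise SamplingError("reference ROI selects no voxels")
    refs = ReferenceSamples(
        air_mean=float(volume.voxels[air_mask].mean()),
        blood_mean=float(volume.voxels[blood_mask].mean()),
        air_n=air_n, blood_n=blood_n,
        sample_locations={"air": air_desc, "aorta": aorta_desc},
    )
    return refs.validate(min_count=min_count)


def recalibrate(values, refs: ReferenceSamples) -> np.ndarray:
    """Map HU values to recalibrated density in g/L.

    Affine, anchored at ``air_mean → 0`` and ``blood_mean → 1050 g/L``.
    Output may be negative for values below measured air (retained).
    """
    span = refs.blood_mean - refs.air_mean
    if span == 0:
        raise DegenerateInputError("air and blood references coincide")
    v = np.asarray(values, dtype=float)
    return BLOOD_DENSITY_GL * (v - refs.air_mean) / span


def recalibrate_volume(volume: CTVolume, refs: ReferenceSamples) -> np.ndarray:
    """Recalibrate a whole voxel grid; returns a float64 density grid."""
    return recalibrate(volume.voxels, refs)
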