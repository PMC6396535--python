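"""Lung segmentation, CT-volume, percentile density and regional partitioning.

The lungs are detected by thresholding at −380 HU and connected-component
analysis: air connected to the lateral/inferior volume border is exterior,
the air column entering from the superior border within a central band is
the trachea/main bronchi, and the remaining low-attenuation components of
sufficient size are lung.  Lung volume ("CT-volume", V_CT) is the voxel
count times the voxel volume, in liters — an anatomic volume that includes
parenchyma and small vessels and excludes the trachea, hence distinct from
physiologic TLC.

PD15 is the 15th-percentile density: the density below which 15% of lung
voxels fall.  The percentile convention is nearest-rank on the sorted voxel
multiset (value at rank ``ceil(p·n)``), which is exact on small samples.

For regional analysis the lungs (both combined) are cut along the
craniocaudal axis into 12 slabs of equal lung volume; the superior-most and
inferior-most slabs are discarded (partial-volume artifacts) and the
remaining ten grouped superior→inferior as apical (3), central (3) and
basal (4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, PartitionError, SegmentationError
from .io import CTVolume

#: label-map codes for exported region masks
REGION_CODES = {"background": 0, "apical": 1, "central": 2, "basal": 3,
                "excluded": 4, "trachea": 5}

#: partition index (1..12) -> region name
_PARTITION_REGION = {1: "excluded", 12: "excluded",
                     **{k: "apical" for k in (2, 3, 4)},
                     **{k: "central" for k in (5, 6, 7)},
                     **{k: "basal" for k in (8, 9, 10, 11)}}

REGIONS = ("apical", "central", "basal")


@dataclass
class LungMask:
    """Boolean lung membership aligned with a :class:`CTVolume`."""

    membership: np.ndarray
    excluded_trachea: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        self.excluded_trachea = np.asarray(self.excluded_trachea, dtype=bool)
        if np.any(self.membership & self.excluded_trachea):
            raise SegmentationError("lung membership and trachea overlap")

    @property
    def v_ct(self) -> float:
        """Total lung volume in liters."""
        return compute_volume(self)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RegionPartition:
    """Equivolumetric craniocaudal partitioning of a lung mask."""

    partition_index: np.ndarray        # int8; 0 outside lungs, 1..12 inside
    region_label: np.ndarray           # uint8 REGION_CODES
    partition_volumes: np.ndarray      # 12 volumes in liters
    fractional_slices: bool            # False = whole-slice fallback used

    def region_mask(self, region: str) -> np.ndarray:
        return self.region_label == REGION_CODES[region]

    @property
    def region_volumes(self) -> dict[str, float]:
        out = {}
        for region in REGIONS:
            parts = [k for k, r in _PARTITION_REGION.items() if r == region]
            out[region] = float(sum(self.partition_volumes[k - 1] for k in parts))
        return out


def _touching_faces(labels: np.ndarray, n_labels: int) -> dict[int, set]:
    faces = {
        "superior": labels[0], "inferior": labels[-1],
        "anterior": labels[:, 0], "posterior": labels[:, -1],
        "left": labels[:, :, 0], "right": labels[:, :, -1],
    }
    touching: dict[int, set] = {}
    for name, face in faces.items():
        for lab in np.unique(face):
            if lab:
                touching.setdefault(int(lab), set()).add(name)
    return touching


def segment_lungs(volume: CTVolume, threshold: float = -380.0,
                  min_lung_volume_l: float = 0.05,
                  trachea_band_fraction: float = 0.5) -> LungMask:
    """Segment both lungs by thresholding, excluding exterior air and trachea.

    Parameters
    ----------
    volume
        A canonical-orientation CT volume in HU.
    threshold
        Voxels strictly below this HU value are lung candidates.  Must lie
        in (−1000, 0); the default −380 HU separates aerated lung from soft
        tissue.
    min_lung_volume_l
        Candidate components smaller than this are ignored (noise, bowel gas).
    trachea_band_fraction
        Fraction of each in-plane axis, centered, within which a component
        touching the superior border counts as trachea rather than exterior.

    Raises
    ------
    SegmentationError
        If no plausible lung component remains.
    """
    if not (-1000.0 < threshold < 0.0):
        raise SegmentationError(f"threshold {threshold} HU outside (-1000, 0)")
    vox = volume.voxels
    cand = vox < threshold
    if not cand.any():
        raise SegmentationError("no voxels below the segmentation threshold")

    labels, n_labels = ndimage.label(cand)
    touching = _touching_faces(labels, n_labels)

    n0, n1, n2 = vox.shape
    b1 = int(round(n1 * (1 - trachea_band_fraction) / 2))
    b2 = int(round(n2 * (1 - trachea_band_fraction) / 2))

    exterior, trachea = set(), set()
    for lab, faces in touching.items():
        lateral = faces & {"anterior", "posterior", "left", "right", "inferior"}
        if lateral:
            exterior.add(lab)
        elif "superior" in faces:
            top = labels[0]
            inside_band = np.zeros_like(top, dtype=bool)
            inside_band[b1:n1 - b1 or None, b2:n2 - b2 or None] = True
            if np.any((top == lab) & inside_band):
                trachea.add(lab)
            else:
                exterior.add(lab)

    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    min_voxels = min_lung_volume_l * 1e6 / volume.voxel_volume_mm3
    lung_labels = [
        lab for lab in range(1, n_labels + 1)
        if lab not in exterior and lab not in trachea and counts[lab] >= min_voxels
    ]
    if not lung_labels:
        raise SegmentationError(
            "no lung component found below the threshold inside the body"
        )
    membership = np.isin(labels, lung_labels)
    trachea_mask = np.isin(labels, sorted(trachea)) if trachea else \
        np.zeros_like(membership)
    return LungMask(membership, trachea_mask, volume.spacing)


def compute_volume(mask: LungMask) -> float:
    """Lung volume in liters: voxel count × per-voxel volume."""
    n = int(np.count_nonzero(mask.membership))
    if n == 0:
        raise DegenerateInputError("empty lung mask has no volume")
    return n * mask.voxel_volume_mm3 * 1e-6


def percentile_density(densities: Sequence[float] | np.ndarray,
                       p: float = 0.15) -> float:
    """Nearest-rank percentile of a density multiset (g/L).

    The value at sorted rank ``ceil(p·n)`` (1-based); for p = 0.15 this is
    PD15, the density at which 15% of voxels have a lower density.
    """
    values = np.asarray(densities, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("percentile of an empty multiset is undefined")
    if not (0.0 < p <= 1.0):
        raise DegenerateInputError(f"percentile fraction {p} outside (0, 1]")
    k = max(1, math.ceil(p * values.size))
    return float(np.partition(values, k - 1)[k - 1])


def partition_regions(mask: LungMask, fractional: bool = True) -> RegionPartition:
    """Split the lungs into 12 equivolumetric craniocaudal partitions.

    Cumulative lung volume superior→inferior is cut at multiples of V_CT/12.
    With ``fractional=True`` (default) slices straddling a boundary are split
    voxel-by-voxel so every partition holds the same volume to within one
    voxel; ``fractional=False`` assigns whole slices by their midpoint (the
    flag is recorded in the output).

    Partitions 1 and 12 are excluded; 2–4 apical, 5–7 central, 8–11 basal.
    """
    member = mask.membership
    counts = member.sum(axis=(1, 2)).astype(np.int64)
    occupied = np.flatnonzero(counts)
    if occupied.size < 12:
        raise PartitionError(
            f"only {occupied.size} occupied axial slices; need at least 12 "
            "for equivolumetric partitioning"
        )
    total = int(counts.sum())
    bounds = total * np.arange(1, 12) / 12.0

    partition_index = np.zeros(member.shape, dtype=np.int8)
    cum = 0
    for z in occupied:
        c = int(counts[z])
        if fractional:
            pos = cum + np.arange(c)
            parts = np.searchsorted(bounds, pos, side="right") + 1
        else:
            mid = cum + c / 2.0
            parts = np.full(c, np.searchsorted(bounds, mid, side="right") + 1,
                            dtype=np.int64)
        idx = np.flatnonzero(member[z].ravel())
        flat = partition_index[z].ravel()
        flat[idx] = parts.astype(np.int8)
        partition_index[z] = flat.reshape(member[z].shape)
        cum += c

    voxvol_l = mask.voxel_volume_mm3 * 1e-6
    part_counts = np.bincount(partition_index.ravel(), minlength=13)[1:13]
    partition_volumes = part_counts * voxvol_l

    region_label = np.zeros(member.shape, dtype=np.uint8)
    for part, region in _PARTITION_REGION.items():
        region_label[partition_index == part] = REGION_CODES[region]
    return RegionPartition(partition_index, region_label, partition_volumes,
                           fractional_slices=fractional)


def region_label_map(partition: RegionPartition,
                     mask: Optional[LungMask] = None) -> np.ndarray:
    """Exportable label map; adds the trachea code when a mask is given."""
    labels = partition.region_label.copy()
    if mask is not None:
        labels[mask.excluded_trachea] = REGION_CODES["trachea"]
    return labels
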