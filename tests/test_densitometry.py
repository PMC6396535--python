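"""Segmentation, volumetry, percentile density and regional partitioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungsms import errors
from lungsms.densitometry import (
    REGION_CODES,
    LungMask,
    compute_volume,
    partition_regions,
    percentile_density,
    region_label_map,
    segment_lungs,
)
from lungsms.io import CTVolume


class TestSegmentation:
    def test_phantom_lungs_recovered(self, normal_phantom):
        volume, truth = normal_phantom
        mask = segment_lungs(volume)
        inter = np.count_nonzero(mask.membership & truth.lung_mask)
        dice = 2 * inter / (mask.membership.sum() + truth.lung_mask.sum())
        assert dice >= 0.99
        # trachea identified and excluded from the lungs
        assert np.count_nonzero(mask.excluded_trachea & truth.trachea_mask) \
            == truth.trachea_mask.sum()
        assert not np.any(mask.membership & mask.excluded_trachea)

    def test_uniform_tissue_volume_fails(self):
        vol = CTVolume(np.full((24, 24, 24), 40.0, np.float32), (3, 3, 3))
        with pytest.raises(errors.SegmentationError):
            segment_lungs(vol)

    def test_lungs_above_threshold_fail(self):
        """Lung-like regions at −379 HU are not detected at the −380 cut."""
        vox = np.full((32, 32, 32), 40.0, np.float32)
        vox[10:22, 10:22, 10:22] = -379.0
        with pytest.raises(errors.SegmentationError):
            segment_lungs(CTVolume(vox, (3, 3, 3)))

    def test_threshold_out_of_range_rejected(self, normal_phantom):
        with pytest.raises(errors.SegmentationError):
            segment_lungs(normal_phantom[0], threshold=10.0)

    def test_lower_threshold_shrinks_mask(self, normal_phantom):
        volume, _ = normal_phantom
        wide = segment_lungs(volume, threshold=-380.0).membership
        narrow = segment_lungs(volume, threshold=-700.0).membership
        assert np.all(narrow <= wide)
        assert narrow.sum() <= wide.sum()


class TestVolume:
    def test_unit_cube_million_voxels_is_one_liter(self):
        mask = LungMask(np.ones((100, 100, 100), bool),
                        np.zeros((100, 100, 100), bool), (1.0, 1.0, 1.0))
        assert compute_volume(mask) == pytest.approx(1.0)

    def test_anisotropic_hand_arithmetic(self):
        member = np.zeros((100, 100, 100), bool)
        member.ravel()[:500_000] = True
        mask = LungMask(member, np.zeros_like(member), (5.0, 0.7, 0.7))
        assert compute_volume(mask) == pytest.approx(1.225)

    def test_phantom_volume_close_to_analytic_target(self, normal_phantom):
        volume, truth = normal_phantom
        target = truth.spec.lung_volume_target * truth.spec.inspiration_fraction
        assert abs(truth.v_ct_l - target) / target < 0.02
        mask = segment_lungs(volume)
        assert compute_volume(mask) == pytest.approx(truth.v_ct_l, rel=1e-3)

    def test_empty_mask_rejected(self):
        mask = LungMask(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5), bool),
                        (1, 1, 1))
        with pytest.raises(errors.DegenerateInputError):
            compute_volume(mask)


def _brute_nearest_rank(values, p):
    ordered = sorted(values)
    k = max(1, math.ceil(p * len(ordered)))
    return ordered[k - 1]


class TestPercentileDensity:
    def test_one_to_hundred_gives_fifteen(self):
        assert percentile_density(np.arange(1.0, 101.0), 0.15) == 15.0

    def test_constant_distribution(self):
        assert percentile_density([60.0] * 37) == 60.0

    def test_median_of_symmetric_values(self):
        vals = [10, 20, 30, 40, 50]
        assert percentile_density(vals, 0.5) == 30.0

    def test_empty_rejected(self):
        with pytest.raises(errors.DegenerateInputError):
            percentile_density([])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(values=st.lists(st.floats(-50, 400, allow_nan=False), min_size=1,
                           max_size=1000),
           p=st.sampled_from([0.05, 0.15, 0.5, 0.85, 1.0]))
    def test_matches_brute_force_sort_oracle(self, values, p):
        assert percentile_density(values, p) == _brute_nearest_rank(values, p)


def _uniform_mask(n_slices=120, per_slice=(6, 7)):
    member = np.zeros((n_slices, 10, 10), bool)
    member[:, 2:2 + per_slice[0], 2:2 + per_slice[1]] = True
    return LungMask(member, np.zeros_like(member), (2.0, 2.0, 2.0))


class TestPartitioning:
    def test_uniform_120_slices_split_into_tens(self):
        """Brute-force oracle: equal slices → each partition is 10 slices."""
        mask = _uniform_mask()
        part = partition_regions(mask)
        for z in range(120):
            labels = np.unique(part.partition_index[z][mask.membership[z]])
            assert labels.tolist() == [z // 10 + 1]
        # apical = slices 11–40, central = 41–70, basal = 71–110 (1-based)
        assert np.all(part.region_label[10:40][mask.membership[10:40]]
                      == REGION_CODES["apical"])
        assert np.all(part.region_label[40:70][mask.membership[40:70]]
                      == REGION_CODES["central"])
        assert np.all(part.region_label[70:110][mask.membership[70:110]]
                      == REGION_CODES["basal"])
        assert np.all(part.region_label[:10][mask.membership[:10]]
                      == REGION_CODES["excluded"])

    @pytest.mark.parametrize("n_slices,per_slice", [(120, (6, 7)), (37, (5, 5)),
                                                    (53, (3, 9))])
    def test_partitions_equivolumetric_within_one_voxel(self, n_slices, per_slice):
        mask = _uniform_mask(n_slices, per_slice)
        part = partition_regions(mask)
        v = compute_volume(mask)
        voxvol = mask.voxel_volume_mm3 * 1e-6
        assert np.all(np.abs(part.partition_volumes - v / 12) <= voxvol + 1e-12)

    def test_region_volumes_conserve_ten_twelfths(self, normal_phantom):
        volume, _ = normal_phantom
        mask = segment_lungs(volume)
        part = partition_regions(mask)
        v = compute_volume(mask)
        total = sum(part.region_volumes.values())
        assert total == pytest.approx(10 / 12 * v, abs=mask.voxel_volume_mm3 * 1e-6)

    def test_whole_slice_fallback_is_flagged_and_coarser(self):
        mask = _uniform_mask(37, (5, 5))
        frac = partition_regions(mask, fractional=True)
        whole = partition_regions(mask, fractional=False)
        assert frac.fractional_slices and not whole.fractional_slices
        assert np.ptp(frac.partition_volumes) <= np.ptp(whole.partition_volumes)

    def test_too_few_slices_rejected(self):
        mask = _uniform_mask(8)
        with pytest.raises(errors.PartitionError):
            partition_regions(mask)

    def test_label_map_includes_trachea_code(self, normal_phantom):
        volume, _ = normal_phantom
        mask = segment_lungs(volume)
        labels = region_label_map(partition_regions(mask), mask)
        assert set(np.unique(labels)) <= set(REGION_CODES.values())
        assert np.count_nonzero(labels == REGION_CODES["trachea"]) \
            == mask.excluded_trachea.sum()
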