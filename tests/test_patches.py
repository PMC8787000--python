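"""ROI partitioning, patch labeling, resampling, augmentation, splits."""
import numpy as np
import pytest

from tzs.boxes import Box
from tzs.patches import (
    AugmentParams,
    PatchSample,
    augment_patch,
    extract_resize_patch,
    label_patches,
    partition_roi,
    split_patients,
)
from tzs.preprocess import Volume3D


class TestPartition:
    @pytest.mark.parametrize("k,expected", [(3, 27), (4, 64), (5, 125)])
    def test_patch_counts(self, k, expected):
        grid = partition_roi(Box([0, 0, 0], [40, 40, 40]), k)
        assert grid.n_patches == expected
        assert len(grid.all_bounds()) == expected

    def test_remainder_goes_to_lowest_intervals(self):
        grid = partition_roi(Box([0, 0, 0], [10, 10, 10]), 3)
        lengths = np.diff(grid.edges[0])
        np.testing.assert_array_equal(lengths, [4, 3, 3])

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_tiling_exact(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            lo = rng.integers(0, 5, 3)
            hi = lo + rng.integers(3 * k, 8 * k, 3)
            roi = Box(lo.astype(float), hi.astype(float))
            grid = partition_roi(roi, k)
            total = sum(b.volume for b in grid.all_bounds())
            assert total == roi.volume
            for ax in range(3):  # contiguous, strictly increasing edges
                edges = grid.edges[ax]
                assert edges[0] == roi.lo[ax] and edges[-1] == roi.hi[ax]
                assert np.all(np.diff(edges) >= 1)
                assert np.ptp(np.diff(edges)) <= 1

    def test_too_small_roi(self):
        with pytest.raises(ValueError):
            partition_roi(Box([0, 0, 0], [2, 10, 10]), 3)
        with pytest.raises(ValueError):
            partition_roi(Box([0, 0, 0], [10, 10, 10]), 1)


class TestLabelPatches:
    roi = Box([0, 0, 0], [30, 30, 30])

    def test_single_center_single_positive(self):
        grid = partition_roi(self.roi, 5)
        box = Box([13, 13, 13], [17, 17, 17])  # center (15,15,15) -> patch (2,2,2)
        labels = label_patches(grid, [box])
        assert labels.sum() == 1
        assert labels[grid.flat_index(2, 2, 2)] == 1

    def test_two_boxes_two_patches(self):
        grid = partition_roi(self.roi, 3)
        labels = label_patches(grid, [Box([1, 1, 1], [3, 3, 3]), Box([25, 25, 25], [29, 29, 29])])
        assert labels.sum() == 2

    def test_two_boxes_sharing_a_patch(self):
        grid = partition_roi(self.roi, 3)
        labels = label_patches(grid, [Box([1, 1, 1], [3, 3, 3]), Box([4, 4, 4], [6, 6, 6])])
        assert labels.sum() == 1

    def test_boundary_center_goes_to_lower_patch(self):
        grid = partition_roi(self.roi, 3)
        # center exactly on the z=10 plane shared by patches (0,..) and (1,..)
        box = Box([8, 13, 13], [12, 17, 17])
        assert box.center[0] == 10.0
        labels = label_patches(grid, [box])
        assert labels.sum() == 1
        assert labels[grid.flat_index(0, 1, 1)] == 1

    def test_outside_center_clamped_with_warning(self):
        grid = partition_roi(self.roi, 3)
        with pytest.warns(UserWarning, match="clamped"):
            labels = label_patches(grid, [Box([28, 28, 28], [40, 40, 40])])
        assert labels.sum() == 1


class TestExtractResize:
    def test_constant_patch_stays_constant(self):
        vol = Volume3D(np.full((16, 16, 16), 3.7), (1, 1, 1))
        out = extract_resize_patch(vol, Box([2, 2, 2], [10, 12, 14]), 8)
        assert np.allclose(out, 3.7)
        normed = extract_resize_patch(vol, Box([2, 2, 2], [10, 12, 14]), 8, norm_range=(3.7, 3.7))
        assert np.allclose(normed, 0.0)

    def test_same_size_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.random((16, 16, 16))
        vol = Volume3D(data, (1, 1, 1))
        out = extract_resize_patch(vol, Box([4, 4, 4], [12, 12, 12]), 8)
        np.testing.assert_allclose(out, data[4:12, 4:12, 4:12], atol=1e-6)

    def test_linear_ramp_preserved(self):
        """Trilinear interpolation is exact on affine intensity fields."""
        z, y, x = np.meshgrid(np.arange(20), np.arange(24), np.arange(28), indexing="ij")
        ramp = 0.5 * z + 0.25 * y - 0.1 * x + 2.0
        vol = Volume3D(ramp, (1, 1, 1))
        out = extract_resize_patch(vol, Box([2, 3, 4], [15, 19, 23]), 16).astype(float)
        lin = [np.linspace(2, 14, 16), np.linspace(3, 18, 16), np.linspace(4, 22, 16)]
        zz, yy, xx = np.meshgrid(*lin, indexing="ij")
        expected = 0.5 * zz + 0.25 * yy - 0.1 * xx + 2.0
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_norm_range_clips_to_unit_interval(self):
        rng = np.random.default_rng(1)
        vol = Volume3D(rng.normal(0, 5, (16, 16, 16)), (1, 1, 1))
        out = extract_resize_patch(vol, Box([0, 0, 0], [16, 16, 16]), 8, norm_range=(-2.0, 2.0))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_degenerate_bounds_error(self):
        vol = Volume3D(np.zeros((16, 16, 16)), (1, 1, 1))
        with pytest.raises(ValueError):
            extract_resize_patch(vol, Box([2, 2, 2], [2.5, 10, 10]), 8)


class TestAugment:
    def _sample(self, vol, bounds, side=8):
        patch = extract_resize_patch(vol, bounds, side)
        return PatchSample(patch, 1, "s1", (0, 0, 0), bounds=bounds)

    def test_identity_augmentation(self):
        rng = np.random.default_rng(2)
        vol = Volume3D(rng.random((24, 24, 24)), (3, 3, 3))
        sample = self._sample(vol, Box([4, 4, 4], [16, 16, 16]))
        params = AugmentParams(max_translation_mm=0.0, zoom_range=(1.0, 1.0), seed=0)
        out = augment_patch(sample, params, vol)
        np.testing.assert_allclose(out.intensities, sample.intensities, atol=1e-6)
        assert out.label == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        vol = Volume3D(rng.random((24, 24, 24)), (3, 3, 3))
        sample = self._sample(vol, Box([6, 6, 6], [14, 14, 14]))
        params = AugmentParams(seed=42)
        a = augment_patch(sample, params, vol)
        b = augment_patch(sample, params, vol)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_translation_converts_mm_to_voxels(self):
        """A +30 mm shift on 3 mm spacing moves the window 10 voxels."""
        rng = np.random.default_rng(4)
        vol = Volume3D(rng.random((40, 40, 40)), (3.0, 3.0, 3.0))
        bounds = Box([10, 10, 10], [18, 18, 18])
        sample = self._sample(vol, bounds)
        params = AugmentParams(max_translation_mm=30.0, zoom_range=(1.0, 1.0), seed=9)
        out = augment_patch(sample, params, vol)
        # replay the draw: same stream as augment_patch's default rng
        replay = np.random.default_rng(9)
        shift_vox = replay.uniform(-30, 30, 3) / 3.0
        assert np.all(np.abs(shift_vox) <= 10.0)
        replay.uniform(0.8, 1.2)  # zoom draw consumed even for fixed range
        expected_window = Box(bounds.lo + shift_vox, bounds.hi + shift_vox)
        expected = extract_resize_patch(vol, expected_window, 8)
        np.testing.assert_allclose(out.intensities, expected, atol=1e-6)

    def test_negative_sample_rejected(self):
        vol = Volume3D(np.zeros((24, 24, 24)), (3, 3, 3))
        sample = PatchSample(np.zeros((8, 8, 8)), 0, "s1", (0, 0, 0),
                             bounds=Box([4, 4, 4], [12, 12, 12]))
        with pytest.raises(ValueError, match="positive"):
            augment_patch(sample, AugmentParams(), vol)


class TestSplitPatients:
    def test_reference_proportions(self):
        ids = [f"P{i:04d}" for i in range(1000)]
        train, val, test = split_patients(ids, (0.7, 0.2, 0.1), seed=0)
        assert (len(train), len(val), len(test)) == (700, 200, 100)

    def test_ten_patients(self):
        ids = [f"P{i}" for i in range(10)]
        train, val, test = split_patients(ids, seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_disjoint_and_exhaustive(self):
        ids = [f"P{i}" for i in range(57)]
        train, val, test = split_patients(ids, seed=2)
        assert train & val == set() and train & test == set() and val & test == set()
        assert train | val | test == set(ids)

    def test_duplicated_scan_ids_split_at_patient_level(self):
        ids = [f"P{i // 2}" for i in range(40)]  # 20 patients, 2 scans each
        train, val, test = split_patients(ids, seed=3)
        assert len(train) + len(val) + len(test) == 20

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b"], seed=0)

    def test_bad_proportions(self):
        with pytest.raises(ValueError):
            split_patients([f"P{i}" for i in range(10)], (0.5, 0.2, 0.1), seed=0)
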