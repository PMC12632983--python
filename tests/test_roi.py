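import numpy as np
import pytest

from wmref.images import LabelVolume, ProbabilityVolume, ROIMask
from wmref.phantom import default_merge_map
from wmref.roi import (
    DEFAULT_FBWM_SIZES_ML,
    FWHM_TO_SIGMA,
    cs_analogue_mask,
    gaussian_smooth,
    make_fbwm_series,
    make_wm_map,
    merge_gm_rois,
    threshold_to_volume,
)


def brute_force_gaussian(values, fwhm_mm, voxel_mm):
    """Direct truncated-kernel convolution with zero padding (independent
    of scipy.ndimage internals up to kernel construction)."""
    sigma = np.asarray(fwhm_mm, float) * FWHM_TO_SIGMA / np.asarray(voxel_mm, float)
    sigma = np.broadcast_to(sigma, (3,))
    out = np.asarray(values, dtype=float)
    for axis, s in enumerate(sigma):
        radius = int(4.0 * s + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        k /= k.sum()
        padded = np.zeros(
            tuple(n + 2 * radius if a == axis else n for a, n in enumerate(out.shape))
        )
        sl = tuple(
            slice(radius, radius + n) if a == axis else slice(None)
            for a, n in enumerate(out.shape)
        )
        padded[sl] = out
        res = np.zeros_like(out)
        for i, kv in enumerate(k):
            shifted = tuple(
                slice(i, i + n) if a == axis else slice(None)
                for a, n in enumerate(out.shape)
            )
            res += kv * padded[shifted]
        out = res
    return out


class TestGaussianSmooth:
    def test_matches_brute_force_on_random_volume(self, rng):
        vol = rng.random((20, 20, 20))
        ours = gaussian_smooth(vol, 5.0, 2.0)
        ref = brute_force_gaussian(vol, 5.0, 2.0)
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_anisotropic_voxels_use_per_axis_sigma(self, rng):
        vol = rng.random((16, 16, 16))
        ours = gaussian_smooth(vol, 6.0, (1.0, 2.0, 3.0))
        ref = brute_force_gaussian(vol, 6.0, (1.0, 2.0, 3.0))
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.random((8, 8, 8))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0, 2.0), vol)

    def test_mass_decreases_with_zero_padding_at_edges(self):
        vol = np.zeros((10, 10, 10))
        vol[0, 0, 0] = 1.0
        assert gaussian_smooth(vol, 8.0, 2.0).sum() < 1.0


class TestThresholdToVolume:
    def test_exact_voxel_target_hit_exactly(self):
        vals = np.linspace(1, 0, 4 * 4 * 4, endpoint=False).reshape(4, 4, 4)
        pm = ProbabilityVolume(values=vals, voxel_size_mm=10.0, fwhm_mm=0.0)
        roi = threshold_to_volume(pm, 5.0)  # 10mm voxels = 1 mL each
        assert roi.n_voxels == 5

    def test_rounds_to_nearest_voxel(self):
        vals = np.linspace(1, 0, 27, endpoint=False).reshape(3, 3, 3)
        pm = ProbabilityVolume(values=vals, voxel_size_mm=10.0, fwhm_mm=0.0)
        assert threshold_to_volume(pm, 2.4).n_voxels == 2
        assert threshold_to_volume(pm, 2.6).n_voxels == 3

    def test_selects_highest_values(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1], vals[0, 0, 0] = 0.9, 0.5
        pm = ProbabilityVolume(values=vals, voxel_size_mm=10.0, fwhm_mm=0.0)
        roi = threshold_to_volume(pm, 1.0)
        assert roi.mask[1, 1, 1] and roi.n_voxels == 1

    def test_unattainable_target_raises(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0] = 1.0
        pm = ProbabilityVolume(values=vals, voxel_size_mm=10.0, fwhm_mm=0.0)
        with pytest.raises(ValueError, match="unattainable"):
            threshold_to_volume(pm, 5.0)

    def test_tie_break_is_deterministic(self):
        vals = np.full((3, 3, 3), 0.5)
        pm = ProbabilityVolume(values=vals, voxel_size_mm=10.0, fwhm_mm=0.0)
        a = threshold_to_volume(pm, 4.0)
        b = threshold_to_volume(pm, 4.0)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.n_voxels == 4


class TestFbwmSeries:
    def test_all_sizes_within_one_voxel(self, labels, fbwm_series):
        vox = labels.voxel_volume_mL
        for roi, target in zip(fbwm_series, DEFAULT_FBWM_SIZES_ML):
            assert abs(roi.volume_mL - target) <= vox + 1e-9

    def test_series_is_nested(self, fbwm_series):
        for small, large in zip(fbwm_series, fbwm_series[1:]):
            assert np.all(large.mask[small.mask])

    def test_small_rois_lie_deeper_than_large(self, labels, wm_map, fbwm_series):
        # mean smoothed-WM value must decrease with ROI size
        means = [wm_map.values[r.mask].mean() for r in fbwm_series]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_rejects_non_increasing_sizes(self, labels):
        with pytest.raises(ValueError, match="increasing"):
            make_fbwm_series(labels, sizes_mL=(2.0, 1.0))

    def test_wm_map_bounded_unit_interval(self, wm_map):
        assert wm_map.values.min() >= 0.0 and wm_map.values.max() <= 1.0

    def test_unknown_wm_region_raises(self, labels):
        with pytest.raises(KeyError):
            make_wm_map(labels, "no_such_region")


class TestCsAnalogue:
    def test_target_volume_within_one_voxel(self, labels, cs_mask):
        assert abs(cs_mask.volume_mL - 2.0) <= labels.voxel_volume_mL + 1e-9

    def test_entirely_within_wm(self, labels, cs_mask):
        wm = labels.labels == labels.code("cerebral_wm")
        assert np.all(wm[cs_mask.mask])

    def test_contained_in_large_fbwm_rois(self, cs_mask, fbwm_series):
        # the deep 2 mL sphere sits inside the 45+ mL smoothed-map ROIs
        big = fbwm_series[-3]
        assert np.all(big.mask[cs_mask.mask])


class TestMergeGmRois:
    def test_default_merge_covers_both_hemispheres(self, labels):
        rois = merge_gm_rois(labels, default_merge_map())
        assert "frontal" in rois
        lh = labels.labels == labels.code("frontal_lh")
        rh = labels.labels == labels.code("frontal_rh")
        assert rois["frontal"].n_voxels == lh.sum() + rh.sum()

    def test_unknown_member_raises(self, labels):
        with pytest.raises(ValueError, match="unknown label"):
            merge_gm_rois(labels, {"bad": [9999]})

    def test_empty_member_list_raises(self, labels):
        with pytest.raises(ValueError, match="empty"):
            merge_gm_rois(labels, {"bad": []})
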