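import numpy as np
import pytest

from wmref.kinetics import FrameSchedule
from wmref.phantom import (
    GM_REGIONS,
    KineticTruth,
    PhantomSpec,
    build_phantom,
    region_tacs,
    simulate_dynamic_pet,
    simulate_input_function,
)
from wmref.roi import extract_tac


class TestBuildPhantom:
    def test_every_declared_region_present(self, labels):
        names = labels.region_names()
        assert "cerebral_wm" in names
        assert "substantia_nigra" in names
        assert "brainstem" in names
        for region in GM_REGIONS:
            if region in (
                "putamen", "caudate", "thalamus",
                "hippocampus", "amygdala", "entorhinal",
            ):
                assert region in names
            else:
                assert f"{region}_lh" in names and f"{region}_rh" in names

    def test_wm_volume_adequate_for_largest_roi(self, labels):
        assert labels.volume_mL("cerebral_wm") >= 250.0

    def test_deterministic(self, labels):
        again = build_phantom(PhantomSpec())
        np.testing.assert_array_equal(labels.labels, again.labels)

    def test_labels_disjoint_by_construction(self, labels):
        # label volume is single-valued; every nonzero code is in the map
        codes = set(np.unique(labels.labels)) - {0}
        assert codes == set(labels.code_map.values())

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            build_phantom(PhantomSpec(grid_shape=(10, 10, 10)))


class TestKineticTruth:
    def test_default_wm_vt_below_all_gm(self, truth):
        wm = truth.vt("cerebral_wm")
        for region in GM_REGIONS:
            assert truth.vt(region) > 2.0 * wm

    def test_scaled_multiplies_selected_K1(self, truth):
        scaled = truth.scaled({"substantia_nigra": 0.9})
        assert scaled.vt("substantia_nigra") == pytest.approx(
            0.9 * truth.vt("substantia_nigra")
        )
        assert scaled.vt("frontal") == truth.vt("frontal")

    def test_rejects_wm_vt_above_gm(self):
        with pytest.raises(ValueError):
            KineticTruth(rates={"cerebral_wm": (0.5, 0.01), "frontal": (0.2, 0.05)})


class TestInputFunctionSimulation:
    def test_peaks_at_requested_time_and_value(self):
        f = simulate_input_function(peak_time_min=1.5, peak_value=40.0)
        assert f(1.5) == pytest.approx(40.0, rel=1e-6)
        t = np.linspace(0, 60, 2000)
        assert np.max(f(t)) <= 40.0 + 1e-6

    def test_starts_at_zero(self):
        f = simulate_input_function()
        assert f(0.0) == pytest.approx(0.0)

    def test_monotone_decay_after_peak(self):
        f = simulate_input_function()
        t = np.linspace(1.5, 60, 500)
        assert np.all(np.diff(f(t)) <= 1e-9)

    def test_rejects_duplicate_decay_rates(self):
        with pytest.raises(ValueError):
            simulate_input_function(decay_rates=(0.3, 0.3, 0.01))


class TestRegionTacs:
    def test_hemisphere_labels_share_parent_kinetics(self, labels, truth, cp, schedule):
        tacs = region_tacs(labels, truth, cp, schedule)
        np.testing.assert_allclose(tacs["frontal_lh"], tacs["frontal_rh"])

    def test_vt_ordering_reflected_in_late_frames(self, labels, truth, cp, schedule):
        tacs = region_tacs(labels, truth, cp, schedule)
        assert tacs["frontal_lh"][-1] > tacs["cerebral_wm"][-1]

    def test_missing_truth_region_raises(self, labels, cp, schedule):
        partial = KineticTruth(
            rates={"cerebral_wm": (0.215, 0.05), "frontal": (0.48, 0.026)}
        )
        with pytest.raises(ValueError, match="missing from truth"):
            region_tacs(labels, partial, cp, schedule)


@pytest.fixture(scope="module")
def small():
    spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=3.5)
    return build_phantom(spec)


class TestSimulateDynamicPet:
    def test_noise_free_unsmoothed_equals_painted_tacs(self, small, truth, cp):
        schedule = FrameSchedule(start_min=[0, 30], end_min=[30, 60])
        img = simulate_dynamic_pet(small, truth, cp, schedule, psf_fwhm_mm=0.0)
        tacs = region_tacs(small, truth, cp, schedule)
        wm = small.mask("cerebral_wm")
        np.testing.assert_allclose(
            extract_tac(img, wm).values, tacs["cerebral_wm"], rtol=1e-6
        )

    def test_psf_pulls_wm_mean_toward_gm(self, small, truth, cp):
        schedule = FrameSchedule(start_min=[40.0], end_min=[60.0])
        img0 = simulate_dynamic_pet(small, truth, cp, schedule, psf_fwhm_mm=0.0)
        img6 = simulate_dynamic_pet(small, truth, cp, schedule, psf_fwhm_mm=6.0)
        wm = small.mask("cerebral_wm")
        # GM is hotter, so spill-in raises the WM mean at late times
        assert extract_tac(img6, wm).values[0] > extract_tac(img0, wm).values[0]

    def test_seed_reproducibility(self, small, truth, cp):
        schedule = FrameSchedule(start_min=[0.0], end_min=[60.0])
        a = simulate_dynamic_pet(small, truth, cp, schedule, noise_scale=20.0, seed=3)
        b = simulate_dynamic_pet(small, truth, cp, schedule, noise_scale=20.0, seed=3)
        c = simulate_dynamic_pet(small, truth, cp, schedule, noise_scale=20.0, seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_noise_sd_scales_with_sqrt_activity_over_duration(self, small, truth, cp):
        # long vs short frame at the same mean activity: SD ratio = sqrt(ratio)
        sched_long = FrameSchedule(start_min=[40.0], end_min=[60.0])
        sched_short = FrameSchedule(start_min=[40.0, 45.0], end_min=[45.0, 50.0])
        img_l = simulate_dynamic_pet(
            small, truth, cp, sched_long, psf_fwhm_mm=0.0, noise_scale=20.0, seed=5
        )
        img_s = simulate_dynamic_pet(
            small, truth, cp, sched_short, psf_fwhm_mm=0.0, noise_scale=20.0, seed=5
        )
        wm = small.mask("cerebral_wm").mask
        clean_l = simulate_dynamic_pet(small, truth, cp, sched_long, psf_fwhm_mm=0.0)
        clean_s = simulate_dynamic_pet(small, truth, cp, sched_short, psf_fwhm_mm=0.0)
        sd_l = np.std(img_l.data[wm, 0] - clean_l.data[wm, 0])
        sd_s = np.std(img_s.data[wm, 0] - clean_s.data[wm, 0])
        expected = np.sqrt(
            clean_s.data[wm, 0].mean() / 5.0
        ) / np.sqrt(clean_l.data[wm, 0].mean() / 20.0)
        assert sd_s / sd_l == pytest.approx(expected, rel=0.05)
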