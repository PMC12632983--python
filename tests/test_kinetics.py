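import numpy as np
import pytest

from wmref.kinetics import (
    FrameSchedule,
    InputFunction,
    OneTCMContext,
    TimeActivityCurve,
    compute_vt_table,
    fit_onetcm,
    onetcm_predict,
)


def numeric_frame_average(K1, k2, cp, schedule, dt=1e-3):
    """Independent oracle: dense trapezoidal convolution + frame averaging."""
    t = np.arange(0.0, schedule.total_min + dt, dt)
    c = cp(t)
    kernel = np.exp(-k2 * t)
    # C(t_i) = K1 * int_0^t_i e^{-k2 (t_i - s)} cp(s) ds via cumulative trapezoid
    conv = np.empty_like(t)
    conv[0] = 0.0
    # incremental trapezoidal update of the convolution integral
    decay = np.exp(-k2 * dt)
    acc = 0.0
    for i in range(1, t.size):
        acc = acc * decay + 0.5 * dt * (c[i] + c[i - 1] * decay)
        conv[i] = acc
    conv *= K1
    out = np.empty(schedule.n_frames)
    for j, (a, b) in enumerate(zip(schedule.start_min, schedule.end_min)):
        sel = (t >= a - 1e-12) & (t <= b + 1e-12)
        out[j] = np.trapezoid(conv[sel], t[sel]) / (b - a)
    return out


class TestFrameSchedule:
    def test_default_covers_60_minutes_in_21_frames(self, schedule):
        assert schedule.n_frames == 21
        assert schedule.total_min == pytest.approx(60.0)
        assert np.all(schedule.duration_min > 0)

    def test_rejects_overlapping_frames(self):
        with pytest.raises(ValueError, match="overlap"):
            FrameSchedule(start_min=[0.0, 1.0], end_min=[1.5, 2.0])

    def test_rejects_negative_start(self):
        with pytest.raises(ValueError):
            FrameSchedule(start_min=[-1.0, 1.0], end_min=[1.0, 2.0])

    def test_roundtrips_through_dataframe(self, schedule):
        back = FrameSchedule.from_frame(schedule.to_frame())
        np.testing.assert_allclose(back.start_min, schedule.start_min)
        np.testing.assert_allclose(back.end_min, schedule.end_min)


class TestInputFunction:
    def test_zero_before_first_sample(self):
        f = InputFunction(time_min=[1.0, 2.0, 3.0], cp=[10.0, 5.0, 2.5])
        assert f(0.5) == 0.0

    def test_linear_between_samples(self):
        f = InputFunction(time_min=[0.0, 2.0], cp=[0.0, 10.0])
        assert f(1.0) == pytest.approx(5.0)

    def test_exponential_tail_matches_last_two_samples(self):
        f = InputFunction(time_min=[0.0, 1.0, 2.0], cp=[10.0, 8.0, 4.0])
        # fitted rate: ln(8/4)/1; value one minute past the end halves again
        assert f(3.0) == pytest.approx(2.0)

    def test_flat_tail_when_not_decaying(self):
        f = InputFunction(time_min=[0.0, 1.0], cp=[3.0, 3.0])
        assert f(10.0) == pytest.approx(3.0)

    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            InputFunction(time_min=[0.0, 0.0], cp=[1.0, 1.0])

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            InputFunction(time_min=[0.0, 1.0], cp=[1.0, -1.0])


class TestClosedFormConvolution:
    def test_matches_numeric_oracle_at_typical_rates(self, cp, schedule):
        pred = onetcm_predict(0.3, 0.04, cp, schedule).values
        oracle = numeric_frame_average(0.3, 0.04, cp, schedule)
        np.testing.assert_allclose(pred, oracle, rtol=5e-4)

    def test_linear_in_K1(self, ctx):
        one = ctx.frame_values(1.0, 0.05)
        np.testing.assert_allclose(ctx.frame_values(0.37, 0.05), 0.37 * one)

    def test_zero_K1_gives_zero_curve(self, ctx):
        assert np.all(ctx.frame_values(0.0, 0.05) == 0)

    def test_memoized_values_are_identical(self, cp, schedule):
        ctx = OneTCMContext(cp, schedule)
        a = ctx.unit_frame_values(0.0731)
        b = ctx.unit_frame_values(0.0731)
        assert a is b

    def test_rejects_nonpositive_k2(self, ctx):
        with pytest.raises(ValueError):
            ctx.unit_frame_values(0.0)

    def test_handles_step_input_before_first_sample(self, schedule):
        # input starting at a nonzero time with a jump: cp = 0 before it
        f = InputFunction(time_min=[5.0, 6.0, 60.0], cp=[20.0, 18.0, 2.0])
        pred = onetcm_predict(0.2, 0.05, f, schedule).values
        # no tissue activity can precede plasma delivery
        early = schedule.end_min <= 5.0
        assert np.all(pred[early] == pytest.approx(0.0, abs=1e-9))
        assert pred[-1] > 0


class TestFit:
    def test_recovers_noise_free_parameters(self, cp, schedule, ctx):
        tac = TimeActivityCurve(schedule=schedule, values=ctx.frame_values(0.215, 0.05))
        fit = fit_onetcm(tac, cp, context=ctx)
        assert fit.converged
        assert fit.K1 == pytest.approx(0.215, rel=1e-5)
        assert fit.k2 == pytest.approx(0.05, rel=1e-5)
        assert fit.VT == pytest.approx(4.3, rel=1e-5)

    def test_vt_equals_K1_over_k2(self, cp, schedule, ctx, rng):
        vals = ctx.frame_values(0.4, 0.03)
        noisy = vals + rng.normal(scale=0.05 * vals.max(), size=vals.shape)
        fit = fit_onetcm(
            TimeActivityCurve(schedule=schedule, values=noisy), cp, context=ctx
        )
        assert fit.VT == pytest.approx(fit.K1 / fit.k2)

    def test_weight_scheme_changes_result_on_noisy_data(self, cp, schedule, ctx, rng):
        vals = ctx.frame_values(0.4, 0.03)
        noisy = vals + rng.normal(scale=0.08 * vals.max(), size=vals.shape)
        tac = TimeActivityCurve(schedule=schedule, values=noisy)
        f_dur = fit_onetcm(tac, cp, weights="duration", context=ctx)
        f_uni = fit_onetcm(tac, cp, weights="uniform", context=ctx)
        assert f_dur.VT != f_uni.VT

    def test_rejects_unknown_weight_scheme(self, cp, schedule, ctx):
        tac = TimeActivityCurve(schedule=schedule, values=ctx.frame_values(0.2, 0.05))
        with pytest.raises(ValueError, match="weight"):
            fit_onetcm(tac, cp, weights="banana", context=ctx)

    def test_flags_boundary_solutions_as_not_converged(self, cp, schedule, ctx):
        # pure noise around zero drives K1 to its lower bound
        rng = np.random.default_rng(7)
        tac = TimeActivityCurve(
            schedule=schedule, values=np.abs(rng.normal(scale=1e-6, size=21))
        )
        fit = fit_onetcm(tac, cp, context=ctx)
        assert not fit.converged

    def test_reports_finite_standard_errors_on_noisy_fit(self, cp, schedule, ctx, rng):
        vals = ctx.frame_values(0.3, 0.04)
        noisy = vals + rng.normal(scale=0.03 * vals.max(), size=vals.shape)
        fit = fit_onetcm(
            TimeActivityCurve(schedule=schedule, values=noisy), cp, context=ctx
        )
        assert fit.converged and np.isfinite(fit.K1_se) and np.isfinite(fit.k2_se)

    def test_deterministic(self, cp, schedule, ctx, rng):
        vals = ctx.frame_values(0.3, 0.04)
        noisy = vals + rng.normal(scale=0.05 * vals.max(), size=vals.shape)
        tac = TimeActivityCurve(schedule=schedule, values=noisy)
        a = fit_onetcm(tac, cp, context=ctx)
        b = fit_onetcm(tac, cp)
        assert (a.K1, a.k2) == (b.K1, b.k2)


class TestComputeVtTable:
    def test_long_format_one_row_per_scan_region(self, cp, schedule, ctx):
        tac = TimeActivityCurve(schedule=schedule, values=ctx.frame_values(0.2, 0.05))
        scans = {("s1", 1): {"a": tac, "b": tac}, ("s1", 2): {"a": tac}}
        table = compute_vt_table(scans, cp)
        assert len(table) == 3
        assert set(table.columns) >= {"subject", "scan", "region", "VT", "converged"}

    def test_duplicate_region_names_rejected(self, cp, schedule, ctx):
        tac = TimeActivityCurve(schedule=schedule, values=ctx.frame_values(0.2, 0.05))
        with pytest.raises(ValueError, match="duplicate"):
            compute_vt_table({("s1", 1): [("a", tac), ("a", tac)]}, cp)
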