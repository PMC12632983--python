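"""One-tissue-compartment (1TCM) kinetic modeling for dynamic PET.

The 1TCM describes tracer exchange between arterial plasma and a single
tissue compartment,

    dC(t)/dt = K1 * Cp(t) - k2 * C(t),

with influx rate ``K1`` (mL cm^-3 min^-1), efflux rate ``k2`` (min^-1) and
total volume of distribution ``VT = K1 / k2`` (mL/cm^3).  The model tissue
curve is the convolution of the plasma input with an exponential,

    C(t) = K1 * int_0^t exp(-k2 (t - s)) Cp(s) ds,

which this module evaluates in closed form for a piecewise-linear plasma
curve, including exact time-averages over acquisition frames (frames of
several minutes make midpoint sampling noticeably biased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "TimeActivityCurve",
    "KineticFit",
    "OneTCMContext",
    "onetcm_predict",
    "fit_onetcm",
    "compute_vt_table",
]

# Optimizer bounds and start point for the bounded nonlinear fit.
K1_BOUNDS = (1e-4, 5.0)
K2_BOUNDS = (1e-4, 2.0)
K1_START = 0.2
K2_START = 0.05


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing in minutes.

    Frames must be non-overlapping with strictly increasing start times.
    """

    start_min: np.ndarray
    end_min: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_min, dtype=float)
        end = np.asarray(self.end_min, dtype=float)
        object.__setattr__(self, "start_min", start)
        object.__setattr__(self, "end_min", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ValueError("frame start/end arrays must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(end <= start):
            raise ValueError("every frame must end after it starts")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if start[0] < 0:
            raise ValueError("schedule must not start before t=0")

    @property
    def n_frames(self) -> int:
        return self.start_min.size

    @property
    def duration_min(self) -> np.ndarray:
        return self.end_min - self.start_min

    @property
    def mid_min(self) -> np.ndarray:
        return 0.5 * (self.start_min + self.end_min)

    @property
    def total_min(self) -> float:
        return float(self.end_min[-1])

    @classmethod
    def default(cls) -> "FrameSchedule":
        """Default 60-min schedule: 6x0.5, 3x1, 2x2, 10x5 min (21 frames)."""
        durations = np.concatenate(
            [np.full(6, 0.5), np.full(3, 1.0), np.full(2, 2.0), np.full(10, 5.0)]
        )
        end = np.cumsum(durations)
        return cls(start_min=end - durations, end_min=end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_start_min": self.start_min, "frame_end_min": self.end_min}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrameSchedule":
        return cls(
            start_min=df["frame_start_min"].to_numpy(float),
            end_min=df["frame_end_min"].to_numpy(float),
        )


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma concentration curve (kBq/mL).

    Interpolation is piecewise linear between samples, zero before the first
    sample, and single-exponential extrapolation (fitted to the last two
    samples) after the last sample.
    """

    time_min: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "cp", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValueError("input function needs >= 2 (time, cp) samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("input-function times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("input-function times must start at >= 0")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("plasma concentrations must be finite and >= 0")

    def _tail_rate(self) -> float:
        """Decay rate of the exponential tail fitted to the last two samples."""
        t0, t1 = self.time_min[-2:]
        c0, c1 = self.cp[-2:]
        if c0 <= 0 or c1 <= 0 or c1 >= c0:
            return 0.0  # flat extrapolation for non-decaying tails
        return float(np.log(c0 / c1) / (t1 - t0))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.time_min, self.cp, left=0.0)
        t_last = self.time_min[-1]
        tail = t > t_last
        if np.any(tail):
            rate = self._tail_rate()
            out = np.where(tail, self.cp[-1] * np.exp(-rate * (t - t_last)), out)
        return out

    def sampled_grid(self, t_end: float, tail_step_min: float = 0.1):
        """Piecewise-linear breakpoints (times, values) covering [0, t_end].

        The exponential tail beyond the last sample is densified so the
        piecewise-linear closed-form convolution remains accurate there.
        """
        times = self.time_min[self.time_min <= t_end]
        extra = []
        if times.size == 0 or times[0] > 0:
            t0 = self.time_min[0]
            extra.append(0.0)
            if t0 > 0 and t0 <= t_end:
                # represent the jump at the first sample with a thin ramp
                extra.append(max(t0 - 1e-9, 0.0))
        t_last = self.time_min[-1]
        if t_end > t_last:
            n = int(np.ceil((t_end - t_last) / tail_step_min))
            extra.extend(np.linspace(t_last, t_end, n + 1)[1:])
        times = np.unique(np.concatenate([times, np.asarray(extra, dtype=float)]))
        return times, self(times)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-wise tissue activity concentration (kBq/cm^3)."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.schedule.n_frames,):
            raise ValueError("TAC length must match the frame schedule")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")


def _phi123(x: np.ndarray):
    """Stable evaluation of phi1=(1-e^-x)/x, phi2=(x-1+e^-x)/x^2,
    phi3=(x^2/2-x+1-e^-x)/x^3 with series fallback near 0."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-3
    xs = np.where(small, 1.0, x)  # avoid divide-by-zero in the exact branch
    em = -np.expm1(-xs)  # 1 - e^-x, accurate
    p1 = em / xs
    p2 = (xs - em) / xs**2
    p3 = (0.5 * xs**2 - xs + em) / xs**3
    if np.any(small):
        t = x[small]
        p1[small] = 1 - t / 2 + t**2 / 6 - t**3 / 24
        p2[small] = 0.5 - t / 6 + t**2 / 24 - t**3 / 120
        p3[small] = 1 / 6 - t / 24 + t**2 / 120 - t**3 / 720
    return p1, p2, p3


class OneTCMContext:
    """Precomputed convolution grid for repeated 1TCM evaluations.

    Merges the plasma-curve breakpoints with the frame boundaries so that the
    exponential (x) piecewise-linear convolution and its running integral are
    exact on every node, and frame time-averages are exact.
    """

    def __init__(self, cp: InputFunction, schedule: FrameSchedule):
        self.schedule = schedule
        grid_t, grid_c = cp.sampled_grid(schedule.total_min)
        bounds = np.unique(np.concatenate([schedule.start_min, schedule.end_min, [0.0]]))
        t = np.unique(np.concatenate([grid_t, bounds]))
        # interpolate cp onto merged nodes (linear within segments: exact)
        c = np.interp(t, grid_t, grid_c, left=0.0)
        self.t = t
        self.dt = np.diff(t)
        self.alpha = c[:-1]
        self.beta = np.diff(c) / self.dt
        self.i_start = np.searchsorted(t, schedule.start_min)
        self.i_end = np.searchsorted(t, schedule.end_min)
        self.frame_dur = schedule.duration_min
        self._cache: dict[float, np.ndarray] = {}

    def unit_frame_values(self, k2: float) -> np.ndarray:
        """Frame-averaged model curve for K1 = 1 at the given k2 (memoized)."""
        if k2 <= 0:
            raise ValueError("k2 must be > 0")
        cached = self._cache.get(k2)
        if cached is not None:
            return cached
        dt, alpha, beta = self.dt, self.alpha, self.beta
        x = k2 * dt
        p1, p2, p3 = _phi123(x)
        g = dt * (alpha * p1 + beta * dt * p2)
        # y_{i+1} = y_i * exp(-x_i) + g_i, solved by exponential rescaling
        expo = k2 * self.t
        if expo[-1] < 600.0:
            s = np.exp(-expo)
            q = np.concatenate([[0.0], np.cumsum(g / s[1:])])
            y = s * q
        else:  # overflow-safe fallback
            y = np.empty(self.t.size)
            y[0] = 0.0
            E = np.exp(-x)
            for i in range(x.size):
                y[i + 1] = y[i] * E[i] + g[i]
        # running integral Y(t) = int_0^t y
        h = y[:-1] * dt * p1 + alpha * dt**2 * p2 + beta * dt**3 * p3
        Y = np.concatenate([[0.0], np.cumsum(h)])
        out = (Y[self.i_end] - Y[self.i_start]) / self.frame_dur
        if len(self._cache) < 64:
            self._cache[k2] = out
        return out

    def frame_values(self, K1: float, k2: float) -> np.ndarray:
        if K1 < 0:
            raise ValueError("K1 must be >= 0")
        if K1 == 0:
            return np.zeros(self.schedule.n_frames)
        return K1 * self.unit_frame_values(k2)


def onetcm_predict(
    K1: float, k2: float, cp: InputFunction, schedule: FrameSchedule
) -> TimeActivityCurve:
    """Noise-free 1TCM tissue curve, frame-averaged over the schedule."""
    ctx = OneTCMContext(cp, schedule)
    return TimeActivityCurve(schedule=schedule, values=ctx.frame_values(K1, k2))


@dataclass(frozen=True)
class KineticFit:
    """Result of a weighted 1TCM fit.  VT = K1/k2 exactly."""

    K1: float
    k2: float
    VT: float
    wrss: float
    converged: bool
    K1_se: float = np.nan
    k2_se: float = np.nan
    n_frames: int = 0
    message: str = ""


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    if weights is None or (isinstance(weights, str) and weights == "duration"):
        return schedule.duration_min.copy()
    if isinstance(weights, str):
        if weights == "uniform":
            return np.ones(schedule.n_frames)
        raise ValueError(f"unknown weight scheme: {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per frame")
    return w


def fit_onetcm(
    tac: TimeActivityCurve,
    cp: InputFunction,
    weights="duration",
    context: OneTCMContext | None = None,
) -> KineticFit:
    """Fit (K1, k2) by weighted bounded nonlinear least squares.

    Deterministic: a coarse log-spaced scan over k2 (with K1 profiled linearly,
    since the model is linear in K1) seeds a bounded trust-region refinement.
    Default weights are frame durations (uniform variance per unit time).
    """
    schedule = tac.schedule
    if schedule.n_frames < 4:
        raise ValueError("1TCM fit requires at least 4 frames")
    ctx = context if context is not None else OneTCMContext(cp, schedule)
    w = _resolve_weights(weights, schedule)
    sw = np.sqrt(w)
    y = tac.values

    def profile(k2: float):
        f = ctx.unit_frame_values(k2)
        denom = np.sum(w * f * f)
        if denom <= 0:
            return 0.0, float(np.sum(w * y * y))
        K1 = float(np.sum(w * f * y) / denom)
        K1 = float(np.clip(K1, *K1_BOUNDS))
        r = y - K1 * f
        return K1, float(np.sum(w * r * r))

    # deterministic coarse scan over k2
    k2_grid = np.geomspace(K2_BOUNDS[0] * 5, K2_BOUNDS[1], 25)
    k2_grid = np.unique(np.append(k2_grid, K2_START))
    scans = [(profile(k2v), k2v) for k2v in k2_grid]
    (K1_0, _), k2_0 = min(scans, key=lambda s: s[0][1])

    def residuals(p):
        return sw * (p[0] * ctx.unit_frame_values(p[1]) - y)

    lo = (K1_BOUNDS[0], K2_BOUNDS[0])
    hi = (K1_BOUNDS[1], K2_BOUNDS[1])
    sol = least_squares(
        residuals,
        x0=[np.clip(K1_0, *K1_BOUNDS), np.clip(k2_0, *K2_BOUNDS)],
        bounds=(lo, hi),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
    )
    K1, k2 = float(sol.x[0]), float(sol.x[1])
    wrss = float(2.0 * sol.cost)
    at_bound = any(
        abs(v - b) < 1e-9 for v, bpair in zip(sol.x, (K1_BOUNDS, K2_BOUNDS)) for b in bpair
    )
    converged = bool(sol.success) and not at_bound

    K1_se = k2_se = np.nan
    dof = schedule.n_frames - 2
    if converged and dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (wrss / dof)
            K1_se, k2_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass

    return KineticFit(
        K1=K1,
        k2=k2,
        VT=K1 / k2,
        wrss=wrss,
        converged=converged,
        K1_se=K1_se,
        k2_se=k2_se,
        n_frames=schedule.n_frames,
        message=str(sol.message),
    )


def compute_vt_table(
    scan_tacs,
    cps,
    weights="duration",
) -> pd.DataFrame:
    """Batch 1TCM fits over scans and regions.

    Parameters
    ----------
    scan_tacs : mapping ``(subject, scan) -> {region: TimeActivityCurve}``
        or mapping ``(subject, scan) -> list of (region, TAC)`` pairs.
    cps : mapping ``(subject, scan) -> InputFunction`` or one InputFunction
        shared by every scan.

    Returns a long-format table with one row per (subject, scan, region);
    failed fits are kept with ``converged = False``, never dropped.
    """
    rows = []
    for key, tacs in scan_tacs.items():
        subject, scan = key
        cp = cps[key] if hasattr(cps, "__getitem__") and not isinstance(
            cps, InputFunction
        ) else cps
        if not isinstance(tacs, dict):
            names = [r for r, _ in tacs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate region names in scan {key}")
            tacs = dict(tacs)
        ctx = None
        for region, tac in tacs.items():
            if ctx is None or ctx.schedule is not tac.schedule:
                ctx = OneTCMContext(cp, tac.schedule)
            fit = fit_onetcm(tac, cp, weights=weights, context=ctx)
            rows.append(
                {
                    "subject": subject,
                    "scan": scan,
                    "region": region,
                    "K1": fit.K1,
                    "k2": fit.k2,
                    "VT": fit.VT,
                    "wrss": fit.wrss,
                    "converged": fit.converged,
                }
            )
            if not fit.converged:
                warnings.warn(
                    f"1TCM fit did not converge for {key} region {region!r}",
                    stacklevel=2,
                )
    return pd.DataFrame(rows)
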