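"""Synthetic test-retest and case-control cohorts.

Variability model (multiplicative, applied to K1 with k2 fixed so VT scales):

* between-subject: one independent lognormal factor per region per subject
  (regional tracer binding differs across people), CV = ``between_subject_cv``;
* within-subject: one global lognormal factor per scan shared by all regions
  (radiosynthesis / calibration / injection day effects), CV =
  ``within_subject_cv`` — this is the scan-level bias that DVR cancels;
* disease: PD subjects have VT reduced by ``pd_effect`` in substantia nigra,
  caudate and brainstem.

Randomness is organized as one master seed with named substreams keyed by
``(stream, group, subject, scan)`` counters, so enlarging a cohort never
perturbs the scans already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .images import DynamicImage, LabelVolume
from .kinetics import FrameSchedule, InputFunction, OneTCMContext, TimeActivityCurve, fit_onetcm
from .phantom import (
    KineticTruth,
    PD_REGIONS,
    region_tacs,
    simulate_dynamic_pet,
    simulate_input_function,
)
from .roi import ROIMask, extract_tac, gaussian_smooth

__all__ = [
    "CohortSpec",
    "cohort_meta",
    "scan_kinetic_truth",
    "scan_noise_rng",
    "iter_cohort_images",
    "ROILevelSimulator",
    "simulate_cohort_vt",
]

# substream tags for the counter-based seeding scheme
_STREAM_BETWEEN = 0
_STREAM_WITHIN = 1
_STREAM_NOISE = 2
_STREAM_DAYS = 3
_GROUP_CODE = {"HS": 0, "PD": 1}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort."""

    n_HS: int = 10
    n_PD: int = 0
    pd_effect: float = 0.10
    between_subject_cv: float = 0.01
    within_subject_cv: float = 0.055
    interscan_days: tuple = (7.0, 1028.0)
    same_day_fraction: float = 1.0 / 3.0
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_HS < 2:
            raise ValueError("n_HS must be >= 2")
        if self.n_PD < 0 or self.n_PD == 1:
            raise ValueError("n_PD must be 0 or >= 2")
        if not (0 <= self.pd_effect < 1):
            raise ValueError("pd_effect must be in [0, 1)")
        for name in ("between_subject_cv", "within_subject_cv", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.interscan_days
        if lo < 0 or hi < lo:
            raise ValueError("interscan_days bounds must satisfy 0 <= lo <= hi")
        if not (0 <= self.same_day_fraction <= 1):
            raise ValueError("same_day_fraction must be in [0, 1]")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")


def _stream(spec: CohortSpec, stream: int, group: str, subject: int, scan: int = 0):
    key = (stream, _GROUP_CODE[group], subject, scan)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=key)
    )


def scan_noise_rng(
    spec: CohortSpec, group: str, subject: int, scan: int
) -> np.random.Generator:
    """The voxel-noise RNG for one scan, as used by the cohort simulators.

    Exposed so replicate experiments can simulate single scans directly and
    still reproduce the exact per-scan noise streams of a full cohort run.
    """
    return _stream(spec, _STREAM_NOISE, group, subject, scan)


def _lognormal_factor(rng, cv: float, size=None):
    """Mean-1 lognormal multiplier(s) with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def cohort_meta(spec: CohortSpec) -> pd.DataFrame:
    """Scan-level metadata table: one row per (subject, scan).

    HS subjects each contribute a test-retest pair (the first
    ``round(same_day_fraction * n_HS)`` pairs are same-day, the rest
    longitudinal with a uniformly drawn interscan interval); PD subjects
    contribute a single scan.
    """
    rows = []
    n_same = int(round(spec.same_day_fraction * spec.n_HS))
    lo, hi = spec.interscan_days
    for s in range(spec.n_HS):
        same_day = s < n_same
        if same_day:
            days = 0.0
        else:
            days = float(_stream(spec, _STREAM_DAYS, "HS", s).uniform(lo, hi))
        for scan in (1, 2):
            rows.append(
                {
                    "subject": f"HS{s + 1:02d}",
                    "group": "HS",
                    "subject_index": s,
                    "scan": scan,
                    "pair_type": "same_day" if same_day else "longitudinal",
                    "interscan_days": days,
                }
            )
    for s in range(spec.n_PD):
        rows.append(
            {
                "subject": f"PD{s + 1:02d}",
                "group": "PD",
                "subject_index": s,
                "scan": 1,
                "pair_type": "single",
                "interscan_days": np.nan,
            }
        )
    return pd.DataFrame(rows)


def scan_kinetic_truth(
    truth: KineticTruth, spec: CohortSpec, group: str, subject: int, scan: int
) -> KineticTruth:
    """Ground-truth kinetics for one scan of one subject.

    Deterministic in (spec.seed, group, subject, scan): between-subject
    factors depend on the subject only, the within-subject factor on the scan.
    """
    regions = sorted(truth.rates)
    rng_b = _stream(spec, _STREAM_BETWEEN, group, subject)
    between = _lognormal_factor(rng_b, spec.between_subject_cv, size=len(regions))
    factors = dict(zip(regions, between))
    if group == "PD":
        for r in PD_REGIONS:
            if r in factors:
                factors[r] *= 1.0 - spec.pd_effect
    rng_w = _stream(spec, _STREAM_WITHIN, group, subject, scan)
    global_factor = float(_lognormal_factor(rng_w, spec.within_subject_cv))
    factors = {r: f * global_factor for r, f in factors.items()}
    return truth.scaled(factors)


def iter_cohort_images(
    labels: LabelVolume,
    truth: KineticTruth,
    spec: CohortSpec,
    cp: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
):
    """Yield ``(meta_row, DynamicImage)`` for every scan, one at a time.

    Images are generated lazily (a full cohort would not fit in memory).
    """
    schedule = schedule if schedule is not None else FrameSchedule.default()
    cp = cp if cp is not None else simulate_input_function(schedule=schedule)
    meta = cohort_meta(spec)
    for _, row in meta.iterrows():
        scan_truth = scan_kinetic_truth(
            truth, spec, row["group"], int(row["subject_index"]), int(row["scan"])
        )
        noise_seed = _stream(
            spec, _STREAM_NOISE, row["group"], int(row["subject_index"]), int(row["scan"])
        ).integers(0, 2**31 - 1)
        img = simulate_dynamic_pet(
            labels,
            scan_truth,
            cp,
            schedule,
            psf_fwhm_mm=spec.psf_fwhm_mm,
            noise_scale=spec.noise_scale,
            seed=int(noise_seed),
        )
        yield row, img


class ROILevelSimulator:
    """Fast scan simulation restricted to the voxels of a fixed ROI set.

    Precomputes, per region, the PSF-smoothed indicator values on the union
    of ROI voxels.  A simulated ROI TAC is then the ROI mean of the mixed
    region curves plus voxel noise drawn only on those voxels — statistically
    identical to extracting the same ROIs from a full image simulation
    (identical mixing weights; only the RNG consumption differs).
    """

    def __init__(
        self,
        labels: LabelVolume,
        rois: dict[str, ROIMask],
        psf_fwhm_mm: float,
    ):
        self.labels = labels
        self.psf_fwhm_mm = psf_fwhm_mm
        union = np.zeros(labels.labels.shape, dtype=bool)
        for m in rois.values():
            union |= m.mask
        self.union_flat = np.flatnonzero(union.ravel())
        self.roi_rows = {
            name: np.searchsorted(self.union_flat, np.flatnonzero(m.mask.ravel()))
            for name, m in rois.items()
        }
        present = labels.region_names()
        self.region_order = present
        weights = np.empty((self.union_flat.size, len(present)))
        for j, name in enumerate(present):
            ind = (labels.labels == labels.code_map[name]).astype(float)
            if psf_fwhm_mm > 0:
                ind = gaussian_smooth(ind, psf_fwhm_mm, labels.voxel_size_mm)
            weights[:, j] = ind.ravel()[self.union_flat]
        self.weights = weights

    def scan_tacs(
        self,
        scan_truth: KineticTruth,
        cp: InputFunction,
        schedule: FrameSchedule,
        noise_scale: float,
        rng: np.random.Generator,
    ) -> dict[str, TimeActivityCurve]:
        curves = region_tacs(self.labels, scan_truth, cp, schedule)
        region_mat = np.stack([curves[n] for n in self.region_order])
        voxel = self.weights @ region_mat  # (n_union, n_frames)
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(
                np.clip(voxel, 0.0, None) / schedule.duration_min
            )
            voxel = voxel + rng.standard_normal(voxel.shape) * sd
        return {
            name: TimeActivityCurve(
                schedule=schedule, values=voxel[rows].mean(axis=0)
            )
            for name, rows in self.roi_rows.items()
        }


def simulate_cohort_vt(
    labels: LabelVolume,
    truth: KineticTruth,
    spec: CohortSpec,
    rois: dict[str, ROIMask],
    cp: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    mode: str = "image",
    weights="duration",
    simulator: ROILevelSimulator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and fit every (scan, ROI) 1TCM.

    ``mode='image'`` runs the full voxel pipeline; ``mode='roi'`` uses
    :class:`ROILevelSimulator` (fast path for replicate experiments).  A
    prebuilt ``simulator`` for the same labels/rois/PSF may be passed to
    amortize its setup across many cohorts.

    Returns ``(vt_table, meta)``; the VT table has one row per
    (subject, scan, region) with fit diagnostics.
    """
    schedule = schedule if schedule is not None else FrameSchedule.default()
    cp = cp if cp is not None else simulate_input_function(schedule=schedule)
    ctx = OneTCMContext(cp, schedule)
    meta = cohort_meta(spec)
    rows = []

    def fit_rows(row, tacs):
        for name, tac in tacs.items():
            fit = fit_onetcm(tac, cp, weights=weights, context=ctx)
            rows.append(
                {
                    "subject": row["subject"],
                    "group": row["group"],
                    "scan": int(row["scan"]),
                    "region": name,
                    "K1": fit.K1,
                    "k2": fit.k2,
                    "VT": fit.VT,
                    "wrss": fit.wrss,
                    "converged": fit.converged,
                }
            )

    if mode == "image":
        for row, img in iter_cohort_images(labels, truth, spec, cp, schedule):
            fit_rows(row, {n: extract_tac(img, m) for n, m in rois.items()})
    elif mode == "roi":
        sim = simulator if simulator is not None else ROILevelSimulator(
            labels, rois, spec.psf_fwhm_mm
        )
        for _, row in meta.iterrows():
            scan_truth = scan_kinetic_truth(
                truth, spec, row["group"], int(row["subject_index"]), int(row["scan"])
            )
            rng = _stream(
                spec,
                _STREAM_NOISE,
                row["group"],
                int(row["subject_index"]),
                int(row["scan"]),
            )
            fit_rows(
                row, sim.scan_tacs(scan_truth, cp, schedule, spec.noise_scale, rng)
            )
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    return pd.DataFrame(rows), meta
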