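"""Reference-region selection, interval regression, group statistics, power.

The selection rule balances two failure modes of a WM reference region:
small ROIs are noisy (high %CoV, high DVR TRV SD), large ROIs are biased by
gray-matter spill-in.  A reference passes the bias criterion when its mean
VT differs from the small deep-WM standard by less than 10%; among passing
references the largest volume is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .quantify import percent_cov

__all__ = [
    "reference_bias_table",
    "select_reference",
    "interscan_regression",
    "RegressionResult",
    "group_compare",
    "GroupStats",
    "sample_size",
]

BIAS_CRITERION_PERCENT = 10.0


def first_scan_vt(vt_table: pd.DataFrame) -> pd.DataFrame:
    """Each subject's first available scan, converged fits only."""
    ok = vt_table[vt_table["converged"].astype(bool)]
    first = ok.groupby(["subject", "region"])["scan"].transform("min")
    return ok[ok["scan"] == first]


def reference_bias_table(
    vt_table: pd.DataFrame,
    references,
    standard_reference: str,
) -> pd.DataFrame:
    """Mean VT, %CoV and percent difference vs the standard, per reference.

    Statistics are over each subject's first scan.  The bias flag is
    strict: |percent difference| < 10 passes, exactly 10 fails.
    """
    first = first_scan_vt(vt_table)
    names = list(references)
    if standard_reference not in set(first["region"]):
        raise ValueError(f"standard reference {standard_reference!r} absent from VT table")
    std_mean = first.loc[first["region"] == standard_reference, "VT"].mean()
    rows = []
    for name in names:
        vals = first.loc[first["region"] == name, "VT"]
        if vals.empty:
            raise ValueError(f"reference {name!r} absent from VT table")
        mean = float(vals.mean())
        pct = 100.0 * (mean - std_mean) / std_mean
        rows.append(
            {
                "reference": name,
                "n": int(vals.size),
                "mean_VT": mean,
                "percent_cov": percent_cov(vals) if vals.size >= 2 else np.nan,
                "percent_difference": pct,
                "passes_bias_criterion": bool(abs(pct) < BIAS_CRITERION_PERCENT),
            }
        )
    return pd.DataFrame(rows)


def select_reference(
    bias_rows: pd.DataFrame,
    trv_sds: pd.DataFrame | None = None,
    volumes_mL: dict | None = None,
) -> tuple[str | None, pd.DataFrame]:
    """Largest-volume reference passing the bias criterion, plus a ranked
    report (bias, %CoV and, when given, DVR-TRV SD) so the trade-off is
    auditable.

    ``trv_sds`` (optional): columns reference, sd_trv.  ``volumes_mL``
    (optional) maps reference name -> volume; without it, table order is
    assumed smallest-to-largest.
    """
    report = bias_rows.copy()
    if volumes_mL is not None:
        report["volume_mL"] = report["reference"].map(volumes_mL)
        report = report.sort_values("volume_mL").reset_index(drop=True)
    if trv_sds is not None:
        report = report.merge(
            trv_sds.rename(columns={"sd_trv": "dvr_trv_sd"})[
                ["reference", "dvr_trv_sd"]
            ],
            on="reference",
            how="left",
        )
    passing = report[report["passes_bias_criterion"]]
    if passing.empty:
        report.attrs["selection_note"] = (
            "no reference passed the <10% VT-bias criterion"
        )
        return None, report
    selected = str(passing.iloc[-1]["reference"])
    report.attrs["selection_note"] = f"selected {selected}: largest reference with <10% bias"
    return selected, report


@dataclass(frozen=True)
class RegressionResult:
    """OLS of GM-averaged TRV on interscan interval."""

    slope: float  # % per day
    intercept: float  # %
    r_squared: float
    p_value: float  # two-tailed, slope != 0
    rss: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("R^2 out of [0, 1]")


def interscan_regression(trv_percent, interscan_days) -> RegressionResult:
    """Ordinary least squares of TRV (%) on interval (days)."""
    y = np.asarray(trv_percent, dtype=float)
    x = np.asarray(interscan_days, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("regression requires >= 3 (days, TRV) pairs")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(np.clip(model.rsquared, 0.0, 1.0)),
        p_value=float(model.pvalues[1]),
        rss=float(model.ssr),
        n=int(y.size),
    )


@dataclass(frozen=True)
class GroupStats:
    """Two-group comparison (group A is the control/reference group)."""

    region: str
    reference: str
    n_A: int
    n_B: int
    mean_A: float
    mean_B: float
    sd_A: float
    sd_B: float
    percent_sd_A: float
    percent_sd_B: float
    percent_difference: float  # 100*(mean_A - mean_B)/mean_A
    t: float
    p: float
    cohens_d: float
    degenerate: bool = False


def group_compare(
    values_A,
    values_B,
    region: str = "",
    reference: str = "",
    welch: bool = False,
) -> GroupStats:
    """Two-tailed unpaired t-test with pooled-SD Cohen's d.

    Default is the classical pooled-variance (Student) test; ``welch=True``
    switches the t-test to unequal variances (d stays pooled-SD by
    convention).  Percent difference is 100*(mean_A - mean_B)/mean_A with A
    the control group.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    pooled = np.sqrt(
        ((a.size - 1) * sd_a**2 + (b.size - 1) * sd_b**2) / (a.size + b.size - 2)
    )
    degenerate = pooled == 0
    if degenerate:
        d = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        t_stat, p = np.nan, np.nan
    else:
        d = (mean_a - mean_b) / pooled
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupStats(
        region=region,
        reference=reference,
        n_A=a.size,
        n_B=b.size,
        mean_A=mean_a,
        mean_B=mean_b,
        sd_A=sd_a,
        sd_B=sd_b,
        percent_sd_A=100.0 * sd_a / mean_a if mean_a != 0 else np.nan,
        percent_sd_B=100.0 * sd_b / mean_b if mean_b != 0 else np.nan,
        percent_difference=(
            100.0 * (mean_a - mean_b) / mean_a if mean_a != 0 else np.nan
        ),
        t=t_stat,
        p=p,
        cohens_d=float(d),
        degenerate=degenerate,
    )


def _power_two_sample(n: int, effect: float, alpha: float) -> float:
    df = 2 * n - 2
    nc = effect * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def _power_paired(n: int, effect: float, alpha: float) -> float:
    df = n - 1
    nc = effect * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size(
    sd_percent: float,
    delta_percent: float,
    alpha: float = 0.05,
    power: float = 0.80,
    design: str = "two-sample",
    n_max: int = 100000,
) -> int:
    """Smallest n (per group) reaching the target power for a two-sided
    t-test at effect size delta/sd, via the exact noncentral-t condition."""
    if sd_percent <= 0:
        raise ValueError("sd must be > 0")
    if delta_percent <= 0:
        raise ValueError("delta must be > 0")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    effect = delta_percent / sd_percent
    if design == "two-sample":
        power_fn = _power_two_sample
    elif design == "paired":
        power_fn = _power_paired
    else:
        raise ValueError("design must be 'two-sample' or 'paired'")
    for n in range(2, n_max + 1):
        if power_fn(n, effect, alpha) >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches the requested power")
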