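"""Outcome measures: DVR, test-retest variability (TRV), cohort summaries.

TRV is the signed percent difference of a test-retest pair relative to the
pair mean:

    TRV = (retest - test) / (test + retest) * 200%

DVR is the ratio of target-region VT to reference-region VT; it cancels any
scan-level multiplicative calibration factor, which is why its test-retest
variability isolates reference-region noise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_trv",
    "compute_dvr",
    "build_trv_table",
    "gm_average_trv",
    "summarize_trv",
    "percent_cov",
]


def compute_trv(test_value, retest_value):
    """Signed test-retest variability in percent; antisymmetric in its args."""
    test = np.asarray(test_value, dtype=float)
    retest = np.asarray(retest_value, dtype=float)
    denom = test + retest
    if np.any(denom == 0):
        raise ValueError("TRV undefined: test + retest = 0")
    out = (retest - test) / denom * 200.0
    return float(out) if out.ndim == 0 else out


def compute_dvr(
    vt_table: pd.DataFrame, reference_region: str, targets=None
) -> pd.DataFrame:
    """DVR = VT_target / VT_reference per scan.

    Scans whose reference fit failed (or has VT <= 0) are excluded with a
    warning; a failed target fit drops only that region.  The reference
    never appears as its own target.
    """
    ref = vt_table[vt_table["region"] == reference_region]
    if ref.empty:
        raise ValueError(f"reference region {reference_region!r} absent from VT table")
    keys = ["subject", "scan"]
    ok = ref["converged"].astype(bool) & (ref["VT"] > 0)
    if not ok.all():
        bad = ref.loc[~ok, keys].to_records(index=False).tolist()
        warnings.warn(
            f"excluding scans with unusable reference {reference_region!r}: {bad}",
            stacklevel=2,
        )
    ref = ref[ok]
    tgt = vt_table[vt_table["region"] != reference_region]
    if targets is not None:
        tgt = tgt[tgt["region"].isin(list(targets))]
    tgt = tgt[tgt["converged"].astype(bool) & (tgt["VT"] > 0)]
    merged = tgt.merge(
        ref[keys + ["VT"]].rename(columns={"VT": "VT_reference"}), on=keys
    )
    merged = merged.rename(columns={"VT": "VT_target"})
    merged["reference"] = reference_region
    merged["DVR"] = merged["VT_target"] / merged["VT_reference"]
    carry = [c for c in ("group", "pair_type", "interscan_days") if c in merged]
    return merged[keys + carry + ["region", "reference", "DVR", "VT_target", "VT_reference"]]


def build_trv_table(
    values: pd.DataFrame, meta: pd.DataFrame, value_col: str
) -> pd.DataFrame:
    """Pair scan 1 and scan 2 per (subject, region) into TRV records.

    ``values`` must have columns subject, scan, region and ``value_col``;
    ``meta`` provides pair_type and interscan_days per (subject, scan).
    Subjects without both scans contribute nothing.
    """
    cols = ["subject", "scan", "region", value_col]
    v = values[cols]
    test = v[v["scan"] == 1].drop(columns="scan")
    retest = v[v["scan"] == 2].drop(columns="scan")
    pairs = test.merge(
        retest, on=["subject", "region"], suffixes=("_test", "_retest")
    )
    if pairs.empty:
        return pd.DataFrame(
            columns=[
                "subject",
                "region",
                "measure",
                "test",
                "retest",
                "trv_percent",
                "pair_type",
                "interscan_days",
            ]
        )
    pairs = pairs.rename(
        columns={f"{value_col}_test": "test", f"{value_col}_retest": "retest"}
    )
    pairs["measure"] = value_col
    pairs["trv_percent"] = compute_trv(
        pairs["test"].to_numpy(), pairs["retest"].to_numpy()
    )
    info = meta[meta["scan"] == 1][["subject", "pair_type", "interscan_days"]]
    pairs = pairs.merge(info, on="subject", how="left")
    return pairs[
        [
            "subject",
            "region",
            "measure",
            "test",
            "retest",
            "trv_percent",
            "pair_type",
            "interscan_days",
        ]
    ]


def gm_average_trv(trv: pd.DataFrame, gm_regions) -> pd.DataFrame:
    """Per-subject mean TRV across the GM regions (within-subject first)."""
    sel = trv[trv["region"].isin(list(gm_regions))]
    out = (
        sel.groupby(["subject", "pair_type"], as_index=False)
        .agg(
            trv_percent=("trv_percent", "mean"),
            interscan_days=("interscan_days", "first"),
            n_regions=("region", "nunique"),
        )
    )
    return out


def summarize_trv(trv: pd.DataFrame, by=("region", "pair_type")) -> pd.DataFrame:
    """Mean +/- SD of TRV per grouping cell; cells with n < 2 are omitted
    with a warning (an SD needs at least two records)."""
    by = list(by)
    rows = []
    for key, g in trv.groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        if len(g) < 2:
            warnings.warn(
                f"omitting TRV summary cell {dict(zip(by, key))}: n={len(g)} < 2",
                stacklevel=2,
            )
            continue
        rows.append(
            dict(
                zip(by, key),
                n=len(g),
                mean_trv=float(g["trv_percent"].mean()),
                sd_trv=float(g["trv_percent"].std(ddof=1)),
            )
        )
    return pd.DataFrame(rows)


def percent_cov(values) -> float:
    """%CoV = 100 * sample SD (n-1) / mean; requires n >= 2 and mean != 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("%CoV requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("%CoV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)
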