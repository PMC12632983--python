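"""End-to-end run: simulate -> build ROIs -> fit -> quantify -> evaluate.

Given one :class:`~wmref.io.RunConfig`, this reproduces the full analysis
on a synthetic cohort and writes every stage table plus a JSON evaluation
report and a run manifest.  Identical config + seed gives byte-identical
numeric tables.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort_vt
from .evaluate import (
    group_compare,
    interscan_regression,
    reference_bias_table,
    select_reference,
)
from .images import LabelVolume
from .io import (
    RunConfig,
    RunManifest,
    save_input_function,
    save_labels,
    save_mask,
    save_schedule,
    save_table,
    validate_config,
)
from .kinetics import FrameSchedule
from .phantom import (
    GM_REGIONS,
    KineticTruth,
    PD_REGIONS,
    PhantomSpec,
    build_phantom,
    default_merge_map,
    simulate_input_function,
)
from .quantify import build_trv_table, compute_dvr, gm_average_trv, summarize_trv
from .roi import cs_analogue_mask, make_fbwm_series, merge_gm_rois

log = logging.getLogger("wmref")

__all__ = ["run_pipeline", "build_rois", "analyze_vt_table", "PipelineError"]


def build_rois(labels: LabelVolume, cfg: RunConfig):
    """FBWM reference series + CS analogue + the 12 merged GM ROIs."""
    series = make_fbwm_series(
        labels, "cerebral_wm", fwhm_mm=cfg.wm_fwhm_mm, sizes_mL=cfg.fbwm_sizes_mL
    )
    cs = cs_analogue_mask(labels, "cerebral_wm", target_mL=cfg.standard_reference_mL)
    gm = merge_gm_rois(labels, default_merge_map())
    extra = {}
    for name in ("substantia_nigra", "brainstem"):
        extra[name] = labels.mask(name)
    rois = {m.name: m for m in series}
    rois[cs.name] = cs
    rois.update(gm)
    rois.update(extra)
    references = [m.name for m in series] + [cs.name]
    volumes = {m.name: m.volume_mL for m in series}
    volumes[cs.name] = cs.volume_mL
    return rois, references, cs.name, volumes


def analyze_vt_table(
    vt: pd.DataFrame,
    meta: pd.DataFrame,
    references,
    standard: str,
    volumes_mL: dict,
    pd_regions=PD_REGIONS,
):
    """All downstream statistics from a fitted VT table.

    Returns a dict of DataFrames/objects: dvr, trv (VT and DVR), summaries,
    GM-averaged TRV, bias table, selection report, interval regressions and
    group statistics.
    """
    meta_cols = meta[["subject", "scan", "group", "pair_type", "interscan_days"]]
    vt = vt.merge(meta_cols, on=["subject", "scan"], how="left", suffixes=("", "_meta"))

    hs_meta = meta[meta["group"] == "HS"]
    hs_vt = vt[vt["group"] == "HS"]

    # DVR per reference, GM targets only
    dvr_frames = []
    for ref in references:
        dvr_frames.append(compute_dvr(vt, ref, targets=GM_REGIONS))
    dvr = pd.concat(dvr_frames, ignore_index=True)

    # TRV of VT per region (HS pairs)
    trv_vt = build_trv_table(hs_vt, hs_meta, "VT")

    # TRV of DVR and GM-averaged DVR TRV, per reference (HS pairs)
    trv_dvr_frames, gm_avg_frames = [], []
    hs_dvr = dvr[dvr["group"] == "HS"]
    for ref in references:
        sub = hs_dvr[hs_dvr["reference"] == ref]
        t = build_trv_table(sub, hs_meta, "DVR")
        t["reference"] = ref
        trv_dvr_frames.append(t)
        g = gm_average_trv(t, GM_REGIONS)
        g["reference"] = ref
        gm_avg_frames.append(g)
    trv_dvr = pd.concat(trv_dvr_frames, ignore_index=True)
    gm_avg = pd.concat(gm_avg_frames, ignore_index=True)

    trv_vt_summary = summarize_trv(trv_vt, by=("region", "pair_type"))
    trv_dvr_summary = summarize_trv(trv_dvr, by=("reference", "region", "pair_type"))
    gm_avg_summary = summarize_trv(gm_avg, by=("reference", "pair_type"))
    gm_avg_overall = summarize_trv(gm_avg, by=("reference",))

    bias = reference_bias_table(hs_vt, references, standard)
    bias["volume_mL"] = bias["reference"].map(volumes_mL)
    selected, selection_report = select_reference(
        bias, gm_avg_overall.rename(columns={"sd_trv": "sd_trv"}), volumes_mL
    )

    # interscan-interval regression on longitudinal GM-averaged DVR TRV
    regressions = {}
    for ref in references:
        pts = gm_avg[(gm_avg["reference"] == ref) & (gm_avg["pair_type"] == "longitudinal")]
        if len(pts) >= 3:
            regressions[ref] = interscan_regression(
                pts["trv_percent"], pts["interscan_days"]
            )

    # HS-vs-PD group comparison per (PD region x reference)
    group_rows = []
    if (vt["group"] == "PD").any():
        scan1 = dvr[dvr["scan"] == 1]
        for ref in references:
            for region in pd_regions:
                sub = scan1[(scan1["reference"] == ref) & (scan1["region"] == region)]
                a = sub.loc[sub["group"] == "HS", "DVR"]
                b = sub.loc[sub["group"] == "PD", "DVR"]
                if len(a) >= 2 and len(b) >= 2:
                    gs = group_compare(a, b, region=region, reference=ref)
                    group_rows.append(asdict(gs))
    group_stats = pd.DataFrame(group_rows)

    return {
        "vt": vt,
        "dvr": dvr,
        "trv_vt": trv_vt,
        "trv_dvr": trv_dvr,
        "gm_avg_trv": gm_avg,
        "trv_vt_summary": trv_vt_summary,
        "trv_dvr_summary": trv_dvr_summary,
        "gm_avg_summary": gm_avg_summary,
        "gm_avg_overall": gm_avg_overall,
        "bias": bias,
        "selected_reference": selected,
        "selection_report": selection_report,
        "regressions": regressions,
        "group_stats": group_stats,
    }


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it, a partial manifest was written."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run every stage and write outputs under ``cfg.out_dir``.

    On any stage failure, a partial manifest covering the outputs written
    so far is still saved and :class:`PipelineError` names the stage.
    """
    log.setLevel(cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.content_hash(), seed=cfg.seed, package_version=__version__
    )

    @contextmanager
    def stage(name):
        try:
            yield
        except Exception as exc:
            manifest.write(out / "manifest.json")
            raise PipelineError(name, exc) from exc

    with stage("config"):
        errors = validate_config(cfg)
        if errors:
            raise ValueError("; ".join(errors))
        cfg.to_yaml(out / "config.yaml")
        manifest.add(out / "config.yaml")

    with stage("simulate"):
        log.info(
            "stage 1/5 simulate: phantom grid %s, %.1f mm voxels",
            cfg.grid_shape, cfg.voxel_size_mm,
        )
        spec = PhantomSpec(grid_shape=tuple(cfg.grid_shape), voxel_size_mm=cfg.voxel_size_mm)
        labels = build_phantom(spec)
        truth = KineticTruth.default()
        schedule = FrameSchedule.default()
        cp = simulate_input_function(schedule=schedule)
        save_labels(labels, out / "labels.nii.gz")
        save_schedule(schedule, out / "schedule.tsv")
        save_input_function(cp, out / "input_function.tsv")
        for p in ("labels.nii.gz", "schedule.tsv", "input_function.tsv"):
            manifest.add(out / p)

    with stage("make-rois"):
        log.info(
            "stage 2/5 make-rois: WM map %.0f mm FWHM, %d reference sizes",
            cfg.wm_fwhm_mm, len(cfg.fbwm_sizes_mL),
        )
        rois, references, standard, volumes = build_rois(labels, cfg)
        for name in references:
            save_mask(rois[name], out / f"roi_{name}.nii.gz")
            manifest.add(out / f"roi_{name}.nii.gz")

    with stage("fit"):
        log.info(
            "stage 3/5 fit: cohort %d HS + %d PD, mode=%s, seed=%d",
            cfg.n_HS, cfg.n_PD, cfg.simulation_mode, cfg.seed,
        )
        cohort = CohortSpec(
            n_HS=cfg.n_HS,
            n_PD=cfg.n_PD,
            pd_effect=cfg.pd_effect,
            between_subject_cv=cfg.between_subject_cv,
            within_subject_cv=cfg.within_subject_cv,
            interscan_days=tuple(cfg.interscan_days),
            same_day_fraction=cfg.same_day_fraction,
            psf_fwhm_mm=cfg.psf_fwhm_mm,
            noise_scale=cfg.noise_scale,
            seed=cfg.seed,
        )
        vt, meta = simulate_cohort_vt(
            labels, truth, cohort, rois, cp, schedule,
            mode=cfg.simulation_mode, weights=cfg.fit_weights,
        )
        n_failed = int((~vt["converged"]).sum())
        log.info("fits: %d total, %d failed", len(vt), n_failed)
        save_table(meta, out / "cohort.tsv")
        save_table(vt, out / "vt.tsv")
        manifest.add(out / "cohort.tsv")
        manifest.add(out / "vt.tsv")

    with stage("quantify"):
        log.info("stage 4/5 quantify: DVR / TRV statistics")
        res = analyze_vt_table(vt, meta, references, standard, volumes)
        for key in (
            "dvr", "trv_vt", "trv_dvr", "gm_avg_trv", "trv_vt_summary",
            "trv_dvr_summary", "gm_avg_summary", "bias", "selection_report",
            "group_stats",
        ):
            df = res[key]
            if isinstance(df, pd.DataFrame) and not df.empty:
                save_table(df, out / f"{key}.tsv")
                manifest.add(out / f"{key}.tsv")

    with stage("evaluate"):
        log.info("stage 5/5 evaluate: report")
        report = {
            "seed": cfg.seed,
            "n_fits": len(vt),
            "n_failed_fits": n_failed,
            "selected_reference": res["selected_reference"],
            "selection_note": res["selection_report"].attrs.get("selection_note", ""),
            "bias": res["bias"].to_dict(orient="records"),
            "interscan_regression": {
                ref: asdict(r) for ref, r in res["regressions"].items()
            },
            "group_stats": res["group_stats"].to_dict(orient="records"),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        manifest.add(out / "report.json")

    manifest.write(out / "manifest.json")
    log.info("done: %s", out / "manifest.json")
    return manifest
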