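"""File formats: NIfTI-1 volumes, TSV tables, YAML config, JSON manifest.

Storage conventions: label volumes as int16, ROI masks as uint8, dynamic
images as float32; schedules and input functions as TSV with the column
names used throughout (frame_start_min/frame_end_min, time_min /
plasma_kBq_per_mL); all result tables as long-format TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .images import DynamicImage, LabelVolume, ROIMask, default_affine
from .kinetics import FrameSchedule, InputFunction

__all__ = [
    "save_labels",
    "load_labels",
    "save_mask",
    "load_mask",
    "save_dynamic",
    "load_dynamic",
    "save_schedule",
    "load_schedule",
    "save_input_function",
    "load_input_function",
    "save_table",
    "load_table",
    "RunConfig",
    "validate_config",
    "RunManifest",
]


def _voxel_size_from(img) -> float:
    zooms = img.header.get_zooms()[:3]
    return float(zooms[0])


def save_labels(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    img.header.set_zooms((labels.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"code_map": labels.code_map}, fh, indent=1)


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"label volume must be 3-D, got {img.ndim}-D: {path}")
    sidecar = Path(str(path) + ".json")
    code_map = {}
    if sidecar.exists():
        code_map = {
            k: int(v) for k, v in json.loads(sidecar.read_text())["code_map"].items()
        }
    else:
        code_map = {
            f"label_{c}": int(c) for c in np.unique(np.asanyarray(img.dataobj)) if c != 0
        }
    return LabelVolume(
        labels=np.asanyarray(img.dataobj).astype(np.int32),
        voxel_size_mm=_voxel_size_from(img),
        code_map=code_map,
        affine=img.affine,
    )


def save_mask(mask: ROIMask, path) -> None:
    aff = default_affine(mask.voxel_size_mm, mask.mask.shape)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), aff)
    img.header.set_zooms((mask.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_mask(path, name: str | None = None) -> ROIMask:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"mask must be 3-D: {path}")
    return ROIMask(
        mask=np.asanyarray(img.dataobj) > 0,
        name=name if name is not None else Path(path).stem,
        voxel_size_mm=_voxel_size_from(img),
    )


def save_dynamic(image: DynamicImage, path, schedule_path=None) -> None:
    aff = default_affine(image.voxel_size_mm, image.data.shape)
    img = nib.Nifti1Image(image.data.astype(np.float32), aff)
    img.header.set_zooms((image.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, str(path))
    if schedule_path is not None:
        save_schedule(image.schedule, schedule_path)


def load_dynamic(path, schedule: FrameSchedule | str | Path) -> DynamicImage:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"dynamic image must be 4-D: {path}")
    if not isinstance(schedule, FrameSchedule):
        schedule = load_schedule(schedule)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"frame axis ({data.shape[3]}) does not match schedule "
            f"({schedule.n_frames} frames): {path}"
        )
    return DynamicImage(
        data=data, schedule=schedule, voxel_size_mm=_voxel_size_from(img)
    )


def save_schedule(schedule: FrameSchedule, path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def load_schedule(path) -> FrameSchedule:
    return FrameSchedule.from_frame(pd.read_csv(path, sep="\t"))


def save_input_function(cp: InputFunction, path) -> None:
    pd.DataFrame({"time_min": cp.time_min, "plasma_kBq_per_mL": cp.cp}).to_csv(
        path, sep="\t", index=False
    )


def load_input_function(path) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    return InputFunction(
        time_min=df["time_min"].to_numpy(float),
        cp=df["plasma_kBq_per_mL"].to_numpy(float),
    )


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (one YAML document)."""

    seed: int = 0
    out_dir: str = "wmref_run"
    log_level: str = "INFO"
    # phantom
    grid_shape: tuple = (90, 90, 90)
    voxel_size_mm: float = 2.0
    # cohort
    n_HS: int = 10
    n_PD: int = 10
    pd_effect: float = 0.10
    between_subject_cv: float = 0.01
    within_subject_cv: float = 0.055
    interscan_days: tuple = (7.0, 1028.0)
    same_day_fraction: float = 1.0 / 3.0
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 12.0
    simulation_mode: str = "roi"  # "roi" or "image"
    # ROI builder
    wm_fwhm_mm: float = 10.0
    fbwm_sizes_mL: tuple = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 45.0, 100.0, 200.0)
    standard_reference_mL: float = 2.0
    # kinetics
    fit_weights: str = "duration"
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "interscan_days", "fbwm_sizes_mL"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        errors = validate_config(cfg)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "interscan_days", "fbwm_sizes_mL"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every block invariant; return all violations at once."""
    errors = []
    if cfg.n_HS < 2:
        errors.append("n_HS must be >= 2")
    if cfg.n_PD < 0 or cfg.n_PD == 1:
        errors.append("n_PD must be 0 or >= 2")
    if not (0 <= cfg.pd_effect < 1):
        errors.append("pd_effect must be in [0, 1)")
    for name in ("between_subject_cv", "within_subject_cv", "noise_scale"):
        if getattr(cfg, name) < 0:
            errors.append(f"{name} must be >= 0")
    if cfg.psf_fwhm_mm < 0:
        errors.append("psf_fwhm_mm must be >= 0")
    if cfg.wm_fwhm_mm <= 0:
        errors.append("wm_fwhm_mm must be > 0")
    if cfg.voxel_size_mm <= 0:
        errors.append("voxel_size_mm must be > 0")
    sizes = cfg.fbwm_sizes_mL
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        errors.append("fbwm_sizes_mL must be strictly increasing")
    if cfg.standard_reference_mL <= 0:
        errors.append("standard_reference_mL must be > 0")
    lo, hi = cfg.interscan_days
    if lo < 0 or hi < lo:
        errors.append("interscan_days bounds must satisfy 0 <= lo <= hi")
    if not (0 <= cfg.same_day_fraction <= 1):
        errors.append("same_day_fraction must be in [0, 1]")
    if cfg.simulation_mode not in ("roi", "image"):
        errors.append("simulation_mode must be 'roi' or 'image'")
    if cfg.fit_weights not in ("duration", "uniform"):
        errors.append("fit_weights must be 'duration' or 'uniform'")
    if cfg.seed < 0 or cfg.seed >= 2**31:
        errors.append("seed must be in [0, 2^31)")
    return errors


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def add(self, path) -> None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"manifest entry does not exist: {p}")
        self.outputs.append(str(p))

    def write(self, path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "outputs": self.outputs,
                    "timestamp": self.timestamp,
                },
                indent=1,
            )
        )
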