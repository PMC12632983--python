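"""Volume containers shared across the pipeline.

All volumes live on one voxel grid (no resampling inside the pipeline); world
coordinates are carried by a NIfTI affine built from the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import FrameSchedule

__all__ = ["LabelVolume", "ProbabilityVolume", "ROIMask", "DynamicImage", "default_affine"]


def default_affine(voxel_size_mm: float, shape) -> np.ndarray:
    """RAS affine with the grid center at the world origin."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_size_mm * (np.asarray(shape[:3], dtype=float) - 1) / 2.0
    return aff


@dataclass
class LabelVolume:
    """3-D integer parcellation with physical voxel size and name<->code map."""

    labels: np.ndarray
    voxel_size_mm: float
    code_map: dict  # region name -> integer code
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        present = set(np.unique(self.labels)) - {0}
        mapped = set(self.code_map.values())
        missing = present - mapped
        if missing:
            raise ValueError(f"labels present but absent from code_map: {sorted(missing)}")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm, self.labels.shape)

    @property
    def voxel_volume_mL(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3  # mm^3 -> mL (cm^3)

    def code(self, name: str) -> int:
        try:
            return self.code_map[name]
        except KeyError:
            raise KeyError(f"unknown region name: {name!r}") from None

    def mask(self, name: str) -> "ROIMask":
        m = self.labels == self.code(name)
        if not m.any():
            raise ValueError(f"empty region: {name}")
        return ROIMask(mask=m, name=name, voxel_size_mm=self.voxel_size_mm)

    def region_names(self):
        present = set(np.unique(self.labels))
        return [n for n, c in self.code_map.items() if c in present]

    def volume_mL(self, name: str) -> float:
        return float(np.count_nonzero(self.labels == self.code(name))) * self.voxel_volume_mL


@dataclass
class ProbabilityVolume:
    """Smoothed binary map with values in [0, 1] (e.g. the smoothed WM map)."""

    values: np.ndarray
    voxel_size_mm: float
    fwhm_mm: float = np.nan  # smoothing provenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("probability volume must be 3-D")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask on the source grid."""

    mask: np.ndarray
    name: str
    voxel_size_mm: float
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"empty ROI mask: {self.name}")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * (self.voxel_size_mm / 10.0) ** 3


@dataclass
class DynamicImage:
    """4-D dynamic PET volume (kBq/cm^3), voxel x frame."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis length {self.data.shape[3]} does not match "
                f"schedule length {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic image contains non-finite values")

    @property
    def shape(self):
        return self.data.shape
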