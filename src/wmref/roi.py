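"""Volume-targeted reference-ROI construction and TAC extraction.

The white-matter reference series is built by binarizing the cerebral-WM
label, smoothing with a Gaussian kernel (default 10 mm FWHM), and
thresholding the smoothed map so the retained volume is closest to each
target size.  Thresholding the same map at decreasing values yields a nested
family of ROIs: small ROIs sit in the deepest WM, large ones extend toward
gray matter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import DynamicImage, LabelVolume, ProbabilityVolume, ROIMask
from .kinetics import TimeActivityCurve

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_FBWM_SIZES_ML",
    "DEFAULT_WM_FWHM_MM",
    "make_wm_map",
    "threshold_to_volume",
    "make_fbwm_series",
    "merge_gm_rois",
    "extract_tac",
    "cs_analogue_mask",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548
DEFAULT_WM_FWHM_MM = 10.0
# target reference volumes (mL), as printed in the source study
DEFAULT_FBWM_SIZES_ML = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 45.0, 100.0, 200.0)


def gaussian_smooth(values: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Gaussian smoothing with per-axis sigma = FWHM/2.3548 in voxel units.

    Zero padding outside the grid (a map that falls to zero outside the head).
    Accepts scalar voxel size (isotropic) or a length-3 sequence.
    """
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    sigma_vox = fwhm * FWHM_TO_SIGMA / vox
    if np.all(sigma_vox == 0):
        return np.asarray(values, dtype=float).copy()
    return ndimage.gaussian_filter(
        np.asarray(values, dtype=float), sigma=sigma_vox, mode="constant", cval=0.0
    )


def make_wm_map(
    labels: LabelVolume, wm_code, fwhm_mm: float = DEFAULT_WM_FWHM_MM
) -> ProbabilityVolume:
    """Binarize the WM label and smooth it into a [0, 1] WM probability map.

    ``wm_code`` may be an integer label code or a region name.
    """
    if isinstance(wm_code, str):
        wm_code = labels.code(wm_code)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    binary = (labels.labels == wm_code).astype(float)
    if not binary.any():
        raise ValueError(f"wm_code {wm_code} not present in label volume")
    smoothed = gaussian_smooth(binary, fwhm_mm, labels.voxel_size_mm)
    np.clip(smoothed, 0.0, 1.0, out=smoothed)
    return ProbabilityVolume(
        values=smoothed, voxel_size_mm=labels.voxel_size_mm, fwhm_mm=fwhm_mm
    )


def threshold_to_volume(
    wm_map: ProbabilityVolume, target_mL: float, name: str | None = None
) -> ROIMask:
    """Threshold the smoothed map so the retained volume is closest to target.

    Voxels are ranked by map value (descending); ties are broken toward the
    higher threshold (smaller ROI) and then by lexicographic voxel index, so
    a target expressible in whole voxels is always hit within half a voxel
    when boundary values are distinct.
    """
    if target_mL <= 0:
        raise ValueError("target_mL must be > 0")
    vox_mL = (wm_map.voxel_size_mm / 10.0) ** 3
    values = wm_map.values.ravel()
    positive = values > 0
    n_pos = int(np.count_nonzero(positive))
    max_mL = n_pos * vox_mL
    if target_mL > max_mL:
        raise ValueError(
            f"target {target_mL} mL unattainable: positive support is only "
            f"{max_mL:.3f} mL"
        )
    n_target = max(1, int(round(target_mL / vox_mL)))
    # stable sort on -value keeps lexicographic voxel order within ties
    order = np.argsort(-values, kind="stable")[:n_target]
    threshold = float(values[order[-1]])
    mask = np.zeros(values.size, dtype=bool)
    mask[order] = True
    mask = mask.reshape(wm_map.values.shape)
    return ROIMask(
        mask=mask,
        name=name if name is not None else f"fbwm_{target_mL:g}mL",
        voxel_size_mm=wm_map.voxel_size_mm,
        threshold_used=threshold,
    )


def make_fbwm_series(
    labels: LabelVolume,
    wm_code="cerebral_wm",
    fwhm_mm: float = DEFAULT_WM_FWHM_MM,
    sizes_mL=DEFAULT_FBWM_SIZES_ML,
) -> list[ROIMask]:
    """Build the nested FBWM reference series from one smoothed WM map."""
    sizes = list(sizes_mL)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes_mL must be strictly increasing")
    wm_map = make_wm_map(labels, wm_code, fwhm_mm)
    return [threshold_to_volume(wm_map, s) for s in sizes]


def merge_gm_rois(labels: LabelVolume, merge_map: dict) -> dict[str, ROIMask]:
    """Union member label codes into named GM ROIs.

    ``merge_map`` maps ROI name -> list of label codes (or region names).
    """
    present = set(np.unique(labels.labels))
    out: dict[str, ROIMask] = {}
    for name, members in merge_map.items():
        if len(members) == 0:
            raise ValueError(f"empty merge for ROI {name!r}")
        codes = [labels.code(m) if isinstance(m, str) else int(m) for m in members]
        unknown = [c for c in codes if c not in present]
        if unknown:
            raise ValueError(f"unknown label code(s) {unknown} in merge for {name!r}")
        mask = np.isin(labels.labels, codes)
        out[name] = ROIMask(mask=mask, name=name, voxel_size_mm=labels.voxel_size_mm)
    return out


def extract_tac(image: DynamicImage, roi: ROIMask) -> TimeActivityCurve:
    """Unweighted in-mask mean per frame."""
    if image.data.shape[:3] != roi.mask.shape:
        raise ValueError("image and ROI grids do not match")
    values = image.data[roi.mask].mean(axis=0, dtype=np.float64)
    return TimeActivityCurve(schedule=image.schedule, values=np.asarray(values, float))


def cs_analogue_mask(
    labels: LabelVolume, wm_code="cerebral_wm", target_mL: float = 2.0
) -> ROIMask:
    """Small deep-WM sphere analogous to a centrum-semiovale reference.

    Seeds at the WM voxel farthest from any non-WM tissue (Euclidean distance
    transform) and grows a sphere of the target volume, restricted to WM.
    """
    if isinstance(wm_code, str):
        wm_code = labels.code(wm_code)
    wm = labels.labels == wm_code
    if not wm.any():
        raise ValueError("WM label absent from volume")
    dist = ndimage.distance_transform_edt(wm, sampling=labels.voxel_size_mm)
    seed = np.unravel_index(np.argmax(dist), wm.shape)
    vox_mL = labels.voxel_volume_mL
    n_target = max(1, int(round(target_mL / vox_mL)))
    grids = np.ogrid[[slice(0, s) for s in wm.shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, seed))
    d2 = np.where(wm, d2, np.inf)
    order = np.argsort(d2.ravel(), kind="stable")[:n_target]
    if not np.all(np.isfinite(d2.ravel()[order])):
        raise ValueError(f"WM too small for a {target_mL} mL sphere")
    mask = np.zeros(wm.size, dtype=bool)
    mask[order] = True
    return ROIMask(
        mask=mask.reshape(wm.shape),
        name=f"cs{target_mL:g}mL_analogue",
        voxel_size_mm=labels.voxel_size_mm,
    )
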