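"""Digital brain phantom and dynamic-PET forward simulation.

The phantom is a nested-ellipsoid desk-scale stand-in for a FreeSurfer
parcellation: a cortical GM shell, an outer cerebral-WM shell, a subcortical
GM shell (six structures), and a deep cerebral-WM core, plus a brainstem
cylinder and a substantia-nigra sphere.  The WM compartment is deliberately
split into a deep core and a thin outer shell: thresholding the smoothed WM
map then places small reference ROIs in deep, spill-free WM while forcing
large (>=100 mL) ROIs into thin WM close to cortex, reproducing the
size-dependent gray-matter spill-in bias seen in real scans.

The forward model is region-wise 1TCM kinetics, a Gaussian point-spread
function applied per frame, and independent Gaussian voxel noise with
variance proportional to local activity per unit frame duration (a
count-statistics proxy for decay-corrected PET data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import DynamicImage, LabelVolume
from .kinetics import FrameSchedule, InputFunction, OneTCMContext
from .roi import gaussian_smooth

__all__ = [
    "PhantomSpec",
    "KineticTruth",
    "DEFAULT_LABEL_CODES",
    "GM_REGIONS",
    "PD_REGIONS",
    "build_phantom",
    "default_merge_map",
    "simulate_input_function",
    "simulate_dynamic_pet",
]

# The 12 evaluated GM regions (cortical parcels are stored as two
# hemisphere codes each and merged back by ``default_merge_map``).
CORTICAL_REGIONS = (
    "frontal",
    "parietal",
    "occipital",
    "temporal",
    "anterior_cingulate",
    "posterior_cingulate",
)
SUBCORTICAL_REGIONS = (
    "putamen",
    "thalamus",
    "caudate",
    "hippocampus",
    "entorhinal",
    "amygdala",
)
GM_REGIONS = CORTICAL_REGIONS + SUBCORTICAL_REGIONS
# regions with reduced VT in the Parkinson cohort
PD_REGIONS = ("substantia_nigra", "caudate", "brainstem")

DEFAULT_LABEL_CODES: dict[str, int] = {
    "cerebral_wm": 2,
    **{f"{name}_lh": 10 + 2 * i for i, name in enumerate(CORTICAL_REGIONS)},
    **{f"{name}_rh": 11 + 2 * i for i, name in enumerate(CORTICAL_REGIONS)},
    **{name: 26 + i for i, name in enumerate(SUBCORTICAL_REGIONS)},
    "substantia_nigra": 36,
    "brainstem": 37,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the nested-ellipsoid phantom (all lengths in mm).

    Semi-axis triples are (x, y, z); the grid center is the world origin.
    """

    grid_shape: tuple = (90, 90, 90)
    voxel_size_mm: float = 2.0
    outer_semi_mm: tuple = (65.0, 60.0, 55.0)  # cortex outer boundary
    wm_shell_semi_mm: tuple = (58.0, 53.0, 48.0)  # cortex/WM interface
    subcortical_semi_mm: tuple = (51.0, 46.0, 41.0)  # WM-shell/deep-GM interface
    core_semi_mm: tuple = (26.0, 24.0, 22.0)  # deep WM core
    brainstem_radius_mm: float = 9.0
    brainstem_center_xy_mm: tuple = (0.0, -8.0)
    brainstem_z_mm: tuple = (-70.0, -45.0)
    sn_center_mm: tuple = (0.0, -8.0, -48.0)
    sn_radius_mm: float = 10.0
    label_codes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 8 voxels")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        for outer, inner, what in (
            (self.outer_semi_mm, self.wm_shell_semi_mm, "cortex shell"),
            (self.wm_shell_semi_mm, self.subcortical_semi_mm, "outer WM shell"),
            (self.subcortical_semi_mm, self.core_semi_mm, "subcortical shell"),
        ):
            if any(o <= i for o, i in zip(outer, inner)):
                raise ValueError(f"nested ellipsoids collapse: {what}")


def _world_coords(spec: PhantomSpec):
    """Open world-coordinate grids (mm), origin at the grid center."""
    return np.ogrid[
        tuple(slice(0, n) for n in spec.grid_shape)
    ], spec.voxel_size_mm


def _coords_mm(spec: PhantomSpec):
    grids, vox = _world_coords(spec)
    return [
        (g - (n - 1) / 2.0) * vox for g, n in zip(grids, spec.grid_shape)
    ]


def _in_ellipsoid(x, y, z, semi):
    a, b, c = semi
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Deterministic label volume from a phantom specification.

    Raises a specification error naming the offending region if any named
    region voxelizes to the empty set, or if the WM compartment is smaller
    than 250 mL (a 200 mL reference series must be constructible).
    """
    spec = spec if spec is not None else PhantomSpec()
    x, y, z = _coords_mm(spec)
    codes = spec.label_codes

    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    outer = _in_ellipsoid(x, y, z, spec.outer_semi_mm)
    wm_outer = _in_ellipsoid(x, y, z, spec.wm_shell_semi_mm)
    sub_outer = _in_ellipsoid(x, y, z, spec.subcortical_semi_mm)
    core = _in_ellipsoid(x, y, z, spec.core_semi_mm)

    # cortical shell, partitioned into 6 parcels x 2 hemispheres
    cortex = outer & ~wm_outer
    xb, yb, zb = np.broadcast_arrays(x, y, z)
    medial = np.abs(xb) <= 10.0
    parcel = np.full(spec.grid_shape, "", dtype=object)
    sel = cortex & medial & (zb >= 20.0)
    parcel[sel & (yb >= 0)] = "anterior_cingulate"
    parcel[sel & (yb < 0)] = "posterior_cingulate"
    rest = cortex & (parcel == "")
    parcel[rest & (yb >= 18.0)] = "frontal"
    rest = cortex & (parcel == "")
    parcel[rest & (yb <= -22.0)] = "occipital"
    rest = cortex & (parcel == "")
    parcel[rest & (zb >= 0.0)] = "parietal"
    rest = cortex & (parcel == "")
    parcel[rest] = "temporal"
    for name in CORTICAL_REGIONS:
        sel = parcel == name
        labels[sel & (xb < 0)] = codes[f"{name}_lh"]
        labels[sel & (xb >= 0)] = codes[f"{name}_rh"]

    # outer WM shell and deep WM core share one label
    labels[wm_outer & ~sub_outer] = codes["cerebral_wm"]
    labels[core] = codes["cerebral_wm"]

    # subcortical GM shell, partitioned by azimuth into 6 structures
    sub_shell = sub_outer & ~core
    azimuth = np.degrees(np.arctan2(yb, xb)) % 360.0
    sector_order = ("putamen", "caudate", "thalamus", "hippocampus", "amygdala", "entorhinal")
    for i, name in enumerate(sector_order):
        sel = sub_shell & (azimuth >= 60.0 * i) & (azimuth < 60.0 * (i + 1))
        labels[sel] = codes[name]

    # brainstem cylinder (overwrites whatever it pierces)
    bx, by = spec.brainstem_center_xy_mm
    z0, z1 = spec.brainstem_z_mm
    stem = ((xb - bx) ** 2 + (yb - by) ** 2 <= spec.brainstem_radius_mm**2) & (
        zb >= z0
    ) & (zb <= z1)
    labels[stem] = codes["brainstem"]

    # substantia nigra sphere, drawn last
    cx, cy, cz = spec.sn_center_mm
    sn = (xb - cx) ** 2 + (yb - cy) ** 2 + (zb - cz) ** 2 <= spec.sn_radius_mm**2
    labels[sn] = codes["substantia_nigra"]

    volume = LabelVolume(
        labels=labels, voxel_size_mm=spec.voxel_size_mm, code_map=dict(codes)
    )

    pretty = {"substantia_nigra": "SN"}
    for name, code in codes.items():
        if not np.any(labels == code):
            raise ValueError(f"empty region: {pretty.get(name, name)}")
    wm_mL = volume.volume_mL("cerebral_wm")
    if wm_mL < 250.0:
        raise ValueError(
            f"WM compartment too small: {wm_mL:.1f} mL < 250 mL (region cerebral_wm)"
        )
    return volume


def default_merge_map() -> dict[str, list[str]]:
    """Merge map collapsing hemisphere codes into the 12 evaluated GM ROIs."""
    merge: dict[str, list[str]] = {
        name: [f"{name}_lh", f"{name}_rh"] for name in CORTICAL_REGIONS
    }
    merge.update({name: [name] for name in SUBCORTICAL_REGIONS})
    return merge


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth 1TCM parameters per region.

    ``rates`` maps region name -> (K1_true, k2_true); VT_true = K1/k2.
    Cerebral WM must have lower VT than every GM region.
    """

    rates: dict

    def __post_init__(self) -> None:
        for name, (k1, k2) in self.rates.items():
            if k1 <= 0 or k2 <= 0:
                raise ValueError(f"non-positive rate constants for region {name!r}")
        if "cerebral_wm" in self.rates:
            wm_vt = self.vt("cerebral_wm")
            for name in self.rates:
                if name in ("cerebral_wm",):
                    continue
                if self.vt(name) <= wm_vt:
                    raise ValueError(
                        f"WM VT must be below GM VT: region {name!r} has "
                        f"VT {self.vt(name):.2f} <= WM {wm_vt:.2f}"
                    )

    def vt(self, region: str) -> float:
        k1, k2 = self.rates[region]
        return k1 / k2

    def regions(self):
        return list(self.rates)

    def scaled(self, factors: dict) -> "KineticTruth":
        """New truth with K1 multiplied per region (k2 fixed), VT scaling."""
        rates = {
            name: (k1 * factors.get(name, 1.0), k2)
            for name, (k1, k2) in self.rates.items()
        }
        return KineticTruth(rates=rates)

    @classmethod
    def default(cls) -> "KineticTruth":
        """Defaults with WM VT = 4.3 mL/cm^3 and GM VT 2.3-4.7x WM."""
        return cls(
            rates={
                "cerebral_wm": (0.215, 0.050),  # VT 4.30
                "frontal": (0.48, 0.026),  # VT 18.5
                "parietal": (0.47, 0.025),  # VT 18.8
                "occipital": (0.50, 0.027),  # VT 18.5
                "temporal": (0.45, 0.025),  # VT 18.0
                "anterior_cingulate": (0.52, 0.027),  # VT 19.3
                "posterior_cingulate": (0.54, 0.027),  # VT 20.0
                "putamen": (0.45, 0.030),  # VT 15.0
                "thalamus": (0.42, 0.030),  # VT 14.0
                "caudate": (0.45, 0.028),  # VT 16.1
                "hippocampus": (0.36, 0.028),  # VT 12.9
                "entorhinal": (0.33, 0.027),  # VT 12.2
                "amygdala": (0.35, 0.028),  # VT 12.5
                "substantia_nigra": (0.36, 0.030),  # VT 12.0
                "brainstem": (0.33, 0.033),  # VT 10.0
            }
        )


def simulate_input_function(
    peak_time_min: float = 1.5,
    peak_value: float = 40.0,
    decay_rates=(2.0, 0.3, 0.01),
    decay_weights=(24.0, 12.0, 4.0),
    schedule: FrameSchedule | None = None,
    t_end_min: float | None = None,
) -> InputFunction:
    """Feng-style plasma curve: linear rise to the peak, then a weighted sum
    of decaying exponentials, continuous at the peak.

    Weights are normalized so the curve equals ``peak_value`` at the peak.
    Returned as an :class:`InputFunction` sampled on a fine grid (dense near
    the peak) and evaluable anywhere.
    """
    rates = np.asarray(decay_rates, dtype=float)
    weights = np.asarray(decay_weights, dtype=float)
    if peak_time_min <= 0:
        raise ValueError("peak_time_min must be > 0")
    if peak_value <= 0:
        raise ValueError("peak_value must be > 0")
    if np.any(rates <= 0) or np.unique(rates).size != rates.size:
        raise ValueError("decay rates must be positive and distinct")
    if np.any(weights <= 0) or weights.shape != rates.shape:
        raise ValueError("decay weights must be positive, one per rate")
    if t_end_min is None:
        t_end_min = schedule.total_min if schedule is not None else 90.0
    if t_end_min <= peak_time_min:
        raise ValueError("curve must extend beyond the peak")

    w = weights * (peak_value / weights.sum())
    rise = np.linspace(0.0, peak_time_min, 16)
    tail_knots = np.concatenate(
        [
            np.arange(peak_time_min, min(peak_time_min + 3.0, t_end_min), 0.02),
            np.arange(peak_time_min + 3.0, min(10.0, t_end_min), 0.05),
            np.arange(10.0, t_end_min, 0.25),
            [t_end_min],
        ]
    )
    tail_knots = np.unique(tail_knots[tail_knots >= peak_time_min])
    tau = tail_knots - peak_time_min
    tail = np.sum(w[:, None] * np.exp(-rates[:, None] * tau[None, :]), axis=0)
    rise_vals = peak_value * rise / peak_time_min
    t = np.concatenate([rise[:-1], tail_knots])
    c = np.concatenate([rise_vals[:-1], tail])
    return InputFunction(time_min=t, cp=c)


def region_tacs(
    labels: LabelVolume,
    truth: KineticTruth,
    cp: InputFunction,
    schedule: FrameSchedule,
) -> dict[str, np.ndarray]:
    """Noise-free frame-averaged 1TCM curve per labelled region."""
    names = labels.region_names()
    # hemisphere sub-labels inherit the parent cortical region's kinetics
    resolved: dict[str, str] = {}
    for n in names:
        base = n[:-3] if n.endswith(("_lh", "_rh")) else n
        if base in truth.rates:
            resolved[n] = base
        else:
            raise ValueError(f"region {n!r} present in labels but missing from truth")
    ctx = OneTCMContext(cp, schedule)
    unit_cache: dict[float, np.ndarray] = {}
    out = {}
    for n, base in resolved.items():
        k1, k2 = truth.rates[base]
        if k2 not in unit_cache:
            unit_cache[k2] = ctx.unit_frame_values(k2)
        out[n] = k1 * unit_cache[k2]
    return out


def simulate_dynamic_pet(
    labels: LabelVolume,
    truth: KineticTruth,
    cp: InputFunction,
    schedule: FrameSchedule,
    psf_fwhm_mm: float = 6.0,
    noise_scale: float = 0.0,
    seed: int = 0,
) -> DynamicImage:
    """Forward-simulate a dynamic PET volume.

    Per frame: paint each region with its noise-free frame-averaged 1TCM
    value, convolve with a Gaussian PSF of the given FWHM, then add
    independent zero-mean Gaussian noise with SD =
    ``noise_scale * sqrt(C(t)/frame_duration)`` per voxel.  Fully
    deterministic given the seed.
    """
    tacs = region_tacs(labels, truth, cp, schedule)
    lut = np.zeros((int(labels.labels.max()) + 1, schedule.n_frames))
    for name, tac in tacs.items():
        lut[labels.code_map[name]] = tac
    n_frames = schedule.n_frames
    data = np.empty(labels.labels.shape + (n_frames,), dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    durations = schedule.duration_min
    for j in range(n_frames):
        frame = lut[labels.labels, j]
        if psf_fwhm_mm > 0:
            frame = gaussian_smooth(frame, psf_fwhm_mm, labels.voxel_size_mm)
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(np.clip(frame, 0.0, None) / durations[j])
            frame = frame + rng.normal(size=frame.shape) * sd
        data[..., j] = frame
    return DynamicImage(
        data=data,
        schedule=schedule,
        voxel_size_mm=labels.voxel_size_mm,
        provenance={
            "seed": int(seed),
            "psf_fwhm_mm": float(psf_fwhm_mm),
            "noise_scale": float(noise_scale),
        },
    )
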