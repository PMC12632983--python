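# Methods

This document describes the models implemented in `wmref`, the choices
behind their default parameters, and what the synthetic data generator
does and does not emulate.

## 1. Scientific problem

Dynamic brain PET with a reversible tracer quantifies regional binding as
the total volume of distribution VT. Ratio measures such as the
distribution volume ratio, DVR = VT(target) / VT(reference), cancel
scan-level calibration error and improve test-retest reproducibility —
but only if the reference region itself is quantified precisely and
without bias. White-matter (WM) references pose a size trade-off:

* a **small, deep** WM region (the 2 mL centrum-semiovale standard) is
  nearly free of gray-matter (GM) signal but has few voxels, so its VT
  estimate is noisy, and that noise propagates into every DVR that uses it;
* a **large** WM region has excellent counting statistics but necessarily
  extends toward the cortex, where the scanner point-spread function (PSF)
  mixes in GM signal ("spill-in") and biases VT upward.

`wmref` builds a family of volume-targeted WM reference regions on a
digital phantom with known ground truth, and quantifies both sides of the
trade-off: VT bias versus reference size, DVR test-retest variability
versus reference size, and the downstream effect on detecting a group
difference in a small target region.

## 2. Kinetic model

The one-tissue compartment model (1TCM) with plasma input Cp(t):

    dC(t)/dt = K1 Cp(t) − k2 C(t),      VT = K1 / k2

* K1 (mL·cm⁻³·min⁻¹): plasma→tissue influx. k2 (min⁻¹): efflux.
* The tissue curve is the convolution C(t) = K1 ∫ e^{−k2(t−s)} Cp(s) ds.

**Closed-form evaluation.** Cp is represented as a piecewise-linear curve
(zero before its first sample, single-exponential extrapolation beyond its
last). On each linear segment the convolution and its running integral
have closed forms in the functions φ₁=(1−e⁻ˣ)/x, φ₂=(x−1+e⁻ˣ)/x²,
φ₃=(x²/2−x+1−e⁻ˣ)/x³ (series-expanded for x<10⁻³ for numerical
stability). Model values are **exact frame time-averages**, not midpoint
samples: with 5-minute late frames, midpoint sampling biases the model
curve noticeably, and the data being fitted are themselves frame averages.

**Fitting.** Weighted bounded nonlinear least squares on (K1, k2), bounds
K1 ∈ [10⁻⁴, 5], k2 ∈ [10⁻⁴, 2], default weights proportional to frame
duration. Because the model is linear in K1, a deterministic coarse scan
over 25 log-spaced k2 values with K1 profiled by weighted linear
regression (variable projection) seeds a trust-region refinement
(`scipy.optimize.least_squares`). This replaces random multi-start
jitter: it is strictly deterministic and at least as robust, because the
1-D profiled objective is easy to bracket. Solutions on a box bound are
flagged `converged = False` and excluded from downstream statistics (with
a warning). Standard errors come from the Gauss–Newton covariance.

**Frame schedule.** Default 60-minute, 21-frame schedule
(6×0.5, 3×1, 2×2, 10×5 min). **Input function.** Feng-style: linear rise
to a 40 kBq/mL peak at 1.5 min, then a weighted sum of three decaying
exponentials (rates 2.0, 0.3, 0.01 min⁻¹; weights 24:12:4, normalized to
the peak), continuous at the peak.

## 3. Phantom

A 90³ grid of 2 mm isotropic voxels containing nested ellipsoidal shells
(all semi-axes in mm):

| structure | geometry |
|---|---|
| cortical GM shell | (65,60,55) → (58,53,48), 6 azimuthal parcels × 2 hemispheres |
| outer WM shell | (58,53,48) → (51,46,41) |
| subcortical GM shell | (51,46,41) → (26,24,22), 6 azimuthal sectors |
| deep WM core | (26,24,22) |
| brainstem | cylinder r=9 at (x,y)=(0,−8), z ∈ [−70,−45] |
| substantia nigra | sphere r=10 at (0,−8,−48), painted last |

The WM compartment (shell + core, ≈270 mL) is deliberately
**non-convex**: thresholding the smoothed WM map to ≥100 mL forces the
ROI into the thin outer shell adjacent to cortex, which is what produces
the large-reference spill-in bias. A convex WM blob cannot reproduce this
at any realistic PSF because its deep interior is everywhere far from GM.

**Ground-truth kinetics** (`KineticTruth.default()`): WM K1=0.215,
k2=0.050 (VT 4.30); GM regions VT 12–20 (2.8–4.7 × WM); substantia nigra
VT 12.0; validation rejects any truth table in which WM VT is not below
every GM VT.

**Image formation.** Per frame: paint each region with its noise-free
frame-averaged 1TCM value; convolve with an isotropic Gaussian PSF
(default **6 mm** FWHM); add independent Gaussian voxel noise with
SD = noise_scale · √(C/Δt). The PSF is coarser than a modern research
scanner (~3 mm) because the phantom's smooth interfaces underrepresent
the WM–GM contact area of a folded brain; 6 mm restores a plausible
effective spill-in fraction.

## 4. Reference-region builder

Following the FreeSurfer-based WM (FBWM) recipe: binarize the WM label,
smooth at **10 mm FWHM** (σ = FWHM/2.3548 per axis, zero padding),
threshold the smoothed map so the retained volume is closest to each
target size (0.5, 1, 2, 5, 10, 20, 45, 100, 200 mL). Voxels are ranked by
map value with deterministic tie-breaking, so the series is exactly
nested and reproducible. The comparison standard is a **2 mL deep-WM
sphere** ("CS analogue") grown at the WM voxel farthest from any non-WM
tissue (Euclidean distance transform), mimicking a template
centrum-semiovale ROI.

## 5. Cohort model

Multiplicative K1 variation with k2 fixed (so VT scales identically):

| component | form | default |
|---|---|---|
| between-subject | independent mean-1 lognormal per region per subject | CV 0.01 |
| within-subject | one global mean-1 lognormal per scan, shared by all regions | CV 0.055 |
| disease (PD) | K1 × (1 − pd_effect) in SN, caudate, brainstem | pd_effect 0.10 |
| voxel noise | SD = noise_scale·√(C/Δt) after PSF | noise_scale 12 |

The within-subject factor is deliberately **global per scan**: it models
radiosynthesis/calibration/injection day effects, which is exactly the
error DVR cancels — the stated motivation for ratio measures. Healthy
subjects get two scans (a configurable fraction same-day, the rest at a
uniform interscan interval, default 7–1028 days); patients get one.

Randomness uses one master seed with counter-keyed substreams per
(stream, group, subject, scan), so enlarging a cohort never perturbs
already-generated scans, and single scans can be regenerated in
isolation (`scan_noise_rng`).

**ROI-level fast path.** For replicate experiments, `ROILevelSimulator`
evaluates the image-level model restricted to the union of ROI voxels:
PSF mixing weights are precomputed from smoothed region indicators, and
voxel noise is drawn only on those voxels. This is the *same* model (the
noise-free test suite asserts equality with full image simulation), not
an approximation; only the RNG consumption differs from image mode. It
preserves the spatial overlap between the 2 mL analogue and the larger
WM ROIs, and hence their noise correlation.

## 6. Quantification and evaluation

* TRV = (retest − test)/(test + retest) × 200 % (signed, antisymmetric,
  bounded by ±200 % for positive inputs).
* DVR = VT(target)/VT(reference); scans whose reference fit failed are
  excluded with a warning.
* GM-averaged DVR TRV: within-subject mean across the 12 GM ROIs first,
  then mean ± SD across subjects.
* Reference bias: percent difference of mean first-scan VT versus the
  2 mL deep-WM standard; the selection rule accepts references with
  |bias| < 10 % (strict) and picks the largest-volume acceptable one.
* Interscan-interval regression: OLS of GM-averaged TRV on interval
  (statsmodels), reporting slope, intercept, R², p, RSS.
* Group comparison: two-tailed unpaired t-test (pooled-variance Student
  by default, Welch optional) with pooled-SD Cohen's d.
* Sample size: exact noncentral-t power for two-sample or paired designs;
  the smallest n reaching the target power.

## 7. What the generator emulates — and what it does not

Emulated: the 1TCM forward model with exact frame averaging; PSF spill-in
as the mechanism of reference bias; count-limited, duration-scaled voxel
noise; scan-level calibration error; region-level biological variation;
a VT-reducing disease effect in PD-relevant regions; same-day versus
longitudinal test-retest structure.

Not emulated: attenuation/scatter/randoms and reconstruction artifacts;
motion; partial-volume correction; metabolite analysis and blood-sampling
error (the input function is noise-free and shared across scans);
anatomical variability between subjects (one phantom for all); radiotracer
displacement or blood-flow effects; spatial noise correlation beyond the
PSF (noise is drawn after smoothing).

Deliberate stylizations (chosen so the qualitative phenomena of interest are
resolvable in minutes-scale Monte-Carlo experiments, and documented in
the project ledger): between-subject CV (1 %) is well below real
intersubject variability (10–20 %), making the case-control effect sizes
larger than published values; the substantia nigra is drawn at r = 10 mm
(≈4.2 mL), larger than anatomy, so its own fit noise does not swamp the
reference-noise effect; the PSF is 6 mm as discussed above. The
*orderings* the package asserts (bias grows with reference size; DVR TRV
SD shrinks with reference size; a 10 mL reference detects a deficit more
sensitively than the 2 mL standard) are the object of study, not the
absolute magnitudes.

## 8. Numerical choices

* φ-functions switch to 4-term Taylor series below x = 10⁻³ (relative
  error < 10⁻¹²), avoiding catastrophic cancellation.
* The convolution recurrence is vectorized by exponential rescaling when
  k2·T < 600 and falls back to a sequential loop otherwise (overflow-safe).
* `OneTCMContext` memoizes unit frame curves per k2 (≤64 entries), making
  the deterministic k2 grid scan nearly free across fits that share an
  input function and schedule.
* ROI means over float32 images accumulate in float64.
* Label volumes are stored as int16 NIfTI with a JSON code-map sidecar;
  masks as uint8; dynamic images as float32.
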