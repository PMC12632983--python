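# wmref

White-matter reference-region optimization for dynamic brain PET, exercised
end-to-end on a synthetic digital phantom with known ground truth.

## The problem

Quantifying a reversible PET tracer with the one-tissue compartment model
(1TCM) yields a total volume of distribution per region,

    dC/dt = K1·Cp(t) − k2·C(t),        VT = K1 / k2.

Ratio outcome measures — the distribution volume ratio,
DVR = VT(target) / VT(reference) — cancel scan-level calibration error and
tighten test-retest reproducibility, *if* the reference region is itself
quantified precisely and without bias. White-matter references face a size
trade-off:

* A small deep white-matter region (the conventional ~2 mL
  centrum-semiovale ROI) is nearly free of gray-matter contamination but
  contains few voxels, so its VT is noisy — and that noise enters every DVR.
* A large white-matter region has excellent counting statistics but extends
  toward cortex, where the scanner point-spread function mixes in
  gray-matter signal and biases VT upward.

`wmref` makes this trade-off measurable. It builds a nested series of
volume-targeted white-matter reference regions (0.5–200 mL) on a phantom
whose kinetics are known exactly, then quantifies: VT bias versus reference
size, test-retest variability (TRV) of gray-matter DVR versus reference
size, and the downstream sensitivity for detecting a Parkinson's-like
binding reduction in the substantia nigra. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

`scripts/acceptance.py` regenerates the headline quantities from scratch
(phantom construction, ROI building, noise-free bias curve, a 10-subject
test-retest cohort, a 12-vs-12 case-control replicate experiment, and a
null-calibration loop) and writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Output at seed 1 (runs in about 3 minutes on one CPU):

```
white_matter_volume_mL: 270.72
true_white_matter_vt: 4.3
deep_wm_reference_vt_with_spill_in: 4.3
vt_bias_percent_0p5mL: -4.94118e-08
vt_bias_percent_1mL: -4.94118e-08
vt_bias_percent_2mL: -4.93271e-08
vt_bias_percent_5mL: 1.38808e-06
vt_bias_percent_10mL: 0.0005848
vt_bias_percent_20mL: 0.098134
vt_bias_percent_45mL: 9.24164
vt_bias_percent_100mL: 28.3055
vt_bias_percent_200mL: 47.2282
gm_dvr_trv_sd_percent_0p5mL: 8.42288  (n=10)
gm_dvr_trv_sd_percent_10mL: 3.01196  (n=10)
gm_dvr_trv_sd_percent_100mL: 0.382901  (n=10)
pd_cohens_d_cs2mL_mean: 1.82129  (n=20)
pd_cohens_d_fbwm10mL_mean: 2.49971  (n=20)
fraction_d_fbwm10mL_exceeds_d_cs2mL: 0.95  (n=20)
null_rejection_rate_fbwm10mL: 0.03  (n=100)
sample_size_unit_effect_two_sample: 17
```

Reading the numbers:

* **Bias.** Up to 20 mL the fitted reference VT is essentially identical to
  the 2 mL deep-white-matter standard (< 0.1 % bias); at 100 mL and beyond,
  spill-in from cortex inflates VT by 28–47 %.
* **Precision.** The between-subject SD of gray-matter-averaged DVR TRV
  falls from 8.4 % with a 0.5 mL reference to 3.0 % at 10 mL and 0.4 % at
  100 mL — more reference voxels means less reference noise in every DVR.
* **Detection.** For a 10 % substantia-nigra binding reduction, the 10 mL
  reference gives a larger Cohen's d than the 2 mL standard (mean 2.50 vs
  1.82) in 95 % of replicates, while the false-positive rate under the null
  stays at the nominal 5 % level. The sweet spot — large enough to be quiet,
  small enough to stay unbiased — sits around 10–20 mL on this phantom.
* `sample_size_unit_effect_two_sample: 17` is the classic noncentral-t
  answer for a unit effect (delta = SD) at alpha 0.05, power 0.80.

Effect sizes here are larger than in clinical data because the cohort
generator deliberately uses a small between-subject variability (see the
stylization notes in docs/methods.md); the *orderings* are the result.

## Pipeline usage

```bash
wmref run --config config.yaml --out results/run1        # all stages
wmref simulate --config config.yaml --out results/run1   # or stage by stage
```

A config YAML may override any `RunConfig` field (seed, cohort sizes,
noise, PSF, reference sizes, `simulation_mode: roi|image`, …); unknown keys
are rejected and all validation errors are reported at once. Each run
writes TSV tables (`vt.tsv`, `dvr_*.tsv`, `bias.tsv`, `cohort.tsv`, …), a
`report.json` with the selected reference and group statistics, and a
`manifest.json` recording the config hash, seed, package version, and
outputs. Reruns with the same config are byte-identical.

## Layout

```
src/wmref/
  kinetics.py   1TCM closed-form model, frame averaging, fitting
  phantom.py    digital phantom, ground-truth kinetics, image simulation
  roi.py        smoothing, volume-targeted reference series, GM ROI merging
  cohort.py     test-retest / case-control cohort generator, ROI-level fast path
  quantify.py   VT/DVR/TRV computation and summaries
  evaluate.py   bias tables, reference selection, regression, t-tests, power
  pipeline.py   staged end-to-end run with manifest and error reporting
  cli.py, io.py command-line interface; NIfTI/TSV/YAML/JSON I/O
tests/          unit + property tests, acceptance tests, oracles
scripts/        acceptance.py
docs/           methods.md
```
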