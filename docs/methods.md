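# Methods

This note documents the models, numerical choices and assumptions behind
`nirbran`, and what the synthetic experiments do and do not demonstrate.

## The calibration problem

The analyte is cellulose content (%, w/w) in the rice bran layer
(de-germinated rice bran). Reference values come from a potassium
dichromate oxidation assay; predictors are near-infrared absorbance
spectra recorded in two geometries on Fourier-transform instrumentation:
diffuse reflectance (DR, 4000–12000 cm⁻¹) and diffuse transmittance
(DT, 5793–12489 cm⁻¹). Cellulose absorbs at the C–H second overtone
(8330 cm⁻¹), the O–H first overtone (6825 cm⁻¹), further overtones through
7500–5400 cm⁻¹, and C–H/O–H combination bands below 5793 cm⁻¹ that only
the DR range covers. The two geometries are complementary: DT collects
more signal at the short-wavelength end and shows both higher absolute
absorbance and stronger baseline drift (transmission is more sensitive to
packing density); DR alone covers the combination-band region.

The pipeline is: pretreat → (optionally) fuse DR and DT → Kennard–Stone
split → PLS1 with interval selection → validate/predict → screen.

## Pretreatment

Model-level conditions are the six used in routine practice: `none`,
Savitzky–Golay first derivative, MSC, SNV, and derivative followed by MSC
or SNV. Choices the literature leaves open:

* **"17-point smoothing"** is read as a Savitzky–Golay window of 17
  points with polynomial order 2 (the common instrument-software
  default); both are configurable. Edges use the polynomial-extension
  policy so every operator preserves variable count and grid alignment.
* The derivative is taken **per grid index**; dividing by the grid step
  to get per-cm⁻¹ units only rescales the variable and has no effect on
  PLS after centring (`delta` is exposed).
* **MSC** regresses each spectrum on the calibration-set mean and inverts
  the fitted slope/offset. The reference is a fitted state: it is
  estimated on calibration data only and reused verbatim for validation
  and prediction spectra (and refitted inside every cross-validation
  fold — held-out samples never contribute to it).
* Chain order follows the printed naming: "1st der + MSC" differentiates
  first. SNV and min-max are strictly per-spectrum and carry no state.

## Fusion

Primary (low-level) fusion concatenates each sample's DR and DT spectra,
DR block first, after applying the same block-level pretreatment (`raw`,
min-max, or first derivative) to each block independently. The block
pretreatment exists to reduce the absorbance-magnitude gap between the
geometries; the derivative variant visibly shrinks the junction
discontinuity. Model-level pretreatment is subsequently applied to the
fused vector as a single spectrum (the whole-vector interpretation; a
per-block alternative would also be defensible but the whole-vector one
matches treating the fused CSV as ordinary spectra). Each fused variable
keeps its origin block and original wavenumber so that selected intervals
can be reported as per-block high–low cm⁻¹ ranges.

## Partitioning

Kennard–Stone max–min selection on Euclidean spectral distance, seeded
with the farthest pair, taking `ceil(0.7 n)` samples as calibration
(99/42 at n = 141). Ties break toward the lowest input index, making the
procedure deterministic. Distances are computed on the spectra as given;
the pipeline computes one split on the raw fused spectra and shares it
across all five model families so family metrics are comparable. Because
extreme spectra are selected first, the calibration range tends to cover
the validation range; this is a tendency, not a theorem, once noise
decouples spectra from contents.

## PLS and model selection

PLS1 on mean-centred X and y (no autoscaling — standard for spectra),
fitted by sequential NIPALS-style deflation; with a single response each
component is available in closed form, so no inner iteration is needed.
The LV count is selected by cross-validation — leave-one-out by default
(deterministic and cheap at n ≈ 99; k-fold venetian blinds available,
and used at the n = 350 scale where LOO buys nothing) — as the argmin of
RMSECV with ties resolved toward fewer LVs, under the cap
`floor(n_calibration/10)` that guards against overfitting. Metrics are
`RMSE = √(Σ(ŷ−y)²/m)` and `R² = 1 − SS_res/SS_tot` in their
cross-validation / validation / external-prediction flavours. A
squared-Pearson R² variant is deliberately not used; commercial packages
differ here, which is one reason published table values are not exactly
recoverable by any reimplementation.

LOO cross-validation is computed by an exact fold-batched implementation
(all n folds deflated simultaneously); it is verified against an explicit
refit-and-predict loop in the tests and falls back to that loop when a
fold-dependent MSC state must be refitted on large problems.

## Interval selection

The pretreated spectrum is cut into 10 contiguous segments of equal size
(remainder spread over the first segments). All combinations of 1–6
segments — `Σ C(10,k) = 847` — are crossed with the six pretreatment
conditions and ranked by cross-validated RMSECV with per-candidate LV
selection. Exhaustive enumeration replaces the "random combination"
wording of sampling-based tools: at 847 candidates it is cheap,
deterministic, and dominates any random subset (a seeded subsample mode
exists for parity). Per-spectrum operators are applied to the full
spectrum before segmentation (a derivative must see its neighbours);
the MSC reference is fitted on the selected variables. Candidates with
fewer variables than admissible LVs are skipped with a logged warning.
Ties rank by fewer LVs, then fewer segments, then lexicographic order.

## Wet-chemistry statistics

Precision is summarised as RSD = SD/mean × 100 % with the sample (n−1)
SD throughout — this convention reproduces the published per-day
repeatability values exactly. Inter-day precision pools all replicates.
Method comparison uses the paired t statistic on per-sample differences
(df = n−1) and product-moment correlation of per-sample means; p-values
come from the t distribution at the stated tails. Two discrepancies in
the published summaries are documented rather than asserted: the pooled
inter-day RSD recomputed from the printed replicates is 0.74 % (0.70 %
was evidently computed from unrounded raw data), and the printed t value
for the means comparison (0.22) is not recoverable from the printed
means under paired or pooled formulas (we obtain ≈ −0.39); the packaged
checks assert the derived values, the degrees of freedom and the
non-significance conclusion. Identical pairs (zero-variance, zero-mean
differences) return the null result t = 0 rather than an error;
zero-variance differences with nonzero mean are an error.

## Screening

A variety is `low`/`high` when its content deviates from the benchmark
(wild type W7 by default) by strictly more than the threshold, 0.43 %
cellulose; a deviation of exactly the threshold is `normal`. Strictness
matters: the known high mutant sits 0.44 % above the predicted benchmark
and must classify high. Whether 0.43 derives from a rule or is ad hoc is
unknown; it is an ordinary parameter here.

## The synthetic generator

The generator emulates the documented structure of the real data, not
its physics (no Kubelka–Munk or radiative transfer, no instrument line
shape):

* contents from a truncated normal, mean 3.89 %, SD 0.55 %, truncated at
  the observed 2.80–4.92 % range, n = 141 by default;
* five constituents (cellulose, water, protein, lipid, starch) as
  Gaussian band sums; band amplitudes give working absorbances of a few
  tenths. One interferent (lipid) is correlated 0.3 with cellulose so
  variable selection is not trivially separable;
* per-sample multiplicative scatter (slope 0.93–1.07, offset ±0.02) and
  baseline drift (random linear + slow sinusoid), with DT drift
  amplitude 3× DR and a DT gain of 1.8 encoding the higher DT
  absorbance; blocks weight the short/long-wavelength ends oppositely
  and carry independent noise (SD 0.002 AU), which is what makes fusion
  genuinely informative;
* reference values carry assay noise of SD 0.05 % cellulose (≈1.3 %
  RSD, the optimized assay's repeatability scale);
* grids default to 8 cm⁻¹ spacing (an FT oversampling of the 16 cm⁻¹
  instrument resolution; the true point spacing is not documented and is
  configurable);
* one root seed; composition, per-block effects and assay noise use
  separately spawned child streams, so `perturbation_free()` can produce
  a twin dataset with identical samples but clean spectra and exact
  references.

What passing the synthetic suite shows: the implementation recovers a
known linear signal through the full pretreat/fuse/split/select/validate
machinery at realistic noise levels, fusion outperforms single blocks
when the blocks carry complementary information, and the 847-candidate
search does not hallucinate signal from pure noise (selection-bias
ceiling R²cv ≤ 0.3 at n = 100). What it does not show: performance on
real rice bran spectra, whose band shapes, collinearity structure and
scatter are richer than Gaussian bands with affine scatter.

### The recovery criterion

The end-to-end recovery check at n = 500 asserts R²cv ≥ 0.85 and
R²p ≥ 0.85 on a fresh 200-sample set, and additionally that prediction
error is dominated by the perturbations the generator injects rather
than by model bias: RMSEP must not exceed twice the content-equivalent
perturbation floor, measured as the RMS prediction difference between
the noisy test spectra and their perturbation-free twins, combined with
the reference-assay noise. This floor is measured at run time from the
paired datasets — nothing in it is fitted to the observed RMSEP.

## Problem sizes and determinism

Experiment sizes used by the packaged checks: recovery at n = 500
calibration-pool / 200 test with 10-fold CV; fusion advantage over 20
replicates at the study size n = 141 with LOO; null-response search over
847 candidates at n = 100 on a 100-point grid, 10 seeds. All randomness
flows from explicit integer seeds; identical configuration and seed give
byte-identical pipeline outputs.

## Known limitations

* PLS1 only (single response); no outlier diagnostics (leverage,
  spectral residuals) or prediction intervals.
* No mid- or decision-level fusion, and no block weighting.
* Kennard–Stone only (no SPXY/duplex/random splitting); Euclidean
  distance only.
* The siPLS-style search is exhaustive over 1–6 of 10 segments; moving
  windows, genetic algorithms and CARS are out of scope.
* Published model metrics obtained on the undeposited real spectra with
  proprietary software are not reproduction targets; the synthetic
  properties above take their place.
* The full six-condition × 847-combination search on study-sized fused
  spectra (1839 variables, LOO) takes tens of minutes on one core; the
  pipeline therefore defaults to full-spectrum condition comparison,
  with the search behind `search: true`.
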