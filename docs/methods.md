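# Methods

This note documents the models implemented in `soyspec`, the defaults and
why they were chosen, the synthetic data the package is benchmarked on,
and the limits of what those benchmarks demonstrate.

## Spectral pretreatment

The quantification recipe is, in order: 2-norm×100 vector normalization,
Savitzky–Golay 2nd derivative, wavelength-region cut, column
mean-centering. The order is the standard chemometric one — scan-wise
transforms run on the full measured range so the derivative window never
crosses a region boundary, the region is cut afterwards, and centering
comes last so the stored column means live on the modeled sub-grid.

* **Normalization** scales each scan to Euclidean norm 100. It is
  idempotent and invariant to positive scaling, which is what makes it a
  scatter correction: a purely multiplicative path-length change cancels
  exactly. Additive baseline shifts do *not* cancel here; they are the
  derivative's job.
* **Savitzky–Golay** (default window 21 points, polynomial order 3,
  derivative 2) differentiates along the wavelength axis by windowed
  least-squares polynomial fits. The polynomial order is not dictated by
  the workflow being reproduced; 3 is the common choice for second
  derivatives (order 2 constrains the curvature estimate too strongly)
  and is exposed as configuration. Edge points evaluate the polynomial
  fitted to the nearest full interior window at the edge offset — no
  reflection or constant padding, so no fabricated data beyond the
  measured range (`scipy.signal.savgol_filter` with `mode="interp"`).
  Derivatives default to per-(grid-step)² units; a flag converts to
  per-nm². PLS is column-scale equivariant after centering, so the choice
  does not affect predictions.
* **Mean-centering** supports two modes. Column (per-wavelength) centering
  is the default for regression: means are estimated on calibration scans
  at fit time, stored in the recipe, and reused unchanged on validation
  and prediction data. Row (per-spectrum) centering subtracts each scan's
  own mean; the class-modeling recipe uses row centering followed by
  normalization, with no derivative. Descriptions of "mean-centering" in
  the source workflow read as per-spectrum centering while conventional
  chemometric mean-centering is per-variable; both are implemented, and
  the defaults (column for regression, row-then-normalize for SIMCA)
  follow each workflow's own stated pretreatment.

## PLS1 regression

Single-trait PLS by NIPALS on centered data: per factor
`w = Xᵀy/‖Xᵀy‖`, `t = Xw`, `p = Xᵀt/(tᵀt)`, `q = yᵀt/(tᵀt)`, then
deflation `X ← X − tpᵀ`, `y ← y − tq`; the regression vector is
`b = W(PᵀW)⁻¹q`. y is centered but never variance-scaled — errors are
reported in trait units. NIPALS (rather than SIMPLS) is the reference
algorithm here; the test suite cross-checks predictions against an
independent implementation and, at full rank, against ordinary least
squares.

**Factor selection** is leave-one-out cross-validation at the sample
level: all replicate scans of the held-out sample leave together
(replicates are pseudo-replicates, so leaving them in the training fold
would leak), and column/y centering are re-estimated inside every fold.
RMSECV is computed on replicate-averaged held-out predictions. The chosen
count is the first local minimum of the RMSECV curve, with ties resolved
to the smaller count and a strictly decreasing curve selecting the
configured maximum. Folds whose rank cannot support the requested factor
count are truncated and counted in the result.

**Per-trait defaults** (spectral region / maximum factors) are the
published study's own settings: total protein 1876–2294 nm / 4; amino
acids 1978–2307 nm / 4–6 (threonine 6, lysine 5, others 4); fat and fatty
acids 1680–1859 nm / 5–6; moisture 1440–1825 nm / 6.

**Diagnostics.** Leverage is `hᵢ = tᵢᵀ(TᵀT)⁻¹tᵢ` (sums to the factor
count); residuals are standardized by RMSEC. Defaults flag
`h > 3k/n` or |standardized residual| > 3. Flagged samples are reported,
never silently dropped; the pipeline refits without them only when
`exclude_outliers` is set, because any fixed exclusion rule is a judgment
call that should be visible in the run log.

## Figures of merit

RMSEP is the root mean squared error on the external validation set
(sample-level, replicates averaged). RPD divides the *calibration*
reference standard deviation (n−1 denominator, the NIR-literature
convention) by RMSEP; RER divides the *validation* reference range by
RMSEP. Suitability tiers follow the published bands, with the gaps the
prose leaves (4.9–5.0, 6.4–6.5 for RPD; "more than" edges for RER) closed
at the upper tier's printed lower edge: RPD [2.5, 5) screening,
[5, 6.5) quality control, ≥ 6.5 process control; RER [4, 10] screening,
(10, 15] quality control, > 15 quantification. R values are Pearson
correlations between reference and predicted values. The group-comparison
test is the pooled-variance two-sided t-test (Welch available).

## SIMCA

Each class gets its own PCA subspace from the SVD of its class-mean-
centered block of preprocessed calibration scans. The pooled residual
standard deviation s₀ of the class's own scans uses the
(n − k − 1)(p − k) degrees-of-freedom convention; a new scan's residual
sd uses (p − k). Membership is the F-test
`(s/s₀)² ≤ F₁₋α(p − k, (n − k − 1)(p − k))`; a scan is assigned to the
accepting class with the smallest distance ratio, or `no_match` when no
class accepts it.

* **α default = 1e-4.** Membership is tested once per scan. At the
  textbook 0.05 level, roughly one scan in twenty from a batch of genuine
  class members is falsely rejected — a triplicate 12-sample validation
  batch would average ~2 spurious `no_match` calls. The default therefore
  controls the batch-level false-rejection rate instead; genuinely foreign
  spectra exceed the critical ratio by orders of magnitude, so the power
  cost against real outliers is nil. The level is configurable.
* **k default = 3 per class** in the pipeline, the dimensionality the
  emulated study itself used. An automatic rule (smallest k reaching 98%
  cumulative class variance, capped) is available; note that on
  noise-dominated data the 98% rule saturates at its cap, because white
  noise spreads variance over many components — it is only meaningful
  when within-class variance is concentrated in a few structured
  directions.
* **Interclass distance** is the pooled-residual ratio
  `ICD(a,b) = √[(s²ₐ→ᵦ + s²ᵦ→ₐ)/(s²ₐ→ₐ + s²ᵦ→ᵦ)]`, where `s²ₓ→ᵧ` is the
  mean squared residual of class-x calibration scans under class-y's
  model. Identical classes give ICD ≈ 1 (verified by null simulation);
  > 3 is the conventional significance threshold. The commercial package
  the study used does not document its exact formula; this Kvalheim-style
  form is the package's choice and is symmetric by construction.
  Discriminating power is the same ratio per wavelength.

## Synthetic data generator

The generator exists so every pipeline stage is testable without the
undeposited instrument data. A scan is

    m · Σₖ fractionₖ · pureₖ(λ) + offset + slope · s(λ) + ε

with `m ~ lognormal(0, 0.02)`, offset and slope Gaussian (sd 0.004
absorbance), `ε` iid Gaussian, and `s(λ)` the wavelength scaled to
[−1, 1]. Pure-component spectra are Gaussian band sums (protein,
oleic-rich fat, polyunsaturated fat, saturated fat, water, carbohydrate)
whose centers sit on published soy band assignments (protein 2063 and
2188 nm; fatty-acid first overtones 1709/1724/1731 nm; water 1450 and
1940 nm; carbohydrate 2100/2273/2480 nm). The default grid is 1350–2558 nm
at 8 nm spacing (152 points): the instrument's quoted 16 nm figure is an
optical resolution, not necessarily a sampling step, and 8 nm keeps the
21-point derivative window at ~168 nm, comparable to the band widths.

Compositions are truncated-normal draws at the published population
statistics (conventional, high-oleic, pooled-soybean) or uniform over the
published ranges (soy products). Amino acids are fixed fractions of
protein (the published soybean means) with 7.5% relative jitter — enough
coupling that amino-acid levels correlate > 0.9 with protein within a
wide-protein population, which is what makes amino-acid calibrations
recoverable at all. Linoleic deviations are drawn anticorrelated with
oleic (r = −0.9, marginal sds preserved): the oleate/polyunsaturate
trade-off is real desaturation-pathway biology, and it keeps the
fatty-acid sum below 100% without renormalization distorting the printed
class statistics. Carbohydrate is the mass-balance remainder.

Two generator constants were calibrated once, jointly, and then frozen:

* `noise_sd = 0.02` absorbance. This is a catch-all error budget — it
  stands in for detector noise *plus* everything the linear mixture model
  leaves out (reference-assay error, particle-size effects,
  nonlinearity). It was set so the protein model's RPD lands in the 5–10
  regime the study reports, which makes the suitability-tier machinery
  exercise realistic values rather than the RPD ≈ 20+ a noiseless linear
  simulation would give.
* Fat first-overtone band heights. Within-class fatty-acid variation
  points along the same spectral direction as the between-class
  difference, so interclass distance grows sublinearly with band
  contrast; at the noise level above, the heights needed for the classes
  to separate at ICD > 3 exaggerate the fat overtone relative to real
  ground-soybean spectra (where it is a modest shoulder and the raw
  class difference is not visually obvious). The band library ships as
  editable YAML, not hard-coded.

`make_study_fixture(seed)` assembles the emulated study: 30 conventional
+ 30 high-oleic (class-labeled) + 47 additional soybeans + 15 soy
products, three scans each, with reference coverage masked to the
original assay counts (amino acids on 32 samples including all products,
protein on 92, fatty acids on 96 soybeans, fat and moisture on 60 each).

**What the synthetic benchmark shows — and does not.** Passing tests show
the estimators are implemented correctly and behave as the theory says on
data satisfying the generator's assumptions: linear mixing, Gaussian
bands, iid noise, scatter that normalization can cancel. They do not show
that a real handheld instrument achieves these error levels: real diffuse
reflectance has particle-size and packing effects, nonlinear
scatter-absorbance coupling, band shifts with matrix composition, and
reference assays with their own biases — none of which are simulated
(deliberately: see Non-goals below).

## Splits and reproducibility

The regression split samples unique sample ids uniformly (no
stratification), 80% calibration by default; every replicate scan follows
its sample. The classification split is stratified per class (80/20 in
each), matching how the two procedures are described in the emulated
study. All randomness — composition draws, scatter/noise realizations,
splits, null simulations — flows from explicit integer seeds; a run is
reproducible from its logged configuration and seed alone. One known
consequence of the unstratified regression split: a few percent of seeds
put no wide-range soy-product sample in the protein validation set, which
collapses the validation range and with it the validation correlation.
That is a property of random splitting at n = 92 with 15 wide-range
samples, not of the estimator.

## Numerical choices and degenerate inputs

* NIPALS stops with an explicit rank error when the weight vector
  collapses (deflated X carries no covariance with y); inside
  cross-validation folds the factor count is truncated instead and the
  fold counted as capped.
* First-local-minimum ties (RMSECV[k] = RMSECV[k+1]) resolve to the
  smaller k.
* A class whose centered block has zero variance (identical scans) is
  rejected as degenerate rather than fitted with s₀ = 0; the threshold is
  relative (1e-20 of the block's sum of squares) so floating-point
  residue on identical scans does not masquerade as variance.
* All-zero spectra cannot be normalized and raise a degenerate-input
  error; constant traits raise before fitting.
* Model files are single JSON bundles holding the fitted recipe (with
  stored column means), loadings, weights, scores and metadata at full
  float precision; save→load reproduces predictions to 1e-12.

## Non-goals

Kubelka–Munk radiative transfer, particle-size simulation, instrument
line-shape modeling, multiplicative scatter correction/SNV/detrending
(the recipe relies on normalization plus derivative, as the emulated
workflow did), PLS2 multi-trait models, variable-selection search beyond
the fixed per-trait regions, prediction uncertainty intervals, and
reading vendor binary formats (spectra travel as CSV).
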