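# Methods

This note records the models implemented by `riceq`, the choices made
where the method description left room, and what the synthetic-data
studies do and do not demonstrate.

## Appearance: yellow-area scoring

A cooked-rice RGB image is converted per pixel to HSV with the standard
hexcone formulas (hue on [0,1) with red at 0; achromatic pixels get hue
0 and saturation 0).  A pixel is classified yellow iff
`hue < hue_threshold`, default 0.167 (≈ 60°, the yellow/green boundary),
with a strict inequality.  The appearance proxy is
`100 · n_yellow / n_total`.

Choices and caveats:

* **Achromatic pixels.**  Under the literal rule, pure-white pixels
  (hue 0) are classified yellow.  Real calibrated imaging of glossy
  white rice yields slightly blue-tinted, low-saturation pixels that
  fall outside the band, so the literal rule works in practice; for
  frames where it does not, an optional saturation gate
  (`saturation >= saturation_gate`) excludes near-achromatic pixels.
  The gate is **disabled by default** to keep the published rule exact;
  enabling it is an explicit configuration choice.
* **Region of interest.**  Whole-frame scoring is the default (the
  imaging protocol fills the frame with rice); a rectangular ROI crop is
  available for frames with container edges.
* **Repeat shots.**  Each sample is photographed four times; the scorer
  scores files independently and the CLI appends the batch mean row.

## Texture: TPA feature extraction

Force curves are parsed from delimited text (column aliases and
comma/tab sniffing), validated (≥ 10 samples, strictly increasing time,
no missing values, errors cite the offending row), and segmented at the
instrument trigger level (default 25 gf) with hysteresis: a compression
cycle is entered when force reaches the trigger and extends over the
surrounding positive-force phase, exiting at force ≤ 0.  This prevents
chatter near the trigger and makes small inter-cycle ripples invisible
to the segmenter.  The adhesion window is the contiguous negative-force
run between the two cycles; the first cycle is split at its force peak
into the down-stroke and up-stroke windows.

Numerical choices:

* **Integration variable is time** (areas in gf·s), the common texture
  analyzer convention; the trapezoidal rule integrates force clipped to
  the relevant sign over each window, with boundary samples included so
  zero crossings are captured.  Baseline is 0 gf with no drift
  correction by default.
* **Durations** T1, T2 are those of the positive-force phases;
  springiness = T2/T1.  A displacement column can be carried through the
  parser for displacement-based variants.
* **Brittleness** is the largest local maximum strictly before the
  hardness peak, detected with a minimum prominence of 5% of hardness so
  noise ripples are ignored; *undefined* (no qualifying peak) is a
  first-class `None`, not 0.  Likewise every ratio with a zero
  denominator is `None` rather than an exception.
* **Adhesiveness sign.**  A3 is a negative area; the feature is reported
  as its magnitude so that stickier rice has *larger* adhesiveness,
  matching its positive correlation with sensory viscosity.

Batch processing emits one row per curve plus per-sample means
(replicates inferred from `<sample>_<n>` file stems) and, when a control
sample is designated, control-relative differences for batch-effect
comparison; failed files are logged and skipped.

## Panel statistics

Scores live in long format (variety, year, replicate, trait, score) with
scores validated to [−3, 3] and unique keys.  The ANOVA is the balanced
additive two-way decomposition without interaction: sensory replicates
are averaged into one value per (variety, year) cell, giving
df = (n_years − 1), (n_varieties − 1) and their product for Year,
Variety and Error.  This is the layout that matches the published
degrees of freedom (1 / 321 / 321 for 322 varieties in 2 years); both F
statistics are tested against the error mean square.  Unbalanced designs
are rejected with the missing cells named.  The decomposition is
computed directly from the closed-form sums of squares (the balanced
case needs no iterative fit); the test suite cross-checks it against an
independent OLS + ANOVA route.

Broad-sense heritability uses the expected-mean-square estimator with
zero truncation: `var_g = max(0, (MS_variety − MS_error) / r)`,
`var_e = MS_error`, `h² = var_g / (var_g + var_e)`, with `r` defaulting
to the number of years (2), the replication count implied by the df
layout above.  The published per-trait h² values are recorded in
`riceq.reference` for context but are not asserted anywhere: they are
not derivable from the published sums of squares under this (or any
verified) estimator for r ∈ {2, 3}, and the printed mean squares are
themselves rounding-inconsistent with SS/DF.  The published variety F
values, by contrast, equal SS_variety/SS_error to within two-decimal
rounding for all six traits, and that identity is what the package
asserts.  P-values come straight from the F/t distributions; no
multiple-testing correction is applied.

## Eating-quality models

`fit_ols` wraps ordinary least squares (intercept always included,
rank-deficient designs rejected with the collinear columns named).
`best_subset` enumerates all non-empty predictor subsets (bounded at 20
predictors), keeps the R²-best subset per size, and selects the overall
winner by R², adjusted R² or BIC; plain R² is monotone in size, so its
winner is always the full model — the adjusted criteria exist for
exactly that reason.

The four published models ship as immutable constants with per-predictor
unit annotations.  The original report does not state the scaling of the
instrument predictors, and raw scales (adhesiveness of order 10²–10³
gf·s, yellow area in percent) are numerically impossible against
coefficients of order one on a −3..+3 response; the constants therefore
annotate adhesiveness as standardized (z-score within the measurement
batch) and yellow area as a fraction of the frame, with sensory traits
on the panel scale.  `predict_ivoe` accepts a unit declaration and fails
hard on mismatch so a caller cannot silently feed percent into a
fraction-scaled coefficient.  Whether the original fits used raw,
control-relative or replicate-mean adhesiveness is unknown; this is a
documented limitation, not resolvable without the raw data.

`evaluate` reports the squared Pearson correlation between predicted and
observed (affine-invariant, the calibration sense of R²) alongside the
calibration line; it is deliberately distinct from the fit-time
coefficient of determination, and both are labelled.

## Synthetic data

The generators define the test conditions; all are deterministic given
their seed and emit ground truth from the generated labels, never by
re-running the analysis under test.

* **Images** (default 320 × 240, 350 elliptical grains): the whole frame
  is grain-textured (the protocol images only rice), so any yellow
  fraction in [0, 1] is achievable; whole grains are colored yellow in
  seeded order and topped up pixel-wise so the ground-truth count equals
  `round(fraction · H · W)` exactly.  Yellow pixels draw hue from
  (0.09, 0.145) — inside the band but clear of the 0.167 threshold —
  with saturation 0.30–0.55; non-yellow pixels are blue-tinted
  near-white (hue ≈ 0.6).  Channel noise (sd 1.5) and 8-bit quantization
  therefore cannot flip a class, and noiseless recovery is exact.  The
  generator emulates class structure and grain texture only — not gloss,
  specular highlights, uneven illumination or chromatic aberration — so
  passing recovery tests demonstrates the classifier's arithmetic, not
  robustness to real optics.
* **Curves**: piecewise-linear two-cycle profiles (triangular
  compressions, triangular adhesion dip) with closed-form areas; the
  sample grid (default 200 Hz) is unioned with the breakpoints so
  trapezoidal integration and the peak are exact to float precision.
  Real curves are smooth and noisy; the optional additive noise covers
  sensitivity checks but no rheological realism is claimed.
* **Panels** (default 322 varieties × 2 years × 3 replicates): per-trait
  variety effects with variance σ²G = 0.15 and variety × year deviations
  with σ²E = 0.05 (so component-trait h² = 0.75), a common factor giving
  the three IVOE-relevant traits pairwise correlation 0.5, small year
  main effects, and replicate-level measurement noise (sd 0.1).  IVOE is
  generated from the published Model-1 structure
  (0.20, 0.35, 0.59, intercept 0.13) with residual noise calibrated at
  run time so the latent model's cell-level R² is 0.87.  Trait means sit
  in the slightly negative range typical of panels judging against a
  premium reference; scores are clipped to [−3, 3] with the clipping
  rate reported (< 1% at defaults).  Note the *IVOE* trait's own
  heritability is lower than 0.75 because the model residual adds
  environmental variance; recovery studies therefore estimate h² on a
  component trait, with replicate noise off and one replicate so the
  generating h² is exact.

## Problem sizes and runtime

The recovery studies run at the study's own scale where that is cheap
(322 × 2 panels, 200 simulation repeats, 50 curve specs, 20 images) and
at 320 × 240 frames rather than the instrument's 3264 × 2448 — the
classifier is resolution-independent (per-pixel, permutation-invariant),
so frame size only scales pixel count.  The whole suite runs in well
under a minute on one core.

## Known limitations

* The hue-threshold rule inherits the achromatic-hue ambiguity described
  above; behaviour on genuinely achromatic pixels differs between the
  literal rule (yellow) and the gated rule (not yellow), and which the
  original imaging script used is unknown.
* Units of published adhesiveness values are unstated at source, so
  printed A3 magnitudes (e.g. ≈ 1366 vs ≈ 300 for high- vs low-viscosity
  samples) are illustrative context, not assertable targets.
* Field-data correlations (year-to-year trait correlations, yellow-area
  vs appearance r, adhesiveness vs viscosity r, hold-out model R²)
  require the undeposited raw data and are out of scope; the synthetic
  recovery studies stand in for them as property checks.
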