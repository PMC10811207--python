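# Methods

## The analysis problem

Diet–mental-health associations are usually estimated by regressing a
symptom score on a composite diet index such as the Dietary
Inflammatory Index (DII). Adjusting such a regression for the foods and
nutrients behind the index is statistically awkward: nutrient intakes
are *exact* linear functions of food intakes (through the composition
matrix), foods are strongly co-consumed, and the number of dietary
regressors can approach the sample size. A conventional
adjust-for-everything OLS fit is then unstable — enormous standard
errors and sign flips — while omitting the adjustment confounds the
index effect with non-inflammatory pathways of the same foods.

`diimlm` implements the hierarchical (semi-Bayes) alternative: exposure
coefficients are themselves modelled through second- and third-stage
design matrices, and their deviations from those predictions are shrunk
empirically.

## The three-level model

For participant ``i``, outcome ``y`` (a DASS-42 subscale total),
covariates ``C``, standardized food grams ``F`` (participants × J),
standardized composition bridge ``Z`` (J × I), and inflammatory effect
scores ``w`` (I):

    y = α + C·c + F·β + ε            ε ~ N(0, σ² I)      (level 1: foods)
    β = Z·π + δ                      δ ~ N(0, τ²_food I)  (level 2: nutrients)
    π = w·γ + θ                      θ ~ N(0, τ²_nut  I)  (level 3: DII)

Marginally this is a Gaussian linear mixed model

    y = X·b + F·δ + (F·Z)·θ + ε,     X = [1, C, x/s],  x = F·Z·w,

with marginal covariance ``V = σ²I + τ²_food F Fᵀ + τ²_nut (FZ)(FZ)ᵀ``.
The DII composite ``x`` is normalized to unit sample SD (``s``), so the
reported coefficient γ is the change in the outcome per 1 SD of the
inflammatory composite; the raw-scale coefficient is kept alongside.
Because the outcome is Gaussian with identity link, penalized
quasi-likelihood estimation coincides exactly with linear-mixed-model
estimation, so the package solves the mixed-model (Henderson) equations
directly rather than iterating a quasi-likelihood approximation.

Estimation details:

* **GLS via the Woodbury identity.** All solves reduce to q × q linear
  algebra with ``q = J + I`` (the stacked random-effect dimension),
  using precomputed Gram blocks, so a fit at n = 3,500, J = 116,
  I = 25 takes well under a second.
* **Variance components** are estimated by restricted maximum
  likelihood, profiled over the fixed effects and σ². The search runs
  over log variance ratios ``λ = τ²/σ²`` with Nelder–Mead from four
  starting points (log λ ∈ {−6, −2, 0, 2}); ratios driven to the lower
  bound (log λ = −30) are clamped to τ² = 0 and flagged as boundary
  estimates. By default a single common τ² is shared by both levels,
  matching the "common variance" convention of empirical-Bayes
  multilevel exposure modelling; ``shared_tau2=False`` estimates the
  levels separately.
* **Empirical-Bayes residual effects.** δ̂ and θ̂ are the posterior
  means ``τ² Uᵀ V⁻¹ (y − X b̂)``; shrunken food and nutrient
  coefficients are rebuilt as ``π̂ = w γ̂ + θ̂``, ``β̂ = Z π̂ + δ̂``.
  Food coefficients are reported both per SD of grams and
  back-transformed to input units.
* **Fixed variance components** (used by the oracle tests and the
  shrinkage limits) bypass REML; with a fixed τ² but free σ² the
  profiled residual variance is found by fixed-point iteration
  (relative tolerance 1e-8, max 200 iterations, both configurable).
* **Intervals.** Conventional fits report normal Wald intervals
  (± 1.96 SE). For the hierarchical DII coefficient the interval and
  p-value use Student's t with *containment* degrees of freedom,
  df = I − 1 (the composite lies in the span of the nutrient-level
  random design, so its information comes from the I nutrient units;
  with a single nutrient the containing level is foods, df = J − 1).
  This is the convention of the multilevel software this model mirrors,
  and it is what keeps the interval calibrated: the plug-in-normal
  version ignores the variance-component uncertainty that matters
  precisely because I is small, and in the calibration study below it
  covers only ~92–93% instead of 95%. No multiplicity adjustment is
  applied across the three outcomes.

Limits that anchor the implementation: at τ² = 0 the model collapses to
OLS on the composite (β ≡ Z w γ exactly); as τ² → ∞ the shrunken food
coefficients converge to the unpenalized food-level OLS fit. Both are
asserted in the test suite, along with exact agreement (1e-8) with a
dense brute-force GLS using the explicit marginal covariance.

## Conventional comparators

* ``fit_simple`` — OLS of the outcome on the DII score.
* ``fit_multiple`` — OLS on [covariates, DII, nutrients, foods].
  Because nutrient intakes are exact linear combinations of food grams,
  this design is always rank deficient; aliased columns are removed by
  an order-preserving Gram–Schmidt rank filter (relative tolerance
  1e-10) so that columns earlier in the priority order (intercept,
  covariates, DII, nutrients, foods) are never the ones dropped. A
  magnitude-pivoted QR would occasionally sacrifice the DII column
  itself, which is the one coefficient the analysis is about.

``compare_models`` puts the three DII coefficients on a common
per-1-SD-of-regressor scale before contrasting CI widths, since the
hierarchical γ is measured per SD of the composite while the
conventional models use the DII score's own units.

## DII engine

Standard construction: per-parameter z-score against a global reference
mean/SD, centered percentile (2·P − 1 ∈ [−1, 1]), multiplied by the
parameter's overall inflammatory effect score, summed over parameters.
Choices:

* Percentile transform defaults to the standard-normal CDF (the
  original construction); ``empirical`` mid-rank percentiles
  ((rank − 0.5)/n) within the cohort are available since study reports
  are often ambiguous about which was used.
* A scalar ``units_scale`` (default 1.0) rescales intakes before
  standardization for reference tables on a different units basis; no
  hard-coded per-100 g factor.
* Quartiles are rank-based with ties to the lower quartile
  (deterministic).
* Energy is an ordinary DII parameter; no energy-residual adjustment is
  applied.
* The packaged reference table generator produces *synthetic* global
  means/SDs/effect scores — plausible in scale only. Any real reference
  table (e.g. transcribed literature values) can be supplied as a CSV
  with columns ``parameter, global_mean, global_sd, effect_score``.

## FFQ intake and eligibility

Daily grams = frequency × portion / days-in-period with day = 1,
week = 7, month = 30.44, year = 365.25 (the questionnaire convention is
rarely stated; these are the astronomical means). Nutrient intake is
the exact matrix product (grams/100) × composition; foods missing from
the composition matrix are a hard error, since silently dropping them
would bias every DII downstream. The ±3 SD daily-energy exclusion is
single-pass: mean and sample SD (ddof = 1) are computed once over the
full sample and applied once, not iterated to convergence. A zero-SD
cohort excludes no one.

## DASS-42 scoring

Each subscale total is the sum of its 14 item responses (0–3), giving
totals in [0, 42]. The standard DASS-42 item→subscale key ships with
the package and is overridable. Missing responses are an error by
default; an explicit ``prorate_missing`` flag rescales the mean of
answered items to 14 items for users who want a prorated total.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with
ground truth recorded for recovery tests:

* **Scale defaults**: 3,550 participants examined, 116 foods, 25
  dietary parameters, an outlier fraction of 49/3550, outcome
  intercepts (13.57, 6.20, 8.04) and noise SD 8 chosen to match
  reported subscale means/SDs, and true hierarchical DII effects of
  3.552/4.264/3.021 per 1 SD of the composite for
  stress/anxiety/depression.
* **Intakes** are log-normal per food with a compound-symmetry latent
  correlation (default 0.4; 0.9 reproduces a strongly collinear diet),
  reflecting that pro- and anti-inflammatory foods are consumed
  together. FFQ records are emitted in long format (period mixture of
  day/week/month/year) and round-trip exactly to the generated grams.
* **Composition** is ~70% sparse and non-negative; every food carries
  energy; columns are rescaled so the cohort mean intake matches the
  reference global mean, centering the z-scores the way a matched
  reference would.
* **Coefficients** are built exactly as the model assumes:
  δ ~ N(0, food_residual_sd²), θ ~ N(0, nutrient_residual_sd²),
  π = w γ_raw + θ, β = Z π + δ, with γ configured per 1 SD of the
  composite. Residual-SD defaults (0.05) keep the random food/nutrient
  contributions at a realistic few score points once accumulated over
  ~100 correlated foods.
* **Covariates** are a reduced demographic set (gender, two continuous
  composites, ordinal education/smoking/socio-economic scales, four
  binary diseases) with marginal frequencies patterned on a large
  university-employee cohort, generated independently of diet.
* **Energy outliers** are planted in the upper tail only (energy is
  bounded below, so a robust low-tail plant is impossible) and escalated
  until the single-pass ±3 SD rule flags exactly the planted set —
  raising the planted energies inflates the cohort SD, which pulls
  natural tail values back inside the fence. The generative
  standardization of food grams uses the non-outlier participants, so
  the post-exclusion analysis sees exactly the generative scale.
* **Outcomes** are generated continuous, then clipped to [0, 42] and
  rounded for the DASS tables; item responses are distributed to sum
  exactly to the clipped totals. Calibration studies score the pre-clip
  values, so their statements concern the linear model rather than the
  mild censoring at the scale ends.

What the generator does *not* emulate: named dishes or portion-size
conventions, diet–covariate confounding, measurement error in the FFQ,
item-level DASS response structure beyond the totals, seasonality, or
misreporting. Passing recovery tests therefore demonstrates correctness
of the estimators under the model's own assumptions, not robustness to
real-data violations of them.

## Calibration studies (problem sizes)

* CI coverage: 500 replicate cohorts at n = 2,000 with the generator's
  default conditions; the Wald 95% interval for γ should cover the true
  effect 93–97% of the time.
* τ²_food recovery: 100 replicates at n = 2,000 with 50 foods and
  τ²_food = 1; the median REML estimate should land in [0.7, 1.3].
* CI-width contrast: 200 replicates at n = 500 with intake correlation
  0.9 (40 foods, 12 nutrients); the hierarchical interval should be
  narrower than the conventional multiple model's in ≥ 95% of
  replicates.

## Known limitations

* Wald intervals ignore the uncertainty in the REML variance
  components; at the default study sizes this is negligible, at much
  smaller n it is not.
* The shared-τ² default ties two scientifically different variances
  together; use ``shared_tau2=False`` when the levels plausibly differ.
* Mixed fixed/estimated variance specifications (one level fixed, the
  other estimated) are not supported.
* The cross-sectional linear model makes no causal claims; covariate
  adjustment here demonstrates mechanics, not confounder sufficiency.
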