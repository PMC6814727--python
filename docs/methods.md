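# Methods

## Problem and pipeline

Smallholder ("scavenging") poultry performance depends strongly on the local
environment: feed comes largely from foraging, so climate, elevation and
cropping intensity shape growth.  phenodist implements a *phenotype
distribution model* for this setting: instead of modelling where birds can
live (presence-only habitat models), it models how heavy they are expected to
get as a function of the environment, and maps that expectation over a
landscape.

The pipeline has five stages:

1. **Cleaning.** Field data are biweekly *group* weighings (total weight of
   `n_birds` birds per household).  These are converted to average individual
   weights by exact division, then filtered: observations below 50 g are
   dropped, households ever reporting more than 30 birds are dropped
   entirely, and observations before 6 weeks of age are dropped.  All three
   boundaries are strict (exactly 50 g / 30 birds / week 6 are kept).  The
   kept set does not depend on filter order because the rules are
   independent predicates; the removal log attributes each removed record to
   the first matching rule, in the order above.
2. **Least-squares means.** Within a breed and age phase (males growing,
   weeks 14–19; females growing 14–19 and adult 20–72, bounds inclusive),
   average weight is regressed on week with a *common intercept* (all chicks
   share hatch weight) and a *household-specific slope*, by ordinary least
   squares.  Each household's LSmean is the model prediction at the
   phase-average week (the mean week over all records of the phase), which
   adjusts for households having been weighed at different ages.  SEs
   propagate the coefficient covariance through `beta0 + s_h * w`, with
   residual variance on `n - (1 + H)` degrees of freedom (floored at 1).
   Rank-deficient designs (e.g. all observations at one week, where
   intercept and slopes are confounded) are solved by minimum-norm least
   squares with a warning rather than an error, so degenerate toys fail
   loudly but controllably.
3. **Boosted additive model.** The household LSmeans are regressed on the 21
   environmental covariates by componentwise L2 gradient boosting with one
   penalized B-spline (P-spline) base-learner per covariate.
4. **Spatial prediction.** The fitted model is evaluated on every grid cell
   whose environment lies inside the training range; out-of-range cells
   (deserts) are masked.  Per-region summaries rank regions per breed.
5. **Evaluation.** In-sample Pearson correlations between predictions and
   LSmeans, per region, gated at more than 25 households.

## The boosting core

With response `y` (LSmeans, grams) and covariates `x_1..x_p`:

* Offset `beta0 = mean(y)`; base-learner `j` is the penalized least-squares
  spline fit `c_j = (B_j'B_j + lambda_j D'D)^{-1} B_j' u` of the current
  residual `u`.
* At each iteration all `p` base-learners are fitted to `u`; the one with the
  smallest residual sum of squares is selected and `nu` times its fit is
  added to the ensemble.  Exact ties select the lowest variable index.
* The in-bag risk path records the training MSE after each step; it is
  non-increasing because the smoother's eigenvalues lie in [0, 1] and
  `nu <= 1`.
* Importance: each step's risk decrease is credited to the selected
  variable; per-variable sums therefore add exactly to
  `risk(0) - risk(m_stop)`.
* Early stopping: `m_stop` minimizes the mean out-of-bag MSE over bootstrap
  resamples (default 25; k-fold available).  Base-learner designs (knots,
  lambdas) are fixed from the full data; only coefficients are re-estimated
  per resample.  Ties take the smallest `m`.  The final model is the
  full-data path truncated at `m_stop`.

### Base-learner construction

The training range `[min, max]` of a covariate is split into `knot_count`
equal segments (default 20); the uniform knot grid is extended `degree`
(default 3) knots past each boundary without clamping, giving
`knot_count + degree` basis functions that form a partition of unity on the
range.  The penalty is a second-order difference on adjacent coefficients.
`lambda` is calibrated per covariate by bisection on `log lambda` so the
effective degrees of freedom `trace(B(B'B + lambda D'D)^{-1}B')` equal a
common target (default 4, tolerance 1e-6); equal flexibility keeps
componentwise selection unbiased across covariates.  Outside the training
range the spline is extended linearly from the boundary (value plus
first derivative), so extrapolated basis rows still sum to one; the range
mask, not the extrapolation, is the safety mechanism on maps.

Base-learner fits are not centered: the offset initialisation makes the
first residuals mean-zero, and exact column-centering would put the constant
vector in the null space of both the centered design and the difference
penalty, making the penalized system singular.  Constant covariates are
dropped with a warning (a constant layer carries no spatial signal).

Defaults `nu = 0.1`, 20 segments, cubic splines, second-order penalty,
df 4, 25 bootstrap resamples are conventional for componentwise boosting;
all are configuration, not code.

### A note on the shrinkage limit

For a single base-learner with smoother eigenvalues `s_i`, boosting leaves a
factor `(1 - nu * s_i)^m` of each eigendirection of the unpenalized fit
unconverged.  Convergence to the unpenalized basis regression ("twicing")
is therefore exponential per direction but can be extremely slow in heavily
penalized directions: with the default 23-function, df-4 basis the smallest
eigenvalue is ~1e-8 and thousands of iterations leave visible differences.
The test of this limit uses a compact 8-function, df-5 basis, where 5000
iterations at `nu = 0.1` reach the unpenalized fit to ~3e-8 RMSE.

## Masking and region ranking

A cell is masked `out_of_range` when **any** model covariate at the cell
falls strictly outside the closed interval `[training min, training max]`
of that covariate, computed from the model's own training households (each
breed-by-phase model masks independently).  This is the conservative
reading of excluding areas whose conditions lie outside the tested
environmental range.  `nodata` cells are never predicted.  Region
suitability is the mean (configurable: median, max) of the unmasked surface
per region; the best region is the argmax, alphabetical on exact ties
(flagged).

## Evaluation

Pearson `r` (Spearman behind a flag) between predictions at household
covariates and the household LSmeans, per region; regions with fewer than 3
households report a missing `r`.  `se_r = (1 - r^2)/sqrt(n - 1)` — the
classical large-sample form, which at `r = 0.89, n = 155` gives 0.0168.
Only regions with `n > 25` (strict) enter the median/min/max summary.
Correlations are in-sample (the same households used for fitting);
out-of-sample precision would be lower.

## The synthetic generator

The generator emulates an on-farm breed-testing design: a gridded landscape
of 21 covariate layers (19 bioclimatic summaries, elevation, cultivated-land
percentage), each a Gaussian random field (white noise smoothed with an
isotropic kernel, scale 3 cells by default) affinely rescaled to a plausible
per-variable range; contiguous rectangular regions (vertical strips); one
"desert" strip whose first layer is shifted entirely above that layer's
range elsewhere, so range masking must exclude it; households placed
uniformly on eligible cells, one breed per household, breeds balanced to
within one household after a seeded shuffle.

Growth: birds share a hatch weight (intercept, default 40 g) and differ in
growth rate,

    mu_hw = intercept + rate_h * w
    rate_h = slope_mean + N(0, slope_sd) + (sum_j f_j(x_hj) + b_h) / ref_week

so at the reference week (default 16.5) the environmental and household
contributions to expected weight are exactly `sum_j f_j(x_hj)` and `b_h`
grams.  Tying these effects to the growth rate (rather than a week-0
offset) keeps the common-hatch-weight assumption of the downstream
household model true in the generator; with `residual_sd = 0` the LSmeans
then recover the generator's truth exactly, which the tests assert to 1e-8
relative.  A group weighing of `n` birds reports `n * (mu + eps)`,
`eps ~ N(0, residual_sd)`; `n` is uniform on 3–25 (a delivered flock of
about 25 with attrition).  Normal weighing noise on the mean individual
weight is an assumption of this generator, not a field fact.

Defaults: three active variables (annual mean temperature, annual
precipitation, elevation) with distinct smooth effects (sine, centred
quadratic, smoothstep) of amplitude 120/90/70 g at the reference week;
`household_sd` 40 g, `residual_sd` 30 g, `slope_mean` 58 g/week (roughly
1 kg at 17 weeks and 2.8 kg at 46 weeks), `slope_sd` 2 g/week.  Males are
weighed biweekly from week 6 to 20, females to week 72.

Contamination injects, on disjoint household sets and flagged in a hidden
truth log: records with implied average weight below 50 g at valid ages;
households with one weighing bumped to 31–40 birds (every record of such a
household is contaminated, since the filter deletes households); records at
weeks 2–5 with plausible (>= 50 g) weights so each injected record is
caught by exactly the intended rule.

What the generator does *not* emulate: real climate geography (values are
rescaled random fields), mortality/attrition dynamics, seasonal feed
cycles, sexual dimorphism in growth, or non-linear growth curves.  Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not predictive validity on real field data.

## Problem sizes and numerical choices

* Default pipeline configuration: 30x30 grid, 21 layers, 5 regions (one
  desert), 480 households, 3 breeds, `m_max` 100, 25 bootstrap resamples —
  a full run takes well under a minute on one core.
* The variable-recovery experiment uses a 40x40 grid with 300 households:
  a coarser grid has too few independent spatial patches, making the 21
  smoothed fields collinear over the sampled cells so that inactive layers
  absorb importance credit from the weakest active effect.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns are byte-identical (verified by
  SHA-256 manifests), including CSV round-trips, which use correctly
  rounded float parsing.
* Ties anywhere (variable selection, `m_stop`, best region, nearest cell)
  break to the lowest index / smallest value / alphabetical first, and are
  flagged where scientifically relevant.

## Known limitations

* The environmental stack is an in-house NPZ container; georeferenced
  GeoTIFF import/export is not provided.
* Eq-style additive household intercepts (household affecting the week-0
  weight rather than the growth rate) are intentionally not modelled; the
  common-intercept assumption is taken at face value.
* Correlation SEs use the large-sample formula; no confidence intervals or
  tests on `r`.
* In-sample evaluation only; no cross-validated spatial transfer metric.
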