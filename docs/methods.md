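# Methods

## The problem

Food banks and pantries increasingly rank individual foods into a
stoplight scheme — green (choose often), yellow (choose sometimes), red
(choose rarely) — using per-serving thresholds on saturated fat, sodium
and added sugar within 11 food categories. The ranking says nothing about
a whole *assortment* of food. The gold-standard assortment measure, the
Healthy Eating Index 2015 (HEI-2015), needs full nutrient detail and is
impractical in pantry operations. This package implements the bridge: it
learns weights for the three tier percentages that best predict HEI and
rescales the result into a single 0–100 score, the Charitable Food
Nutrition Index (CFNI), that can be computed from a stoplight inventory
alone.

## Tier ranking

An item's tier is decided per nutrient by inclusive cutoffs
(`value <= green_max` → green, `<= yellow_max` → yellow, else red) and
aggregated by the **worst nutrient**: one disqualifying nutrient sets the
rank. Inclusive comparison follows the "no more than" phrasing
conventional in nutrient guidelines; both choices are configuration-level
conventions and the thresholds file can be swapped without touching code.
Condiments/cooking staples and miscellaneous foods are never ranked and
are removed from numerator *and* denominator before any cart measure, so
a cart's three percentages always sum to 100 over its ranked weight.
Carts with no ranked food at all have undefined percentages and are
dropped with a logged warning.

The bundled `her_thresholds.yaml` is a default transcription in the
structure of the charitable-food guideline family (SWAP-aligned);
deployments tracking a specific guideline revision should supply their
own file. All tests that depend on concrete cutoffs use an explicitly
stated toy configuration.

## HEI-2015 engine

Scoring uses ratio-of-totals densities: constituents are summed over the
cart, then divided by total energy. Three density bases are supported —
amount per 1000 kcal, percent of energy (4 kcal/g for added sugar,
9 kcal/g for fat; these conversions are fixed here because they are part
of the scoring definition), and the (MUFA+PUFA)/SFA fatty-acid ratio.
Components score piecewise-linearly between a zero-point and a
full-points density standard, in the adequacy direction (more is better)
or the moderation direction (less is better), and the 13 components sum
to the 0–100 total. Degenerate case: when SFA is exactly zero the
fatty-acid ratio is scored at its limit — full points if any unsaturated
fat is present, zero if the cart has no fat at all — and the event is
logged. The engine is standards-agnostic; `hei2015_standards.yaml`
carries the canonical 13 standards and the tests verify the engine on
small toy standards with hand-computed expectations.

## Weight learning

HEI is regressed on %green and %red (with %yellow the simplex
complement, including it would be collinear):

* **model3** — OLS via the normal equations.
* **model1** — ridge with the penalty chosen by an information
  criterion, `n·log(RSS/n) + w·df(λ)`, where `df(λ)` is the trace of the
  ridge hat matrix (`Σ dᵢ²/(dᵢ²+λ) + 1` for the unpenalized intercept).
  BIC (`w = log n`) is the default because it shrinks more aggressively
  than AIC, matching the intended "regularized, avoid overfitting" role
  of this estimator; AIC is selectable.
* **model2** — ridge with the penalty chosen by seeded k-fold (default
  10-fold) held-out mean squared error.

Ridge is solved in closed form on centered predictors standardized by
their sample SD (n−1), with an unpenalized intercept, and coefficients
are reported on the raw percentage scale; λ = 0 therefore reproduces OLS
exactly. The λ grid is 101 log-spaced points in [1e−4, 1e4]; selection
ties break toward larger λ (more shrinkage).

## The index transform

For a fitted model `HEI ≈ c + b_G·G + b_R·R` and any composition on the
simplex `G + Y + R = 100`,

    c + b_G·G + b_R·R = (c/100 + b_G)·G + (c/100)·Y + (c/100 + b_R)·R.

The three weights are rescaled by their theoretical extremes over the
simplex — `offset = 100·min(w)`, `scale = 100·(max(w) − min(w))` — so the
index spans exactly [0, 100]: whenever green carries the largest weight
and red the smallest, the all-green cart scores 100 and the all-red cart
scores 0. Theoretical (not sample-based) anchoring was chosen so the
formula is a fixed, portable instrument: its value for a given
composition never depends on the sample it is applied to. Note this
implies the index of an *average* composition equals the average index
(the transform is affine), which differs from what sample-based 0–100
rescaling would report for the same data. Reported formula constants are
rounded to 4 decimals; internal arithmetic is full precision.

## Validation

* Pearson correlations of HEI with each tier percentage (t-transform
  p-values, n−2 df).
* HEI quintiles by stable rank (ties by input order; remainder carts go
  to the lowest-index quintiles, so n = 503 gives sizes
  101/101/101/100/100), with per-quintile mean compositions and a linear
  trend test treating quintile as numeric 1–5 (unadjusted two-sided
  p-values; a categorical-contrast trend would be a reasonable
  alternative but the numeric regressor is the simpler default).
* 5-fold cross-validated correlation: seeded random partition into folds
  whose sizes differ by at most 1; each fold is scored by an index built
  from a model fitted on the other folds. Because the index is an affine
  rescaling of predicted HEI, each fold correlation equals the
  correlation of predicted with observed HEI exactly. The SD over the
  five fold correlations uses the sample (n−1) formula.

## Synthetic data

**Composition level.** (G, R) are bivariate normal with means
(50.1, 23.9) and SDs (14.1, 12.4); Y = 100 − G − R; draws with any
component outside [0, 100] are rejected (rejection preserves moments
better than clipping). HEI is the generating plane
`56.72 + 0.270·G − 0.278·R` plus Gaussian noise, truncated to [0, 100]
since the index is bounded; under the defaults fewer than 1% of draws
are affected (asserted by simulation). A symmetric Dirichlet was
rejected as the composition sampler: moment matching shows the target
signal fraction needs corr(G, R) ≈ −0.69, stronger than a Dirichlet can
reach (≈ −0.56).

Two parameters are not fixed by the study conditions and are calibrated
by moment matching (`calibrate_generator`): the G–R correlation solves

    b_G²σ_G² + b_R²σ_R² + 2 b_G b_R ρ_GR σ_G σ_R = (ρ·σ_HEI)²

for a target index–HEI correlation ρ = 0.585 and HEI SD 11.4, giving
ρ_GR ≈ −0.690 and noise SD `11.4·√(1 − 0.585²) ≈ 9.246`. Simplex
truncation attenuates the realized predictor variance slightly, so the
simulated correlation sits a little below the analytic target (about
0.56 at n = 50 000, verified by Monte-Carlo within ±0.03); this
attenuation is a property of the stated construction and is left as is.

**Item level.** A seeded catalog draws per-serving nutrients from
per-category normal distributions (clipped at zero) and per-pound
constituent densities from coarse plate-level templates. Carts hold
5–80 items; each cart always contains at least one condiments item so
the not-ranked exclusion path is exercised. Carts differ in a latent
healthiness preference (softmax tilt over a catalog-wide health score)
— without it every cart samples the catalog identically and the
between-cart composition signal that the fitting stage needs would
vanish. The item-level generator emulates structure (categories,
exclusions, additive constituents, green-HEI association), not the
study's marginal numbers; the composition-level generator is the one
calibrated to those. Neither models real food co-occurrence,
seasonality, or inventory dynamics, so passing tests demonstrate the
machinery, not distributional realism.

## Problem sizes and determinism

Default analyses run at n = 503 carts; recovery checks average 20
simulation replicates, and calibration checks use 50 000 draws. All
randomized operations take an explicit seed (default 20220921, recorded
in every report); reports serialize with stable key order and
6-significant-digit floats, so a fixed seed yields byte-identical
output.

## Known limitations

* The default tier thresholds are a structural stand-in, not an official
  transcription of any specific guideline revision.
* The HEI engine collapses the upstream 28-ratio constituent bookkeeping
  of nutrition-software exports into the 13 component densities; the
  mapping from richer exports to the 15 constituent fields is the
  caller's responsibility.
* Exact ridge coefficients under information-criterion selection depend
  on the grid and criterion convention; other software makes other
  choices, so coefficient-level agreement across tools is approximate
  even on identical data.
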