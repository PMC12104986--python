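# Methods

## The estimation problem

Presence-only records tell us where a species was seen, not where it is
absent. The package treats the landscape as a finite set of grid cells and
models the *distribution of presences across cells* as a Gibbs (maximum
entropy / log-linear) density constrained by environmental features: among
all densities whose feature expectations match the presence sample, the
fitted one is closest to uniform. Equivalently, the coefficients β
maximize the penalized log-likelihood of the presences under
`raw(x) = exp(βᵀf(x))/Z`, with Z summed over a background sample that
characterizes the available environment.

Assumptions worth stating plainly:

* the background sample represents availability (we sample cell centroids
  uniformly over valid cells; presences are not excluded);
* sampling effort is spatially unbiased once records are thinned to one
  per cell — residual survey bias is *not* modelled (no bias layer is
  applied by default, although the virtual-species sampler accepts one);
* predictors are meaningful at the grid resolution, and transfers in time
  hold the species–environment relationship fixed.

## Features and penalties

Continuous predictors are min–max scaled to [0, 1] on the training data.
Feature classes: linear, quadratic, pairwise products of distinct
continuous predictors, forward/reverse hinges `max(0, (v−t)/(1−t))` /
`max(0, (t−v)/t)` and step functions `1[v > t]` at empirical quantile
knots (default 50 per variable per direction; the demo uses 8 to keep a
64 × 64 example fast), and one indicator per observed class of a
categorical predictor (always expanded, whatever the requested classes).

The L1 penalty per feature is `λ_j = m · base(class_j, n) · sd_j/√n`,
where `m` is the global multiplier, `n` the presence count, `sd_j` the
feature's standard deviation over presences (floored at 1e-4 so constant
features are not free), and `base` the published per-class default tables
interpolated by sample size (linear/quadratic/product 1.0 → 0.05 as n goes
10 → 100; hinge 0.5; threshold 2.0 → 1.0; categorical 0.65 → 0.25). These
tables are exposed in `features.regularization_base` so deviations are
explicit.

Fitting splits each coefficient into positive and negative parts and runs
bound-constrained L-BFGS-B on the exact objective (no smoothing of |·|);
tolerance 1e-9 on relative objective change, at most 10,000 iterations,
coefficients below 1e-8 counted as zero. The objective is convex, and on
tiny discrete problems the optimum is verified against an independent
nested grid search in the test suite.

One consequence of these defaults worth knowing: with a few hundred
presences the penalty (~1e-3) is much smaller than the sampling noise of
the presence feature means (~1e-2), so "no-signal" data yield small but
non-zero coefficients; what is guaranteed is that the *fitted
distribution* stays near uniform, and that presences identical to the
background give exactly β = 0.

## Outputs

`raw` sums to 1 over the training background. The cloglog transform
`1 − exp(−e^H · raw)` (H = entropy of the fitted raw distribution) maps to
(0, 1) and anchors interpretation: a cell whose expected abundance is one
individual scores 1 − 1/e ≈ 0.632. Predictions onto new stacks can clamp
out-of-range predictor values to the training range; clamping is off for
within-range prediction and on for scenario transfers.

Variable importance is reported two ways: *permutation importance*
(shuffle one variable jointly across presences and background, rebuild all
its features, measure the training-AUC drop, average over permutations,
normalize to 100) and *percent contribution*, a coefficient-magnitude
proxy `Σ |β_j| · sd(f_j)` over the background per variable, normalized to
100 (product features credit half to each variable). The original
sequential-optimizer bookkeeping of contribution is path-dependent and not
reproducible from a formula, so the proxy is a deliberate substitute;
rankings, not decimals, are the meaningful output.

Response curves sweep one variable across its training range with the
other continuous variables fixed at their background mean (median
optional) and categorical variables at their mode.

## Predictor screening

The Pearson matrix is computed at a fixed seeded sample of 10,000 valid
cells (bounded cost; the sampling basis is configurable). While any pair
of continuous predictors has |r| above the threshold (default 0.7), the
variable with the highest mean absolute correlation to the remaining ones
is removed — unless it is on the priority list, in which case its partners
go. Ties remove the lexicographically later name, making runs
deterministic. Categorical predictors are exempt (Pearson is undefined on
nominal codes) and always kept. Two priority variables violating the
threshold with each other raise an error rather than being silently
resolved. After selection, variance inflation factors
(`1/(1−R²)`, OLS of each kept predictor on the others) are reported, with
a warning at ≥ 5. The same pruning loop can be run directly on a supplied
correlation matrix (`env.select_from_matrix`) for audits and worked
examples — necessary because some textbook example matrices are not
realizable as data.

## Evaluation and model choice

Spatial blocks are the four quadrants around the median presence
longitude/latitude (k-means on coordinates available for other k);
background points follow the same split. Each fold trains on three blocks
and validates on the fourth. Metrics:

* AUC — rank-based, ties count ½;
* AUC_diff — |train − validation| AUC, an overfitting gauge;
* AICc — `2k − 2lnL + 2k(k+1)/(n−k−1)` with k = non-zero coefficients and
  lnL the presence log-likelihood under raw standardized over the
  background (+∞ when n ≤ k+1, so such models cannot win);
* CBI — Spearman correlation between moving-window presence/expected
  frequency ratios and the window midpoints (101 windows, width 10% of
  the reference prediction range). Note the windows overlap heavily, so a
  single null replicate has a standard deviation near 0.3; null behaviour
  should be judged on averages over replicates.

The tuning table ranks all feature-family × multiplier combinations by
AICc (ties: fewer parameters, then lower multiplier). Because step-like
threshold/hinge fits can win AICc while being ecologically implausible,
the final *selection* is made within a caller-chosen family as the
candidate minimizing mean AUC_diff (ties: maximal CBI); response curves
for every candidate are exported for visual inspection rather than scored
automatically.

## Thresholds, classes, scenarios, MESS

MTP is the minimum predicted value at training presences; P10 the 10th
percentile by linear interpolation between order statistics (the quantile
convention is a choice; none is canonical); the fixed threshold is
1 − 1/e. Four classes: High (fixed, 1], Moderate (p10, fixed], Low
(mtp, p10], Negligible [0, mtp] — a cell exactly at a boundary joins the
lower class, fixing the one boundary the "values exceeding 0.632" wording
leaves open. Class areas are cell counts × cell area; percentages are
taken against the full non-nodata extent, and the partition always sums to
that extent exactly.

Scenario projection predicts cloglog with clamping, binarizes at the fixed
threshold, and reports high-suitability km², percent change versus the
present map, and the altitude distribution (min/quartiles/max) of high
cells from a DEM on the model grid. MESS similarity per variable follows
the percentile construction (negative outside the training envelope,
100 at the median, linear in the tail distance beyond the range) with the
surface being the per-cell minimum over variables; constant reference
variables are excluded with a warning.

## The virtual-species generator

Purpose: give every downstream stage a ground truth. Continuous layers are
Gaussian-smoothed white noise fields (length-scale in cells), empirically
whitened and mixed through the Cholesky factor of a target correlation
matrix — achieved pairwise correlations match the target to numerical
precision, so collinearity screening can be tested against constructed
structure. The categorical soil layer thresholds an auxiliary smooth field
at quantiles, giving spatially coherent patches. Truth surfaces compose
per-variable responses (unimodal Gaussian, linear, quadratic, categorical
weights) through a logistic (default) or product link; presences are
drawn cell-wise proportional to suitability × optional bias, with
sub-cell jitter; "future" stacks shift continuous layer means while soil
and terrain stay fixed.

Default truth: unimodal responses on two climate-like variables
(optima 45 and 635, widths 8 and 60, amplitude 5) plus mild soil-class
weights, logistic intercept −8. This makes the species sparsely
distributed — median suitability ≈ 0.15, roughly a fifth of cells above
the 0.632 anchor — so that thresholds, Boyce windows and scenario
contraction are all exercised away from saturation. The demo's severe
scenario shifts the two drivers by ~1.5 landscape standard deviations,
contracting the true range by roughly 90%.

What the generator does *not* emulate: real climatologies' spatial
anisotropy and teleconnections, survey bias and imperfect detection,
non-equilibrium occupancy, or dispersal limits. Passing the recovery
benchmarks therefore shows the estimator and pipeline are correct and
well-calibrated under the stated sampling model, not that any real-data
application is unbiased.

## Benchmark problem sizes

The recovery benchmark uses a 160 × 160 one-km grid (25,600 cells), 500
presences and 20,000 background points with linear+quadratic features —
the background size matching the modelling convention emulated, on a grid
large enough to hold it without replacement. The bundled demo is 64 × 64
with 300 presences, 2,000 background points and 8 hinge knots; the full
5 × 10 tuning grid with 4-fold block CV runs in well under a minute there.

## Known limitations

* Percent contribution is a proxy (see above); only rankings transfer.
* No CRS reprojection: occurrences and rasters must arrive in the grid's
  CRS (labels are compared as strings).
* AICc for presence-background models is itself a convention (likelihood
  over the background-standardized raw output); comparisons are only
  meaningful within a fixed background.
* The iterative |r| screen is greedy; it does not find a maximum
  low-correlation subset, it reproduces the field's standard procedure.
* Block CV with four quadrant blocks can leave folds environmentally
  unbalanced on small landscapes; candidates that fail in a fold are
  excluded and logged rather than imputed.
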