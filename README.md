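# maxsdm

Presence-only maximum-entropy species distribution modelling, built as a
tested, reusable pipeline: occurrence gridding, collinearity-driven
predictor selection, feature-class/regularization tuning under spatial
block cross-validation, threshold-based suitability classification,
climate-scenario range projection, and extrapolation (MESS) diagnostics —
plus a virtual-species generator so the whole workflow can be exercised
and validated offline against a known truth.

It is aimed at ecologists and biogeographers who model sparsely recorded
species (rare trees, relict taxa, poorly surveyed groups) from
opportunistic presence records and gridded environmental layers, and who
need the full decision trail — what was removed, why a model was chosen,
where projections extrapolate — as plain-text artifacts.

## The model

Given presence records and a background sample of the study area, the
package fits a Gibbs (log-linear) distribution over landscape cells

    raw(x) = exp( Σ_j β_j f_j(x) ) / Z,

where the features f_j are transformations of the environmental predictors
(linear, quadratic, pairwise-product, hinge and threshold classes, plus
indicators for categorical predictors), and Z normalizes over the
background so that raw sums to 1. The coefficients maximize the penalized
presence log-likelihood

    (1/n) Σ_i η(x_i) − log Z − Σ_j λ_j |β_j|,
    λ_j = m · base(class_j, n) · sd_j / √n,

with `m` the global regularization multiplier and `base` the published
per-feature-class defaults interpolated by sample size. The optimization
is convex and solved exactly (positive/negative coefficient split +
L-BFGS-B). Suitability is reported on the *cloglog* scale,
`1 − exp(−e^H · raw)` with H the entropy of the fitted distribution, under
which a cell expected to hold one individual scores `1 − 1/e ≈ 0.632`.

Model choice follows a 5 × 10 grid (feature families L, LQ, LQH, LQHP,
LQHPT × multipliers 0.5–5.0) scored by AICc, by the train–validation AUC
difference under 4-block spatial cross-validation, and by the Continuous
Boyce Index; suitability maps are cut at the minimum-training-presence,
10th-percentile and fixed 0.632 thresholds into High / Moderate / Low /
Negligible classes with area accounting; future scenarios are predicted
with clamping, binarized at 0.632, and summarized as percent range change
and the altitude distribution of high-suitability cells.

## Worked example

Generate the bundled virtual species (64 × 64 km landscape, 8 correlated
climate/terrain layers, soil classes, 300 presences, one severe-warming
scenario) and run everything:

```bash
maxsdm simulate demo --seed 7
maxsdm run-all demo/config.yaml
```

or in Python:

```python
from maxsdm.pipeline import make_demo, PipelineConfig, run_pipeline
demo = make_demo("demo", seed=7)
out = run_pipeline(PipelineConfig.from_yaml(demo / "config.yaml"))
```

The run directory then holds, among other artifacts
(`selection.json`, `tuning.csv`, `model.json`, `importance.csv`,
`areas_present.csv`, `scenarios.csv`, suitability/class/MESS rasters):

```
kept:    ['bio4', 'bio15', 'bio12', 'bio3', 'slope', 'aspect', 'soil']
removed: [['bio9', 0.121], ['bio8', 0.133]]
selected: {'classes': 'LQ', 'reg_mult': 2.5,
           'auc_diff': 0.0432, 'cbi': 0.914}
thresholds: {'mtp': 0.0039, 'p10': 0.4660, 'fixed': 0.6321}

     class    km2       pct          variable  contribution  permutation
      High 1247.0      30.4             bio15          60.9         52.4
  Moderate  820.0      20.0              bio4          37.1         39.5
       Low 1836.0      44.8              soil           1.1          5.0
Negligible  193.0       4.7             bio12           0.4          1.7

 scenario    period   high_km2   percent_change
SSP5-like 2071-2100       50.0           −96.0
```

Reading this: the two layers the generator made collinear with the
prioritized climate variables (bio9 with bio4, bio8 with bio12) were
removed by the iterative |r| > 0.7 screen; tuning selected a
linear+quadratic model at multiplier 2.5 with the smallest overfitting gap
(AUC_diff 0.043) and a validation Boyce index of 0.91; the two variables
that truly drive the virtual species (bio15, bio4) dominate both
importance measures; and the severe scenario collapses the
high-suitability range by 96% — close to the 89% contraction of the
generating truth itself.

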