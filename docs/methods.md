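# Methods

`spectransfer` implements a plot-level pipeline for spectral grain-yield
(GY) prediction in winter-wheat breeding trials and for studying how such
models transfer between trials (a *trial* is one field experiment in one
year at one location). This note documents the models, the synthetic data
they are validated on, the numerical choices, and what the validation
does and does not show.

## The prediction model

**Spectral predictor.** The normalized difference red edge index

    NDRE1 = (rho_NIR - rho_RE) / (rho_NIR + rho_RE)

is computed per pixel from reflectance bands centered at 780 nm (NIR) and
700 nm (red edge). It saturates less than NDVI over dense cereal canopies
and tracks canopy chlorophyll and biomass through grain filling. Pixels
where both bands are zero are undefined and become nodata.

**Plot aggregation.** Plot boundary polygons are buffered inward by 0.20 m
(configurable) so boundary pixels — mixed soil/canopy signal, neighbour
overlap — are excluded. Membership is pixel-center-in-polygon: it is
deterministic and reproducible by a trivial oracle. From the NDRE1 pixels
of each plot, 23 statistics form the predictor vector per measurement
date: the 21 quantiles at 5% steps (including minimum, median, maximum),
the mean and the standard deviation. Quantiles interpolate linearly
between order statistics (NumPy's `linear` method); the SD uses the
sample formula (n − 1). Plots with fewer than 10 valid pixels (default)
are omitted: 23 statistics from fewer pixels are degenerate.

**Outlier screening.** Training plots with jointly anomalous predictor
vectors (sensor artifacts, lodged or damaged plots) are removed before
model fitting. The 23·d predictors are standardized, projected onto the
leading principal components (smallest number explaining ≥ 95% of the
variance, capped at 10, deterministic sign convention), and scored with
the classic local outlier factor (reachability formulation) using
Mahalanobis distance in score space — equivalently Euclidean distance on
variance-whitened scores. Zero distances between duplicate points are
floored at machine epsilon so scores stay defined.

The removal threshold on log LOF is the *far-out* Tukey fence
(Q3 + 3·IQR) with an absolute floor of log 2. The inner 1.5·IQR fence is
deliberately not used: log-LOF is right-skewed even for perfectly clean
Gaussian data — after PCA the 23 statistics collapse to one to three
effective dimensions, where boundary points have genuinely elevated
density ratios — and the inner fence was measured to discard 4–10% of
clean plots. The floor encodes that a density ratio below 2 is not
outlying in any practical sense. On clean synthetic trials the combined
rule removes 0.1–0.7% of plots, removes all gross (+10 SD) planted
outliers, and is stable under re-filtering. Filtering is applied to the
training partition only: a deployed model cannot discard the plots it
must predict. If more than 10% of rows would be removed the filter aborts
instead, since that indicates a parameterization problem.

**Regression.** GY is regressed on the predictors with PLS1
(single-response partial least squares), NIPALS variant, after
autoscaling the predictors (mean 0, SD 1) and centering the response.
The only tuned hyperparameter is the number of latent variables,
chosen by 10-fold cross-validation as the argmin of pooled out-of-fold
RMSE over 1…max_latent components, ties broken toward fewer components;
autoscaling is re-estimated inside every training fold. The default
search range is min(20, n_predictors, n_train/2). One CV pass is used
(not repeated CV). Fold assignment is a seeded uniform shuffle followed
by a block partition (fold sizes differ by at most one). Coefficients
are reported on the original predictor scale with an intercept, so
prediction is a plain affine map; models serialize to JSON for audit.
With as many components as the predictor rank, PLS1 predictions coincide
with least squares (verified to 1e-8 against an independent solve);
rank-deficient requests are reduced with a warning.

The modelling surface follows the statsmodels convention:
`PLSYieldModel(endog, exog)` with `fit(n_latent)` / `fit_cv()` returning a
results object with `params`, `cv_rmse`, `predict` and `summary()`.

## The transfer experiment

All ordered train × test trial pairs are evaluated, classified by shared
year/location: WYWL (within year, within location — the same trial),
WYAL, AYWL, AYAL. For a 2-location × 3-year campaign this is 36 cells
(6/6/12/12). WYWL models are evaluated on a held-out random 20% of the
trial's harvested plots (seeded, unstratified, one split per trial so all
date modes share it); across-trial models train on all usable plots of
the train trial and are evaluated on all harvested plots of the test
trial.

**Date matching.** Measurement dates are paired by least day-of-year
difference, ignoring calendar year. Ties go to the earlier test date. A
test date claimed by several train dates is kept only for the closest
claimant (earlier train date on ties); other claims are dropped and
logged — this prevents one test date from leaking into several
positionally aligned predictor blocks. Stage labels "SS_TT" concatenate
the train and test Zadoks stages ("NA" if missing).

**Date modes.** Per matched-pair list of length n: each individual date;
date increments i = 1…n−2 (the first i+1 pairs in temporal order); and
the full-season "all times" model. Test-matrix columns are renamed
positionally to the train columns, so column j of the test matrix always
holds the test date matched to train pair j. The outlier filter runs on
each mode's own training matrix. Pooled multi-trial ("global") training
is out of scope by design.

**Metrics.** R² is the squared Pearson correlation of observed and
predicted yield — deliberately not 1 − SSres/SStot, because breeding
applications need relative ranking of genotypes and tolerate level
shifts. The systematic components are reported separately: bias =
mean(predicted − observed) and offset = intercept of the least-squares
regression of observed on predicted; RMSE, RRMSE_mean (= 100·RMSE /
mean observed, %) and MAE complete the set. These sign conventions are
emitted with the results metadata. Combination types are compared by
one-way ANOVA with Tukey's HSD at α = 0.05 and an insert-and-absorb
compact letter display, treating each train × test combination's metric
as one observation.

## The synthetic campaign generator

No public plot-level dataset couples multispectral rasters, plot
polygons and breeding-trial yields across multiple years and locations,
so validation runs on simulated campaigns with known ground truth.

Each trial is a regular grid of rectangular plots (default 1.5 m × 8 m —
a typical breeding-plot footprint; plot size is configurable because
real layouts vary), with every fifth row (1-based rows 1, 6, 11, …) sown
to one of two reference cultivars and all other plots unreplicated. Plot
yield is `gy_mean + g(genotype) + eps`, with genotype effects N(0, 6²)
dt/ha and plot residual N(0, 4²) dt/ha by default. Per measurement date
d, standardized plot NDRE1 is constructed as

    z_d = rho_d * z_GY + sqrt(1 - rho_d^2) * eta_d,   eta_d ~ N(0,1) iid,

so corr(NDRE1, GY) = rho_d in expectation, then mapped to NDRE1 units by
a stage-dependent seasonal mean level, a between-plot SD of 0.06, and a
trial-level additive offset, and clipped to [−1, 1] (a warning fires if
clipping threatens the target correlation). Pixel values are the plot
mean plus N(0, 0.05²) noise, either as per-plot pixel samples (default
64 pixels, desk scale) or rendered into full two-band reflectance
rasters at 5 cm pixel size (within the 3–6 cm range of typical UAV
orthomosaics) with NIR + RE fixed at 0.8. Randomness uses one master
seed per trial with fixed-offset substreams, so adding dates does not
perturb earlier dates and identical configs are bit-identical.

The default six-trial campaign reproduces the study layout: two
locations ("HZ", "MR") × three years (2020–22) with the published UAV
measurement dates and growth stages (8, 9, 7, 6, 8 and 13 dates),
harvested-plot fractions matching the reported plot counts (10–35%
unharvested), higher yield levels in the favourable 2021 season and at
the better-soil MR site, and trial-specific NDRE1 level offsets. The
default seasonal signal curve rises from rho ≈ 0.1 at tillering to a
plateau of 0.85 at anthesis/early milk ripeness (Zadoks 65–75) and
declines through dough ripeness, matching the published seasonal pattern
of spectral-yield correlation.

**What the generator does not emulate:** photogrammetric and
illumination artifacts, band co-registration error, spatial soil trends,
weeds/disease/lodging processes (late-season disease is only expressible
as reduced rho_d), and — importantly — non-random harvest missingness:
real unharvested plots are selected by pathogen scores and lodging,
while the generator censors at random. Passing validation therefore
shows the *pipeline machinery* is correct and calibrated, not that the
field-data accuracies are reproduced; the published accuracies depend on
unreleased data.

## Validation studies and problem sizes

The validation studies (`spectransfer.studies`, also run by
`scripts/acceptance.py`) use desk-scale problem sizes chosen to keep
sampling error well inside the tested tolerances:

- *Parameter recovery*: one 1000-plot trial, seven dates, rho peaking at
  0.85 on date 4. The WYWL individual-date R² profile must peak at that
  date within ±0.07 of rho² = 0.72 (test split holds 200 plots).
- *Offset robustness*: two 1000-plot trials with equal yield levels; the
  test trial regenerated with a +0.08 NDRE1 offset. Because PLS
  prediction is affine, R² is essentially unchanged while |bias| grows
  several-fold.
- *Multi-date gain*: two dates with rho = 0.6 and independent noise;
  pooling targets population R² 2rho²/(1+rho²) ≈ 0.53 vs 0.36 for a
  single date.
- *Null calibration*: six 2500-plot trials with rho = 0 everywhere, so
  every test set holds ≥ 500 plots; all 252 grid models must stay below
  R² = 0.05. The type-I behaviour of the Tukey comparison is checked by
  100 seeded label permutations of the 36 full-model R² values (the
  types are exchangeable by construction under permutation; re-running
  hundreds of full campaigns would test the same property at far higher
  cost), requiring a shared letter in ≥ 95% of replicates.
- *Outlier recovery*: five plots shifted +10 column SDs must all be
  removed with ≤ 2% of clean plots lost.

## Known limitations

- The across-trial evaluation assumes the test trial's yields exist for
  scoring; in deployment they are exactly what is unknown.
- Quantile/SD conventions and the pixel-membership rule are documented
  choices, not assertions about what any particular GIS tool does; other
  zonal-statistics implementations may differ at boundary pixels.
- LOF thresholding is distribution-based per training matrix; with very
  small training sets (< ~10·k_neighbors rows) the fence estimate is
  noisy.
- The generator's correlation construction is exact only in expectation
  and before clipping; strong level offsets combined with high pixel
  noise attenuate realized correlations (a warning is emitted).
- No geographic reprojection: rasters and polygons must share a CRS.
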