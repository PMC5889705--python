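# Methods

This note documents the models implemented in `pinyonmap`, the synthetic
study system they are exercised on, the defaults that matter, and the
numerical and design choices that were genuinely open.

## The estimation problem

A map produced by any pixel classifier misallocates area: raw pixel
counts per class are biased by commission and omission errors. The
design-based remedy is to treat the mapped classes as strata, draw a
stratified random reference sample, and re-weight the observed
confusion by the mapped-area weights. With n_ij reference samples of
class j inside map stratum i, n_i· samples in stratum i, and stratum
weight W_i = A_i / A:

- proportion-of-area matrix: p̂_ij = W_i n_ij / n_i·
- reference-class total: p̂_·j = Σ_i p̂_ij, error-adjusted area Â_j = A p̂_·j
- standard error: S(p̂_·j) = sqrt( Σ_i W_i² r_ij(1 − r_ij)/(n_i· − 1) ),
  r_ij = n_ij / n_i·, and S(Â_j) = A · S(p̂_·j)
- overall accuracy Ô = Σ p̂_jj; user's Û_i = p̂_ii/p̂_i·; producer's
  P̂_j = p̂_jj/p̂_·j.

These estimators are unbiased under stratified random sampling by map
class, which is exactly how both the shipped worked example and the
synthetic pipeline draw their assessment samples. Rows of p̂ sum to W_i
and Σ_j Â_j = A by construction; both are asserted in tests. Intervals
are reported as Â_j ± 1.96·S(Â_j) and, separately, the 2·SE margin,
because published area margins use either multiplier; both are labelled
rather than guessed at. A stratum with a single sample and off-diagonal
counts makes the variance term 0/0 and is rejected as an estimation
error. Kappa is computed on raw counts by default; an area-proportion
basis is available, and the two can differ by several points — reports
carry both. An empty reference column makes producer's accuracy
undefined; it is reported as NaN, not an exception.

## The backprop pixel classifier

The mapping stage uses a deliberately classical one-hidden-layer
backpropagation network rather than a modern softmax MLP: logistic
activations in hidden and output layers, squared-error loss summarized
as the RMS error over samples and output nodes, weights initialized
uniform(−0.5, 0.5) from a seed, features min–max scaled to [0, 1] with
constants taken from the training rows only, and training stopped at
the first of RMS ≤ 0.04 or an iteration cap. The target class is coded
one-hot over the four covers; prediction takes the arg-max of the four
output activations (ties broken toward the lowest class index) and the
reported "probability" map is the winning activation's share of the
activation sum.

Defaults: hidden width 8 (not critical; recorded in the model file),
learning rate 0.20, full-batch updates, momentum 0.9, cap 4,000
iterations. The momentum term and the cap deserve a note: plain
full-batch descent at rate 0.20 on this loss needs tens of thousands of
iterations to reach RMS 0.04 on a 2,143-sample training set, whereas
the same loop with momentum 0.9 gets there in roughly two thousand.
Momentum is the textbook cure for exactly this plateau and changes
nothing about the loss, activations or stopping rule, so it is on by
default; setting `momentum=0` restores the plain update. Training RMS
is recorded per iteration; the final value never exceeds the first
(asserted per seed), and identical data, config and seed reproduce
identical weights bit for bit.

Constant training features are rejected by name rather than silently
producing a 0/0 scale. Nodata in any input feature propagates to both
output maps.

## The synthetic study system

The generator emulates the structure of an isolated semi-arid sierra so
that every downstream stage can be validated against known truth:

- **DEM**: a seeded superposition of 14 Gaussian bumps (widths 25–70
  cells) plus low-amplitude white noise, affinely rescaled so the
  minimum and maximum hit 280 and 1,662 m exactly. On the default
  288×288 grid of 10 m cells this relief yields a terrain-ruggedness
  regime of roughly TRI ≈ 18–22 m, slope ≈ 30–38°, VRM ≈ 0.004 — the
  ruggedness scale the association model's coefficients are calibrated
  to. Gaussian bumps were chosen over fractal noise because they are
  smooth enough for meaningful slope/aspect and trivially seedable.
- **Climate surfaces**: mean warm-month temperature (MTWM) is a
  lapse-rate transform of block-mean elevation (8×8-cell blocks by
  default), with seeded block noise, clipped into 23.5–25.2 °C. The
  block-constancy deliberately reproduces the resolution mismatch
  between a coarse climate product and a 10 m scene. MMAX is a nearly
  collinear shift of MTWM (a realistic victim for collinearity
  pruning), and two pure-noise covariates exist solely so screening has
  something to reject.
- **Cover truth**: on cells at or above a 1,010 m eligibility floor,
  pine presence is Bernoulli with probability
  inverse-logit(25.351 + 0.178·TRI − 1.159·MTWM + 28.476·VRM) — a
  positive ruggedness effect, a negative warm-temperature effect.
  Remaining cells are banded on dithered elevation: mostly bare ground
  below ~560 m, scrub to 800 m, chaparral above. The generator refuses
  to emit a scene missing any of the four classes.
- **Reflectance**: each class has a fixed 10-band mean spectrum chosen
  so class NDVI centres sit at 0.355 (pine), 0.26 (chaparral), 0.125
  (scrub) and ~0.03 (bare). Each cell carries a lognormal multiplicative
  brightness factor (sd 0.35 on the log scale) shared across bands —
  the stand-in for topographic illumination, which scales all bands
  jointly and therefore cancels exactly in NDVI — plus independent
  additive Gaussian noise (sd 0.007) per band. The result: per-class
  NDVI distributions match the intended ranges (≥95% of pine cells in
  0.30–0.41; scrub < chaparral < pine medians), while raw band values
  overlap across classes enough that classification is a non-trivial
  problem with a realistic error matrix.
- **Reference samples**: stratified random, without replacement, exact
  per-class counts (defaults 536/764/405/438), seeded. The allocation
  is a free parameter; nothing in the estimators depends on it beyond
  n_i· ≥ 2.

What the generator does **not** emulate: radiative transfer,
atmospheric effects, spatial autocorrelation of class patches beyond
what elevation banding induces, mixed pixels, georeferencing, or the
spectral shapes of real vegetation. Passing tests therefore demonstrate
correctness of the estimators and the training/assessment machinery
under the stated sampling designs — not that the classifier would reach
any particular accuracy on real imagery.

All generator outputs are pure functions of (config, seed); each
operation draws from its own child stream of the scene seed so stages
can be rerun in isolation.

## Terrain metrics

Slope and aspect use Horn's 3×3 finite differences with edge
replication (an optional nodata border is available); aspect is degrees
clockwise from north of the downslope direction, with flat cells set to
nodata. TRI defaults to Riley's sqrt of summed squared centre–neighbour
differences; because GIS packages disagree (QGIS/GDAL use the mean
absolute difference), the sum-absolute and mean-absolute variants are
selectable and the choice is recorded in output metadata. VRM builds
unit surface normals from slope/aspect (flat cells contribute (0,0,1))
and returns 1 − |resultant|/n over a square window, 3×3 by default —
zero on any plane regardless of tilt, which is asserted, as is
agreement of every metric with naive double-loop reference
implementations to 1e-10 on random DEMs.

## Screening and association modelling

Candidate covariates are screened in two deterministic stages: (1) drop
any variable whose two-group Kruskal–Wallis p (chi-square, df = 1, tie
corrected) is at or above α = 0.0005 — the Bonferroni-style threshold
is taken as given rather than derived from the candidate count; (2)
walk the survivors in ascending-p order and, for each pair with
Spearman |r_s| > 0.7, drop the member with the larger p. Processing in
ascending-p order makes the keep/drop outcome independent of input
column order. The full audit trail (H, p, pass flags, every pruned pair
with its r_s) is retained. An empty retained set is flagged, not an
exception. The final model is a single binomial logistic fit on the
retained set (maximum likelihood via IRLS through statsmodels GLM),
reported R-style: estimate, standard error, Wald z, p, AIC, residual
deviance on n − k degrees of freedom. Perfect separation and rank
deficiency raise fit errors naming the offending terms. "Stepwise"
selection beyond this screen is deliberately not implemented; the
screening pipeline plus one final fit is reproducible and sufficient
for coefficient-recovery validation.

The cross-validated random forest uses stratified, seeded k-folds
(default k = 10, 500 trees) and scores each held-out fold at a fixed
0.5 threshold: AUC (rank formulation), sensitivity, specificity,
TSS = sensitivity + specificity − 1 (an identity asserted per fold),
and binary kappa. The forest learner itself is scikit-learn's; the
folds, metrics and report are package code.

## Validation strategy and problem sizes

- The shipped error-matrix fixture reproduces every published
  proportion cell, the column totals, overall/user's/producer's
  accuracies, the error-adjusted pine area (6,654 ha unrounded) and its
  2·SE margin (319 ha) at printed precision — a pure arithmetic check
  with no randomness.
- The analytic SE of p̂_·j is checked against the empirical SD of 2,000
  simulated stratified samples (100 per stratum) from a fixed
  population with the worked example's composition; agreement within
  10% relative.
- Logistic parameter recovery: 20 seeded scenes, 600 eligible-zone
  samples each; each generating coefficient must fall within ±2
  estimated SEs in ≥90% of replicates.
- End-to-end: 20 seeded scene→classify→assess runs on the default
  288×288 scene must keep overall assessment accuracy ≥0.85 and the
  1.96·SE pine-area interval must cover the true synthetic pine area in
  ≥17 of 20 runs.

These problem sizes (288×288 cells, 2,143 training points, 400
assessment points per stratum, 2,000 Monte-Carlo draws, 20 replicates)
were chosen so the full suite exercises every claim in about a minute
while keeping each check's statistical power meaningful.

## Known limitations

- The brightness field is white across cells; real illumination is
  spatially coherent with aspect, which would correlate classification
  errors spatially and widen true area-estimate variability relative to
  the analytic SE (which conditions on the map).
- Eq.-style variance estimation ignores the finite-population
  correction; for assessment samples that are a large fraction of a
  stratum the reported SE is conservative.
- The MTWM surface is clipped into its configured range, so its
  association signal within the pine-eligible zone is weaker than the
  lapse rate alone would give; coefficient recovery still holds because
  the fitted model matches the generating one.
- The classifier is intentionally not state of the art; it is the
  classical network the mapping literature used, implemented exactly.
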