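# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic study does and does not establish.

## Grid model and distances

Rasters follow the common north-up convention: row-major storage, origin at
the top-left corner, square cells, cell-centre registration.  All per-cell
geometric tests (buffering, zonal membership, point-to-cell assignment) use
cell centres.  Geographic grids (degrees) use the haversine great-circle
distance with Earth radius 6371 km; projected grids use planar distance in
CRS units.  The package never reprojects or resamples — input layers must
already share one grid, and assembling a stack verifies shape, origin and
cell size per layer, raising an alignment error naming the first offending
layer.  The nodata mask of a stack is the union of per-layer nodata, so
every retained cell has a finite value in every layer.

Raster I/O uses the single-band ESRI ASCII grid format and zone polygons
are GeoJSON; both are plain text, which keeps every input and artifact
diffable and makes bit-reproducibility checkable with a file hash.

## Occurrence handling

Occurrences are (species, lon, lat) records in WGS84 decimal degrees.
Exact duplicate triples are collapsed at ingestion: duplicates carry no
spatial information for presence-background estimation.  Spatial
rarefaction is a greedy scan in input order retaining a point iff it lies
at least `min_dist_km` from every previously retained point of the same
species; greedy thinning is deterministic, idempotent, and maximal for the
scan order (an optional shuffle-first mode exists for sensitivity checks).
Defaults: 20 km for the target and related beetles, 5 km for host plants.
Rarefaction precedes the train/test split.  Splits draw
round-half-up(`test_frac`·n) test points (so 25% of a multiple of four is
exact) with a seeded generator; replicate r of a replicated fit uses seed
`seed + r`, i.e. repeated random subsampling rather than cross-validation
folds.

Species-level record filters for the richness analysis: host species need
at least 15 records, related beetle species more than 3.  Whether the
host threshold is inclusive ("≥ 15") or strict (("> 15") is configurable;
the default is inclusive.

## The presence-background model

The suitability model is the Gibbs density over the N cells of the
calibration background, P(x) = exp(λ·f(x))/Z.  Features are linear and
quadratic terms (pairwise products optional, off by default) of layers
min–max scaled to [0, 1] by the background range; on transfer,
out-of-range values are clamped to that range and extrapolation risk is
reported separately by MOP rather than hidden by the clamp.

λ minimizes the penalized negative log-likelihood

    −(mean presence score) + log Z + Σ_j b_j |λ_j|,

with the ℓ1 term smoothed as √(λ² + ε), ε = 1e−8, and solved by L-BFGS-B to
projected-gradient tolerance 1e−6 (max 10 000 iterations) from λ = 0.  The
objective is convex, so the optimum is unique up to the penalty's
flat directions and the fit is deterministic.

**Penalty scale.**  The effective per-feature weight is b_j = β·s_j/√m,
where s_j is the feature's standard deviation over the m presence samples
and β (default 0.1) a per-class multiplier.  This is the standard
presence-background convention: the penalty should be commensurate with
the sampling error of the presence feature means it regularizes.  A
constant per-feature weight of 0.1 would exceed the typical presence-mean
gradient on smooth landscapes (features scaled to [0,1] have SDs around
0.15–0.2) and soft-threshold every coefficient to zero regardless of how
informative the data are.  With the scaled form, β → 0 gives the MLE and
β → ∞ gives the uniform model, and increasing β weakly decreases Σ|λ_j|.

**Estimator precision.**  On the synthetic study conditions (100×100 grid,
two layers smoothed to correlation length 10 and z-scored, λ = (2, −1),
m = 500), the Fisher information of a [0,1]-scaled feature gives a
per-coefficient sampling SE near 0.3.  Single fits therefore scatter
around the truth with errors occasionally above 0.5; the *mean* estimate
over 10 independent samples recovers both coefficients within ±0.2, and
every individual fit's suitability surface rank-correlates above 0.8 with
the truth.  Tests check exactly these two statements.

Training gain for the jackknife screen is the mean presence log raw output
minus log(1/N), i.e. the penalized model's improvement over the uniform
null; each layer is scored alone and left-out.

## Thresholding

Both rules operate on the suitability of the training presences under the
median replicate map.  *Minimum training presence* is the smallest training
value; binarizing at it omits no training point by construction.  The *10th
percentile* threshold is the largest training value t whose strictly-below-t
training fraction is ≤ 0.10 — equivalently the (⌊0.1 n⌋+1)-th order
statistic — which guarantees at most 10% training omission for every n and
under ties.  (For n = 20 this is the 3rd-smallest value, omitting 2/20.)
Binary maps are 1 where suitability ≥ t on valid cells.

## MOP transfer diagnostics

For every valid projection cell the MOP distance is the mean Euclidean
distance — on variables z-scored by the calibration mean/SD, since climate
layers have incommensurable units — to its nearest ⌈mobility_fraction·N⌉
calibration cells (k-d tree; exhaustive enumeration reproduces it to
1e−10 on small grids).  Similarity is 1 − distance/max(distance) over the
projection extent.  The default mobility fraction is 0.10.  Strict
extrapolation is flagged wherever any raw variable leaves the calibration
min–max envelope; flagged cells still receive a similarity value.  Note
that with k = 1 (small backgrounds at the default fraction) identical
calibration and projection stacks give zero distances and similarity 1
everywhere; with k > 1 the mean nearest-k distance is positive even for
identical stacks, and only the relative surface is meaningful.
Calibration backgrounds above 20 000 cells are subsampled with a seeded
generator (disabled for the oracle tests).

## Partial ROC

Suitability is first rescaled by its maximum and converted to integers in
[0, 1000] by flooring ×1000 values.  Raw Gibbs outputs are of order 1/N, so
direct ×1000 conversion would floor everything to zero; rescaling by the
maximum preserves ranks, which is all ROC uses (verified by a
rank-invariance test under monotone transforms).  The ROC curve is built
over all 1001 integer thresholds with x = proportion of valid cells
predicted present and y = sensitivity of the test points; only the band
with sensitivity ≥ 1 − E (E = 0.05) is kept, and the statistic is the
trapezoid area ratio of the model curve to the 1:1 line over that band.
Each of 500 bootstrap replicates resamples ⌈0.5·n⌉ test points with
replacement; `n_boot=1, resample_frac=1` is treated as the degenerate
point-estimate mode without resampling.

Significance is summarized two ways: the primary p is the proportion of
bootstrap ratios ≤ 1; secondarily a one-sample t-test of the ratios
against 1, with a Welch (unequal-variance) two-sample form available for
comparing a model's ratio distribution against a null model's.

The band-restricted ratio carries a small positive finite-sample bias:
with 100 uninformative test points the mean ratio sits near 1.01–1.03
rather than exactly 1, so the fraction of null runs with mean ratio ≤ 1 is
well below one half.  The null property tested is therefore |mean ratio −
1| ≤ 0.1 under independence, which holds with wide margin, rather than a
median-centering claim.

## SMCE

Risk aggregation is a nested tree of weighted criteria; every internal
node's child weights must sum to 1 (enforced at construction, tolerance
1e−9), so the composite is a convex combination of standardized leaves and
tree evaluation equals the flat weighted sum with path-product leaf weights
(property-tested on random trees).  Two leaf standardizations: *goal*
(linear min–max, clipped) and *convex*, (e^{a·u} − 1)/(e^a − 1) on the unit
scale with default a = 2 — convex, endpoint-anchored, reducing to the goal
function as a → 0.  Continuous suitability leaves use the convex form
(de-emphasizing the many near-zero raw cells), binary and stress leaves the
goal form (binary leaves pass through unchanged on {0, 1}).

The shipped beetle trees use level-1 weights 0.4 (potential distribution),
0.35 (vulnerable hosts and related species), 0.25 (forest stress), with
0.6/0.4 continuous/binary under the distribution node.  The printed
sub-weights for hosts (0.2), related species (0.3) and binary suitable
area (0.2) cannot sum to one within a node and are renormalized to
2/7, 3/7, 2/7 under their parent; for the species modelled without a
related-beetle group the host node splits 0.5/0.5.  The three stress
factors (plague-insect probability, standing-dead-tree probability,
anthropogenic-impact index) share their node equally, 1/3 each.

Zonal risk is the mean composite over cell centres inside each zone
polygon; zones touching no valid cell get a missing mean and a flag.
Zone means are classed into five equal-frequency (quantile) classes,
"very low" … "very high"; degenerate distributions collapse duplicate
quantile breaks and the remaining classes are assigned from the low end
(an all-constant surface puts every zone in "very low").  "High risk"
reporting uses the top two classes.  Quantile breaks are scale-free but
relative: the classes rank zones within a study and do not carry absolute
meaning across studies.

## Synthetic study

The generator emulates the study inputs on a 0.05° WGS84 grid:
environmental layers are Gaussian-smoothed white noise (kernel width =
correlation length, in cells), z-scored per layer; ground-truth suitability
is a Gibbs density over the same scaled features the model uses, so fitted
coefficients are directly comparable to generating ones (a misspecified
logistic variant exists for robustness checks); occurrences sample cells
proportional to suitability with uniform within-cell jitter; stress layers
are independent smoothed fields squashed through a logistic; zones are
rectangles tiling the extent with lognormal production tonnage.  All
generators are pure functions of their seed.

Default study conditions: a 60×60 fixture grid with two environmental
layers (correlation length 8), 80 presences per target beetle, 40 per
host/related species, 3 hosts, 2 related beetles, 16 zones; model settings
5 replicates / 25% test, 200-km buffer, 20-km and 5-km rarefaction; partial
ROC with E = 0.05, 500 bootstraps, 50% resampling.  The recovery and
evaluation studies use a 100×100 grid (correlation length 10) with
λ = (2, −1), 500 training and 100 test points.  These sizes keep a full
pipeline run around two seconds while leaving every statistic comfortably
estimable.

What passing tests show — and do not.  The synthetic landscapes are
stationary Gaussian fields and the truth is (mostly) within the fitted
model family; real climate and NDVI layers are non-stationary, collinear
and measured with error, real occurrences carry sampling bias that
rarefaction only partially removes, and real host/stress layers are
themselves model outputs with their own error.  Passing therefore
establishes the correctness of the estimators, diagnostics and aggregation
algebra, and the faithfulness of the protocol — not the ecological
validity of any particular real-world risk map.

## Degenerate inputs and tie-breaks

Constant layers: rejected in PCA (zero variance, named in the error);
given unit denominator in feature scaling and MOP z-scoring (they
contribute nothing).  Empty intersections (region vs valid cells, zones vs
raster) raise or flag rather than silently producing empty results.
All-zero suitability cannot be discretized.  Thresholding an all-equal
training list returns that value under both rules.  Ties at the p10
threshold resolve conservatively (the omission bound still holds).  The
median across an even number of replicates is the midpoint average
(numpy convention).

## Reproducibility

Every source of randomness is an explicit seed argument; the pipeline
derives stage seeds from the single configured seed.  Artifacts are
written with fixed numeric formats and sorted JSON keys; the run manifest
records the config, package version and SHA-256 of every input and
artifact, and contains no timestamps, so two runs with the same config are
byte-identical (tested).
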