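# Methods

This note documents the models, conventions and numerical choices behind
`envenomap`, and what the synthetic validation does and does not
demonstrate.

## Spatial data model

All rasters are cell-center registered on a shared `GridSpec` (rows
counted from the north, square cells, half-open cell intervals
`[edge, edge + cell_size)`). Every point→cell mapping goes through one
function, so the convention cannot drift between stages. Two rasters are
co-registered iff their `GridSpec`s are equal; the loaders verify this
and refuse mixed grids.

Distances are great-circle kilometres on a sphere of radius 6371 km for
geographic grids and Euclidean in coordinate units for planar synthetic
grids; the grid's `crs_tag` selects the metric. The distance-to-city
layer measures from each cell *center* to the exact city point, so a
city-containing cell carries a small nonzero value unless the city sits
on the center. Units (km) are recorded in raster metadata.

Nodata uses union-mask semantics: any algebra touching a masked cell
yields a masked cell. Nothing is silently zero-filled.

Raster I/O is multi-band float32 TIFF with GeoTIFF georeferencing tags
(ModelPixelScale/ModelTiepoint) plus a JSON image description carrying
the grid, CRS tag, layer names and nodata convention; NaN encodes
nodata. Round-trips are bit-exact for float32 payloads.

## Occurrence preparation

**Thinning.** The protocol requires a minimum pairwise spacing (default
1 km, matching the ~1 km working resolution). We use seeded greedy
thinning: shuffle points by the seed, then accept each point iff it is at
least `min_dist_km` from every previously accepted point. The result
satisfies the spacing constraint and is maximal (every removed point lies
within `min_dist_km` of a kept one); it is deterministic given the seed
and idempotent. Other maximal subsets exist; the seed is part of the run
configuration precisely so the choice is reproducible.

**Pseudo-absences.** 5000 background points (the protocol default) are
drawn uniformly *without replacement* over the cells of the ecoregions
containing at least one presence, excluding presence cells, and jittered
uniformly within their cell. Excluding presence cells avoids assigning
contradictory labels to one cell; a `--allow-presence-cells` knob
restores unconstrained sampling. Sampling distinct cells rather than
independent coordinates means 5000 backgrounds occupy 5000 cells;
duplicated cells would add no information and distort the weighting. If
fewer candidate cells exist than requested, all of them are used and a
warning is logged.

**Weighting.** Presences carry weight 1 and absences weight
`n_presence / n_absence`, which makes the weighted prevalence exactly
0.5 for any class sizes (an algebraic identity, tested as such). Every
model adapter consumes these row weights.

## Predictor screening

**Topographic heterogeneity** is the population standard deviation of
elevation within an odd `window × window` neighborhood (default 3),
computed mask-aware (masked neighbors are excluded; a cell becomes masked
only when its whole neighborhood is masked; windows truncate at the grid
edge). The heterogeneity literature contains several variants; windowed
SD is the canonical one, and a terrain-ruggedness-index variant
(`metric="tri"`) is provided. The metric and window are recorded in the
output layer name.

**VIF selection.** VIF(p) = 1/(1−R²) from the least-squares regression
of predictor p on all others with intercept (statsmodels OLS; perfect
collinearity reported as infinity). Selection is drop-worst stepwise:
while any VIF ≥ 10, remove the predictor with the largest VIF (ties drop
the later-listed name, keeping earlier-listed predictors) and recompute.
VIF is computed on the training-table rows by default — the collinearity
that matters for fitting is the one in the fitted sample — and can be run
on full-raster values instead.

## Ensemble models

Five member algorithms, all consuming the row weights:

| member | realization | key defaults |
|---|---|---|
| glm | weighted logistic regression on linear+quadratic terms | L2 with C = 1e4 (numerical stabilizer) |
| gam | weighted logistic regression on per-layer cubic B-spline bases | 6 knots, C = 100 |
| gbm | stochastic gradient-boosted trees | 150 trees, depth 3, lr 0.1, subsample 0.8 |
| rf | random forest (weighted bootstrap/impurity) | 250 trees, min leaf 2 |
| maxent | L1-penalized weighted logistic regression on linear, quadratic, pairwise-product and two-sided hinge features (the maxent–penalized-logistic equivalence) | 10 hinge knots per layer at equispaced quantiles; penalty C chosen from {0.05, 0.2, 1, 5} by weighted log-loss on an internal stratified 20% holdout |

Predictors are standardized per model from the training rows. All fits
are deterministic given the seed.

**Metrics.** AUC is the weighted Mann–Whitney statistic (pair (i,j)
weighted by w_i·w_j, ties counted ½). Sensitivity/specificity are
weighted with the `score ≥ t` convention for predicted presence. The
binarization threshold maximizes sensitivity+specificity over the
observed unique scores plus a −∞ sentinel; ties resolve to the smallest
threshold. All four are verified against O(n²) brute-force oracles.

**Evaluation.** Repeated stratified split-sampling: per repetition,
floor(0.7·n) rows of each class train (remainder test), all members are
refit on the training split, the ensemble scores the held-out split, and
we record held-out AUC and TSS at that repetition's max-sens+spec
threshold. Reported AUC/TSS are means over 20 repetitions. Stratification
prevents single-class test sets for species with few records.

**Aggregation and final maps.** The published combination rule for the
five members is a design point we had to fix: the default is the
unweighted mean of member scores, with AUC-weighted mean (weights ∝
member mean AUC, renormalized) as an option; the mode travels in map
provenance. Final maps come from members refit on the full training
table — the 20 repetitions serve only evaluation — and the binary
threshold is computed once on the full-data ensemble scores at the
training rows, not averaged over per-repetition thresholds. The reported
TSS convention (max-threshold TSS on held-out data) is likewise recorded
here because published tables rarely state it.

## Vulnerability

Per species: vulnerability = binary exposure × distance-to-nearest-city
(km), cellwise ("masking" a binary layer with a distance layer and
multiplying by it are the same operation for a {0,1} layer). Combined
exposure across species defaults to richness (sum of binary maps —
cumulative hazard) with union as the alternative; the definition is
recorded in the output because the two differ wherever more than one
species is present. Values are exposure·km and deliberately not
normalized; an optional min–max rescale would only serve cartography.
The per-cell index table carries row/col, lon/lat, exposure, distance
and vulnerability, with quartile summaries.

## Synthetic landscapes and virtual species

The generator emulates the statistical structure of a country-scale
study's inputs at desk scale:

- **Environment:** Gaussian random fields (white noise smoothed with a
  Gaussian kernel, sigma = 6 cells by default, standardized) mixed
  through the Cholesky factor of a requested cross-correlation matrix.
  Achieved correlations are within ±0.1 of the request on grids ≥ 2500
  cells. This is simple and dependency-light; it does not reproduce
  anisotropy, elevation gradients or the heavy-tailed distributions of
  real bioclimatic surfaces.
- **Ecoregions:** a Voronoi partition around random seed cells (labels
  1..n, covering exactly the unmasked cells).
- **Cities:** distinct random unmasked cell centers — real facility
  layers are population-clustered, which this does not mimic.
- **Virtual species:** logistic linear–quadratic responses,
  η = intercept + Σ (b₁z + b₂z²), suitability = logistic(η). The default
  demonstration species, η = 5 − 20(z₁−0.5)² − 20(z₂+0.3)², is a sharp
  unimodal niche occupying roughly 10% of a typical landscape at truth
  threshold 0.5 — the narrow-ranged, strong-signal regime in which niche
  models are expected to discriminate well (the truth scores themselves
  achieve presence/background AUC ≈ 0.95, which bounds any model from
  above). Broader niches lower that ceiling sharply: a species occupying
  ~35% of the landscape caps AUC near 0.79 regardless of the model.
- **Occurrences:** cells drawn with probability proportional to true
  suitability, jittered within-cell; optional Thomas-process clustering
  (offspring scattered around suitability-sampled parents) mimics survey
  clumping and is off by default.

Default desk-scale conditions: 100×100 grid at 30 arcsec (~92×92 km),
5 layers, 4 ecoregions, 8 cities, 300 presences for signal-recovery
runs, 200 for protocol/null runs, 5000 backgrounds, 20 evaluation
repetitions, 5 independent landscape seeds for medians. These sizes make
a full five-member, 20-repetition evaluation a ~1-minute computation per
landscape while leaving every protocol parameter at its production
value.

Passing the synthetic recovery checks shows the machinery is correct and
the protocol recovers known truth under its own assumptions
(environmentally determined occupancy, unbiased detection within the
sampled region, predictors that include the truly relevant ones). It
does not certify performance on real data, where sampling bias,
unmeasured drivers, dispersal limitation and identification error all
operate.

## Reproducibility

A master seed is hashed (SHA-256 over `"{master}:{stage}:{context}"`,
first 4 bytes, mod 2³¹) into per-stage, per-species seeds, so any stage
can be rerun in isolation with the seed the pipeline used. No stage
touches global random state. The run manifest records the config, the
derived seeds and SHA-256 checksums of every artifact; rerunning a
config reproduces identical checksums.

## Known limitations

- Thinning is O(n²) and greedy; for very large occurrence sets a spatial
  index and/or max-independent-set formulations would be preferable.
- The GAM member uses unpenalized-by-default spline logistic regression
  rather than penalized likelihood with smoothness selection; with few
  records and many knots it can overfit more than a classical GAM.
- No reprojection: all inputs must share one grid and CRS.
- Vulnerability ignores population density and road-network travel time;
  straight-line distance to a city is a coarse accessibility proxy.
- The distance raster is exact but brute-force over cities; fine for
  hundreds of cities, slow for tens of thousands.
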