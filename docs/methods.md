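# Methods

This note documents the models and procedures oroniche implements, the
assumptions behind them, the parameters that matter, and the design
choices made where the methodology left the design open.

## Range-overlap similarity

Ranges are compared on a common raster support: each range polygon is
rasterized by the cell-centre rule (a cell belongs to the range iff its
centre lies inside the polygon), which makes every overlap count exactly
reproducible. The Sørensen Similarity Index is

    SSI(A, B) = 2|A ∩ B| / (|A| + |B|)

on cell counts. Because published range layers carry mapping error, a
corrected index divides by an error factor *e*: the SSI obtained by
comparing two independently produced maps of the *same* (focal) species.
We implement

    cSSI = min(1, SSI / e),    0 < e ≤ 1,

so a comparison exactly as similar as the focal self-comparison scores 1.
Division is a design choice — a correction of this form is the only one
that normalises the self-comparison to 1 while leaving disjoint ranges
at 0; the divisor is exposed in configuration. Classification applies
cSSI ≥ threshold (default 0.60) inclusively; results are ranked by
descending cSSI with ties broken alphabetically.

Whether overlap should be computed on polygon areas or on a raster
support is a genuine alternative; the raster support was chosen because
it gives a single arithmetic pathway that a brute-force cell loop can
verify exactly.

## Terrain predictors

**Abruptness (ABR)** is local relief: per cell, max(elev) − min(elev)
over all valid cells whose centres lie within a fixed radius (default
5 km) of the focal cell centre, focal cell included. Two readings of
"maximum elevation difference within a buffer" exist — window range, or
maximum |difference from the focal cell|; we use the window range
because it is a proper relief measure (translation-invariant,
monotone in the radius, and symmetric in sign). The neighbourhood is
circular, since a buffer connotes a radius. Ecologically, abruptness
measures the elevation span reachable within a home-range-sized
neighbourhood, which is what distinguishes steep massifs from high
plateaus.

**Slope and aspect** use the Horn 3×3 average-gradient stencil; slope in
degrees, aspect as the compass direction of the upslope gradient
(degrees clockwise from north), with nodata on flat cells and borders.

**Distance-to-class rasters** (DIS-ROCK, DIS-FOREST, DIS-URBAN) give the
Euclidean distance from each cell centre to the nearest cell centre of a
land-cover class — an exact distance transform on planar grids,
great-circle nearest-neighbour search on geographic ones. An absent
class yields an all-infinite raster plus a warning rather than an error,
so variable menus remain usable on partial landscapes.

## Occurrence preparation

Five record-quality concerns are handled:

1. *verification* — unverified records dropped (optional);
2. *location uncertainty* — records above 1 km uncertainty dropped;
3. *pseudoreplication* — greedy spatial thinning in seeded random order
   with a 10 km minimum distance (broad scale), or one record per grid
   cell (fine scale). Greedy thinning is maximal for its insertion
   order: every removed record lies within the minimum distance of a
   kept one;
4. *source-type homogeneity* and 5. *geographic homogeneity* — no
   quantitative rule exists for "similar amounts", so these are
   implemented as stratified down-sampling: the larger strata are
   sub-sampled (seeded) until no stratum exceeds a configurable ratio
   (default 1.5×) of the smallest.

**Sampling bias** is corrected with a bias grid of per-region positive
weights; background cells are drawn from the calibration area with
probability proportional to weight (the multiplicative-weight semantics
presence-background software attaches to bias files). The default
demonstration uses a 4:1 west:east weighting. Background points are
drawn with replacement — they are points, not cells, and with-replacement
sampling keeps the drawn fraction exactly proportional to weight.

The **calibration area** is the union of buffers (default 500 km) around
presence records; background points come only from it, which prevents
trivially inflated discrimination against distant, obviously unsuitable
regions.

The **correlation screen** removes redundant predictors: on a background
sample, repeatedly find the pair with the highest |Spearman ρ| above the
cutoff (default 0.65) and drop its lower-priority member. Priority
encodes a-priori ecological standing; the default ordering puts local
relief and warm-season temperature ahead of the variables that merely
track the elevation gradient (elevation itself, the remaining climate
surfaces). Categorical variables are not screened; constants are dropped
with a warning.

## Maximum-entropy model

The core model is the Gibbs distribution over the calibration support
(background sample plus training presences, presences appended without
deduplication, as is standard for presence-background construction):

    raw(x) = exp(Σⱼ λⱼ fⱼ(x)) / Z,

fitted by minimising the convex objective

    L(λ) = ln Z(λ) − (1/m) Σᵢ η(xᵢ) + Σⱼ βⱼ|λⱼ|,

with per-feature penalty βⱼ = β·sⱼ/√m (sⱼ = the feature's standard
deviation over the m presences, floored at 10⁻³ so near-constant
features still carry a penalty; β is the global regularization
multiplier). At the optimum each feature's expectation under raw lies
within βⱼ of its presence mean (the KKT box), which the test suite
checks after every fit.

*Features.* Continuous variables are rescaled to [0, 1] by background
min/max and expand to linear, quadratic and forward-hinge features
(hinge knots at background quantiles, default 20 per variable);
categorical variables expand to one indicator per category; product
features are available but off by default. The default class set is
linear+quadratic+hinge from 15 presences upward, linear+quadratic below
— a deliberate simplification of the reference software's sample-size
tables, exposed in configuration. Predictions clamp continuous features
to the training range.

*Optimizer.* Cyclic coordinate descent: per coordinate, a Newton step on
the smooth part followed by soft-thresholding, safeguarded by
backtracking on the true objective, so descent is monotone. Convergence
is declared when a full cycle improves the objective by less than the
tolerance (default 10⁻⁷; 10⁻¹² in oracle comparisons); the iteration cap
defaults to 5000 cycles. On random instances the fits agree with an
independent generic convex optimizer (L-BFGS-B on the
positive/negative-part split) to ~10⁻¹⁴ in objective value. Per-update
objective improvements are credited to the updated feature's source
variable; these credits are what the percent-contribution metric
normalises, mirroring how the reference implementation attributes gain.

*Outputs.* Raw values are probabilities on the calibration support
(Σ raw = 1 there). The logistic transform is
raw·e^H / (1 + raw·e^H) with H the entropy of the fitted raw
distribution; a completely uninformative model maps to 0.5 everywhere.

*Replicates.* Each candidate is fitted on n (default 50) independent
seeded 75/25 presence splits. Five per-replicate metrics are recorded:
regularised training gain (ln N − objective, zero for the uniform
model), test gain, test AUC against the shared background draw, the
10-percentile training-presence logistic threshold, and the fraction of
support cells at or above it.

## Evaluation and selection

* **AUC** — rank-statistic form, (wins + ½ ties)/(n_p·n_b); the
  test-AUC background is the same background draw used in training, the
  presence-background convention.
* **AICc** — −2lnL + 2k + 2k(k+1)/(n−k−1) with lnL the sum of log raw
  probabilities at the presences and k the number of nonzero
  coefficients; reported missing when n ≤ k+1 or a presence has zero raw
  probability. It is computed on a model refit on *all* presences (a
  single model per candidate, selected and refit after the replicate
  stage).
* **MPA** — minimal predicted area: the fraction of calibration cells at
  or above the threshold that keeps a chosen share of presences inside
  (default: all of them, i.e. the minimum presence prediction; a 90 %
  inclusion level is available in configuration). Scale-invariant under
  monotone transforms, so raw and logistic give the same value.
* **max SSS** — binarisation threshold maximising sensitivity +
  specificity over the observed scores; ties resolve to the lowest
  qualifying threshold (documented, and pinned by a test).
* **Representative replicate** — the five replicate metrics are
  standardised, projected by PCA, and the replicate closest to the cloud
  centroid in the components covering ≥ 95 % of variance is chosen
  (cutoff configurable; at 1.0 the choice provably equals the
  standardized distance-to-mean argmin).
* **Candidate ranking** — candidates are ranked on each evaluator (AUC
  high, AICc low, MPA low) and ordered by rank sum, ties broken by lower
  AICc. How the three evaluators should be combined is genuinely
  underdetermined; rank-sum was chosen as the simplest symmetric rule
  and is isolated in one function should a user prefer another.
* **Importance** — percent contribution (training-gain credits,
  averaged over replicates), permutation importance (training-AUC drop
  when a variable's values are permuted across training points,
  normalised to 100 %), and jackknife gains (refits with only/without
  each variable).

Response curves sweep one variable across its background range with the
others fixed at background means (modal category for categorical
variables). Note that L1 shrinkage biases curve shape at larger β — a
quadratic optimum recovered exactly at β=0 drifts by 1–2 °C at β=1 in
the synthetic experiments — which is inherent to penalised estimation,
not a defect of the curve extraction.

The suitability–elevation profile bins the prediction by elevation
(default 100 m bins) and reports the lowest bin whose mean suitability
reaches the binarisation threshold: the lower suitable-elevation
boundary of a massif.

## Synthetic data: what it emulates, and what it does not

The generators provide the statistical structure the analysis assumes,
with defaults chosen once as a realistic mountain-system configuration:

* **Landscape** — 200×200 cells at 1 km; three ridges built as Gaussian
  bumps (half-width 6 km, amplitude 2.5 km over a 200 m base) along
  random segments, combined by maximum so overlapping massifs do not
  stack; 25 m Gaussian micro-relief. The fine-scale variant uses 100 m
  cells, narrower ridges (half-width 800 m, amplitude 1.4 km over
  800 m), 5 m noise, and a rock/forest/urban/meadow land cover in which
  rock outcrops (slope > 35° or above 2100 m) cover roughly a fifth of
  the terrain, as in a high-alpine massif.
* **Climate** — temperature = 22 °C − 6.5 °C/km · elevation + a
  per-region offset + noise. Two vertical-band regions offset by 8 °C
  reproduce the scale dependence of the elevation–temperature
  correlation: near-perfect within a region, visibly weaker across the
  grid. The remaining surfaces (temperature seasonality, precipitation
  and its derivatives) are distinct affine functions of elevation with
  independent noise — enough structure for the correlation screen and
  variable-importance machinery to have real work to do.
* **Land cover** — six classes by threshold rules on (elevation,
  temperature, uniform noise): ice below 0 °C, water below 120 m, an
  urban sprinkle in warm lowlands, agriculture above 15 °C, forest above
  6 °C, open natural areas in between (the alpine belt).
* **Virtual species** — suitability is a product of per-predictor
  responses (linear / Gaussian / threshold); presences are drawn
  cell-wise with probability proportional to suitability, then jittered
  within the cell and furnished with uncertainty, source-type, region
  and verification metadata.
* **Range fixtures** — comparison ranges with a controlled overlap
  fraction against a template, built from a seeded sample of template
  cells topped up with the nearest outside cells.

What the synthetic data does **not** emulate: spatial autocorrelation of
residual climate noise, anisotropic lapse rates, seasonal range
differences, observation error in the predictors, or real-world
land-cover fragmentation. Passing tests therefore demonstrate that the
machinery is correct and that the method recovers known generating
structure under its own assumptions — not that any particular ecological
conclusion transfers to real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down studies chosen
to exercise every stage at meaningful size: parameter recovery uses the
full 200×200 landscape with 80 presences, 2000 background points and 50
replicates across 20 seeds; the pipeline demonstrations use 80–120 cell
grids, 10 replicates and 2000 background points. Oracle comparisons use
instances up to 200 cells × 6 features, where an off-the-shelf convex
optimizer is dependable to ~10⁻¹⁴.

Degenerate inputs are handled explicitly: constant features keep a zero
coefficient; a categorical variable with one category is dropped with a
warning; an all-zero suitability surface refuses to sample; an empty
post-filter record set aborts the pipeline naming the stage; a candidate
whose every replicate has zero gain receives a uniform contribution
attribution with a warning.

Determinism is end-to-end: one master seed fans out to fixed per-stage
seeds through `SeedSequence((master, stage_key, index))`, and report
tables are written with fixed float formatting, so identical
(inputs, config, seed) produce byte-identical outputs.

## Known limitations

* The per-feature penalty β·s/√m is a simple, dimensionally sensible
  stand-in for the reference implementation's per-feature-class tuning
  tables; absolute β values are therefore not interchangeable with that
  software's.
* Hinge features are forward-only; threshold features are not generated.
* AICc counts nonzero coefficients as parameters, the convention used by
  the model-selection literature for L1-regularised maxent, though the
  effective degrees of freedom argument behind it is approximate.
* Geographic (lon/lat) grids are supported for distances and
  rasterization, but slope/aspect on them use a mean-latitude metre
  conversion rather than a per-row one.
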