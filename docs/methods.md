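# Methods

This note records the models implemented in `sqimap`, the assumptions and
defaults behind them, and the design choices made where the underlying
methodology is genuinely open.

## AHP weighting

Weights are derived from reciprocal pairwise-comparison matrices
(Saaty 1–9 scale). Two prioritisation methods are provided:

* **Principal eigenvector** (default): power iteration from the uniform
  vector, stopping when the relative change drops below 1e-10 (at most
  10,000 sweeps). Deterministic — no randomness anywhere in the AHP stage.
* **Column-normalized row mean**: the textbook hand approximation (divide
  each column by its sum, average rows).

For a perfectly consistent matrix (`a_ij = w_i/w_j`) both methods recover
the generating weights exactly; they differ in the third decimal for
mildly inconsistent judgements. The eigenvector is the default because it
reproduces the reference wheat–barley hierarchy (the built-in matrices in
`sqimap.ahp`) to four decimals.

λmax is estimated as the mean of the component-wise ratios `(A·w)/w`,
which is exact at the principal eigenvector; then
`CI = (λmax − n)/(n − 1)` and `CR = CI/RI` with the tabulated random
index RI(n), n = 1..15. A matrix is acceptable when CR ≤ 0.10. For
n ≤ 2 every reciprocal matrix is consistent and RI = 0; CR is defined
as 0 there rather than left undefined.

Strict Saaty-scale validation (all off-diagonal entries in
{1/9..1/2, 1, 2..9}) is on by default for user-supplied matrices and off
for the built-in ones, which contain intermediate ratios such as 0.5.

## Standard scoring functions

Both SSF branches are piecewise linear with a floor of 0.1 (not 0): a
worst-case indicator still contributes a small positive amount, so the
weighted index stays in [0.1, 1] and a single catastrophic indicator
cannot zero the index. Both branches pass through 0.55 at the midpoint
and satisfy `positive(x) + negative(x) = 1.1` identically.

Threshold defaults (L/U) per indicator come from two rules, recorded
per-entry in the catalog's `source_rule` field:

* **table_edges** — where the agronomic literature gives numeric
  suitability-class edges for wheat, L is the worst-class edge and U the
  best-class edge (e.g. slope 0–30 %, depth 20–120 cm, OM 0.5–2 %,
  pH 7.0–8.5 as a "less is better" ramp). The total-N class edges are
  used decimal-corrected (0.045–0.32 %), consistent with observed total-N
  ranges; the published row mixes two decimal scales.
* **percentile_5_95 / marginal_min_max** — for texture fractions, bulk
  density and the micronutrients no usable numeric edges exist; L/U are
  the 5th/95th percentiles of the supplied survey, falling back to the
  reference survey's descriptive min/max when the catalog is built
  without data.

Whether a real study used class edges or dataset percentiles is usually
unstated; both rules are first-class and the catalog always records which
produced each value. Texture is scored as three numeric columns
(clay/silt/sand %); categorical texture-class lookups are out of scope.
Missing measurements propagate as missing scores and the affected points
get a missing SQI (no silent imputation; an explicit `renormalize` flag
rescales the remaining weights instead and records that it did).

## Interpolation and model selection

Fifteen candidates, Euclidean distances on projected metre coordinates,
coordinates centred internally for numerical stability (predictions are
translation-invariant to 1e-9):

* **IDW** powers 1–3, global neighbourhood (no search radius), exact at
  data points by construction.
* **RBF splines**: thin-plate (`r² log r`, linear drift), completely
  regularized spline and spline with tension in their standard GIS
  formulations (modified Bessel `K₀` kernels; linear drift for CRS,
  constant for tension). The width/tension parameter defaults to one mean
  nearest-neighbour distance.
* **Kriging** ordinary / simple / universal × gaussian / spherical /
  exponential. The empirical semivariogram uses 12 equal-width bins up to
  half the maximum pairwise distance, fitted by least squares weighted by
  pair counts, nugget floored at 0; ranges are practical ranges (the
  gaussian/exponential models reach 95 % of the sill at the range).
  Simple kriging's known mean defaults to the sample mean; universal
  kriging uses a first-order (linear in x, y) drift. The lag-0 covariance
  is nugget + partial sill, so kriging is exact at data points.

Model selection is leave-one-out cross-validation: each point is withheld,
the surface refitted, and the candidate with minimum RMSE
(`√(Σ(ẑᵢ − zᵢ)²/n)`) wins; ties break by the fixed candidate order (IDW
1–3, TPS, CRS, ST, kriging variants). For kriging the variogram is fitted
once on the full point set and reused across folds (the kriging weights
are still re-solved per fold) — the convention of GIS geostatistics
suites, and the variogram is not meaningfully altered by removing one of
hundreds of points. Rasterisation predicts at cell centres and sets cells
outside a configurable buffer of the samples' convex hull to no-data;
a cell-count cap guards against accidental huge rasters.

## SQI, classification, areas

SQI is the weighted linear combination of scores; the 0–100 index is
`100 × SQI` (the only bridge that connects [0.1, 1] scores to the 0–100
class table). Class intervals are half-open upward — S1 [80, 100]
(closed at 100), S2 [60, 80), S3 [50, 60), N1 [20, 50), N2 [0, 20) —
which resolves the printed class table's integer gaps into an exhaustive,
non-overlapping rule. Classification runs per-point or per-cell through
the same function.

Two orders of operations are supported and recorded in the run manifest:
**interpolate-then-score** (default; parameter maps precede the index, as
in the usual GIS workflow) and **score-then-interpolate** (interpolate
the per-point SQI directly). Mask polygons are applied by cell-centre
point-in-polygon tests; mask categories get raster codes 10, 11, … above
the class codes 1–5, documented in a sidecar legend file. Areas are
`count × cellsize²` in hectares; shares are over data cells and sum
to 100.

## Yield validation

Observed yield (kg ha⁻¹) is regressed on SQI by ordinary least squares
and agreement summarised as `R² = 1 − SS_res/SS_tot`. For a simple OLS
fit this equals the squared Pearson correlation, so the report carries
both `r2` and `pearson_r` (they must agree to 1e-9; the redundancy is a
cheap internal check). Formulations that invert the ratio — which can
exceed 1 — are deliberately not implemented.

## Synthetic surveys

The generator emulates the statistical signature of a gridded semi-arid
soil survey, not any real area's geology:

* **Geometry**: 6.48 × 6.48 km (~4,199 ha), sampling nodes every 400 m
  → 256 points; truth rasters at 90 m cells. All defaults overridable.
* **Spatial structure**: stationary Gaussian random fields with
  exponential covariance, correlation length 800 m (twice the sampling
  interval — long enough that interpolation beats the field mean, which
  the workflow presumes). Fields are synthesised by circulant embedding
  on a doubled torus (exact covariance, O(N log N)); rare negative
  embedding eigenvalues are clipped to zero.
* **Marginals**: each parameter is transformed from the unit-variance
  field to a 24-row catalog of descriptive statistics. |skew| < 0.5 maps
  affinely; stronger skew maps through a moment-matched shifted lognormal
  (σ solved in closed form from the skewness cubic
  `(w+2)²(w−1) = s²`, `w = exp(σ²)`), reflected for negative skew. All
  branches are monotone in the latent field, so spatial ranks are
  preserved. Values are finally clipped to the catalog min/max and the
  clipped fraction logged in the survey manifest. For several
  heavy-tailed parameters (slope, hydraulic conductivity, depth) the
  recorded min/max sit well inside the bulk of any distribution matched
  to their mean/SD/skew, so clipping is substantial (up to ~26 % of
  cells) and shifts the post-clip moments; the moment-matching guarantee
  therefore applies to the pre-clip transform (`clip=False`), which is
  what the moment tests check, while the clipped field is what the
  pipeline consumes.
* **Sampling**: nodes at `(k + ½) × spacing` from the lower-left corner,
  optional uniform positional jitter (GPS error), values read from the
  truth rasters by bilinear interpolation so a sample's value is
  consistent with its recorded position. Parameters are independent
  fields by default; an optional shared-latent loading makes chosen
  parameters covary.
* **Yields**: `yield = base + gain·SQI + N(0, noise_sd)`, floored at a
  configurable minimum. Defaults are solved from the variance
  decomposition `R² = gain²·var(SQI)/(gain²·var(SQI)+noise_sd²)` so the
  population R² is 0.67 with mean yield 1,600 kg ha⁻¹ and a ±3 SD span
  of ≈ 900–3,000.
* **Determinism**: one integer seed; per-parameter streams derived via
  `SeedSequence(seed, crc32(name))`; identical seeds give bit-identical
  outputs.

What passing tests on these surveys do *not* show: real soils violate
stationarity and cross-correlate strongly (texture–CEC–AWC), slope is
terrain- not random-field-driven, and survey errors are not bilinear
reads; synthetic recovery rates are therefore an upper bound on what the
pipeline would achieve on comparable field data.

## Test design notes

* The end-to-end recovery check (scoring + weighting + classification of
  a densely sampled survey against the known truth classes) uses a
  4 × 4 km domain sampled every 100 m (correlation length / 8) with 30 m
  jitter, CRS interpolation, and measures agreement over the convex hull
  of the samples — the mapped area; the pipeline itself declares cells
  beyond the hull no-data. Recovery there is 95–97 %. At the 400 m
  survey spacing recovery drops to roughly 80–88 %: exponential-covariance
  fields are continuous but not differentiable, so interpolation error
  decays slowly with density. The jitter prevents the degenerate case of
  samples sitting exactly on cell centres, which would make recovery
  trivially exact.
* Moment checks compare grid means/SDs against the catalog within three
  standard errors, with the effective sample size computed exactly from
  the lag-count sums of the exponential correlation (a 34 × 34 grid at
  200 m cells has an effective n of ~16 for the mean) and the SD's
  sampling error scaled by the fitted marginal's analytic kurtosis.
  Transform monotonicity makes the Gaussian-field correlation an upper
  bound on the transformed field's, so the effective n is conservative.

## Known limitations

* No geodesy: coordinates are planar metres; masks must already be in the
  raster's frame (a frame mismatch is detected and reported, never
  reprojected).
* Rasters are ESRI ASCII grids only.
* Isotropic variograms only; no co-kriging; no group-decision (multi-
  expert) AHP aggregation or fuzzy variants.
* The interpolation leaderboard depends on unstated implementation
  conventions (variogram binning, spline tension defaults), so RMSE
  values from other GIS suites will differ in detail even on identical
  data; the selection machinery, not any specific RMSE table, is the
  contract.
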