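# Methods

This note documents the statistical methods implemented in `habselect`,
their assumptions, tunable parameters, and the numerical choices that are
this implementation's own.

## 1. Resource units and EGVs

All spatial layers are rectangular grids (`RasterGrid`: values, origin at
the top-left corner, square cell size in metres, nodata marker) read and
written as ESRI ASCII grids — a plain-text format with a 6-line header.
Cells are half-open: a point on a shared boundary belongs to the cell to
its east/south, so every point maps to exactly one cell.

`aggregate_to_ru` converts a 30 m categorical cover raster plus continuous
layers into 90 m resource units (aggregation factor 3, configurable). Each
RU gets one proportion column per cover class (so Σ proportions = 1 exactly
per RU) and the block mean of every continuous layer. An RU whose fine
block is more than 50% nodata (configurable) in any layer is dropped from
the table and set to nodata in every RU-scale raster, keeping all layers
co-registered.

Supporting operations: Euclidean distance layers via
`scipy.ndimage.distance_transform_edt`; Pearson screening that flags EGV
pairs with |r| ≥ 0.7 (constant columns are excluded with a warning); PCA on
z-scored EGVs via scikit-learn; global Moran's I with row-standardized rook
or queen contiguity; overall accuracy and Cohen's kappa from a confusion
matrix.

## 2. Home ranges, use, and availability

Availability is per animal (a "design III" study): the RUs whose centres
fall inside the animal's 100% minimum convex polygon (convex hull of its
locations; collinear point sets are an error). Because the hull passes
through the outermost points, an RU containing a used location can have its
*centre* just outside the polygon; availability therefore always includes
the RUs actually used (`include_ru_ids`), so use is never outside
availability. Availability proportions π are computed over dominant cover
classes (argmax of the proportion columns; ties go to the smaller class
code). Percent-MCP < 100 trims the farthest points from the centroid
before taking the hull.

## 3. Manly selection ratios (design III)

Per animal j and category i, with used counts u and availability π:

- ŵᵢⱼ = (uᵢⱼ/u₊ⱼ)/πᵢⱼ, and the log-likelihood statistic
  χ²_Lj = 2 Σᵢ uᵢⱼ ln(uᵢⱼ/(u₊ⱼπᵢⱼ)) on Iⱼ − 1 degrees of freedom
  (zero counts contribute nothing; a category used but unavailable is an
  error).
- Global ratio: ŵᵢ = Σⱼuᵢⱼ / Σⱼu₊ⱼπᵢⱼ, pooling only the animals for which
  the category is available. Global χ²_L = Σⱼχ²_Lj with df = Σⱼ(Iⱼ − 1),
  which is why df need not be a multiple of the number of animals when some
  MCP lacks a category.
- Confidence intervals use the Bonferroni normal critical value
  z_{α/(2I)} over the I simultaneous category intervals. Because ratios
  are non-negative, the lower bound is clipped at 0. Status: *selected*
  if CI low > 1, *avoided* if CI high < 1, otherwise *proportional*;
  a single animal gives no variance and is *undetermined*.

**Variance choice.** The default standard error is the design III ratio
estimator

    var(ŵᵢ) = K/(K−1) · Σⱼ (uᵢⱼ − ŵᵢ·u₊ⱼπᵢⱼ)² / (Σⱼ u₊ⱼπᵢⱼ)²,

with K the number of animals contributing to the category. The simpler
among-animal estimator s²({ŵᵢⱼ})/K is available via
`variance="among_animal"` but is *not* the default: ŵᵢⱼ divides by πᵢⱼ, so
when a category is nearly unavailable to one animal its per-animal ratio
explodes and the among-animal variance becomes heavy-tailed. In simulation
(20 replicates, 9 animals, strong selection on one class) the ratio
estimator covers the truth at the nominal ≥ 95% rate while the among-animal
estimator does not; the two agree when animals are homogeneous and
availabilities are comfortably non-zero (cross-checked in the test suite).

## 4. K-select

EGVs are standardized globally (population SD, constants dropped with a
warning). An animal's marginality is m = mean(used z) − mean(available z);
the analysis unit is the RU, so repeated locations in one RU are collapsed
to the unique used RUs. K-select is the eigenanalysis of
C = Σₖ wₖ mₖ mₖᵀ (weights default to uniform); by construction
Σλ = Σₖ wₖ ‖mₖ‖², the weighted mean squared marginality — an invariant the
tests enforce.

Significance of one animal's marginality: draw its number of used RUs
*without replacement* from its available RUs N times (default 10,000),
recompute ‖m*‖², and report the add-one estimator
p = (1 + #{‖m*‖² ≥ ‖m‖²obs}) / (N + 1). Ties count as exceedances, the
estimator can never return 0, and its floor is 1/(N+1) — 1/10001 ≈ 0.000099
at the default N. The joint first-eigenvalue test randomizes all animals
simultaneously and compares the observed λ₁ to its null distribution.
Bonferroni adjustment across K animal-level tests uses α/K (0.05/6 = 0.0083,
0.05/8 = 0.0062 at 4 truncated decimals).

## 5. Spatial thinning

Exact duplicate coordinates are collapsed first (first occurrence kept).
The Clark–Evans index is R = mean nearest-neighbour distance divided by its
expectation 1/(2√(n/area)) under complete spatial randomness; **no edge
correction** is applied — the reference area is the animal's MCP area, the
same window the points define, and at the sample sizes involved the
uncorrected index is adequate to drive thinning toward R ≈ 1 (the
calibration test accepts R = 1 ± 0.1 for homogeneous Poisson points).

Thinning is greedy and deterministic: find the current closest pair, remove
the member whose removal yields the larger mean nearest-neighbour distance
(tie → the higher index), recompute R, and stop when R ≥ 1 − tolerance
(default 0.01; the pipeline uses 0.05) or when `min_points` is reached, in
which case the result is flagged `converged = false`. The full R trajectory
is recorded.

## 6. Mahalanobis suitability and evaluation

The niche model is the mean vector and sample covariance (denominator
n − 1) of the EGVs at the thinned, settled-period used locations, on their
original scales. Each RU's D² = (x − μ)ᵀΣ⁻¹(x − μ) maps to suitability via
the χ²(p) survival function (p = number of EGVs): 1 at the niche centre,
strictly decreasing in D². If locations are drawn from the fitted normal
itself, their D² is exactly χ²(p) — a calibration the tests verify by
Kolmogorov–Smirnov at n = 5,000.

**Conditioning.** Mahalanobis distance is invariant to per-variable
rescaling, but the raw covariance mixes units (metres², degrees²,
proportions²), so its condition number is dominated by scale. Degeneracy is
therefore assessed on the *correlation* matrix; condition numbers above
1e8 raise unless a ridge epsilon is supplied (added as ridge·diag(Σ)).

**Column selection.** The cover-class proportions sum to 1 per RU, so the
full set makes Σ exactly singular — and when a class is (nearly) absent
from the used locations the remaining proportions still sum to a constant.
`select_niche_columns` drops columns that are constant at the used
locations and then the proportion column with the largest variance there,
leaving a complement that genuinely varies.

**Evaluation.** The Fᵢ curve uses 20 fixed suitability classes of width
0.05. Eᵢ is each class's share of valid map area, Pᵢ the share of
evaluation points; classes with Eᵢ = 0 are excluded and P, E renormalized,
so ΣPᵢ = ΣEᵢ = 1 over retained classes. Fᵢ = Pᵢ/Eᵢ, with Fᵢ = 1 marking
random use. The reclassification threshold is the lower bound of the first
class (scanning upward) from which F stays above 1; a `last_upcrossing`
rule is available. The Boyce index is the Spearman correlation of Fᵢ with
class rank, reported with the adjusted r² of the least-squares line of Fᵢ
on rank; constant F (zero variance) returns a flagged null with a warning.
Uniform evaluation points over the valid area give F ≈ 1 everywhere and a
Boyce index near 0 (null calibration enforced in the tests).

## 7. Synthetic generator

The generator exists to give every estimator a known target; its scope is
deliberately minimal.

- **Landscape** (30 m cells, default 90×90): cover = argmax over
  k smoothed Gaussian random fields (patch size set by `patch_smoothing`);
  regenerated up to 5 times if any class is absent (then an error). Elevation
  is an independent smooth field (350 ± 80 m), slope its gradient magnitude
  in degrees, NDVI a clipped smooth field, and two Euclidean-distance layers
  measure distance from a meandering river polyline and from scattered
  water points.
- **Telemetry**: each animal has a home-range disc (centres random within
  the landscape with a margin, radii default 0.25 × the minimum extent;
  discs must lie inside the landscape and contain ≥ 10 RUs). Used RUs are
  drawn with probability ∝ exp(Σᵥ βᵥ zᵥ) over the disc's RUs, z the globally
  standardized EGVs; the linear predictor is evaluated with EGVs in sorted
  name order so that permuting a user-supplied `egv_order` cannot change
  the distribution. Points are placed uniformly inside the chosen RU cell.
  Two behavioural periods ("exploratory", "settled") can use different β
  matrices. Defaults (9 animals, 150–200 points per animal per period, 16
  EGVs when `n_cover_classes` ≥ 10 — this package's default exercises 11)
  are sized so that a full pipeline run takes seconds.
- **Determinism**: a single integer seed determines all outputs through a
  `SeedSequence` spawning scheme (landscape, continuous layers, centres,
  and each animal get independent streams), so adding animals does not
  perturb the landscape.

Limits: circular home ranges, no movement autocorrelation within a period,
no observation error, and cover patches with a single characteristic scale.
These are adequate for estimator validation, not for emulating real
movement data.

## 8. Pipeline and problem sizes

The CLI runs eight stages (simulate, egv, homerange, ratios, kselect, thin,
suitability, evaluate) against one output directory; each stage reads its
declared inputs from disk, so stages can be re-run individually, and a
`manifest.json` records the config hash, the seed, and a SHA-256 checksum
per output. Floats are written with 10 significant digits. Config keys and
defaults: `aggregation_factor` 3, `correlation_threshold` 0.7, `alpha`
0.05, `randomization_n` 10000 (the joint λ₁ test caps at 1000),
`thinning_tolerance` 0.05, `thinning_min_points` 10, `ridge` 0.0,
`fi_classes` 20, `holdout` 0.0.

The acceptance suite's problem sizes are this package's own choices, set
for tight Monte-Carlo behaviour at desk scale: null calibration uses ~200
animal-level p-values with N = 199 randomizations each; parameter recovery
uses 20 replicates (seeds 1000–1019) of 9 animals at β = 3 on one cover
class; the p-value-floor demonstration uses 200 used RUs from the top 5% of
one EGV among 2,000 available with N = 10,000.
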