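# habselect

Fine-scale habitat selection and habitat-suitability analysis for telemetry
data, built around the classic used-versus-available designs of wildlife
ecology:

- **Resource units (RUs).** Co-registered 30 m rasters (categorical land
  cover plus continuous layers such as elevation, slope, an NDVI-like index
  and Euclidean-distance layers) are aggregated to 90 m resource units:
  per-class proportions for the cover layer, block means for continuous
  layers. Pearson screening, PCA, Moran's I and kappa accuracy support the
  EGV (eco-geographical variable) preparation step.
- **Manly selection ratios, design III.** Each animal has its own
  availability (RUs inside its 100% minimum convex polygon) and used sample.
  Per category *i* and animal *j*, the ratio is
  ŵᵢⱼ = (uᵢⱼ/u₊ⱼ)/πᵢⱼ; the global ratio pools counts,
  ŵᵢ = Σⱼuᵢⱼ / Σⱼu₊ⱼπᵢⱼ, with a log-likelihood χ²_L statistic and
  Bonferroni-adjusted confidence intervals. A category is *selected* when
  the CI lies above 1 and *avoided* when it lies inside [0, 1).
- **K-select.** Each animal's marginality vector m = mean(used z) −
  mean(available z) on globally standardized EGVs; eigenanalysis of the
  weighted cross-product matrix summarizes selection common to the set of
  animals. Significance comes from a randomization test: re-draw the used
  RUs without replacement from availability, recompute ‖m‖², and use the
  add-one estimator p = (1 + #{‖m*‖² ≥ obs}) / (N + 1).
- **Spatial thinning.** Duplicate locations are removed and each animal's
  settled-period points are greedily thinned (always breaking the current
  closest pair) until the Clark–Evans aggregation index reaches R ≈ 1,
  i.e. spatial randomness.
- **Mahalanobis D² suitability.** A multivariate-normal niche model (mean
  and covariance of the EGVs at the thinned used locations) gives each RU a
  squared Mahalanobis distance; the χ²(p) survival function maps D² to a
  suitability value in [0, 1]. Evaluation uses the predicted-to-expected
  curve Fᵢ = Pᵢ/Eᵢ over 20 suitability classes of width 0.05, the Boyce
  index (Spearman correlation of Fᵢ with class rank), and reclassification
  of the map at the Fᵢ = 1 boundary.
- **Synthetic data.** A seeded generator produces patchy landscapes, EGV
  stacks and telemetry from an exponential resource-selection function with
  known coefficients, so every stage can be tested end to end against
  ground truth with no external data.

Raster I/O uses the plain-text ESRI ASCII grid format; home-range polygons
are written as GeoJSON.

## Worked example

The `habselect` CLI runs the whole pipeline from a YAML config. With a
synthetic landscape of 6 cover classes and 9 animals whose settled-period
selection coefficient is β = 1.5 on the (standardized) proportion of cover
class 0:

```yaml
# config.yaml
synthetic:
  seed: 7
  grid_rows: 90
  grid_cols: 90
  n_cover_classes: 6
  n_animals: 9
  points_per_animal_per_period: 150
  selection_coefficients:   # one row per animal, one column per EGV
    - [1.5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
    # ... (9 rows)
```

```bash
habselect run-all --config config.yaml --outdir run/
```

Headline outputs from that run (`run/selection_ratios_settled.csv`,
`run/kselect_*`, `run/evaluation.json`):

| category | ŵ (global) | 95% Bonferroni CI | status |
|---|---|---|---|
| 0 | 14.89 | (11.39, 18.38) | selected |
| 1 | 0.091 | (0.060, 0.122) | avoided |
| 2 | 0.129 | (0.075, 0.182) | avoided |
| 3 | 0.112 | (0.032, 0.191) | avoided |
| 4 | 0.062 | (0.013, 0.111) | avoided |
| 5 | 0.091 | (0.036, 0.145) | avoided |

global χ²_L = 6202.5 on 45 df (p < 1e-300); all 9 animals' marginality
randomization p-values ≤ 0.033 with 5 of 9 at the 1/10001 floor; first
eigenvalue λ₁ = 1.91 (joint randomization p = 0.001). Thinning retains
437 of 1,350 settled locations. The suitability map evaluated on the
thinned points gives Boyce r = 0.88 (adjusted r² = 0.60), and the Fᵢ = 1
reclassification marks 10.3% of the core zone suitable versus 1.1% of the
buffer — the generator's selected habitat is rare, so a small suitable
area concentrated where the simulated animals live is the expected answer.

Each stage can also be run (and re-run) individually — `habselect simulate`,
`habselect egv`, …, `habselect evaluate` — against the same output
directory; a `manifest.json` records the config hash, seed and a checksum
per output file.

The same operations are importable directly:

```python
from habselect import (mcp, availability, used_units, DesignIIIInput,
                       global_ratios, standardize, marginality,
                       kselect_eigen, marginality_randomization)
```

## Documentation

`docs/methods.md` describes the statistical methods, their assumptions,
all tunable parameters, and the numerical choices made in this
implementation.
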