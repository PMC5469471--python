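# meadowpack

Multi-scale evaluation of pack-stock (horse and mule) disturbance on
subalpine meadow plant communities.

Recreational pack stock graze mountain meadows intermittently, and any
disturbance signal is easily swamped by the enormous natural variation
among meadows (climate, snowmelt, basin hydrology) and within them
(local soil-moisture gradients). `meadowpack` is the analysis pipeline
for a matched observational design that controls both scales, for
ecologists and wilderness managers analysing plot-based meadow surveys:

1. **Among meadows** — each grazed meadow is paired with an ungrazed
   control selected by generalized Mahalanobis distance
   d(x, y) = √((x−y)ᵀ S⁻¹ (x−y)) over 27 remotely sensed geospatial and
   hydro-climatic covariates.
2. **Within meadows** — every 4 m² plot's soil volumetric water content
   is standardized to its meadow mean (z-scores), species response
   curves are smoothed along that axis, and plots are stratified into
   Dry / Intermediate / Wet vegetation community types.
3. **Responses** — three community metrics per (pair, stratum): bare
   ground (%), Bray–Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) between the
   paired meadows' mean species-cover vectors, and multivariate species
   dispersion (mean distance of the eight 25 × 25 cm subplots to their
   principal-coordinates centroid, with the negative-eigenvalue
   correction).
4. **Inference** — stock-minus-control differences are bootstrapped
   (B = 1000, plot-level resampling, percentile 95% CIs), and pruned
   regression trees attribute the explained variance to Stock Use
   metrics versus Within-pair and Between-pairs physical covariates
   (splits retained only above 10% of total sum of squares).

Because vegetation data of this kind are rarely shareable, the package
includes a first-class synthetic landscape generator
(`meadowpack.simulate`): correlated meadow covariates, stock-night
histories, transect/plot/subplot sampling, Gaussian-niche communities
along the moisture gradient, and injectable disturbance effects for
parameter-recovery testing.

## Worked example

```python
import meadowpack as mp
from meadowpack.matching import matches_to_pairs

# a synthetic landscape: 1000 candidate meadows, 22 with stock use,
# disturbance injected above 230 max stock nights/ha
meadows, stock_use = mp.generate_landscape(n_meadows=1000, n_stock=22, seed=7)
eligible = mp.filter_eligible_stock(meadows, stock_use)
pairs = matches_to_pairs(mp.match_meadows(eligible, meadows, stock_use))

effect = mp.EffectConfig(bare_dry_effect=50.0, use_threshold=230.0,
                         wet_dispersion_factor=3.0)
sampled = sorted({p.stock_meadow_id for p in pairs}
                 | {p.control_meadow_id for p in pairs})
dataset = mp.generate_dataset(sampled, meadows, stock_use,
                              effect_config=effect, seed=7)

results = mp.PackStockModel(dataset, pairs=pairs, b_reps=1000, seed=7).fit()
print(results.summary())
```

```
Pack-stock meadow analysis
============================================================
pairs: 22   bootstrap B: 1000   seed: 7
moisture breaks (z): -0.50 / +0.50
bare vs vegetation cover r = -0.94; bare vs veg+litter r = -0.98

CART attribution (% of total SS by covariate class)
response          stratum         n     R2  StockUse  Within  Between
bare_ground_diff  All            22   0.69       0.0    68.6      0.0
bare_ground_diff  Dry            22   0.83      71.1    11.5      0.0
bare_ground_diff  Intermediate   22   0.74       0.0    74.1      0.0
bare_ground_diff  Wet            22   0.87       0.0    87.3      0.0
dissimilarity     All            22   0.64       0.0    47.1     16.5
dissimilarity     Dry            22   0.72       0.0    71.8      0.0
dissimilarity     Intermediate   18   0.87       0.0    86.6      0.0
dissimilarity     Wet            22   0.84      13.0    71.2      0.0
dispersion_diff   All            22   0.80       0.0    60.9     19.4
dispersion_diff   Dry            22   0.95       0.0    94.8      0.0
dispersion_diff   Intermediate   18   0.82       0.0    82.4      0.0
dispersion_diff   Wet            22   0.72      48.5     0.0     23.8

paired-difference cells: 256 (102 difference CIs exclude 0)
```

Read the table the way a field study would: at the whole-meadow scale
("All") stock use explains nothing — physical differences within and
between the matched pairs dominate. The injected disturbance surfaces
exactly where it was placed: the Dry bare-ground model attributes 71%
of its sum of squares to a stock-use metric, and the Wet dispersion
model 48%, while every other cell stays with the landscape covariates.
`results.estimates_frame()` holds the per-pair bootstrapped differences
with their CIs, and `results.contributions_frame()` the per-covariate
tree contributions.

The same workflow runs from the shell over CSV tables
(meadows, stock_use, plots, species_cover):

```sh
meadowpack run --config examples/demo.yml --stages all --seed 7 --outdir out/
```

writing `pairs.csv`, `strata.csv`, `curves.csv`, `responses.csv`,
`boot_estimates.csv`, `cart_contributions.csv` and a hashed manifest.

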