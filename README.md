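# pestmap

Globally gridded estimation of crop-specific pesticide application rates.

National inventories of pesticide use are sparse: one country may report
annual applied mass per active ingredient, state by state, while most
others report at best aggregated class totals. `pestmap` implements the
estimation chain that bridges that gap — it turns a state-level usage
panel (high/low applied mass per active ingredient × crop × state × year)
into conditioned, quality-scored global maps of annual application rates
(APR, kg of ingredient per hectare of crop per year), for a reference
year and projections a decade ahead. It is written for environmental
exposure modellers and agrochemical risk analysts who need gridded
ingredient-level inputs rather than country-level class totals.

## The method

1. **Panel reanalysis.** Missing high/low bounds are reconstructed from
   the ingredient- and crop-specific mean high-to-low ratio; the
   reference year is interpolated from its neighbours; national series
   take the max of state highs, the mean of state lows, and the median
   mass *M* (sum over states of the band midpoint). The top-*k*
   ingredients per crop are selected under record-completeness rules,
   with the mass-coverage factor *F_M* tracking the selected share.
2. **Trends and prefactors.** State median-mass series are smoothed with
   cubic smoothing splines (roughness by generalized cross-validation)
   and the national smoothed series is fit by ordinary least squares,
   *M_r*(i,j,t) = a·t + b. Mapping prefactors
   *F*(i,j,t) = *M_r*(t) / *M_s*(reference year), floored at 0, carry
   the temporal projection.
3. **State rates.** Crop layers are aggregated into 6 dominant crops and
   4 aggregated classes, capped at 95% cell saturation, and state APR is
   smoothed mass / state crop area.
4. **Spatial inference.** State median APR is regressed one covariate at
   a time on state-mean environmental covariates (20 soil, climate,
   agronomic and socio-economic fields). The five strongest by |R| are
   combined as

   H, L = Σₖ Wₖ·[αₖXₖ + βₖ ± CIₖ(Xₖ)],  Wₖ = |n·Rₖ| / Σ|n·Rₖ|,

   where CI is the 95% mean-response confidence band — giving raw global
   high/low surfaces on crop cells.
5. **Conditioning.** Banned/not-approved (country, ingredient) pairs are
   zeroed; GM-resistance-specific ingredients are capped at the
   reference-country rate in approving countries and set to 30% of it
   elsewhere; both bounds are scaled per country by
   min[*F_M*·*R_c*, H/L ratio in the reference country], where
   *R_c* = reported national mass / integrated estimate, neighbour-imputed
   where unreported; prefactors project the maps to 2020 and 2025.
6. **Quality.** Per-cell quality index
   QI = (QF_SA·QF_HT·Π_Z QF_Z)^(1/(2+z)) combines crop-matching,
   trend-regression and class-mass-validation quality factors.

Because the real source stack (tens of GB of rasters and registries) is
impractical as a test fixture, the package ships a first-class synthetic
world generator (`pestmap.world`) whose zero-noise configuration is an
exact fixed point of the entire chain — every stage provably recovers the
generating truth.

## Worked example

```python
from pestmap import WorldConfig, PipelineConfig, generate_world, run_pipeline

bundle = generate_world(WorldConfig(grid_rows=48, grid_cols=96,
                                    noise_sd_frac=0.05, n_bans=2, seed=3))
result = run_pipeline(bundle, PipelineConfig())
print(len(result.finals), result.f_m)
```

Running `python examples/04_full_pipeline.py` (which adds exports) prints:

```
selected 15 (ingredient, crop) pairs, F_M = 1.000

country correction ratios R_c (reported inventory / integrated estimate):
  country 0: R_c = 1.007 (reported)
  country 1: R_c = 1.079 (reported)
  ...
banned (ai_02, country 1): max rate inside = 0.0
banned (ai_00, country 4): max rate inside = 0.0

quality index for ai_00 on Corn: min 0.926, max 0.940 (constant per country)

wrote 109 products to .../run; manifest verifies: True
```

All 5 ingredients × 3 crops pass selection, so the coverage factor is 1;
*R_c* near 1 means the integrated estimates already track the inventory
totals (they differ by the generator's 5% perturbation); banned
country–ingredient pairs integrate to exactly zero mass; the quality
index is constant within each country because its class-validation factor
is a national quantity. The other scripts in `examples/` walk through
world generation, panel reanalysis, spatial inference and the
cross-validation harness individually.

A thin CLI wraps the same calls: `pestmap simulate`, `pestmap run`,
`pestmap validate`, `pestmap report` (see `pestmap --help`).

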