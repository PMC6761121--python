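# Methods

This note documents the estimation model, the synthetic-world generator,
the numerical choices, and the limits of what the test suite shows.

## Model and assumptions

The package estimates the annual application rate (APR, kg/ha/yr) of an
active ingredient *i* on a crop class *j* everywhere the crop grows,
seeded by a single country's state-resolved usage panel. The chain makes
these assumptions explicit:

* **State masses bound the truth.** Each panel cell carries a high and a
  low bound on applied mass; the central estimate is the band midpoint.
  The midpoint convention makes the median state-resolved, which the
  state-rate step requires, and is exact when bounds are symmetric about
  the truth.
* **Use trends are locally linear in time.** Median-mass series are
  smoothed (cubic smoothing spline) before a first-order fit; higher
  orders fit history better but extrapolate erratically over a decade,
  so only the linear trend is used for projection. Prefactors
  F(t) = M_r(t)/M_s(ref) are floored at 0; F(ref) ≡ 1 since
  reference-year maps come from conditioning, not from the trend.
* **Rates transfer through environmental covariates.** The monovariate
  linear model APR = αX̄ + β fitted across states is assumed to hold
  globally at cell level. The high/low envelope is the 95% mean-response
  band of each regression — a band on the mean rate surface, not a
  prediction interval for single cells, because the product is a mean
  rate map. The top 5 covariates by |R| are combined with weights
  |n·R| (ingredients fitted from more states and stronger correlations
  dominate); when every selected |R| is 0 the weights fall back to equal.
* **Governance is binary and static.** A ban zeroes the ingredient
  country-wide through the projection horizon. GM conditioning applies
  only to the six resistance-tagged ingredients on dominant crops:
  approving countries are capped cellwise at the reference country's
  crop-area-weighted mean rate (the operational reading of "the
  reference country is the upper bound"), non-approving countries are
  *set* to 30% of it (replacement, not scaling), and bans win.
* **Inventory totals correct level, not pattern.** The country factor
  min[F_M·R_c, H/L ratio of the reference country] rescales both bounds
  uniformly within a country; the spatial pattern inside the country is
  left to the covariate inference. The reference country is exempt. The
  cap ratio is per (ingredient, crop), following the index structure of
  the conditioning identity; only total (not class-resolved) masses are
  used for conditioning, classes being reserved for validation.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| k_ingredients | 20 | — | ingredients kept per crop at the reference year |
| record rules | ≤10 missing of 25, ≤5 of last 10 | years | keeps trend fits meaningful |
| top_k_covariates | 5 | — | covariates combined in inference |
| CI level | 0.95 | — | two-sided mean-response band |
| crop saturation | 0.95 | — | max crop fraction of a cell; excess rescaled proportionally, preserving class shares |
| GM fraction | 0.30 | — | non-approving-country rate relative to reference |
| spline λ | GCV | — | roughness penalty chosen by generalized cross-validation per series |
| ref year / horizon | 2015 / 2025 | year | projection window |

## The synthetic world

The generator emulates the statistical structure of the real source
stack so that every stage is testable without external data:

* countries are nearest-seed (Voronoi) partitions of the grid, relabelled
  so the largest is the reference country, itself partitioned into
  states; adjacency is rook contiguity of the label grid;
* covariates are smoothed white-noise fields (Gaussian filter, σ = 3
  cells, wrap in longitude), standardized, so |R| rankings are
  nondegenerate;
* each (ingredient, crop) truth surface is linear in 1–5 covariates with
  the intercept chosen to keep the surface strictly positive — no
  clamping, so state regressions can be exact;
* per-crop areas are spatially uniform (same hectares in every cell).
  This is deliberate: state rates are area-weighted means of the truth
  while state covariate means are unweighted, and uniform areas make the
  two coincide, which the exactness tests require;
* panel masses are exact state integrals of the truth times a linear
  national time trend (slope ±2%/yr by default), perturbed by relative
  Gaussian noise (5%), split into a symmetric ±20% high/low band, and
  thinned by 5% missingness;
* country totals integrate the truth, split multi-class ingredient mass
  equally across classes, and perturb each class total by 5% relative
  noise.

What the synthetic world does **not** emulate: realistic marginal
distributions of soil/climate layers, correlated covariates, political
geography, nonlinear dose–environment relations, or reporting biases
that correlate with wealth. Passing tests therefore demonstrate the
correctness of the computational chain and its statistical calibration
under the stated generative model — not the fidelity of any real-world
map.

### The zero-noise fixed point

With noise, spread, missingness and perturbation all zero and
single-covariate truth surfaces, the pipeline run with one covariate per
combination reproduces the truth to ~1e-13 kg/ha and national masses to
~1e-15 relative. The single-covariate restriction is structural: with
multiple selected covariates, covariates other than the generating one
acquire nonzero sample correlations across the finite set of states and
enter the weighted sum with nonzero weight, so exact recovery is only
defined for the single-covariate configuration. Noisy, multi-covariate
recovery is instead checked statistically: fitted slopes fall within 3
standard errors of the generating slopes for ≥95% of triples across 20
seeds (observed ≈97%).

## Cross-validation harness

Cells are reduced to equal-count bin averages taken along the rate axis,
so each point carries the mean rate together with the mean of every
covariate and remains jointly usable by the multi-covariate combination
(binning each covariate separately would break the cell correspondence
the combined prediction needs). A seeded random split at the calibration
fraction defines the calibration points; per-covariate polynomials
(order 1 by default; 2–3 available for comparison) are fitted there,
weighted by calibration |R|, and scored on the validation points with
R, NRMSE (RMSE as % of the validation-set value range — the range
normalization makes the score unit-free and comparable across
calibration fractions) and rank = (1 − |R|)·100 + NRMSE.

## Numerical choices and degenerate inputs

* Correlation on zero-variance input is defined as 0 (the covariate
  carries no signal); such covariates can still enter with equal weights
  if nothing else is available, and that event is logged.
* Fits need ≥3 complete states; fewer drops the covariate. Confidence
  bands need n > 2.
* Covariates missing in a cell drop out with cellwise weight
  renormalization (logged); cells without the crop are no-data (NaN
  internally, format-native no-data on disk).
* Exactly collinear smoothing input bypasses the GCV search (which is
  ill-conditioned at zero residual) and returns the line.
* Ranking ties break lexicographically by ingredient id; covariate
  selection ties break lexicographically by covariate name — both make
  selection order-invariant.
* Countries with no reported inventory take the mean R_c of reported
  neighbours, else the global mean (logged as a fallback); the same
  machinery fills missing class-validation factors.
* A reference H/L ratio with zero denominator omits the conditioning cap
  rather than producing an infinite factor (logged).
* Multi-class ingredient mass is divided equally among its classes in
  totals and validation alike, so the two sides of the comparison use
  one convention.
* The quality index drops the crop-matching factor for pasture/hay
  (whose matching is not quantifiable) and reduces the exponent
  accordingly; a zero class-validation factor forces QI = 0 for that
  country, as the geometric mean dictates.
* QF_HT uses the covariates actually combined (the top 5), not all 20;
  its n is the mean n-fraction of those covariates (identical when no
  state is missing).

## Problem sizes and formats

Default study grids are 72×144 (zero-noise fixed point) and 48×96
(statistical suites, 20 seeds), with 8 countries, 12 states, 5
ingredients and 3 crops — small enough for exhaustive property testing
while exercising every code path. Rasters are written as GeoTIFF (WGS84
geokeys, pixel-scale/tiepoint geotransform, no-data tag, via tifffile)
and NetCDF (classic format via xarray's scipy backend, with coordinate
vectors and a CRS attribute); PNG output is a rendered preview only.
Every export directory carries a SHA256 manifest for re-verification.

## Known limitations

* Historical (pre-reference-year) reconstruction is out of scope: ban
  and GM chronologies are held static at the reference-year snapshot.
* Trade, embargoes, organic-farming transitions and other aleatory
  drivers are not modelled; the high/low band is assumed to contain such
  fluctuations.
* The conditioning factor corrects national totals only; subnational
  misallocation of the covariate model is invisible to it.
* NetCDF output uses the classic format, not NetCDF-4/HDF5.
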