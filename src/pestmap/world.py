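"""Self-consistent synthetic worlds for pipeline testing and recovery studies.

A world bundles a regular lat/lon grid partitioned into countries (country
0 plays the role of the reference country whose state-level usage panel
seeds the pipeline, itself partitioned into states), standardized
spatially autocorrelated covariate fields, per-(ingredient, crop) true
application-rate surfaces that are exactly linear in a small set of
covariates, a state usage panel integrated from the truth with
configurable noise / high-low spread / missingness, country inventory
totals consistent with the truth up to a configurable perturbation, and
ban / GM registries.

With all noise terms at zero the world is an exact fixed point: every
pipeline stage recovers the generating truth to floating-point accuracy,
which the test-suite and acceptance checks exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .conditioning import BanRegistry, GMRegistry
from .grids import AreaGrid, GridSpec, RegionMask, cell_area_grid, rook_adjacency
from .inference import CovariateStack
from .quality import PESTICIDE_CLASSES
from .usage import CROP_CLASSES, PANEL_COLUMNS

#: Covariate names mirroring the twenty environmental layers used for
#: global inference (soil, hydroclimatic, agronomic, socio-economic).
COVARIATE_NAMES = [
    "sand",
    "silt",
    "clay",
    "soc",
    "porosity",
    "soil_thickness",
    "water_table_depth",
    "precipitation",
    "temperature",
    "net_radiation",
    "npp",
    "evapotranspiration",
    "thermal_climate",
    "n_rate",
    "p_rate",
    "crop_yield",
    "water_security",
    "population_density",
    "gdp",
    "hdi",
]


@dataclass(frozen=True)
class WorldConfig:
    grid_rows: int = 72
    grid_cols: int = 144
    bbox: tuple[float, float, float, float] = (-180.0, 180.0, -56.0, 84.0)
    n_states: int = 12
    n_countries: int = 8
    n_ai: int = 5
    n_crops: int = 3
    years: tuple[int, int] = (1992, 2016)
    ref_year: int = 2015
    n_covariates: int = 20
    covariates_per_response: tuple[int, int] = (2, 5)
    noise_sd_frac: float = 0.05
    highlow_spread_frac: float = 0.20
    missing_rate: float = 0.05
    faostat_perturb_frac: float = 0.05
    trend_slope_frac: float = 0.02
    covariate_autocorr_sigma: float = 3.0
    n_bans: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_states", "n_countries", "n_ai", "n_crops", "n_covariates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_crops > len(CROP_CLASSES):
            raise ValueError(f"n_crops must be <= {len(CROP_CLASSES)}")
        for name in ("noise_sd_frac", "highlow_spread_frac", "missing_rate", "faostat_perturb_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        lon0, lon1, lat0, lat1 = self.bbox
        if not (lon0 < lon1 and lat0 < lat1):
            raise ValueError("bbox is not well-ordered")
        lo, hi = self.covariates_per_response
        if not 1 <= lo <= hi <= self.n_covariates:
            raise ValueError("covariates_per_response out of range")
        if self.years[0] > self.years[1] or not self.years[0] <= self.ref_year <= self.years[1]:
            raise ValueError("reference year must lie inside the year range")

    @property
    def ais(self) -> list[str]:
        return [f"ai_{i:02d}" for i in range(self.n_ai)]

    @property
    def crops(self) -> list[str]:
        return CROP_CLASSES[: self.n_crops]

    @property
    def covariate_names(self) -> list[str]:
        base = list(COVARIATE_NAMES)
        while len(base) < self.n_covariates:
            base.append(f"x_{len(base):02d}")
        return base[: self.n_covariates]


@dataclass
class WorldBundle:
    config: WorldConfig
    grid_spec: GridSpec
    state_mask: RegionMask
    country_mask: RegionMask
    crop_areas: AreaGrid
    covariates: CovariateStack
    true_coefficients: pd.DataFrame  # ai, crop, covariate, slope; plus intercept rows
    true_intercepts: dict[tuple[str, str], float]
    true_apr: dict[tuple[str, str], np.ndarray]
    true_trend_slopes: dict[tuple[str, str], float]
    usage_panel: pd.DataFrame
    faostat_totals: dict[int, float]  # country -> total tonnes/yr (all classes)
    faostat_by_class: dict[tuple[int, str], float]
    bans: BanRegistry
    gm: GMRegistry = field(default_factory=GMRegistry)
    ai_classes: dict[str, set[str]] = field(default_factory=dict)

    def mass_ratio(self, ai: str, crop: str, year: int) -> float:
        """True national-mass ratio M(t) / M(ref_year)."""
        s = self.true_trend_slopes[(ai, crop)]
        return 1.0 + s * (year - self.config.ref_year)


def _voronoi_labels(
    shape: tuple[int, int], n_regions: int, rng: np.random.Generator, where: np.ndarray | None = None
) -> np.ndarray:
    """Nearest-seed labelling of (a subset of) grid cells; -1 elsewhere."""
    rows, cols = shape
    cand = np.argwhere(where) if where is not None else np.argwhere(np.ones(shape, bool))
    if len(cand) < n_regions:
        raise ValueError(f"infeasible geometry: {n_regions} regions for {len(cand)} cells")
    seeds = cand[rng.choice(len(cand), size=n_regions, replace=False)]
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1).astype(int)
    if where is not None:
        labels = np.where(where, labels, -1)
    # relabel by decreasing size so region 0 is the largest
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    out = labels.copy()
    for old, new in remap.items():
        out[labels == old] = new
    return out


def _smooth_standard_field(
    shape: tuple[int, int], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    field = rng.standard_normal(shape)
    if sigma > 0:
        field = gaussian_filter(field, sigma=sigma, mode=("nearest", "wrap"))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_world(config: WorldConfig) -> WorldBundle:
    """Draw a complete, self-consistent world from a seeded generator.

    True rate surfaces are linear in 1-5 covariates with a strictly
    positive intercept margin (no clamping, so state regressions can be
    exact); state panel masses are the exact area integrals of the truth
    times a linear national time trend, then perturbed by relative noise,
    split into a symmetric high/low band, and thinned by missingness.
    """
    rng = np.random.default_rng(config.seed)
    lon0, lon1, lat0, lat1 = config.bbox
    spec = GridSpec(config.grid_rows, config.grid_cols, lon0, lon1, lat0, lat1)
    shape = spec.shape
    n_cells = shape[0] * shape[1]
    if config.n_countries > n_cells:
        raise ValueError("infeasible geometry: more countries than cells")

    country_labels = _voronoi_labels(shape, config.n_countries, rng)
    country_mask = RegionMask(labels=country_labels, adjacency=rook_adjacency(country_labels))
    ref_cells = country_labels == 0
    if config.n_states > int(ref_cells.sum()):
        raise ValueError("infeasible geometry: more states than reference-country cells")
    state_labels = _voronoi_labels(shape, config.n_states, rng, where=ref_cells)
    state_mask = RegionMask(labels=state_labels)

    covs = {
        name: _smooth_standard_field(shape, config.covariate_autocorr_sigma, rng)
        for name in config.covariate_names
    }
    stack = CovariateStack(spec=spec, grids=covs)

    # uniform per-cell crop areas (same hectares in every cell) so that
    # area-weighted state rates coincide with unweighted cell means
    cell_ha = cell_area_grid(spec)
    min_ha = float(cell_ha.min())
    per_crop_ha = 0.90 * min_ha / config.n_crops
    crop_areas = AreaGrid(
        spec=spec, layers={crop: np.full(shape, per_crop_ha) for crop in config.crops}
    )

    # true linear surfaces
    lo_k, hi_k = config.covariates_per_response
    names = config.covariate_names
    coef_rows = []
    intercepts: dict[tuple[str, str], float] = {}
    true_apr: dict[tuple[str, str], np.ndarray] = {}
    trend_slopes: dict[tuple[str, str], float] = {}
    for ai in config.ais:
        for crop in config.crops:
            n_use = int(rng.integers(lo_k, hi_k + 1))
            used = list(rng.choice(names, size=n_use, replace=False))
            raw = np.zeros(shape)
            for cov in used:
                slope = float(rng.normal(0.0, 0.3))
                coef_rows.append({"ai": ai, "crop": crop, "covariate": cov, "slope": slope})
                raw += slope * covs[cov]
            margin = 0.5 + float(rng.uniform(0.0, 1.0))
            intercept = margin - float(raw.min())
            intercepts[(ai, crop)] = intercept
            true_apr[(ai, crop)] = raw + intercept
            trend_slopes[(ai, crop)] = float(
                rng.uniform(-config.trend_slope_frac, config.trend_slope_frac)
            )

    # bans (never in the reference country); truth zeroed where banned
    bans = BanRegistry()
    if config.n_bans > 0 and config.n_countries > 1:
        for _ in range(config.n_bans):
            country = int(rng.integers(1, config.n_countries))
            ai = str(rng.choice(config.ais))
            bans.banned.add((country, ai))
        for (country, ai) in bans.banned:
            inside = country_labels == country
            for crop in config.crops:
                true_apr[(ai, crop)] = np.where(inside, 0.0, true_apr[(ai, crop)])

    # pesticide classes: ingredients cycle through one- and two-class tags
    ai_classes: dict[str, set[str]] = {}
    for i, ai in enumerate(config.ais):
        primary = PESTICIDE_CLASSES[i % 3]
        classes = {primary}
        if i % 2 == 1:
            classes.add(PESTICIDE_CLASSES[(i + 1) % 3])
        ai_classes[ai] = classes

    # usage panel: exact state integrals of truth x linear national trend,
    # then relative noise, symmetric high/low band, missingness
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    state_ids = state_mask.region_ids()
    records = []
    for ai in config.ais:
        for crop in config.crops:
            apr = true_apr[(ai, crop)]
            area = crop_areas.layers[crop]
            s = trend_slopes[(ai, crop)]
            for state in state_ids:
                inside = state_labels == state
                base = float(np.sum(apr[inside] * area[inside]))  # kg/yr at ref year
                for year in years:
                    g = 1.0 + s * (year - config.ref_year)
                    m = base * g
                    if config.noise_sd_frac > 0:
                        m = max(0.0, m * (1.0 + config.noise_sd_frac * rng.standard_normal()))
                    high = m * (1.0 + config.highlow_spread_frac)
                    low = m * (1.0 - config.highlow_spread_frac)
                    if rng.random() < config.missing_rate:
                        high = low = np.nan
                    records.append((ai, crop, int(state), int(year), high, low))
    panel = pd.DataFrame(records, columns=PANEL_COLUMNS)

    by_class, totals = make_faostat_totals(
        true_apr,
        crop_areas,
        country_mask,
        ai_classes,
        perturb=config.faostat_perturb_frac,
        rng=rng,
    )

    return WorldBundle(
        config=config,
        grid_spec=spec,
        state_mask=state_mask,
        country_mask=country_mask,
        crop_areas=crop_areas,
        covariates=stack,
        true_coefficients=pd.DataFrame(coef_rows, columns=["ai", "crop", "covariate", "slope"]),
        true_intercepts=intercepts,
        true_apr=true_apr,
        true_trend_slopes=trend_slopes,
        usage_panel=panel,
        faostat_totals=totals,
        faostat_by_class=by_class,
        bans=bans,
        gm=GMRegistry(approvals=set()),
        ai_classes=ai_classes,
    )


def make_faostat_totals(
    true_apr: dict[tuple[str, str], np.ndarray],
    crop_areas: AreaGrid,
    country_mask: RegionMask,
    ai_classes: dict[str, set[str]],
    perturb: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[dict[tuple[int, str], float], dict[int, float]]:
    """Country inventory totals [tonnes/yr] integrated from the truth.

    Multi-class ingredients have their mass divided equally across their
    classes (so class totals sum to the ingredient total). ``perturb``
    applies independent relative perturbations per (country, class);
    country grand totals are the sums of the perturbed class totals.
    Returns (per-(country, class) totals, per-country grand totals).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for ai in {ai for ai, _ in true_apr}:
        if ai not in ai_classes:
            raise ValueError(f"ingredient {ai} has no pesticide-class assignment")
        unknown = ai_classes[ai] - set(PESTICIDE_CLASSES)
        if unknown:
            raise ValueError(f"unknown pesticide classes {sorted(unknown)} for {ai}")
    ids = [int(c) for c in country_mask.region_ids()]
    by_class: dict[tuple[int, str], float] = {
        (c, z): 0.0 for c in ids for z in PESTICIDE_CLASSES
    }
    for (ai, crop), apr in true_apr.items():
        mass_kg = apr * crop_areas.layers[crop]
        classes = sorted(ai_classes[ai])
        for country in ids:
            m_t = float(np.sum(mass_kg[country_mask.labels == country])) / 1000.0
            for z in classes:
                by_class[(country, z)] += m_t / len(classes)
    if perturb > 0:
        for key in sorted(by_class):
            by_class[key] = max(0.0, by_class[key] * (1.0 + perturb * rng.standard_normal()))
    totals = {c: 0.0 for c in ids}
    for (c, _z), v in by_class.items():
        totals[c] += v
    return by_class, totals


# ---------------------------------------------------------------------------
# bundle serialization (NetCDF grids + delimited tables)


def save_bundle(bundle: WorldBundle, out_dir: str | Path) -> None:
    """Write a bundle to a directory: grids as NetCDF, tables as CSV."""
    import xarray as xr

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = bundle.grid_spec
    coords = {"lat": spec.lats(), "lon": spec.lons()}
    ds = xr.Dataset(
        {
            "state": (("lat", "lon"), bundle.state_mask.labels),
            "country": (("lat", "lon"), bundle.country_mask.labels),
            **{f"cov_{k}": (("lat", "lon"), v) for k, v in bundle.covariates.grids.items()},
            **{f"area_{c}": (("lat", "lon"), g) for c, g in bundle.crop_areas.layers.items()},
            **{
                f"true_apr_{ai}_{crop}": (("lat", "lon"), g)
                for (ai, crop), g in bundle.true_apr.items()
            },
        },
        coords=coords,
        attrs={"crs": "EPSG:4326"},
    )
    ds.to_netcdf(out / "grids.nc", engine="scipy")
    bundle.usage_panel.to_csv(out / "usage_panel.csv", index=False)
    bundle.true_coefficients.to_csv(out / "true_coefficients.csv", index=False)
    pd.DataFrame(
        [(c, z, v) for (c, z), v in bundle.faostat_by_class.items()],
        columns=["country", "pclass", "tonnes"],
    ).to_csv(out / "faostat_totals.csv", index=False)
    pd.DataFrame(
        [(c, a) for c, a in sorted(bundle.bans.banned)], columns=["country", "ai"]
    ).to_csv(out / "bans.csv", index=False)
    pd.DataFrame(
        [(c, crop, a) for c, crop, a in sorted(bundle.gm.approvals)],
        columns=["country", "crop", "ai"],
    ).to_csv(out / "gm_approvals.csv", index=False)
    pd.DataFrame(
        [(a, z) for a, zs in bundle.ai_classes.items() for z in sorted(zs)],
        columns=["ai", "pclass"],
    ).to_csv(out / "ai_classes.csv", index=False)
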