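"""End-to-end orchestration: usage panel -> conditioned rate and quality maps.

Runs the full estimation chain on a world bundle (synthetic or loaded):
bound reconstruction, reference-year interpolation, national summaries,
ingredient selection, spline smoothing and trend projection, state rates,
covariate regressions and weighted global inference, then ban / GM /
inventory conditioning, temporal projection, and quality-index mapping.
The result is a pure function of (bundle, config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conditioning as cond
from . import inference as inf
from . import quality as qual
from . import usage
from .grids import CropMatchTable, cell_area_grid, cap_crop_saturation, compute_state_apr, zonal_crop_areas
from .rasters import MapProduct, apr_layer_name, qi_layer_name, write_raster
from .world import WorldBundle


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the estimation chain (defaults mirror the reference study)."""

    k_ingredients: int = 20
    top_k_covariates: int = 5
    ref_year: int = 2015
    horizon: int = 2025
    projection_years: tuple[int, ...] = (2020, 2025)
    max_missing_total: int = 10
    max_missing_recent: int = 5
    crop_saturation: float = 0.95
    spline_lam: float | None = None  # None = generalized cross-validation
    f_m_override: float | None = None
    total_states: int | None = None  # None = number of states in the bundle


@dataclass
class PipelineResult:
    selection: usage.SelectionResult
    trends: dict[tuple[str, str], usage.TrendFit]
    prefactors: dict[tuple[str, str], dict[int, float] | None]
    state_apr: pd.DataFrame
    fits: dict[tuple[str, str], dict[str, inf.CovariateFit]]
    weights: dict[tuple[str, str], inf.WeightSet]
    raw_apr: dict[tuple[str, str], inf.RawGlobalAPR]
    corrections: dict[int, cond.CountryCorrection]
    finals: dict[tuple[str, str], cond.FinalAPR]
    qf_sa: dict[str, float | None]
    qf_ht: dict[tuple[str, str], float]
    qf_z: dict[int, dict[str, float]]
    qi: dict[tuple[str, str], np.ndarray]
    f_m: float
    log: list[str] = field(default_factory=list)

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.finals)


def run_pipeline(
    bundle: WorldBundle,
    config: PipelineConfig = PipelineConfig(),
    match_table: CropMatchTable | None = None,
) -> PipelineResult:
    log: list[str] = []
    cfg = config
    ref_year = cfg.ref_year

    # --- usage reanalysis -------------------------------------------------
    panel = usage.fill_missing_bounds(bundle.usage_panel, log=log)
    panel = usage.interpolate_reference_year(panel, ref_year=ref_year)
    series = usage.summarize_states(panel, years=bundle.config.years)
    selection = usage.rank_and_select(
        series,
        k=cfg.k_ingredients,
        ref_year=ref_year,
        max_missing_total=cfg.max_missing_total,
        max_missing_recent=cfg.max_missing_recent,
        log=log,
    )
    f_m = cfg.f_m_override if cfg.f_m_override is not None else selection.f_m
    pairs = selection.selected_pairs()

    sel_state = series.state.merge(
        selection.selected.rename(columns={"ai": "ai", "crop": "crop"}),
        on=["ai", "crop"],
    )
    sel_series = usage.NationalSeries(state=sel_state, national=series.national, years=series.years)
    state_smoothed = usage.smooth_state_series(sel_series, lam=cfg.spline_lam, log=log)
    national = usage.national_smoothed(state_smoothed)

    trends: dict[tuple[str, str], usage.TrendFit] = {}
    prefactors: dict[tuple[str, str], dict[int, float] | None] = {}
    for (ai, crop), grp in national.groupby(["ai", "crop"]):
        fit = usage.fit_linear_trend(grp["year"].to_numpy(), grp["m_s"].to_numpy(), ai=ai, crop=crop)
        trends[(ai, crop)] = fit
        ref = grp.loc[grp["year"] == ref_year, "m_s"]
        m_ref = float(ref.iloc[0]) if len(ref) else np.nan
        prefactors[(ai, crop)] = usage.compute_prefactors(
            fit, m_ref, ref_year=ref_year, horizon=cfg.horizon, log=log
        )

    # --- crop grids and state rates --------------------------------------
    cell_ha = cell_area_grid(bundle.grid_spec)
    areas = cap_crop_saturation(bundle.crop_areas, cell_ha, cfg.crop_saturation)
    state_areas = zonal_crop_areas(areas, bundle.state_mask)
    state_apr = compute_state_apr(state_smoothed, state_areas, log=log)
    apr_ref = state_apr[state_apr["year"] == ref_year]

    # --- spatial inference ------------------------------------------------
    means = inf.state_covariate_means(bundle.covariates, bundle.state_mask)
    total_states = cfg.total_states or bundle.config.n_states
    fits: dict[tuple[str, str], dict[str, inf.CovariateFit]] = {}
    weights: dict[tuple[str, str], inf.WeightSet] = {}
    raw_apr: dict[tuple[str, str], inf.RawGlobalAPR] = {}
    for ai, crop in pairs:
        rows = apr_ref[(apr_ref["ai"] == ai) & (apr_ref["crop"] == crop)]
        by_state = rows.set_index("state")["apr_median"]
        pair_fits: dict[str, inf.CovariateFit] = {}
        for cov, cov_means in means.groupby("covariate"):
            joined = cov_means.set_index("state")["mean"].to_frame("x").join(by_state, how="inner")
            fit = inf.fit_apr_covariate(
                joined["apr_median"].to_numpy(),
                joined["x"].to_numpy(),
                ai=ai,
                crop=crop,
                covariate=cov,
                total_states=total_states,
            )
            if fit is not None:
                pair_fits[cov] = fit
        if not pair_fits:
            log.append(f"pipeline: no covariate fit for ({ai},{crop}), pair dropped")
            continue
        fits[(ai, crop)] = pair_fits
        wset = inf.compute_weights(list(pair_fits.values()), k=cfg.top_k_covariates, log=log)
        weights[(ai, crop)] = wset
        crop_present = areas.layers[crop] > 0
        raw_apr[(ai, crop)] = inf.infer_raw_global(
            pair_fits, wset, bundle.covariates, crop_present, log=log
        )

    # --- conditioning -----------------------------------------------------
    countries = bundle.country_mask
    ref_country = 0
    ref_inside = countries.labels == ref_country

    conditioned: dict[tuple[str, str], inf.RawGlobalAPR] = {}
    usa_ref: dict[tuple[str, str], tuple[float, float]] = {}
    for (ai, crop), apr in raw_apr.items():
        step = cond.apply_bans(apr, bundle.bans, countries)
        area = areas.layers[crop]
        w = np.where(ref_inside & np.isfinite(step.high), area, 0.0)
        wsum = w.sum()
        if wsum > 0:
            usa_h = float(np.nansum(np.where(w > 0, step.high, 0.0) * w) / wsum)
            usa_l = float(np.nansum(np.where(w > 0, step.low, 0.0) * w) / wsum)
        else:
            usa_h = usa_l = np.nan
        usa_ref[(ai, crop)] = (usa_h, usa_l)
        step = cond.apply_gm_conditioning(
            step,
            bundle.gm,
            usa_apr_high=usa_h,
            usa_apr_low=usa_l,
            bans=bundle.bans,
            countries=countries,
            reference_country=ref_country,
            dominant_crops=set(usage.DOMINANT_CROPS),
            log=log,
        )
        conditioned[(ai, crop)] = step

    m_c = cond.country_masses(list(conditioned.values()), areas, countries)
    ratios = cond.correction_ratios(m_c, bundle.faostat_totals)
    corrections = cond.impute_missing_rc(
        ratios, [int(c) for c in countries.region_ids()], countries.adjacency, m_c=m_c, log=log
    )

    finals: dict[tuple[str, str], cond.FinalAPR] = {}
    for (ai, crop), apr in conditioned.items():
        usa_h, usa_l = usa_ref[(ai, crop)]
        usa_ratio = usa_h / usa_l if usa_l and np.isfinite(usa_l) and usa_l > 0 else None
        step = cond.faostat_condition(
            apr, corrections, f_m=f_m, usa_ratio=usa_ratio, countries=countries,
            reference_country=ref_country, log=log,
        )
        finals[(ai, crop)] = cond.project_estimates(
            step, prefactors.get((ai, crop)), ref_year=ref_year,
            years=cfg.projection_years, log=log,
        )

    # --- quality ----------------------------------------------------------
    if match_table is None:
        match_table = CropMatchTable(dominant=list(areas.layers), aggregated={})
    qf_sa = qual.qf_sa(match_table)
    for crop in areas.layers:
        qf_sa.setdefault(crop, 1.0)

    qf_ht: dict[tuple[str, str], float] = {}
    for (ai, crop), wset in weights.items():
        used = [fits[(ai, crop)][name] for name in wset.names()]
        n_frac = float(np.mean([f.n_frac for f in used]))
        qf_ht[(ai, crop)] = qual.qf_ht(n_frac, [f.r for f in used], log=log)

    report = qual.class_mass_report(
        list(finals.values()), areas, countries, bundle.ai_classes,
        bundle.faostat_by_class, year=ref_year, log=log,
    )
    qf_z: dict[int, dict[str, float]] = {}
    for row in report.table.itertuples():
        qf_z.setdefault(int(row.country), {})[row.pclass] = qual.qf_z(
            row.mass_est, row.mass_reported
        )
    # countries absent from the reported class totals inherit the neighbour
    # mean per class, falling back to the global mean (mirrors R_c handling)
    all_ids = [int(c) for c in countries.region_ids()]
    for z in qual.PESTICIDE_CLASSES:
        have = {c: d[z] for c, d in qf_z.items() if z in d}
        if not have:
            continue
        global_mean = float(np.mean(list(have.values())))
        for c in all_ids:
            if c in have:
                continue
            neigh = [have[n] for n in countries.adjacency.get(c, set()) if n in have]
            qf_z.setdefault(c, {})[z] = float(np.mean(neigh)) if neigh else global_mean

    qi: dict[tuple[str, str], np.ndarray] = {}
    for (ai, crop) in finals:
        if (ai, crop) not in qf_ht:
            continue
        qi[(ai, crop)] = qual.qi_grid(
            qf_sa.get(crop), qf_ht[(ai, crop)], qf_z, bundle.ai_classes.get(ai, set()), countries
        )

    return PipelineResult(
        selection=selection,
        trends=trends,
        prefactors=prefactors,
        state_apr=state_apr,
        fits=fits,
        weights=weights,
        raw_apr=raw_apr,
        corrections=corrections,
        finals=finals,
        qf_sa=qf_sa,
        qf_ht=qf_ht,
        qf_z=qf_z,
        qi=qi,
        f_m=float(f_m),
        log=log,
    )


# ---------------------------------------------------------------------------
# product export


def export_products(
    result: PipelineResult,
    bundle: WorldBundle,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("netcdf",),
) -> dict:
    """Write rate and quality maps plus diagnostic tables; return a manifest
    of relative paths to SHA256 content hashes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = bundle.grid_spec
    suffix = {"netcdf": ".nc", "gtiff": ".tif", "png": ".png"}
    written: list[Path] = []
    for (ai, crop), final in result.finals.items():
        for year, grids in final.grids.items():
            for bound, key in (("H", "high"), ("L", "low")):
                name = apr_layer_name(crop, ai, year, bound)
                product = MapProduct(name=name, grid=grids[key], spec=spec, units="kg/ha/yr")
                for fmt in formats:
                    written.append(write_raster(product, out / f"{name}{suffix[fmt]}", fmt=fmt))
    for (ai, crop), grid in result.qi.items():
        name = qi_layer_name(crop, ai)
        product = MapProduct(name=name, grid=grid, spec=spec, units="1")
        for fmt in formats:
            written.append(write_raster(product, out / f"{name}{suffix[fmt]}", fmt=fmt))

    result.selection.ranked.to_csv(out / "selection.csv", index=False)
    pd.DataFrame(
        [
            {"ai": ai, "crop": crop, "slope": t.slope, "intercept": t.intercept,
             "r2": t.r2, "rmse": t.rmse, "n_years": t.n_years}
            for (ai, crop), t in result.trends.items()
        ]
    ).to_csv(out / "trends.csv", index=False)
    pd.DataFrame(
        [
            {"ai": ai, "crop": crop, "covariate": name, "weight": w}
            for (ai, crop), ws in result.weights.items()
            for name, w in ws.weights.items()
        ]
    ).to_csv(out / "weights.csv", index=False)
    pd.DataFrame(
        [
            {"country": c.country, "m_c": c.m_c, "m_c_fao": c.m_c_fao, "r_c": c.r_c,
             "source": c.source}
            for c in result.corrections.values()
        ]
    ).to_csv(out / "corrections.csv", index=False)
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
    written += [out / "selection.csv", out / "trends.csv", out / "weights.csv", out / "corrections.csv"]

    manifest = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest() for p in written
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every file listed in the manifest; True if all match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(
        hashlib.sha256((out / rel).read_bytes()).hexdigest() == digest
        for rel, digest in manifest.items()
    )
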