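"""Reanalysis of state-level pesticide-use panels.

A usage panel records, for each (active ingredient, crop class, state,
year), a high and a low bound on the annually applied mass [kg/yr], with
either or both bounds possibly missing. This module reconstructs missing
bounds, interpolates the reference year, aggregates states into national
series, selects the top-used ingredients, smooths the historical median
mass with cubic smoothing splines, fits linear trends and turns projected
masses into mapping prefactors that scale reference-year maps forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

PANEL_COLUMNS = ["ai", "crop", "state", "year", "mass_high", "mass_low"]

#: The ten crop classes: six dominant crops and four aggregated classes.
DOMINANT_CROPS = ["Corn", "Soyabean", "Wheat", "Cotton", "Rice", "Alfalfa"]
AGGREGATED_CROPS = ["VegFru", "OrcGra", "PasHay", "Other"]
CROP_CLASSES = DOMINANT_CROPS + AGGREGATED_CROPS

DEFAULT_YEARS = (1992, 2016)
DEFAULT_REF_YEAR = 2015


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
    both = panel["mass_high"].notna() & panel["mass_low"].notna()
    bad = both & (panel["mass_high"] < panel["mass_low"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} panel rows have high < low")
    if ((panel[["mass_high", "mass_low"]] < 0).any()).any():
        raise ValueError("negative masses in panel")
    return panel


def fill_missing_bounds(panel: pd.DataFrame, log: list[str] | None = None) -> pd.DataFrame:
    """Complete cells where exactly one bound is present.

    The fill factor is the (ai, crop)-specific mean high/low ratio over all
    state-years where both bounds exist. Cells with both or neither bound
    are untouched; cells with no ratio available stay missing (logged).
    Idempotent: a second pass finds nothing left to fill.
    """
    panel = validate_panel(panel).copy()
    both = panel["mass_high"].notna() & panel["mass_low"].notna()
    pos = both & (panel["mass_low"] > 0)
    ratios = (
        panel.loc[pos]
        .assign(ratio=lambda d: d["mass_high"] / d["mass_low"])
        .groupby(["ai", "crop"])["ratio"]
        .mean()
    )
    key = pd.MultiIndex.from_frame(panel[["ai", "crop"]])
    r = pd.Series(ratios.reindex(key).to_numpy(), index=panel.index)

    only_low = panel["mass_low"].notna() & panel["mass_high"].isna()
    only_high = panel["mass_high"].notna() & panel["mass_low"].isna()
    can_low = only_low & r.notna()
    can_high = only_high & r.notna()
    panel.loc[can_low, "mass_high"] = panel.loc[can_low, "mass_low"] * r[can_low]
    panel.loc[can_high, "mass_low"] = panel.loc[can_high, "mass_high"] / r[can_high]
    if log is not None:
        n_filled = int(can_low.sum() + can_high.sum())
        n_left = int(((only_low | only_high) & r.isna()).sum())
        log.append(f"fill_missing_bounds: filled {n_filled}, no ratio for {n_left}")
    return panel


def interpolate_reference_year(
    panel: pd.DataFrame, ref_year: int = DEFAULT_REF_YEAR
) -> pd.DataFrame:
    """Fill missing reference-year bounds with the mean of the two adjacent
    years, per bound independently; no-op where a neighbour is missing."""
    panel = validate_panel(panel).copy()
    wide = panel.pivot_table(
        index=["ai", "crop", "state"],
        columns="year",
        values=["mass_high", "mass_low"],
        dropna=False,
    )
    rows = []
    for bound in ("mass_high", "mass_low"):
        sub = wide[bound] if bound in wide.columns.get_level_values(0) else None
        if sub is None or not {ref_year - 1, ref_year + 1} <= set(sub.columns):
            continue
        need = (
            (ref_year not in sub.columns or sub[ref_year].isna())
            & sub[ref_year - 1].notna()
            & sub[ref_year + 1].notna()
        )
        filled = 0.5 * (sub.loc[need, ref_year - 1] + sub.loc[need, ref_year + 1])
        for (ai, crop, state), val in filled.items():
            rows.append((ai, crop, state, bound, val))
    if not rows:
        return panel

    fill = pd.DataFrame(rows, columns=["ai", "crop", "state", "bound", "value"])
    fill = fill.pivot_table(
        index=["ai", "crop", "state"], columns="bound", values="value"
    ).reset_index()
    fill["year"] = ref_year
    merged = panel.merge(fill, on=["ai", "crop", "state", "year"], how="left")
    for bound in ("mass_high", "mass_low"):
        if bound in fill.columns:
            take = merged[bound + "_x"].isna() & merged[bound + "_y"].notna()
            merged.loc[take, bound + "_x"] = merged.loc[take, bound + "_y"]
        merged = merged.rename(columns={bound + "_x": bound})
    # rows present only in `fill` (the panel had no ref-year record at all)
    key = ["ai", "crop", "state", "year"]
    extra = fill.merge(panel[key], on=key, how="left", indicator=True)
    extra = extra[extra["_merge"] == "left_only"].drop(columns="_merge")
    out = pd.concat([merged[PANEL_COLUMNS], extra.reindex(columns=PANEL_COLUMNS)], ignore_index=True)
    return out


@dataclass
class NationalSeries:
    """State and national mass summaries of a reconstructed panel.

    ``state`` rows: ai, crop, state, year, mass_high, mass_low,
    state_median (midpoint of the high-low band, kg/yr).
    ``national`` rows: ai, crop, year, max_high (max over states),
    mean_low (mean over reporting states), median_mass (sum of state
    medians, kg/yr), n_states.
    """

    state: pd.DataFrame
    national: pd.DataFrame
    years: tuple[int, int] = DEFAULT_YEARS

    def missing_years(self, ai: str, crop: str) -> set[int]:
        have = set(
            self.national.loc[
                (self.national["ai"] == ai)
                & (self.national["crop"] == crop)
                & self.national["median_mass"].notna(),
                "year",
            ]
        )
        lo, hi = self.years
        return set(range(lo, hi + 1)) - have


def summarize_states(
    panel: pd.DataFrame, years: tuple[int, int] = DEFAULT_YEARS
) -> NationalSeries:
    """National range and median-mass series from a state panel.

    Per (ai, crop, year): the maximum of the state "high" bounds, the mean
    of the state "low" bounds, and the national median mass M = sum over
    states of the per-state band midpoint (high+low)/2.
    """
    panel = validate_panel(panel)
    state = panel.copy()
    state["state_median"] = 0.5 * (state["mass_high"] + state["mass_low"])
    has = state["state_median"].notna()
    nat = (
        state[has]
        .groupby(["ai", "crop", "year"])
        .agg(
            max_high=("mass_high", "max"),
            mean_low=("mass_low", "mean"),
            median_mass=("state_median", "sum"),
            n_states=("state", "nunique"),
        )
        .reset_index()
    )
    return NationalSeries(state=state, national=nat, years=years)


@dataclass
class SelectionResult:
    """Top-k ingredient selection with the mass-coverage factor F_M."""

    ranked: pd.DataFrame  # ai, crop, median_mass at reference year, rank
    selected: pd.DataFrame  # crop, ai
    f_m: float  # selected national mass / total national mass, cross-crop
    f_m_by_crop: dict[str, float]
    shortfall: dict[str, int] = field(default_factory=dict)

    def selected_pairs(self) -> list[tuple[str, str]]:
        return [(r.ai, r.crop) for r in self.selected.itertuples()]


def rank_and_select(
    series: NationalSeries,
    k: int = 20,
    ref_year: int = DEFAULT_REF_YEAR,
    max_missing_total: int = 10,
    max_missing_recent: int = 5,
    recent_window: int = 10,
    log: list[str] | None = None,
) -> SelectionResult:
    """Rank ingredients per crop by reference-year median mass and keep the
    top k that pass the record-completeness rules.

    Eligibility: at most ``max_missing_total`` missing years over the full
    record and at most ``max_missing_recent`` missing years within the last
    ``recent_window`` years. Ties in mass break lexicographically by ai.
    F_M is the selected share of the total reference-year national mass
    (union across crops); per-crop shares are also reported.
    """
    nat = series.national
    ref = nat[nat["year"] == ref_year]
    if ref.empty:
        raise ValueError(f"reference year {ref_year} absent from series")
    lo, hi = series.years
    recent_lo = hi - recent_window + 1

    rows, sel_rows, shortfall = [], [], {}
    for crop, grp in ref.groupby("crop"):
        grp = grp.sort_values(["median_mass", "ai"], ascending=[False, True])
        n_kept = 0
        for rank, r in enumerate(grp.itertuples(), start=1):
            miss = series.missing_years(r.ai, crop)
            miss_recent = {y for y in miss if y >= recent_lo}
            eligible = (
                len(miss) <= max_missing_total and len(miss_recent) <= max_missing_recent
            )
            take = eligible and n_kept < k
            rows.append(
                {
                    "ai": r.ai,
                    "crop": crop,
                    "median_mass": r.median_mass,
                    "rank": rank,
                    "eligible": eligible,
                    "selected": take,
                }
            )
            if take:
                sel_rows.append({"crop": crop, "ai": r.ai})
                n_kept += 1
        n_eligible = sum(1 for x in rows if x["crop"] == crop and x["eligible"])
        if n_eligible < k:
            shortfall[crop] = k - n_eligible
            if log is not None:
                log.append(f"rank_and_select: crop {crop} has only {n_eligible} eligible ai")

    ranked = pd.DataFrame(rows)
    selected = pd.DataFrame(sel_rows, columns=["crop", "ai"])
    total = ranked["median_mass"].sum()
    sel_mass = ranked.loc[ranked["selected"], "median_mass"].sum()
    f_m = float(sel_mass / total) if total > 0 else 1.0
    f_m_by_crop = {}
    for crop, grp in ranked.groupby("crop"):
        t = grp["median_mass"].sum()
        f_m_by_crop[crop] = float(grp.loc[grp["selected"], "median_mass"].sum() / t) if t > 0 else 1.0
    return SelectionResult(
        ranked=ranked, selected=selected, f_m=f_m, f_m_by_crop=f_m_by_crop, shortfall=shortfall
    )


def smooth_median_series(
    years: np.ndarray,
    values: np.ndarray,
    lam: float | None = None,
    log: list[str] | None = None,
) -> np.ndarray:
    """Cubic smoothing-spline fit evaluated at the observed years.

    ``lam`` is the roughness penalty; None selects it by generalized
    cross-validation. Missing values are excluded from the fit. With fewer
    than 4 points the raw series is returned unchanged (logged).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    out = np.full_like(values, np.nan)
    if ok.sum() < 4:
        if log is not None:
            log.append(f"smooth_median_series: only {int(ok.sum())} points, raw series kept")
        out[ok] = values[ok]
        return out
    x, y = years[ok], values[ok]
    if np.allclose(y, np.polyval(np.polyfit(x, y, 1), x), rtol=0, atol=1e-12 * max(1.0, np.abs(y).max())):
        # exactly collinear data: the smoothing spline is the line itself;
        # skip GCV, which is ill-conditioned at zero residual
        out[ok] = y
        return out
    spline = make_smoothing_spline(x, y, lam=lam)
    out[ok] = spline(x)
    return out


@dataclass
class TrendFit:
    """First-order trend M_r(t) = a*t + b on the smoothed national series."""

    ai: str
    crop: str
    slope: float  # kg/yr per year
    intercept: float  # kg/yr
    r2: float
    rmse: float
    n_years: int
    flagged: bool = False

    def predict(self, year: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(year, dtype=float) + self.intercept


def fit_linear_trend(
    years: np.ndarray, m_s: np.ndarray, ai: str = "", crop: str = ""
) -> TrendFit:
    """OLS line through the smoothed (year, mass) points with diagnostics."""
    years = np.asarray(years, dtype=float)
    m_s = np.asarray(m_s, dtype=float)
    ok = np.isfinite(m_s)
    x, y = years[ok], m_s[ok]
    if x.size == 0:
        raise ValueError("no points to fit")
    if x.size == 1:
        return TrendFit(ai, crop, 0.0, float(y[0]), r2=np.nan, rmse=0.0, n_years=1, flagged=True)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    return TrendFit(ai, crop, float(slope), float(intercept), r2=r2, rmse=rmse, n_years=int(x.size))


def compute_prefactors(
    fit: TrendFit,
    m_s_ref: float,
    ref_year: int = DEFAULT_REF_YEAR,
    horizon: int = 2025,
    log: list[str] | None = None,
) -> dict[int, float] | None:
    """Mapping prefactors F(t) = M_r(t) / M_s(ref_year) for ref < t <= horizon.

    F(ref_year) = 1 by convention; negative projections are floored at 0.
    Returns None (ingredient dropped from projection) when the reference
    smoothed mass is not positive.
    """
    if not np.isfinite(m_s_ref) or m_s_ref <= 0:
        if log is not None:
            log.append(
                f"compute_prefactors: M_s({ref_year})<=0 for ({fit.ai},{fit.crop}), dropped"
            )
        return None
    out = {ref_year: 1.0}
    for t in range(ref_year + 1, horizon + 1):
        out[t] = max(0.0, float(fit.predict(t)) / m_s_ref)
    return out


def smooth_state_series(
    series: NationalSeries,
    lam: float | None = None,
    smooth_bounds: bool = False,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Smooth each (ai, crop, state) median-mass series over years.

    Returns state rows with smoothed ``mass_median``; the high/low bounds
    pass through raw unless ``smooth_bounds`` (they only annotate the state
    rate table — downstream bounds come from the regression confidence
    band). The national smoothed series is the per-year sum of smoothed
    state series.
    """
    cols = [("state_median", "mass_median")]
    if smooth_bounds:
        cols += [("mass_high", "mass_high"), ("mass_low", "mass_low")]
    rows = []
    for (ai, crop, state), grp in series.state.groupby(["ai", "crop", "state"]):
        grp = grp.sort_values("year")
        yrs = grp["year"].to_numpy()
        out = {"ai": ai, "crop": crop, "state": state, "year": yrs}
        for col, name in cols:
            out[name] = smooth_median_series(yrs, grp[col].to_numpy(), lam=lam, log=log)
        if not smooth_bounds:
            out["mass_high"] = grp["mass_high"].to_numpy()
            out["mass_low"] = grp["mass_low"].to_numpy()
        rows.append(pd.DataFrame(out))
    return pd.concat(rows, ignore_index=True)


def national_smoothed(state_smoothed: pd.DataFrame) -> pd.DataFrame:
    """National smoothed median mass: per-year sum of smoothed state series."""
    return (
        state_smoothed.groupby(["ai", "crop", "year"])["mass_median"]
        .sum(min_count=1)
        .reset_index(name="m_s")
    )
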