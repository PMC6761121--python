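"""Governance, biotechnology and inventory conditioning of raw rate maps.

The raw globally inferred high/low application-rate surfaces are
conditioned in a fixed order: (1) national bans zero out banned
ingredients country-wide; (2) genetically-modified-crop approvals cap
GM-specific ingredients at the reference-country rate in approving
countries and set them to 30% of it elsewhere; (3) country inventory
totals rescale both bounds by min[F_M * R_c, H/L ratio of the reference
country], where R_c is the ratio of the reported to the integrated
national mass, neighbour-imputed where unreported; (4) mapping prefactors
project the conditioned reference-year maps forward in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import AreaGrid, RegionMask, zonal_sum
from .inference import RawGlobalAPR

KG_PER_TONNE = 1_000.0
GM_FRACTION = 0.30

#: Ingredients with GM-resistant crop lines; only these are subject to
#: biotechnology conditioning.
GM_ACTIVE_INGREDIENTS = {
    "glyphosate",
    "glufosinate",
    "2,4-d",
    "dicamba",
    "isoxaflutole",
    "mesotrione",
}


@dataclass
class BanRegistry:
    """(country, ai) pairs that are banned or not approved (B/NA).

    Unlisted pairs default to approved; a ban holds through the projection
    horizon.
    """

    banned: set[tuple[int, str]] = field(default_factory=set)

    def is_banned(self, country: int, ai: str) -> bool:
        return (country, ai) in self.banned

    def countries(self) -> set[int]:
        return {c for c, _ in self.banned}


@dataclass
class GMRegistry:
    """(country, dominant crop, ai) approvals of pesticide-resistant GM crops."""

    approvals: set[tuple[int, str, str]] = field(default_factory=set)
    gm_ais: set[str] = field(default_factory=lambda: set(GM_ACTIVE_INGREDIENTS))

    def approves(self, country: int, crop: str, ai: str) -> bool:
        return (country, crop, ai) in self.approvals

    def pairs(self) -> set[tuple[str, str]]:
        return {(ai, crop) for _, crop, ai in self.approvals}


def apply_bans(
    apr: RawGlobalAPR, bans: BanRegistry, countries: RegionMask
) -> RawGlobalAPR:
    """Zero both bounds over every country that bans this ingredient."""
    known = set(int(c) for c in countries.region_ids())
    unknown = bans.countries() - known
    if unknown:
        raise ValueError(f"ban registry references unknown countries {sorted(unknown)}")
    high, low = apr.high.copy(), apr.low.copy()
    for country in bans.countries():
        if bans.is_banned(country, apr.ai):
            inside = countries.labels == country
            high[inside] = np.where(np.isnan(high[inside]), np.nan, 0.0)
            low[inside] = np.where(np.isnan(low[inside]), np.nan, 0.0)
    return RawGlobalAPR(ai=apr.ai, crop=apr.crop, high=high, low=low)


def apply_gm_conditioning(
    apr: RawGlobalAPR,
    gm: GMRegistry,
    usa_apr_high: float,
    usa_apr_low: float,
    bans: BanRegistry,
    countries: RegionMask,
    reference_country: int = 0,
    dominant_crops: set[str] | None = None,
    log: list[str] | None = None,
) -> RawGlobalAPR:
    """Biotechnology conditioning for GM-specific ingredients on dominant crops.

    Approving countries: cellwise cap at the reference-country mean rate.
    Non-approving, non-banning countries: rate replaced by 30% of the
    reference rate on crop cells. Banned countries stay 0 (bans win).
    Non-GM ingredients and aggregated crops pass through unchanged.
    """
    if apr.ai not in gm.gm_ais:
        return apr
    relevant = {(c, crop, ai) for (c, crop, ai) in gm.approvals if ai == apr.ai}
    if dominant_crops is not None:
        bad = {t for t in relevant if t[1] not in dominant_crops}
        if bad:
            raise ValueError(f"GM approvals reference non-dominant crops: {sorted(bad)}")
    if not relevant and not gm.approvals:
        return apr
    high, low = apr.high.copy(), apr.low.copy()
    for country in (int(c) for c in countries.region_ids()):
        if country == reference_country:
            continue
        inside = countries.labels == country
        if bans.is_banned(country, apr.ai):
            continue  # already zeroed by apply_bans
        if gm.approves(country, apr.crop, apr.ai):
            high[inside] = np.minimum(high[inside], usa_apr_high)
            low[inside] = np.minimum(low[inside], usa_apr_low)
        else:
            high[inside] = np.where(np.isnan(high[inside]), np.nan, GM_FRACTION * usa_apr_high)
            low[inside] = np.where(np.isnan(low[inside]), np.nan, GM_FRACTION * usa_apr_low)
    if log is not None:
        log.append(f"gm_conditioning: applied to ({apr.ai},{apr.crop})")
    return RawGlobalAPR(ai=apr.ai, crop=apr.crop, high=high, low=low)


def country_masses(
    aprs: list[RawGlobalAPR], areas: AreaGrid, countries: RegionMask
) -> dict[int, float]:
    """Integrated national pesticide mass M_c [tonnes/yr].

    Sums median rate x crop area over all (ai, crop) surfaces per country.
    """
    totals: dict[int, float] = {int(c): 0.0 for c in countries.region_ids()}
    for apr in aprs:
        median = 0.5 * (np.nan_to_num(apr.high) + np.nan_to_num(apr.low))
        mass_kg = median * areas.layers[apr.crop]
        for country, m in zonal_sum(mass_kg, countries).items():
            totals[country] += m / KG_PER_TONNE
    return totals


@dataclass
class CountryCorrection:
    country: int
    m_c: float  # integrated estimate, tonnes/yr
    m_c_fao: float | None  # reported total, tonnes/yr (None = unreported)
    r_c: float
    source: str  # reported | neighbor-imputed | global-fallback


def correction_ratios(
    m_c: dict[int, float], faostat_totals: dict[int, float]
) -> dict[int, CountryCorrection]:
    """R_c = reported mass / integrated mass for countries reporting both."""
    out = {}
    for country, est in m_c.items():
        fao = faostat_totals.get(country)
        if fao is not None and est > 0:
            out[country] = CountryCorrection(
                country=country, m_c=est, m_c_fao=fao, r_c=fao / est, source="reported"
            )
    return out


def impute_missing_rc(
    corrections: dict[int, CountryCorrection],
    all_countries: list[int],
    adjacency: dict[int, set[int]],
    m_c: dict[int, float] | None = None,
    log: list[str] | None = None,
) -> dict[int, CountryCorrection]:
    """Complete the R_c map by neighbour averaging.

    Unreported countries take the arithmetic mean R_c of their reported
    neighbours; countries with no reported neighbour fall back to the
    global mean of reported R_c (logged).
    """
    if not corrections:
        raise ValueError("no country reports a correction ratio")
    global_mean = float(np.mean([c.r_c for c in corrections.values()]))
    out = dict(corrections)
    for country in all_countries:
        if country in out:
            continue
        neigh = [out[n].r_c for n in adjacency.get(country, set()) if n in corrections]
        if neigh:
            r_c, source = float(np.mean(neigh)), "neighbor-imputed"
        else:
            r_c, source = global_mean, "global-fallback"
            if log is not None:
                log.append(f"impute_missing_rc: country {country} uses global fallback")
        out[country] = CountryCorrection(
            country=country,
            m_c=(m_c or {}).get(country, np.nan),
            m_c_fao=None,
            r_c=r_c,
            source=source,
        )
    return out


def faostat_condition(
    apr: RawGlobalAPR,
    corrections: dict[int, CountryCorrection],
    f_m: float,
    usa_ratio: float | None,
    countries: RegionMask,
    reference_country: int = 0,
    log: list[str] | None = None,
) -> RawGlobalAPR:
    """Scale both bounds by min[F_M * R_c, reference H/L ratio] per country.

    The reference country (whose panel seeded the whole estimate) is
    exempt. The cap prevents runaway corrections for single ingredients;
    when the reference low bound is 0 the cap is undefined and the factor
    is F_M * R_c alone (logged).
    """
    high, low = apr.high.copy(), apr.low.copy()
    for country, corr in corrections.items():
        if country == reference_country:
            continue
        factor = f_m * corr.r_c
        if usa_ratio is not None and np.isfinite(usa_ratio):
            factor = min(factor, usa_ratio)
        elif log is not None:
            log.append(
                f"faostat_condition: reference H/L undefined for ({apr.ai},{apr.crop}), cap omitted"
            )
        inside = countries.labels == country
        high[inside] *= factor
        low[inside] *= factor
    return RawGlobalAPR(ai=apr.ai, crop=apr.crop, high=high, low=low)


@dataclass
class FinalAPR:
    """Conditioned high/low rate grids per (ai, crop, year) [kg/ha/yr]."""

    ai: str
    crop: str
    grids: dict[int, dict[str, np.ndarray]]  # year -> {"high","low"}

    def high(self, year: int) -> np.ndarray:
        return self.grids[year]["high"]

    def low(self, year: int) -> np.ndarray:
        return self.grids[year]["low"]

    def median(self, year: int) -> np.ndarray:
        return 0.5 * (self.grids[year]["high"] + self.grids[year]["low"])


def project_estimates(
    final_ref: RawGlobalAPR,
    prefactors: dict[int, float] | None,
    ref_year: int = 2015,
    years: tuple[int, ...] = (2020, 2025),
    log: list[str] | None = None,
) -> FinalAPR:
    """Scale the conditioned reference-year maps by the mapping prefactor
    F(i, j, t) for each projection year; zeros (bans) stay zero."""
    grids = {ref_year: {"high": final_ref.high, "low": final_ref.low}}
    for year in years:
        if prefactors is None or year not in prefactors:
            if log is not None:
                log.append(
                    f"project_estimates: no prefactor for ({final_ref.ai},{final_ref.crop},{year})"
                )
            continue
        f = prefactors[year]
        grids[year] = {"high": final_ref.high * f, "low": final_ref.low * f}
    return FinalAPR(ai=final_ref.ai, crop=final_ref.crop, grids=grids)
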