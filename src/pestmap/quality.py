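"""Data-quality factor calculus and gridded quality-index maps.

Three quality factors feed a per-cell quality index:

* QF_SA — crop-inventory matching quality: 1 for dominant crops, the mean
  of the matched and partial-match-adjusted fractions for aggregated
  classes, undefined for pasture/hay;
* QF_HT — historical-trend regression quality,
  [n + mean_k |R_k|] / 2 over the covariates actually used;
* QF_Z — country-level class-mass validation quality,
  1 - |M_Z - M_Z,ref| / (M_Z + M_Z,ref) for each validated pesticide class
  Z (herbicides, insecticides, bactericides+fungicides).

The quality index is their geometric mean,
QI = (QF_SA * QF_HT * prod_Z QF_Z)^(1/(2+z)) with z the number of classes
the ingredient belongs to, mapped onto the grid as a constant per country.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditioning import FinalAPR
from .grids import AreaGrid, CropMatchTable, RegionMask, zonal_sum

PESTICIDE_CLASSES = ("herbicides", "insecticides", "bactericides_fungicides")
PASHAY = "PasHay"

#: Crop-pool matching counts between the US state-panel crop lists and the
#: global gridded crop inventory: pool size, crops with no counterpart,
#: and crops matched only partially, per aggregated class. Dominant crops
#: match one-to-one. Pasture/hay is built from a land-fraction layer and
#: its matching is not quantifiable.
REFERENCE_CROP_MATCH = CropMatchTable(
    dominant=["Corn", "Soyabean", "Wheat", "Cotton", "Rice", "Alfalfa"],
    aggregated={
        "VegFru": {"total": 58, "unmatched": 19, "partial": 12},
        "OrcGra": {"total": 33, "unmatched": 5, "partial": 3},
        "Other": {"total": 24, "unmatched": 5, "partial": 7},
        "PasHay": {"total": 9, "unmatched": 0, "partial": 8},
    },
)


def qf_sa(match: CropMatchTable) -> dict[str, float | None]:
    """Crop-matching quality per crop class.

    Dominant crops score 1. Aggregated classes score the mean of
    (1 - unmatched/total) and (1 - partial/total). Pasture/hay is not
    quantifiable (None) and is dropped from the quality index.
    """
    out: dict[str, float | None] = {crop: 1.0 for crop in match.dominant}
    for crop, row in match.aggregated.items():
        if row["total"] <= 0:
            raise ValueError(f"zero crop count for class {crop}")
        if crop == PASHAY:
            out[crop] = None
            continue
        matched = 1.0 - row["unmatched"] / row["total"]
        partial_adj = 1.0 - row["partial"] / row["total"]
        out[crop] = 0.5 * (matched + partial_adj)
    return out


def qf_ht(n_frac: float, r_list: list[float], log: list[str] | None = None) -> float:
    """Historical-trend quality: [n_frac + mean(|R_k|)] / 2 over the
    covariates used; with no covariates, n_frac / 2 (logged)."""
    if not 0.0 <= n_frac <= 1.0:
        raise ValueError("n_frac must be in [0, 1]")
    if any(abs(r) > 1.0 + 1e-12 for r in r_list):
        raise ValueError("|R| must be <= 1")
    if not r_list:
        if log is not None:
            log.append("qf_ht: empty correlation list, using n_frac/2")
        return n_frac / 2.0
    return (n_frac + float(np.mean(np.abs(r_list)))) / 2.0


def qf_z(m_z: float, m_z_ref: float) -> float:
    """Class-mass validation quality: 1 - |M - M_ref| / (M + M_ref).

    Symmetric in its arguments; 1 when both masses are zero (no evidence
    of disagreement).
    """
    if m_z < 0 or m_z_ref < 0:
        raise ValueError("masses must be nonnegative")
    if m_z == 0.0 and m_z_ref == 0.0:
        return 1.0
    return 1.0 - abs(m_z - m_z_ref) / (m_z + m_z_ref)


def quality_index(
    qf_sa_value: float | None, qf_ht_value: float, qf_z_values: list[float]
) -> float:
    """Geometric-mean quality index.

    QI = (QF_SA * QF_HT * prod QF_Z)^(1/(2+z)) with z = len(qf_z_values).
    When QF_SA is undefined (pasture/hay) it is dropped and the exponent
    becomes 1/(1+z). All factors must lie in [0, 1].
    """
    factors = [qf_ht_value] + list(qf_z_values)
    if qf_sa_value is not None:
        factors = [qf_sa_value] + factors
    if any(f < 0 or f > 1 for f in factors):
        raise ValueError("quality factors must be in [0, 1]")
    prod = float(np.prod(factors))
    return prod ** (1.0 / len(factors))


def qi_grid(
    qf_sa_value: float | None,
    qf_ht_value: float,
    qf_z_by_country: dict[int, dict[str, float]],
    ai_classes: set[str],
    countries: RegionMask,
) -> np.ndarray:
    """Per-cell quality index for one (ai, crop): constant per country.

    ``qf_z_by_country`` maps country -> class -> QF_Z; only the classes the
    ingredient belongs to (among the validated ones) enter the product.
    Unlabelled cells are NaN.
    """
    classes = [z for z in PESTICIDE_CLASSES if z in ai_classes]
    out = np.full(countries.labels.shape, np.nan)
    for country in (int(c) for c in countries.region_ids()):
        zs = [qf_z_by_country[country][z] for z in classes] if classes else []
        out[countries.labels == country] = quality_index(qf_sa_value, qf_ht_value, zs)
    return out


@dataclass
class ClassMassReport:
    """Estimated vs reported per-(country, class) masses and relative errors."""

    table: pd.DataFrame  # country, pclass, mass_est, mass_reported, rel_error
    average_error: dict[str, float]  # per class, over reporting countries


def split_mass_by_class(mass: float, classes: set[str]) -> dict[str, float]:
    """Divide an ingredient's mass equally among its pesticide classes."""
    valid = [z for z in PESTICIDE_CLASSES if z in classes]
    if not valid:
        return {}
    share = mass / len(valid)
    return {z: share for z in valid}


def class_mass_report(
    finals: list[FinalAPR],
    areas: AreaGrid,
    countries: RegionMask,
    ai_classes: dict[str, set[str]],
    reported_by_class: dict[tuple[int, str], float],
    year: int = 2015,
    log: list[str] | None = None,
) -> ClassMassReport:
    """Estimated national masses per pesticide class vs reported totals.

    A multi-class ingredient's mass is divided equally among its classes.
    Relative error per reporting country: |est - reported| / reported;
    countries reporting 0 are excluded from the average (logged).
    """
    est: dict[tuple[int, str], float] = {}
    for final in finals:
        median = np.nan_to_num(final.median(year))
        mass_kg = median * areas.layers[final.crop]
        per_country = zonal_sum(mass_kg, countries)
        for country, m in per_country.items():
            for z, share in split_mass_by_class(m / 1000.0, ai_classes[final.ai]).items():
                est[(country, z)] = est.get((country, z), 0.0) + share

    rows = []
    for (country, z), reported in sorted(reported_by_class.items()):
        estimate = est.get((country, z), 0.0)
        if reported == 0.0:
            if log is not None:
                log.append(f"class_mass_report: country {country} class {z} reports 0, excluded")
            rel = np.nan
        else:
            rel = abs(estimate - reported) / reported
        rows.append(
            {
                "country": country,
                "pclass": z,
                "mass_est": estimate,
                "mass_reported": reported,
                "rel_error": rel,
            }
        )
    table = pd.DataFrame(rows, columns=["country", "pclass", "mass_est", "mass_reported", "rel_error"])
    avg = {
        z: float(g["rel_error"].dropna().mean()) if g["rel_error"].notna().any() else np.nan
        for z, g in table.groupby("pclass")
    }
    return ClassMassReport(table=table, average_error=avg)
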