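"""Regular lat/lon grids, crop-area layers and zonal statistics.

Everything downstream works on a single WGS84 regular grid: row 0 is the
northernmost row, cells are cell-center registered, and per-cell surface
areas come from the spherical-cap formula on the authalic sphere, so the
area of a cell depends only on its row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Authalic Earth radius [m]: the sphere with the same surface area as the
# WGS84 ellipsoid.
EARTH_RADIUS_M = 6_371_007.1810
M2_PER_HA = 1.0e4

#: Maximum fraction of a cell's surface that crops may occupy.
DEFAULT_CROP_SATURATION = 0.95


@dataclass(frozen=True)
class GridSpec:
    """Regular WGS84 lat/lon grid, cell-center registered, row 0 north."""

    n_rows: int
    n_cols: int
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -56.0
    lat_max: float = 84.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("bounding box is not well-ordered")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, north to south."""
        edges = np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def lons(self) -> np.ndarray:
        edges = np.linspace(self.lon_min, self.lon_max, self.n_cols + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def lat_edges(self) -> np.ndarray:
        return np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)

    def lon_edges(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_cols + 1)

    def geotransform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style geotransform (origin at the NW corner)."""
        return (self.lon_min, self.dlon, 0.0, self.lat_max, 0.0, -self.dlat)


def cell_area_grid(spec: GridSpec) -> np.ndarray:
    """Per-cell surface area in hectares, shape (n_rows, n_cols).

    Spherical cap band area: R^2 * dlon_rad * (sin(lat_top) - sin(lat_bot))
    per row; constant along a row.
    """
    lat_edges = np.deg2rad(spec.lat_edges())
    dlon_rad = np.deg2rad(spec.dlon)
    band = EARTH_RADIUS_M**2 * dlon_rad * (np.sin(lat_edges[:-1]) - np.sin(lat_edges[1:]))
    return np.repeat(band[:, None], spec.n_cols, axis=1) / M2_PER_HA


@dataclass
class RegionMask:
    """Integer region labels on a grid; -1 codes ocean / no-data.

    ``adjacency`` (optional) maps a region label to the set of labels of
    rook-contiguous neighbouring regions; used for country-level
    neighbour imputation.
    """

    labels: np.ndarray
    adjacency: dict[int, set[int]] = field(default_factory=dict)

    NODATA: int = -1

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != self.NODATA]

    def land(self) -> np.ndarray:
        return self.labels != self.NODATA


def rook_adjacency(labels: np.ndarray, nodata: int = -1) -> dict[int, set[int]]:
    """Region adjacency from rook (4-neighbour) contiguity of a label grid."""
    adj: dict[int, set[int]] = {int(r): set() for r in np.unique(labels) if r != nodata}
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        touch = (a != b) & (a != nodata) & (b != nodata)
        for x, y in zip(a[touch].ravel(), b[touch].ravel()):
            adj[int(x)].add(int(y))
            adj[int(y)].add(int(x))
    return adj


@dataclass
class AreaGrid:
    """Per crop-class area layers [ha], all on one GridSpec."""

    spec: GridSpec
    layers: dict[str, np.ndarray]

    def total(self) -> np.ndarray:
        out = np.zeros(self.spec.shape)
        for grid in self.layers.values():
            out = out + grid
        return out

    def crops(self) -> list[str]:
        return list(self.layers)


@dataclass
class CropMatchTable:
    """Crop-inventory matching bookkeeping feeding the QF_SA quality factor.

    For each aggregated class: how many member crops exist in the source
    inventory, how many found no counterpart (unmatched, inventory A) and
    how many matched only partially (inventory B). Dominant crops match
    exactly by construction.
    """

    dominant: list[str]
    aggregated: dict[str, dict[str, int]]  # class -> {total, unmatched, partial}

    def unmatched_fraction(self, crop: str) -> float:
        row = self.aggregated[crop]
        return row["unmatched"] / row["total"]

    def partial_fraction(self, crop: str) -> float:
        row = self.aggregated[crop]
        return row["partial"] / row["total"]


def aggregate_crop_classes(
    layers: dict[str, np.ndarray],
    match_table: pd.DataFrame,
    spec: GridSpec,
) -> tuple[AreaGrid, dict[str, dict[str, int]]]:
    """Sum individual crop layers into aggregated class grids.

    ``match_table`` needs columns ``crop``, ``crop_class`` where
    ``crop_class`` is either a class name or ``"unmatched"``. A crop mapped
    to two classes is an error. Returns the class AreaGrid plus per-class
    match counts (total / unmatched) for quality tracking.
    """
    counts = match_table.groupby("crop")["crop_class"].nunique()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"crops mapped to multiple classes: {list(dupes.index)}")

    class_layers: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, int]] = {}
    for cls, rows in match_table.groupby("crop_class"):
        members = list(rows["crop"])
        if cls == "unmatched":
            continue
        grid = np.zeros(spec.shape)
        for crop in members:
            if crop in layers:
                grid = grid + np.asarray(layers[crop], dtype=float)
        class_layers[cls] = grid
        n_total = len(members)
        n_unmatched = sum(1 for crop in members if crop not in layers)
        stats[cls] = {"total": n_total, "unmatched": n_unmatched}
    unmatched_rows = match_table[match_table["crop_class"] == "unmatched"]
    stats["__unmatched__"] = {"total": len(match_table), "unmatched": len(unmatched_rows)}
    return AreaGrid(spec=spec, layers=class_layers), stats


def cap_crop_saturation(
    areas: AreaGrid,
    cell_areas: np.ndarray,
    saturation: float = DEFAULT_CROP_SATURATION,
) -> AreaGrid:
    """Rescale class areas so their cellwise sum never exceeds
    ``saturation`` x cell area.

    Where the sum exceeds the cap, every class in that cell is scaled by
    the common factor cap/sum, preserving class shares; other cells are
    untouched. Idempotent.
    """
    total = areas.total()
    cap = saturation * cell_areas
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(total > cap, cap / np.where(total > 0, total, 1.0), 1.0)
    return AreaGrid(
        spec=areas.spec,
        layers={crop: grid * factor for crop, grid in areas.layers.items()},
    )


def zonal_crop_areas(areas: AreaGrid, mask: RegionMask) -> pd.DataFrame:
    """Exact per-(crop, region) area sums [ha]; columns crop, region, area_ha."""
    ids = mask.region_ids()
    if ids.size == 0:
        return pd.DataFrame(columns=["crop", "region", "area_ha"])
    land = mask.land()
    labels = mask.labels[land]
    nbins = int(ids.max()) + 1
    rows = []
    for crop, grid in areas.layers.items():
        sums = np.bincount(labels, weights=np.asarray(grid)[land], minlength=nbins)
        for rid in ids:
            rows.append({"crop": crop, "region": int(rid), "area_ha": sums[rid]})
    return pd.DataFrame(rows)


def zonal_sum(grid: np.ndarray, mask: RegionMask) -> dict[int, float]:
    """Sum of ``grid`` over each region (NaNs treated as 0)."""
    land = mask.land()
    vals = np.nan_to_num(np.asarray(grid, dtype=float))[land]
    labels = mask.labels[land]
    ids = mask.region_ids()
    sums = np.bincount(labels, weights=vals, minlength=int(ids.max()) + 1 if ids.size else 0)
    return {int(r): float(sums[r]) for r in ids}


def compute_state_apr(
    state_series: pd.DataFrame,
    state_areas: pd.DataFrame,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """State-level application rates [kg/ha/yr] = state mass / state crop area.

    ``state_series`` columns: ai, crop, state, year, mass_high, mass_low,
    mass_median (smoothed state masses, kg/yr). ``state_areas`` columns:
    crop, region, area_ha. States with zero crop area but positive mass are
    excluded (rate undefined) and logged; zero mass gives rate 0.
    """
    areas = state_areas.rename(columns={"region": "state"})
    merged = state_series.merge(areas, on=["crop", "state"], how="left")
    zero_area = (merged["area_ha"].isna() | (merged["area_ha"] <= 0)) & (
        merged["mass_median"] > 0
    )
    if log is not None and zero_area.any():
        n = int(zero_area.sum())
        log.append(f"state_apr: dropped {n} state-year rows with mass>0 on zero crop area")
    merged = merged[~zero_area].copy()
    area = merged["area_ha"].where(merged["area_ha"] > 0)
    for bound in ("high", "low", "median"):
        merged[f"apr_{bound}"] = (merged[f"mass_{bound}"] / area).where(
            merged[f"mass_{bound}"] > 0, 0.0
        )
    return merged[
        ["ai", "crop", "state", "year", "apr_high", "apr_low", "apr_median", "area_ha"]
    ]
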