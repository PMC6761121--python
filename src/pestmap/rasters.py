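"""Georeferenced raster products: GeoTIFF, NetCDF and PNG previews.

Internal no-data is NaN. GeoTIFF files carry the WGS84 geokeys, the pixel
scale/tiepoint geotransform and a GDAL-style no-data tag, written and read
through tifffile; NetCDF files carry coordinate vectors and a CRS
attribute, written through xarray. PNG is a rendered lossy preview only
and is rejected on read.

Layer names encode their key: ``APR_<crop>_<ai>_<year>_<H|L>`` for rate
maps and ``QI_<crop>_<ai>`` for quality-index maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .grids import GridSpec

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 2 = geographic lat/lon
_GT_RASTER_TYPE = 1025  # 1 = PixelIsArea
_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS84

_APR_RE = re.compile(r"^APR_(?P<crop>[^_]+)_(?P<ai>.+)_(?P<year>\d{4})_(?P<bound>[HL])$")
_QI_RE = re.compile(r"^QI_(?P<crop>[^_]+)_(?P<ai>.+)$")


def apr_layer_name(crop: str, ai: str, year: int, bound: str) -> str:
    if bound not in ("H", "L"):
        raise ValueError("bound must be 'H' or 'L'")
    return f"APR_{crop}_{ai}_{year}_{bound}"


def qi_layer_name(crop: str, ai: str) -> str:
    return f"QI_{crop}_{ai}"


def parse_layer_name(name: str) -> dict:
    """Invert the layer naming convention back to its key fields."""
    m = _APR_RE.match(name)
    if m:
        return {
            "kind": "APR",
            "crop": m["crop"],
            "ai": m["ai"],
            "year": int(m["year"]),
            "bound": m["bound"],
        }
    m = _QI_RE.match(name)
    if m:
        return {"kind": "QI", "crop": m["crop"], "ai": m["ai"]}
    raise ValueError(f"layer name {name!r} does not follow the naming convention")


@dataclass
class MapProduct:
    name: str
    grid: np.ndarray
    spec: GridSpec
    units: str = "kg/ha/yr"

    def key(self) -> dict:
        return parse_layer_name(self.name)


def write_raster(product: MapProduct, path: str | Path, fmt: str | None = None) -> Path:
    """Write a product as GeoTIFF (.tif), NetCDF (.nc) or PNG preview (.png)."""
    path = Path(path)
    fmt = fmt or {".tif": "gtiff", ".tiff": "gtiff", ".nc": "netcdf", ".png": "png"}.get(
        path.suffix.lower()
    )
    if fmt == "gtiff":
        _write_gtiff(product, path)
    elif fmt == "netcdf":
        _write_netcdf(product, path)
    elif fmt == "png":
        _write_png(product, path)
    else:
        raise ValueError(f"unsupported raster format for {path}")
    return path


def read_raster(path: str | Path) -> MapProduct:
    """Inverse of write_raster for GeoTIFF and NetCDF; PNG is rejected."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_gtiff(path)
    if suffix == ".nc":
        return _read_netcdf(path)
    if suffix == ".png":
        raise ValueError("PNG is a rendered preview, not a data-exchange format")
    raise ValueError(f"unsupported raster format for {path}")


def _write_gtiff(product: MapProduct, path: Path) -> None:
    spec = product.spec
    geokeys = (
        1, 1, 0, 3,  # version, revision, minor, number of keys
        _GT_MODEL_TYPE, 0, 1, 2,
        _GT_RASTER_TYPE, 0, 1, 1,
        _GEOGRAPHIC_TYPE, 0, 1, 4326,
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (spec.dlon, spec.dlat, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_min, spec.lat_max, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(
        path,
        np.asarray(product.grid, dtype=np.float64),
        extratags=extratags,
        metadata=None,
        description=f"{product.name} [{product.units}]",
    )


def _read_gtiff(path: Path) -> MapProduct:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        if _GEO_KEY_DIRECTORY not in tags or _MODEL_PIXEL_SCALE not in tags:
            raise ValueError(f"{path}: CRS/georeferencing tags missing")
        keys = tags[_GEO_KEY_DIRECTORY].value
        keydict = {keys[i]: keys[i + 3] for i in range(4, len(keys), 4)}
        if keydict.get(_GEOGRAPHIC_TYPE) != 4326:
            raise ValueError(f"{path}: expected WGS84 (EPSG:4326) geokey")
        dlon, dlat, _ = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        lon_min, lat_max = tie[3], tie[4]
        n_rows, n_cols = grid.shape
        spec = GridSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            lon_min=lon_min,
            lon_max=lon_min + dlon * n_cols,
            lat_min=lat_max - dlat * n_rows,
            lat_max=lat_max,
        )
        desc = tags.get("ImageDescription")
        name, units = _parse_description(desc.value if desc else path.stem)
    return MapProduct(name=name, grid=grid, spec=spec, units=units)


def _parse_description(desc: str) -> tuple[str, str]:
    m = re.match(r"^(?P<name>\S+) \[(?P<units>[^\]]*)\]$", desc.strip())
    if m:
        return m["name"], m["units"]
    return desc.strip(), ""


def _write_netcdf(product: MapProduct, path: Path) -> None:
    spec = product.spec
    da = xr.DataArray(
        np.asarray(product.grid, dtype=np.float64),
        dims=("lat", "lon"),
        coords={"lat": spec.lats(), "lon": spec.lons()},
        name=product.name,
        attrs={"units": product.units, "crs": "EPSG:4326"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path) -> MapProduct:
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [v for v in ds.data_vars]
        if len(names) != 1:
            raise ValueError(f"{path}: expected a single layer, found {names}")
        da = ds[names[0]].load()
    if "crs" not in da.attrs:
        raise ValueError(f"{path}: CRS attribute missing")
    lat = da["lat"].values
    lon = da["lon"].values
    n_rows, n_cols = da.shape
    dlat = abs(lat[1] - lat[0]) if n_rows > 1 else 1.0
    dlon = abs(lon[1] - lon[0]) if n_cols > 1 else 1.0
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lon_min=float(lon.min()) - dlon / 2,
        lon_max=float(lon.max()) + dlon / 2,
        lat_min=float(lat.min()) - dlat / 2,
        lat_max=float(lat.max()) + dlat / 2,
    )
    return MapProduct(
        name=str(da.name), grid=np.asarray(da.values), spec=spec, units=da.attrs.get("units", "")
    )


def _write_png(product: MapProduct, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.asarray(product.grid, dtype=float)
    fig, ax = plt.subplots(figsize=(8, 4.2), dpi=120)
    spec = product.spec
    im = ax.imshow(
        grid,
        extent=(spec.lon_min, spec.lon_max, spec.lat_min, spec.lat_max),
        cmap="viridis",
        interpolation="nearest",
    )
    ax.set_title(f"{product.name} [{product.units}]", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
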