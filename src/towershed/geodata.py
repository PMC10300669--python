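"""Georeferenced rasters, tower tables, and coordinate plumbing.

The central container is :class:`DEMGrid`, a single-band elevation raster
(terrain or bathymetry, metres, north-up, cell-center registered) with a
CRS tag and a missing-data mask.  Towers are given in WGS-84 latitude and
longitude, as telemetry deployments record them, and are projected onto the
DEM's CRS where needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geotiff
from ._geotiff import NotARasterError
from .crs import CRS

__all__ = [
    "Affine",
    "Extent",
    "DEMGrid",
    "Tower",
    "TowerSet",
    "EXTENT_LIMITED",
    "read_dem",
    "write_dem",
    "read_towers",
    "write_towers",
    "coord_to_cell",
    "cell_center",
    "ground_distance",
    "NotARasterError",
]

log = logging.getLogger("towershed")

#: Sentinel for a tower whose reception range is limited only by the DEM extent.
EXTENT_LIMITED = None

EARTH_RADIUS_M = 6_371_000.0

Affine = tuple[float, float, float, float, float, float]


@dataclass(frozen=True)
class Extent:
    """An axis-aligned bounding box in CRS units."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate extent {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax


@dataclass
class DEMGrid:
    """Elevation raster: values in metres, north-up, cell-center registered.

    ``transform`` is the GDAL-style affine (a, b, c, d, e, f) mapping pixel
    coordinates measured from the top-left *corner*: x = c + a·col,
    y = f + e·row with e < 0, so row 0 is the northernmost row and the
    center of cell (r, c) sits at pixel coordinates (c + ½, r + ½).
    """

    values: np.ndarray
    transform: Affine
    crs: CRS
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DEM values must be a 2-D grid")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values")
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0:
            raise ValueError("rotated transforms are not supported")
        if a <= 0 or e >= 0:
            raise ValueError("transform must have positive x-scale and negative y-scale (north-up)")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def resolution(self) -> tuple[float, float]:
        a, _, _, _, e, _ = self.transform
        return a, -e

    @property
    def extent(self) -> Extent:
        a, _, c, _, e, f = self.transform
        return Extent(c, f + e * self.nrows, c + a * self.ncols, f)

    def cell_centers_x(self) -> np.ndarray:
        a, _, c, _, _, _ = self.transform
        return c + a * (np.arange(self.ncols) + 0.5)

    def cell_centers_y(self) -> np.ndarray:
        _, _, _, _, e, f = self.transform
        return f + e * (np.arange(self.nrows) + 0.5)


@dataclass(frozen=True)
class Tower:
    """A named observation point (radio tower or submerged receiver).

    ``height_m`` is measured above the local surface — ground for terrain,
    seabed for bathymetry.  ``max_range_m`` of ``None`` means the reception
    range is limited only by the DEM extent.
    """

    name: str
    lat: float
    lon: float
    height_m: float
    max_range_m: float | None = EXTENT_LIMITED

    def __post_init__(self) -> None:
        if self.height_m < 0:
            raise ValueError(f"tower {self.name!r}: height_m must be ≥ 0, got {self.height_m}")
        if self.max_range_m is not None and self.max_range_m <= 0:
            raise ValueError(f"tower {self.name!r}: max_range_m must be > 0, got {self.max_range_m}")

    def xy(self, crs: CRS) -> tuple[float, float]:
        """The tower's position in the given CRS."""
        return crs.from_wgs84(self.lat, self.lon)


class TowerSet:
    """An ordered collection of uniquely named towers."""

    def __init__(self, towers: list[Tower] | tuple[Tower, ...]):
        names = [t.name for t in towers]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate tower names: {sorted(dup)}")
        self._towers = list(towers)
        self._by_name = {t.name: t for t in self._towers}

    def __iter__(self):
        return iter(self._towers)

    def __len__(self) -> int:
        return len(self._towers)

    def __getitem__(self, key: int | str) -> Tower:
        if isinstance(key, str):
            return self._by_name[key]
        return self._towers[key]

    @property
    def names(self) -> list[str]:
        return [t.name for t in self._towers]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def read_dem(path: str | Path, extent: Extent | None = None) -> DEMGrid:
    """Read a single-band GeoTIFF into a :class:`DEMGrid`.

    Declared nodata values (and NaNs) are mapped into the nodata mask; the
    raster is cropped to ``extent`` (cells whose centers fall inside) when
    one is given.
    """
    values, transform, crs, nodata = _geotiff.read_array(path)
    values = np.asarray(values, dtype=np.float64)
    if nodata is None:
        mask = ~np.isfinite(values)
    elif math.isnan(nodata):
        mask = np.isnan(values)
    else:
        mask = (values == nodata) | ~np.isfinite(values)
    dem = DEMGrid(values=values, transform=transform, crs=crs, nodata_mask=mask)
    if extent is not None:
        dem = crop(dem, extent)
    return dem


def crop(dem: DEMGrid, extent: Extent) -> DEMGrid:
    """Sub-grid of cells whose centers lie inside ``extent``."""
    xs = dem.cell_centers_x()
    ys = dem.cell_centers_y()
    cols = np.nonzero((xs >= extent.xmin) & (xs <= extent.xmax))[0]
    rows = np.nonzero((ys >= extent.ymin) & (ys <= extent.ymax))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("extent does not intersect the DEM")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    a, b, c, d, e, f = dem.transform
    new_transform = (a, b, c + a * c0, d, e, f + e * r0)
    return DEMGrid(
        values=dem.values[r0:r1, c0:c1].copy(),
        transform=new_transform,
        crs=dem.crs,
        nodata_mask=dem.nodata_mask[r0:r1, c0:c1].copy(),
    )


def write_dem(dem: DEMGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a DEM to a single-band float32 GeoTIFF with a nodata tag."""
    out = dem.values.astype(np.float32)
    out[dem.nodata_mask] = nodata
    _geotiff.write_array(path, out, dem.transform, dem.crs, nodata=nodata)


_TOWER_COLUMNS = ["name", "lat", "lon", "height_m", "max_range_m"]


def read_towers(path: str | Path, dem: DEMGrid | None = None) -> TowerSet:
    """Read a tower table (CSV: name,lat,lon,height_m,max_range_m).

    An empty max_range_m means the range is limited by the DEM extent.
    Towers whose position falls outside the DEM extent are accepted but
    logged, so planning tables may list not-yet-covered sites.
    """
    df = pd.read_csv(path, dtype={"name": str})
    missing = [c for c in _TOWER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tower CSV {path} lacks required columns: {missing}")
    towers: list[Tower] = []
    for i, row in df.iterrows():
        try:
            rng = row["max_range_m"]
            rng = None if pd.isna(rng) else float(rng)
            tower = Tower(
                name=str(row["name"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                height_m=float(row["height_m"]),
                max_range_m=rng,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"tower CSV row {i + 1} ({row['name']!r}): {exc}") from exc
        towers.append(tower)
    ts = TowerSet(towers)
    if dem is not None:
        ext = dem.extent
        for t in ts:
            x, y = t.xy(dem.crs)
            if not ext.contains(x, y):
                log.warning("tower %s at (%.6f, %.6f) lies outside the DEM extent", t.name, t.lat, t.lon)
    return ts


def write_towers(towers: TowerSet, path: str | Path) -> None:
    rows = [
        {
            "name": t.name,
            "lat": t.lat,
            "lon": t.lon,
            "height_m": t.height_m,
            "max_range_m": "" if t.max_range_m is None else t.max_range_m,
        }
        for t in towers
    ]
    pd.DataFrame(rows, columns=_TOWER_COLUMNS).to_csv(path, index=False)


def coord_to_cell(dem: DEMGrid, x: float, y: float) -> tuple[int, int]:
    """CRS coordinate → (row, col) of the containing cell."""
    ext = dem.extent
    if not ext.contains(x, y):
        raise ValueError(f"coordinate ({x}, {y}) is outside the DEM extent {ext}")
    a, _, c, _, e, f = dem.transform
    col = int(min((x - c) / a, dem.ncols - 1))
    row = int(min((y - f) / e, dem.nrows - 1))
    return row, col


def cell_center(dem: DEMGrid, row: int, col: int) -> tuple[float, float]:
    """(row, col) → CRS coordinate of the cell center."""
    if not (0 <= row < dem.nrows and 0 <= col < dem.ncols):
        raise IndexError(f"cell ({row}, {col}) out of range for {dem.nrows}×{dem.ncols} grid")
    a, _, c, _, e, f = dem.transform
    return c + a * (col + 0.5), f + e * (row + 0.5)


def haversine_m(
    lat1: float | np.ndarray,
    lon1: float | np.ndarray,
    lat2: float | np.ndarray,
    lon2: float | np.ndarray,
    radius_m: float = EARTH_RADIUS_M,
) -> float | np.ndarray:
    """Great-circle distance on a sphere of the given radius (metres)."""
    p1 = np.radians(np.asarray(lat1, dtype=np.float64))
    p2 = np.radians(np.asarray(lat2, dtype=np.float64))
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=np.float64) - np.asarray(lon1, dtype=np.float64))
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * radius_m * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def ground_distance(
    p1: tuple[float, float],
    p2: tuple[float, float],
    crs: CRS,
    earth_radius_m: float = EARTH_RADIUS_M,
) -> float:
    """Horizontal ground distance between two points in one CRS (metres).

    Geographic CRS → spherical haversine ((x, y) = (lon, lat) degrees);
    projected CRS → Euclidean.
    """
    if crs.is_geographic:
        return float(haversine_m(p1[1], p1[0], p2[1], p2[0], earth_radius_m))
    return math.hypot(p2[0] - p1[0], p2[1] - p1[1])
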