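"""Synthetic terrain, bathymetry and receiver layouts with known geometry.

Every surface has a closed form evaluated at cell centers — flat planes,
Gaussian hills and ridges, staircases, island-dotted basins — so the
expected visibility structure can be derived analytically or by a dense
brute-force oracle, and the whole library is testable without downloading
any real DEM.  Fixtures default to a projected metre-unit CRS (UTM) so LOS
tests decouple from geodesy; a geographic-CRS fixture exercises the
haversine paths.  Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crs import CRS
from .geodata import DEMGrid, Tower, TowerSet, cell_center

__all__ = ["FixtureSpec", "make_dem", "grid_receivers", "tower_at_cell", "PROJECTED_CRS", "DEFAULT_ORIGIN"]

KINDS = ("flat", "gaussian_hill", "ridge", "staircase", "basin_with_islets")

#: Default projected CRS for fixtures (UTM zone 36N, metre units).
PROJECTED_CRS = CRS(32636)
#: Top-left corner of the default fixture grid (easting, northing).
DEFAULT_ORIGIN = (728000.0, 3604000.0)
_GEOGRAPHIC_ORIGIN = (35.40, 32.56)  # lon, lat of the top-left corner
_M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic DEM.

    Shape parameters that do not apply to ``kind`` are ignored.  Islet
    centers, when not given explicitly, are drawn uniformly over the
    central 80 % of the grid from ``seed``.
    """

    kind: str = "flat"
    nrows: int = 41
    ncols: int = 41
    resolution_m: float = 30.0
    value: float = 0.0
    hill_height_m: float = 50.0
    hill_sigma_m: float = 150.0
    ridge_height_m: float = 50.0
    ridge_position: float = 0.5  # fraction of the east-west extent
    ridge_sigma_m: float = 30.0
    step_height_m: float = 10.0
    step_every_cols: int = 8
    basin_depth_m: float = -20.0
    islet_height_m: float = 2.0
    islet_sigma_m: float = 60.0
    n_islets: int = 3
    islet_centers: tuple[tuple[float, float], ...] | None = None  # fractions of extent
    seed: int = 0
    geographic: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")


def _surface(spec: FixtureSpec, x: np.ndarray, y: np.ndarray, extent) -> np.ndarray:
    """Evaluate the analytic fixture surface at metre coordinates (x, y)."""
    if spec.kind == "flat":
        return np.full_like(x, spec.value)
    if spec.kind == "gaussian_hill":
        xc = 0.5 * (extent[0] + extent[2])
        yc = 0.5 * (extent[1] + extent[3])
        r2 = (x - xc) ** 2 + (y - yc) ** 2
        return spec.value + spec.hill_height_m * np.exp(-r2 / (2 * spec.hill_sigma_m**2))
    if spec.kind == "ridge":
        xr = extent[0] + spec.ridge_position * (extent[2] - extent[0])
        return spec.value + spec.ridge_height_m * np.exp(-((x - xr) ** 2) / (2 * spec.ridge_sigma_m**2))
    if spec.kind == "staircase":
        col = np.floor((x - extent[0]) / ((extent[2] - extent[0]) / spec.ncols))
        return spec.value + spec.step_height_m * np.floor(col / spec.step_every_cols)
    if spec.kind == "basin_with_islets":
        z = np.full_like(x, spec.basin_depth_m)
        for fx, fy in _islet_centers(spec):
            cx = extent[0] + fx * (extent[2] - extent[0])
            cy = extent[1] + fy * (extent[3] - extent[1])
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            z += (spec.islet_height_m - spec.basin_depth_m) * np.exp(-r2 / (2 * spec.islet_sigma_m**2))
        return z
    raise AssertionError(spec.kind)


def _islet_centers(spec: FixtureSpec) -> tuple[tuple[float, float], ...]:
    if spec.islet_centers is not None:
        return tuple(spec.islet_centers)
    rng = np.random.default_rng(spec.seed)
    return tuple((float(fx), float(fy)) for fx, fy in rng.uniform(0.1, 0.9, size=(spec.n_islets, 2)))


def make_dem(spec: FixtureSpec) -> DEMGrid:
    """Evaluate a fixture surface at cell centers → DEMGrid."""
    if spec.geographic:
        lat0 = _GEOGRAPHIC_ORIGIN[1]
        dlat = spec.resolution_m / _M_PER_DEG_LAT
        dlon = spec.resolution_m / (_M_PER_DEG_LAT * np.cos(np.radians(lat0)))
        transform = (dlon, 0.0, _GEOGRAPHIC_ORIGIN[0], 0.0, -dlat, lat0)
        crs = CRS(4326)
        # evaluate the surface in local metre coordinates so shapes match
        cols = (np.arange(spec.ncols) + 0.5) * spec.resolution_m
        rows = -(np.arange(spec.nrows) + 0.5) * spec.resolution_m
        mx, my = np.meshgrid(cols, rows)
        m_extent = (0.0, -spec.nrows * spec.resolution_m, spec.ncols * spec.resolution_m, 0.0)
        values = _surface(spec, mx, my, m_extent)
    else:
        x0, y0 = DEFAULT_ORIGIN
        res = spec.resolution_m
        transform = (res, 0.0, x0, 0.0, -res, y0)
        crs = PROJECTED_CRS
        xs = x0 + (np.arange(spec.ncols) + 0.5) * res
        ys = y0 - (np.arange(spec.nrows) + 0.5) * res
        mx, my = np.meshgrid(xs, ys)
        extent = (x0, y0 - spec.nrows * res, x0 + spec.ncols * res, y0)
        values = _surface(spec, mx, my, extent)
    return DEMGrid(values=values, transform=transform, crs=crs)


def tower_at_cell(
    dem: DEMGrid,
    row: int,
    col: int,
    name: str = "T1",
    height_m: float = 10.0,
    max_range_m: float | None = None,
) -> Tower:
    """A tower placed exactly at a fixture cell center (handy in tests)."""
    x, y = cell_center(dem, row, col)
    lat, lon = dem.crs.to_wgs84(x, y)
    return Tower(name=name, lat=lat, lon=lon, height_m=height_m, max_range_m=max_range_m)


def grid_receivers(
    rows: int,
    cols: int,
    spacing_m: float,
    height_m: float,
    range_m: float | None,
    origin: tuple[float, float] | None = None,
    crs: CRS = PROJECTED_CRS,
) -> TowerSet:
    """A rows × cols regular array of identical receivers.

    ``origin`` is the projected (x, y) of the northwest receiver; receivers
    step east along columns and south along rows at ``spacing_m``, so the
    nearest-neighbour separation equals the spacing.  Names run R001,
    R002, … row-major.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be ≥ 1")
    if spacing_m <= 0:
        raise ValueError("spacing_m must be > 0")
    if origin is None:
        origin = (DEFAULT_ORIGIN[0] + 200.0, DEFAULT_ORIGIN[1] - 200.0)
    x0, y0 = origin
    towers: list[Tower] = []
    width = len(str(rows * cols))
    k = 0
    for i in range(rows):
        for j in range(cols):
            k += 1
            x = x0 + j * spacing_m
            y = y0 - i * spacing_m
            lat, lon = crs.to_wgs84(x, y)
            towers.append(
                Tower(name=f"R{k:0{max(3, width)}d}", lat=lat, lon=lon, height_m=height_m, max_range_m=range_m)
            )
    return TowerSet(towers)
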