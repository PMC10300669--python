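"""Per-tower Boolean viewsheds and the precalculated-set cache.

A viewshed is computed by looping the point-to-point LOS test over every
cell center of the DEM extent: cells beyond the tower's reception range are
false automatically, cells where the LOS question is undefined (nodata
target, aquatic invalidity) are marked invalid rather than merely
not-visible.  Because these loops are the slow part of the workflow, the
resulting rasters are stored on disk as a named set — one directory per
target height, one GeoTIFF per tower, plus a JSON manifest — and all
composite analyses run off the stored set.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _geotiff
from .geodata import DEMGrid, Tower, TowerSet, coord_to_cell, haversine_m
from .crs import CRS
from .los import SightConfig, _ResolvedSight, _blocked_at, _segment_samples

__all__ = ["ViewshedRaster", "PrecalcSet", "compute_viewshed", "precalculate_set", "load_set", "set_dir_name"]

_INVALID = 255  # uint8 encoding: 1 visible, 0 not visible, 255 invalid/nodata


@dataclass
class ViewshedRaster:
    """Boolean visibility grid for one tower at one target height.

    ``valid`` is false where LOS is undefined; no cell is both visible and
    invalid, and no visible cell lies beyond ``max_range_m``.
    """

    visible: np.ndarray
    valid: np.ndarray
    tower_name: str
    target_height_m: float
    curved: bool
    max_range_m: float | None
    transform: tuple[float, float, float, float, float, float]
    crs: CRS

    def __post_init__(self) -> None:
        self.visible = np.asarray(self.visible, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.visible.shape != self.valid.shape:
            raise ValueError("visible and valid grids must share a shape")
        if np.any(self.visible & ~self.valid):
            raise ValueError("a cell cannot be both visible and invalid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.visible.shape

    def to_uint8(self) -> np.ndarray:
        out = self.visible.astype(np.uint8)
        out[~self.valid] = _INVALID
        return out


def _distance_grid(dem: DEMGrid, x0: float, y0: float, radius_m: float) -> np.ndarray:
    xs = dem.cell_centers_x()
    ys = dem.cell_centers_y()
    if dem.crs.is_geographic:
        lon, lat = np.meshgrid(xs, ys)
        return haversine_m(y0, x0, lat, lon, radius_m)
    gx, gy = np.meshgrid(xs - x0, ys - y0)
    return np.hypot(gx, gy)


def compute_viewshed(
    dem: DEMGrid,
    tower: Tower,
    target_height_m: float,
    cfg: SightConfig,
    target_elevation_field: np.ndarray | None = None,
    validity: np.ndarray | None = None,
) -> ViewshedRaster:
    """Boolean viewshed of one tower: one LOS test per valid in-range cell.

    The default target elevation is ground + target_height_m; the aquatic
    module supplies an absolute elevation field and a validity mask instead.
    """
    if target_height_m < 0:
        raise ValueError("target_height_m must be ≥ 0")
    x0, y0 = tower.xy(dem.crs)
    if not dem.extent.contains(x0, y0):
        raise ValueError(f"tower {tower.name!r} lies outside the DEM extent")
    trow, tcol = coord_to_cell(dem, x0, y0)
    if dem.nodata_mask[trow, tcol]:
        raise ValueError(f"tower {tower.name!r} sits on a nodata cell")

    r = cfg.resolved(dem)
    ground = float(dem.values[trow, tcol])
    A = ground + tower.height_m

    if validity is not None:
        valid = np.asarray(validity, dtype=bool) & ~dem.nodata_mask
    else:
        valid = ~dem.nodata_mask
    valid = valid.copy()

    if target_elevation_field is not None:
        target_elev = np.asarray(target_elevation_field, dtype=np.float64)
        if target_elev.shape != dem.values.shape:
            raise ValueError("target_elevation_field shape must match the DEM")
        valid &= np.isfinite(target_elev)
    else:
        target_elev = dem.values + target_height_m

    dist_grid = _distance_grid(dem, x0, y0, r.earth_radius_m)
    in_range = np.ones(dem.values.shape, dtype=bool)
    if tower.max_range_m is not None:
        in_range = dist_grid <= tower.max_range_m

    visible = np.zeros(dem.values.shape, dtype=bool)
    xs = dem.cell_centers_x()
    ys = dem.cell_centers_y()
    vals = dem.values
    nodmask = dem.nodata_mask
    two_r = 2.0 * r.earth_radius_m
    p1 = (x0, y0)

    rows_to_do, cols_to_do = np.nonzero(valid & in_range)
    for rr, cc in zip(rows_to_do, cols_to_do):
        p2 = (xs[cc], ys[rr])
        dist, srows, scols, D = _segment_samples(dem, p1, p2, r.sample_step_m, r.earth_radius_m)
        if D == 0:
            visible[rr, cc] = True
            continue
        terrain = vals[srows, scols]
        nod = nodmask[srows, scols]
        if r.curved:
            drop = dist * dist / two_r
            terrain = terrain - drop
            B = target_elev[rr, cc] - D * D / two_r
        else:
            B = target_elev[rr, cc]
        sight = A + (dist / D) * (B - A)
        visible[rr, cc] = _blocked_at(dist, terrain, sight, nod, D, r.endpoint_exclusion_m) is None

    return ViewshedRaster(
        visible=visible,
        valid=valid,
        tower_name=tower.name,
        target_height_m=target_height_m,
        curved=r.curved,
        max_range_m=tower.max_range_m,
        transform=dem.transform,
        crs=dem.crs,
    )


def set_dir_name(target_height_m: float, dem: DEMGrid) -> str:
    """Set-directory naming convention, e.g. TransAlt0.3m_Res30."""
    rx, _ = dem.resolution
    res = str(round(rx)) if rx >= 1 else f"{rx:g}"
    return f"TransAlt{target_height_m:g}m_Res{res}"


def _safe_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", name) + ".tif"


class PrecalcSet:
    """A stored collection of per-tower viewsheds sharing one grid and one
    target height, described by a JSON manifest."""

    def __init__(self, directory: Path, manifest: dict, rasters: dict[str, ViewshedRaster]):
        self.directory = Path(directory)
        self.manifest = manifest
        self._rasters = rasters

    @property
    def names(self) -> list[str]:
        return [t["name"] for t in self.manifest["towers"]]

    @property
    def target_height_m(self) -> float:
        return float(self.manifest["target_height_m"])

    @property
    def transform(self):
        return tuple(self.manifest["transform"])

    @property
    def crs(self) -> CRS:
        return CRS.from_string(self.manifest["crs"])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.manifest["nrows"]), int(self.manifest["ncols"])

    def raster(self, name: str) -> ViewshedRaster:
        if name not in self._rasters:
            raise KeyError(f"no viewshed for tower {name!r}; available: {self.names}")
        return self._rasters[name]

    def __iter__(self):
        return (self._rasters[n] for n in self.names)


def _build_manifest(dem: DEMGrid, towers: TowerSet, target_height_m: float, cfg: SightConfig) -> dict:
    r = cfg.resolved(dem)
    return {
        "crs": str(dem.crs),
        "transform": list(dem.transform),
        "nrows": dem.nrows,
        "ncols": dem.ncols,
        "target_height_m": target_height_m,
        "curved": r.curved,
        "earth_radius_m": r.earth_radius_m,
        "sample_step_m": r.sample_step_m,
        "endpoint_exclusion_m": r.endpoint_exclusion_m,
        "towers": [
            {
                "name": t.name,
                "lat": t.lat,
                "lon": t.lon,
                "height_m": t.height_m,
                "max_range_m": t.max_range_m,
                "file": _safe_filename(t.name),
            }
            for t in towers
        ],
    }


def precalculate_set(
    dem: DEMGrid,
    towers: TowerSet,
    target_heights: list[float],
    cfg: SightConfig,
    out_dir: str | Path,
    overwrite: bool = False,
    target_fields: dict[float, tuple[np.ndarray, np.ndarray]] | None = None,
    extra_manifest: dict | None = None,
    progress=None,
) -> list[PrecalcSet]:
    """Compute and store one viewshed set per target height.

    ``target_fields`` optionally maps a target height to an (absolute
    elevation field, validity mask) pair, as the aquatic module produces.
    Deterministic: identical inputs reproduce bit-identical rasters.  An
    existing set directory whose manifest conflicts is refused unless
    ``overwrite`` is passed.
    """
    if not target_heights:
        raise ValueError("target_heights must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sets: list[PrecalcSet] = []
    for h in target_heights:
        set_dir = out_dir / set_dir_name(h, dem)
        manifest = _build_manifest(dem, towers, h, cfg)
        if extra_manifest:
            manifest.update(extra_manifest)
        manifest_path = set_dir / "manifest.json"
        if manifest_path.exists():
            existing = json.loads(manifest_path.read_text())
            if existing != manifest and not overwrite:
                raise FileExistsError(
                    f"{set_dir} already holds a set with a conflicting manifest; pass overwrite=True to replace it"
                )
        set_dir.mkdir(exist_ok=True)
        field, validity = (None, None) if not target_fields else target_fields.get(h, (None, None))
        rasters: dict[str, ViewshedRaster] = {}
        for t in towers:
            vs = compute_viewshed(
                dem, t, h, cfg, target_elevation_field=field, validity=validity
            )
            _geotiff.write_array(
                set_dir / _safe_filename(t.name), vs.to_uint8(), dem.transform, dem.crs, nodata=_INVALID
            )
            rasters[t.name] = vs
            if progress is not None:
                progress(t.name, h)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        sets.append(PrecalcSet(set_dir, manifest, rasters))
    return sets


def load_set(directory: str | Path) -> PrecalcSet:
    """Load a stored set, checking every listed raster exists and that its
    geometry matches the manifest."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory} has no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    expected_transform = tuple(float(v) for v in manifest["transform"])
    expected_shape = (int(manifest["nrows"]), int(manifest["ncols"]))
    rasters: dict[str, ViewshedRaster] = {}
    for entry in manifest["towers"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"set {directory} is missing the raster for tower {entry['name']!r} ({fpath.name})")
        arr, transform, crs, _nodata = _geotiff.read_array(fpath)
        if arr.shape != expected_shape or not _transforms_close(transform, expected_transform):
            raise ValueError(
                f"raster {fpath.name} geometry does not match the set manifest "
                f"(shape {arr.shape} vs {expected_shape}, transform {transform} vs {expected_transform})"
            )
        rasters[entry["name"]] = ViewshedRaster(
            visible=arr == 1,
            valid=arr != _INVALID,
            tower_name=entry["name"],
            target_height_m=float(manifest["target_height_m"]),
            curved=bool(manifest["curved"]),
            max_range_m=entry["max_range_m"],
            transform=expected_transform,
            crs=crs,
        )
    return PrecalcSet(directory, manifest, rasters)


def _transforms_close(a, b, tol: float = 1e-9) -> bool:
    return all(math.isclose(x, y, rel_tol=0, abs_tol=tol * max(1.0, abs(y))) for x, y in zip(a, b))
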