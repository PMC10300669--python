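"""Point-to-point line of sight over a DEM.

A sight line between a tower (at its height above ground) and a target (at
its height above the local surface) is sampled at fixed spacing; the target
is visible when no terrain sample between the endpoints rises strictly
above the line.  Earth curvature is modelled by lowering each terrain
sample by the spherical tangent-plane drop d²/(2R) — the second-order
Taylor term of a sphere falling away below its tangent — with the tower as
the zero-drop origin.  The target endpoint itself is lowered by the same
rule, so the "sight line" is a chord of the curved Earth expressed in the
tower's tangent frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geodata import DEMGrid, EARTH_RADIUS_M, ground_distance, haversine_m

__all__ = ["SightConfig", "ElevationProfile", "LOSResult", "curvature_drop", "sample_profile", "line_of_sight"]


@dataclass(frozen=True)
class SightConfig:
    """Settings for the sight-line model.

    sample_step_m / endpoint_exclusion_m of ``None`` resolve per-DEM to half
    the smaller cell dimension: half-cell sampling cannot skip a cell along
    the line, and the half-cell exclusion keeps a tower's or target's own
    cell from occluding itself.
    """

    earth_radius_m: float = EARTH_RADIUS_M
    curved: bool = False
    sample_step_m: float | None = None
    endpoint_exclusion_m: float | None = None

    def __post_init__(self) -> None:
        if self.earth_radius_m <= 0:
            raise ValueError("earth_radius_m must be > 0")
        if self.sample_step_m is not None and self.sample_step_m <= 0:
            raise ValueError("sample_step_m must be > 0")
        if self.endpoint_exclusion_m is not None and self.endpoint_exclusion_m < 0:
            raise ValueError("endpoint_exclusion_m must be ≥ 0")

    def resolved(self, dem: DEMGrid) -> "_ResolvedSight":
        rx, ry = dem.resolution
        if dem.crs.is_geographic:
            # convert degree-valued cell size to metres at the grid center
            lat0 = float(np.mean(dem.cell_centers_y()))
            mx = rx * math.pi / 180.0 * self.earth_radius_m * math.cos(math.radians(lat0))
            my = ry * math.pi / 180.0 * self.earth_radius_m
            half_cell = 0.5 * min(mx, my)
        else:
            half_cell = 0.5 * min(rx, ry)
        step = self.sample_step_m if self.sample_step_m is not None else half_cell
        excl = self.endpoint_exclusion_m if self.endpoint_exclusion_m is not None else half_cell
        return _ResolvedSight(self.earth_radius_m, self.curved, step, excl)


@dataclass(frozen=True)
class _ResolvedSight:
    earth_radius_m: float
    curved: bool
    sample_step_m: float
    endpoint_exclusion_m: float


def curvature_drop(d, cfg: SightConfig | _ResolvedSight):
    """Height by which a point at ground distance d falls below the tower's
    tangent plane: d²/(2R) on a sphere of radius R; 0 in the flat model."""
    d_arr = np.asarray(d, dtype=np.float64)
    if np.any(d_arr < 0):
        raise ValueError("distance must be ≥ 0")
    if not cfg.curved:
        out = np.zeros_like(d_arr)
    else:
        out = d_arr * d_arr / (2.0 * cfg.earth_radius_m)
    return float(out) if np.ndim(d) == 0 else out


@dataclass
class ElevationProfile:
    """Terrain and sight-line elevations sampled along a segment.

    ``terrain_curved`` is terrain minus the curvature drop (equal to
    ``terrain`` in the flat model); ``sightline`` interpolates linearly
    between the endpoint heights, the far endpoint already lowered by the
    drop at full distance.  Nodata samples carry NaN terrain.
    """

    distances: np.ndarray
    terrain: np.ndarray
    terrain_curved: np.ndarray
    sightline: np.ndarray
    nodata: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def any_nodata(self) -> bool:
        return bool(self.nodata.any())

    @property
    def total_distance_m(self) -> float:
        return float(self.distances[-1])

    def to_csv(self, path) -> None:
        """Plain CSV `distance_m,terrain_m,terrain_curved_m,sightline_m`."""
        import pandas as pd

        pd.DataFrame(
            {
                "distance_m": self.distances,
                "terrain_m": self.terrain,
                "terrain_curved_m": self.terrain_curved,
                "sightline_m": self.sightline,
            }
        ).to_csv(path, index=False)


@dataclass
class LOSResult:
    """Outcome of a line-of-sight test.

    ``valid`` is false when the question is undefined (target on a nodata
    cell); an invalid result is never reported as visible.
    """

    visible: bool
    blocking_distance_m: float | None
    profile: ElevationProfile
    valid: bool = True


def _segment_samples(dem: DEMGrid, p1, p2, step_m: float, radius_m: float):
    """Sample points, distances and nearest-cell indices along p1→p2.

    Endpoints are always included; interior spacing is D/⌈D/step⌉ ≤ step.
    """
    x1, y1 = p1
    x2, y2 = p2
    D = ground_distance(p1, p2, dem.crs, radius_m)
    n_seg = max(1, math.ceil(D / step_m)) if D > 0 else 1
    t = np.linspace(0.0, 1.0, n_seg + 1)
    xs = x1 + t * (x2 - x1)
    ys = y1 + t * (y2 - y1)
    if dem.crs.is_geographic and D > 0:
        dist = haversine_m(y1, x1, ys, xs, radius_m)
        dist[0], dist[-1] = 0.0, D
    else:
        dist = t * D
    a, _, c, _, e, f = dem.transform
    cols = np.clip(((xs - c) / a).astype(np.int64), 0, dem.ncols - 1)
    rows = np.clip(((ys - f) / e).astype(np.int64), 0, dem.nrows - 1)
    return dist, rows, cols, D


def _require_inside(dem: DEMGrid, p, label: str) -> None:
    if not dem.extent.contains(*p):
        raise ValueError(f"{label} {p} is outside the DEM extent")


def sample_profile(
    dem: DEMGrid,
    p1: tuple[float, float],
    p2: tuple[float, float],
    cfg: SightConfig,
    h1_m: float = 0.0,
    h2_m: float = 0.0,
) -> ElevationProfile:
    """Extract the elevation profile along the straight segment p1 → p2.

    Elevations are nearest-cell lookups; nodata samples become NaN rather
    than being interpolated away.  The sight line runs from terrain(p1)+h1
    to the curvature-lowered terrain(p2)+h2.
    """
    _require_inside(dem, p1, "profile start")
    _require_inside(dem, p2, "profile end")
    r = cfg.resolved(dem)
    dist, rows, cols, D = _segment_samples(dem, p1, p2, r.sample_step_m, r.earth_radius_m)
    terrain = dem.values[rows, cols].astype(np.float64)
    nod = dem.nodata_mask[rows, cols]
    terrain[nod] = np.nan
    drop = curvature_drop(dist, r)
    terrain_curved = terrain - drop
    A = terrain[0] + h1_m
    B = terrain_curved[-1] + h2_m
    with np.errstate(invalid="ignore"):
        frac = dist / D if D > 0 else np.zeros_like(dist)
        sightline = A + frac * (B - A)
    return ElevationProfile(dist, terrain, terrain_curved, sightline, nod)


def _blocked_at(
    dist: np.ndarray,
    terrain_curved: np.ndarray,
    sightline: np.ndarray,
    nod: np.ndarray,
    D: float,
    excl: float,
) -> float | None:
    """Distance of the first strictly blocking interior sample, else None.

    Ties (terrain exactly on the line) do not block; nodata samples do not
    block; samples within the endpoint-exclusion zone do not block.
    """
    interior = (dist > excl) & (dist < D - excl)
    with np.errstate(invalid="ignore"):
        blocking = interior & ~nod & (terrain_curved > sightline)
    idx = np.nonzero(blocking)[0]
    if idx.size == 0:
        return None
    return float(dist[idx[0]])


def line_of_sight(
    dem: DEMGrid,
    p1: tuple[float, float],
    tower_height_m: float,
    p2: tuple[float, float],
    target_height_m: float,
    cfg: SightConfig,
) -> LOSResult:
    """Test visibility from a tower at p1 to a target at p2.

    The sight line runs from ground(p1)+tower_height to the
    curvature-lowered ground(p2)+target_height; the target is visible when
    no interior terrain sample (outside the endpoint-exclusion zones) lies
    strictly above it.
    """
    if tower_height_m < 0 or target_height_m < 0:
        raise ValueError("heights must be ≥ 0")
    profile = sample_profile(dem, p1, p2, cfg, tower_height_m, target_height_m)
    if math.isnan(profile.terrain[0]):
        raise ValueError(f"tower at {p1} sits on a nodata cell")
    if math.isnan(profile.terrain[-1]):
        return LOSResult(visible=False, blocking_distance_m=None, profile=profile, valid=False)
    r = cfg.resolved(dem)
    D = profile.total_distance_m
    block = _blocked_at(
        profile.distances, profile.terrain_curved, profile.sightline, profile.nodata, D, r.endpoint_exclusion_m
    )
    return LOSResult(visible=block is None, blocking_distance_m=block, profile=profile)
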