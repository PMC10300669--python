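"""Independent brute-force LOS/viewshed oracle for cross-checking the engine.

Deliberately written as a plain per-sample loop sharing no code with
towershed.los / towershed.viewshed: nearest-cell lookup by its own floor
arithmetic, curvature as an explicit d*d/(2R) subtraction, strict-above
blocking, half-cell endpoint exclusion.  Slow by design; use on small grids.
"""

from __future__ import annotations

import math

import numpy as np


def _haversine(lat1, lon1, lat2, lon2, radius):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(min(1.0, h)))


def _distance(dem, p, q, radius):
    if dem.crs.is_geographic:
        return _haversine(p[1], p[0], q[1], q[0], radius)
    return math.hypot(q[0] - p[0], q[1] - p[1])


def _cell_at(dem, x, y):
    a, _, c, _, e, f = dem.transform
    col = int(math.floor((x - c) / a))
    row = int(math.floor((y - f) / e))
    col = min(max(col, 0), dem.ncols - 1)
    row = min(max(row, 0), dem.nrows - 1)
    return row, col


def los_visible(
    dem,
    p1,
    z1_abs,
    p2,
    z2_abs,
    curved=False,
    radius=6_371_000.0,
    step=None,
    exclusion=None,
):
    """True iff no interior terrain sample rises strictly above the chord.

    z1_abs/z2_abs are absolute endpoint elevations (surface + height); the
    default step is a tenth of the smaller cell dimension.
    """
    rx, ry = dem.resolution
    if dem.crs.is_geographic:
        lat_mid = 0.5 * (p1[1] + p2[1])
        mx = rx * math.pi / 180.0 * radius * math.cos(math.radians(lat_mid))
        my = ry * math.pi / 180.0 * radius
        cell = min(mx, my)
    else:
        cell = min(rx, ry)
    if step is None:
        step = cell / 10.0
    if exclusion is None:
        exclusion = cell / 2.0

    D = _distance(dem, p1, p2, radius)
    if D == 0:
        return True
    n_seg = max(1, math.ceil(D / step))
    z2_eff = z2_abs - (D * D / (2 * radius) if curved else 0.0)
    for k in range(1, n_seg):
        t = k / n_seg
        x = p1[0] + t * (p2[0] - p1[0])
        y = p1[1] + t * (p2[1] - p1[1])
        d = _distance(dem, p1, (x, y), radius)
        if d <= exclusion or d >= D - exclusion:
            continue
        row, col = _cell_at(dem, x, y)
        if dem.nodata_mask[row, col]:
            continue
        z = float(dem.values[row, col])
        if curved:
            z -= d * d / (2 * radius)
        line = z1_abs + (d / D) * (z2_eff - z1_abs)
        if z > line:
            return False
    return True


def viewshed(
    dem,
    tower_xy,
    tower_height,
    target_height,
    curved=False,
    radius=6_371_000.0,
    max_range=None,
    step=None,
    target_elevation=None,
    validity=None,
):
    """Brute-force Boolean viewshed over all cell centers."""
    trow, tcol = _cell_at(dem, *tower_xy)
    z1 = float(dem.values[trow, tcol]) + tower_height
    a, _, c, _, e, f = dem.transform
    visible = np.zeros((dem.nrows, dem.ncols), dtype=bool)
    for row in range(dem.nrows):
        for col in range(dem.ncols):
            if validity is not None and not validity[row, col]:
                continue
            if dem.nodata_mask[row, col]:
                continue
            x = c + a * (col + 0.5)
            y = f + e * (row + 0.5)
            d = _distance(dem, tower_xy, (x, y), radius)
            if max_range is not None and d > max_range:
                continue
            if target_elevation is not None:
                z2 = float(target_elevation[row, col])
            else:
                z2 = float(dem.values[row, col]) + target_height
            visible[row, col] = los_visible(
                dem, tower_xy, z1, (x, y), z2, curved=curved, radius=radius, step=step
            )
    return visible
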