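"""Coordinate reference systems and WGS-84 ↔ UTM transforms.

Only the CRS machinery a viewshed analysis needs is provided: an EPSG-coded
CRS tag attached to every raster, a geographic/projected distinction, and
transverse-Mercator (UTM, WGS-84 ellipsoid) forward/inverse transforms so
that tower tables given in latitude/longitude can be placed on a projected
DEM.  The series expansions are the classical transverse-Mercator ones
(accurate to well under a centimetre inside a UTM zone), which is far below
a DEM cell at viewshed scales.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = ["CRS", "WGS84", "utm_forward", "utm_inverse"]

# WGS-84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_S = 10000000.0


@dataclass(frozen=True)
class CRS:
    """A coordinate reference system identified by an EPSG code.

    Supported codes: 4326 (WGS-84 geographic) and the UTM zones
    32601–32660 (north) / 32701–32760 (south).  Anything else can be
    carried through raster I/O untouched but cannot be transformed.
    """

    epsg: int

    @classmethod
    def from_string(cls, text: str) -> "CRS":
        m = re.fullmatch(r"(?i)epsg:(\d+)", text.strip())
        if not m:
            raise ValueError(f"unsupported CRS string {text!r}; expected 'EPSG:<code>'")
        return cls(int(m.group(1)))

    @property
    def is_geographic(self) -> bool:
        return self.epsg == 4326

    @property
    def is_utm(self) -> bool:
        return 32601 <= self.epsg <= 32660 or 32701 <= self.epsg <= 32760

    @property
    def utm_zone(self) -> int:
        if not self.is_utm:
            raise ValueError(f"EPSG:{self.epsg} is not a UTM CRS")
        return self.epsg % 100

    @property
    def utm_south(self) -> bool:
        return 32701 <= self.epsg <= 32760

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"EPSG:{self.epsg}"

    def to_wgs84(self, x: float, y: float) -> tuple[float, float]:
        """Transform a point in this CRS to (lat, lon) degrees."""
        if self.is_geographic:
            return y, x
        if self.is_utm:
            return utm_inverse(x, y, self.utm_zone, self.utm_south)
        raise ValueError(f"no transform available for EPSG:{self.epsg}")

    def from_wgs84(self, lat: float, lon: float) -> tuple[float, float]:
        """Transform (lat, lon) degrees to (x, y) in this CRS."""
        if self.is_geographic:
            return lon, lat
        if self.is_utm:
            return utm_forward(lat, lon, self.utm_zone)
        raise ValueError(f"no transform available for EPSG:{self.epsg}")


WGS84 = CRS(4326)


def _central_meridian(zone: int) -> float:
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return math.radians(-183.0 + 6.0 * zone)


def utm_forward(lat: float, lon: float, zone: int) -> tuple[float, float]:
    """WGS-84 geographic → UTM easting/northing (metres) for a fixed zone.

    Northing is returned in the northern-hemisphere convention; callers
    using a southern zone add the 10 000 km false northing themselves via
    :class:`CRS`.
    """
    phi = math.radians(lat)
    lam = math.radians(lon)
    lam0 = _central_meridian(zone)

    sin_phi = math.sin(phi)
    cos_phi = math.cos(phi)
    tan_phi = math.tan(phi)

    n = _A / math.sqrt(1.0 - _E2 * sin_phi * sin_phi)
    t = tan_phi * tan_phi
    c = _EP2 * cos_phi * cos_phi
    a = cos_phi * (lam - lam0)

    e4 = _E2 * _E2
    e6 = e4 * _E2
    m = _A * (
        (1 - _E2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * _E2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * math.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * math.sin(4 * phi)
        - (35 * e6 / 3072) * math.sin(6 * phi)
    )

    easting = _FALSE_EASTING + _K0 * n * (
        a
        + (1 - t + c) * a**3 / 6
        + (5 - 18 * t + t * t + 72 * c - 58 * _EP2) * a**5 / 120
    )
    northing = _K0 * (
        m
        + n
        * tan_phi
        * (
            a * a / 2
            + (5 - t + 9 * c + 4 * c * c) * a**4 / 24
            + (61 - 58 * t + t * t + 600 * c - 330 * _EP2) * a**6 / 720
        )
    )
    return easting, northing


def utm_inverse(easting: float, northing: float, zone: int, south: bool = False) -> tuple[float, float]:
    """UTM easting/northing → WGS-84 (lat, lon) degrees."""
    x = easting - _FALSE_EASTING
    y = northing - (_FALSE_NORTHING_S if south else 0.0)
    lam0 = _central_meridian(zone)

    m = y / _K0
    e4 = _E2 * _E2
    e6 = e4 * _E2
    mu = m / (_A * (1 - _E2 / 4 - 3 * e4 / 64 - 5 * e6 / 256))

    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * math.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * math.sin(4 * mu)
        + (151 * e1**3 / 96) * math.sin(6 * mu)
        + (1097 * e1**4 / 512) * math.sin(8 * mu)
    )

    sin1 = math.sin(phi1)
    cos1 = math.cos(phi1)
    tan1 = math.tan(phi1)

    c1 = _EP2 * cos1 * cos1
    t1 = tan1 * tan1
    n1 = _A / math.sqrt(1 - _E2 * sin1 * sin1)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1 * sin1) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tan1 / r1) * (
        d * d / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1 * c1 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1 * t1 - 252 * _EP2 - 3 * c1 * c1) * d**6 / 720
    )
    lam = lam0 + (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1 * c1 + 8 * _EP2 + 24 * t1 * t1) * d**5 / 120
    ) / cos1

    return math.degrees(phi), math.degrees(lam)
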