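"""Export analysis rasters to GeoTIFF and KMZ.

GeoTIFF keeps the analysis exact (uint8 Boolean/mask bands, uint16 count
bands, invalid cells as nodata, georeferencing copied from the source DEM).
KMZ — a zip of a KML 2.2 ground overlay plus a rendered PNG — is the
take-it-to-Google-Earth format: counts render on a monotone ramp with more
towers darker, invalid cells as opaque black shadows, and zero/background
cells transparent.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from PIL import Image

from . import _geotiff
from .composite import CountRaster, MaskRaster
from .viewshed import ViewshedRaster

__all__ = ["Palette", "write_geotiff", "write_kmz"]

RGBA = tuple[float, float, float, float]

_INVALID_U8 = 255
_INVALID_U16 = 65535
_BLACK: RGBA = (0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class Palette:
    """Value-range → RGBA colour map (components in [0, 1]).

    ``entries`` are (lo, hi, rgba) with inclusive, non-overlapping ranges;
    ``transparent_zero`` renders value 0 fully transparent regardless of
    entries; invalid cells always render ``invalid_rgba``.
    """

    entries: tuple[tuple[float, float, RGBA], ...]
    transparent_zero: bool = True
    invalid_rgba: RGBA = _BLACK

    def __post_init__(self) -> None:
        spans = sorted((lo, hi) for lo, hi, _ in self.entries)
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 <= hi:
                raise ValueError("palette ranges overlap")
        for lo, hi, rgba in self.entries:
            if lo > hi:
                raise ValueError(f"palette range ({lo}, {hi}) is inverted")
            if not all(0.0 <= ch <= 1.0 for ch in rgba):
                raise ValueError(f"palette colour {rgba} outside [0, 1]")

    @classmethod
    def count_ramp(cls, max_count: int, transparent_zero: bool = True) -> "Palette":
        """Monotone ramp for cumulative counts: more towers → darker."""
        max_count = max(1, int(max_count))
        entries = []
        for k in range(1, max_count + 1):
            shade = 0.85 - 0.75 * (k - 1) / max(1, max_count - 1) if max_count > 1 else 0.35
            entries.append((float(k), float(k), (0.05, shade * 0.55, shade, 1.0)))
        return cls(tuple(entries), transparent_zero=transparent_zero)

    @classmethod
    def flat(cls, rgba: RGBA = (1.0, 0.85, 0.0, 1.0), transparent_zero: bool = True) -> "Palette":
        """Single-colour palette for Boolean masks (nonzero → rgba)."""
        return cls(((0.5, float("inf"), rgba),), transparent_zero=transparent_zero)

    def apply(self, values: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Render values to an RGBA uint8 image."""
        out = np.zeros(values.shape + (4,), dtype=np.uint8)
        vals = np.asarray(values, dtype=np.float64)
        for lo, hi, rgba in self.entries:
            sel = (vals >= lo) & (vals <= hi) & valid
            if self.transparent_zero:
                sel &= vals != 0
            out[sel] = [round(ch * 255) for ch in rgba]
        inv = [round(ch * 255) for ch in self.invalid_rgba]
        out[~np.asarray(valid, dtype=bool)] = inv
        return out


def _raster_parts(raster):
    if isinstance(raster, ViewshedRaster):
        return raster.to_uint8(), raster.valid, raster.visible.astype(np.int64), _INVALID_U8
    if isinstance(raster, MaskRaster):
        band = raster.mask.astype(np.uint8)
        band[~raster.valid] = _INVALID_U8
        return band, raster.valid, raster.mask.astype(np.int64), _INVALID_U8
    if isinstance(raster, CountRaster):
        band = raster.counts.astype(np.uint16)
        band[~raster.valid] = _INVALID_U16
        return band, raster.valid, raster.counts.astype(np.int64), _INVALID_U16
    raise TypeError(f"cannot export object of type {type(raster).__name__}")


def write_geotiff(raster: ViewshedRaster | CountRaster | MaskRaster, path: str | Path) -> None:
    """Write a result raster as a single-band GeoTIFF, invalid = nodata."""
    band, _valid, _values, nodata = _raster_parts(raster)
    _geotiff.write_array(path, band, raster.transform, raster.crs, nodata=nodata)


def _wgs84_bounds(raster) -> tuple[float, float, float, float]:
    """(north, south, east, west) of the raster's outer edge in WGS-84."""
    a, _, c, _, e, f = raster.transform
    nrows, ncols = _raster_parts(raster)[1].shape
    xs = (c, c + a * ncols)
    ys = (f + e * nrows, f)
    if raster.crs.is_geographic:
        return ys[1], ys[0], xs[1], xs[0]
    lats, lons = [], []
    for x in xs:
        for y in ys:
            lat, lon = raster.crs.to_wgs84(x, y)
            lats.append(lat)
            lons.append(lon)
    return max(lats), min(lats), max(lons), min(lons)


_KML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<kml xmlns="http://www.opengis.net/kml/2.2">
  <Document>
    <GroundOverlay>
      <name>{name}</name>
      <Icon><href>overlay.png</href></Icon>
      <LatLonBox>
        <north>{north:.9f}</north>
        <south>{south:.9f}</south>
        <east>{east:.9f}</east>
        <west>{west:.9f}</west>
      </LatLonBox>
    </GroundOverlay>
  </Document>
</kml>
"""


def write_kmz(
    raster: ViewshedRaster | CountRaster | MaskRaster,
    path: str | Path,
    palette: Palette | None = None,
    name: str = "towershed overlay",
) -> None:
    """Write a KMZ ground overlay: ZIP(doc.kml + overlay.png).

    The overlay PNG is rendered at the raster's own resolution and the KML
    lat/lon box equals the raster's WGS-84 bounds.
    """
    _band, valid, values, _nodata = _raster_parts(raster)
    if values.size == 0:
        raise ValueError("cannot export an empty raster")
    if palette is None:
        if isinstance(raster, CountRaster):
            palette = Palette.count_ramp(int(values.max()) if values.size else 1)
        else:
            palette = Palette.flat()
    rgba = palette.apply(values, valid)
    png_buf = io.BytesIO()
    Image.fromarray(rgba, mode="RGBA").save(png_buf, format="PNG")
    north, south, east, west = _wgs84_bounds(raster)
    kml = _KML_TEMPLATE.format(name=escape(name), north=north, south=south, east=east, west=west)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("doc.kml", kml)
        zf.writestr("overlay.png", png_buf.getvalue())
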