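"""Minimal GeoTIFF reading/writing on top of tifffile.

Handles exactly the subset of the GeoTIFF spec a viewshed workflow touches:
single-band rasters, an axis-aligned affine transform expressed through the
ModelPixelScale + ModelTiepoint tags, an EPSG code in the GeoKeyDirectory,
and the GDAL_NODATA ASCII tag.  Rotated/sheared transforms are rejected.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import tifffile

from .crs import CRS

# TIFF/GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_TYPE = 3072

_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2
_RASTER_PIXEL_IS_AREA = 1


class NotARasterError(ValueError):
    """Raised when a path does not name a readable single-band GeoTIFF."""


def _geokey_directory(crs: CRS) -> tuple[int, ...]:
    if crs.is_geographic:
        keys = [
            (_KEY_MODEL_TYPE, 0, 1, _MODEL_GEOGRAPHIC),
            (_KEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA),
            (_KEY_GEOGRAPHIC_TYPE, 0, 1, crs.epsg),
        ]
    else:
        keys = [
            (_KEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED),
            (_KEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA),
            (_KEY_PROJECTED_TYPE, 0, 1, crs.epsg),
        ]
    flat: list[int] = [1, 1, 0, len(keys)]
    for entry in keys:
        flat.extend(entry)
    return tuple(flat)


def write_array(
    path: str | Path,
    values: np.ndarray,
    transform: tuple[float, float, float, float, float, float],
    crs: CRS,
    nodata: float | int | None = None,
) -> None:
    """Write a single-band GeoTIFF.

    ``transform`` is the (a, b, c, d, e, f) affine with x = c + a·col + b·row,
    y = f + d·col + e·row for pixel-corner coordinates; only axis-aligned
    north-up transforms (b = d = 0, e < 0) are supported.
    """
    a, b, c, d, e, f = transform
    if b != 0 or d != 0:
        raise ValueError("rotated/sheared transforms are not supported")
    if e >= 0:
        raise ValueError("transform must be north-up (negative row scale)")

    geokeys = _geokey_directory(crs)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(a), float(-e), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(c), float(f), 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
    ]
    if nodata is not None:
        if isinstance(nodata, float) and not float(nodata).is_integer():
            nodata_str = repr(float(nodata))
        else:
            nodata_str = str(int(nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_str) + 1, nodata_str))

    tifffile.imwrite(
        path,
        np.ascontiguousarray(values),
        photometric="minisblack",
        extratags=extratags,
    )


def read_array(
    path: str | Path,
) -> tuple[np.ndarray, tuple[float, float, float, float, float, float], CRS, float | None]:
    """Read a single-band GeoTIFF → (values, transform, crs, nodata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        raise NotARasterError(f"{path} is not a readable raster: {exc}") from exc

    with tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim == 3:
            if values.shape[-1] != 1 and values.shape[0] != 1:
                raise NotARasterError(
                    f"{path} is a multi-band raster; a single elevation band is required"
                )
            values = values.reshape(values.shape[-2:] if values.shape[0] == 1 else values.shape[:2])
        elif values.ndim != 2:
            raise NotARasterError(f"{path} has unsupported dimensionality {values.ndim}")

        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise NotARasterError(f"{path} lacks GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        i, j, _, x, y, _ = tie[:6]
        # shift tiepoint to pixel (0, 0) corner
        origin_x = x - i * sx
        origin_y = y + j * sy
        transform = (float(sx), 0.0, float(origin_x), 0.0, float(-sy), float(origin_y))

        if _TAG_GEO_KEYS not in tags:
            raise NotARasterError(f"{path} has no CRS (GeoKeyDirectory missing)")
        crs = _parse_geokeys(tags[_TAG_GEO_KEYS].value, path)

        nodata: float | None = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            if isinstance(raw, bytes):
                raw = raw.decode("ascii", "ignore")
            raw = raw.strip().strip("\x00")
            if raw and raw.lower() != "nan":
                nodata = float(raw)
            elif raw.lower() == "nan":
                nodata = math.nan

    return values, transform, crs, nodata


def _parse_geokeys(directory, path) -> CRS:
    entries = list(directory)
    if len(entries) < 4:
        raise NotARasterError(f"{path} has a malformed GeoKeyDirectory")
    n_keys = entries[3]
    epsg = None
    model = None
    for k in range(n_keys):
        key_id, loc, _count, value = entries[4 + 4 * k : 8 + 4 * k]
        if loc != 0:
            continue
        if key_id == _KEY_MODEL_TYPE:
            model = value
        elif key_id in (_KEY_GEOGRAPHIC_TYPE, _KEY_PROJECTED_TYPE):
            epsg = value
    if epsg is None:
        raise NotARasterError(f"{path} has no EPSG code in its GeoKeyDirectory")
    if model == _MODEL_GEOGRAPHIC and epsg != 4326:
        raise NotARasterError(f"{path}: unsupported geographic CRS EPSG:{epsg}")
    return CRS(int(epsg))
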