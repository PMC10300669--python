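"""Submerged-receiver viewsheds over bathymetry.

In an aquatic array both the receivers and the tags sit under water and the
seabed is the blocking surface.  The tag (target) depth can be specified in
two ways: a constant height above the seabed (the aquatic analogue of
height above ground) or a constant depth below the water surface (for
pelagic species).  Either way some cells can make the LOS question
undefined — asking for a target 5 m above the seabed in 3 m of water places
it in the air, and a below-surface depth can land under the seabed — and
such cells are marked invalid rather than not-visible, as are land cells
(seabed at or above the water surface).  The water column itself adds no
blocking: sight lines are straight, acoustic refraction is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geodata import DEMGrid, Tower, coord_to_cell
from .los import SightConfig
from .viewshed import ViewshedRaster, compute_viewshed

__all__ = ["HeightMode", "AquaticConfig", "target_elevation_field", "aquatic_viewshed"]


class HeightMode(str, Enum):
    ABOVE_SEABED = "above_seabed"
    BELOW_SURFACE = "below_surface"


@dataclass(frozen=True)
class AquaticConfig:
    """Water surface level and target-depth convention.

    ``water_level_m`` is the surface elevation on the bathymetry's vertical
    datum (≈0 for oceans, site-specific for lakes); ``offset_m`` is metres
    above the seabed or below the surface depending on ``mode``.
    """

    water_level_m: float = 0.0
    mode: HeightMode = HeightMode.ABOVE_SEABED
    offset_m: float = 0.0

    def __post_init__(self) -> None:
        if self.offset_m < 0:
            raise ValueError("offset_m must be ≥ 0")
        object.__setattr__(self, "mode", HeightMode(self.mode))

    def manifest_entry(self) -> dict:
        return {
            "water_level_m": self.water_level_m,
            "mode": self.mode.value,
            "offset_m": self.offset_m,
        }


def target_elevation_field(bathy: DEMGrid, cfg: AquaticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Absolute target elevations and their validity over a bathymetry grid.

    above_seabed: target = seabed + offset, valid while it stays at or
    below the surface.  below_surface: target = surface − offset, valid
    while it stays at or above the seabed.  Land cells (seabed at or above
    the water level) are always invalid.  Boundary equality — a target
    exactly at the surface or exactly on the seabed — counts as valid.
    """
    seabed = bathy.values
    wl = cfg.water_level_m
    under_water = (seabed < wl) & ~bathy.nodata_mask
    if cfg.mode is HeightMode.ABOVE_SEABED:
        elevation = seabed + cfg.offset_m
        valid = under_water & (elevation <= wl)
    else:
        elevation = np.full_like(seabed, wl - cfg.offset_m)
        valid = under_water & (seabed <= wl - cfg.offset_m)
    return elevation, valid


def aquatic_viewshed(
    bathy: DEMGrid,
    receiver: Tower,
    cfg_sight: SightConfig,
    cfg_aquatic: AquaticConfig,
) -> ViewshedRaster:
    """Viewshed of a submerged receiver (height_m = metres above seabed).

    Delegates to the terrestrial engine with the aquatic target-elevation
    field and validity mask; invalid cells (land, impossible depths) come
    back as nodata so they render as shadows, not as "not visible".
    """
    x, y = receiver.xy(bathy.crs)
    if not bathy.extent.contains(x, y):
        raise ValueError(f"receiver {receiver.name!r} lies outside the bathymetry extent")
    row, col = coord_to_cell(bathy, x, y)
    if bathy.nodata_mask[row, col]:
        raise ValueError(f"receiver {receiver.name!r} sits on a nodata cell")
    seabed = float(bathy.values[row, col])
    if seabed >= cfg_aquatic.water_level_m:
        raise ValueError(
            f"receiver {receiver.name!r} is on land (seabed {seabed:g} m ≥ water level "
            f"{cfg_aquatic.water_level_m:g} m)"
        )
    if seabed + receiver.height_m > cfg_aquatic.water_level_m:
        raise ValueError(
            f"receiver {receiver.name!r} would sit above the water surface "
            f"(seabed {seabed:g} m + height {receiver.height_m:g} m > water level "
            f"{cfg_aquatic.water_level_m:g} m)"
        )
    elevation, valid = target_elevation_field(bathy, cfg_aquatic)
    return compute_viewshed(
        bathy,
        receiver,
        cfg_aquatic.offset_m,
        cfg_sight,
        target_elevation_field=elevation,
        validity=valid,
    )
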