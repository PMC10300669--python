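"""Cumulative and subtractive algebra over a precalculated viewshed set.

Both analyses are pure Boolean set algebra on the stored per-tower rasters:
cumulative coverage is an element-wise sum (how many selected towers see
each cell), subtractive coverage is AND over the viewing towers and
NOT-OR over the obstructed ones — the area in sight of every viewing tower
but of none of the obstructed ones, which is the footprint a partially
detected tag must lie in.  Validity propagates conservatively: a cell
invalid in any participating raster is invalid in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crs import CRS
from .viewshed import PrecalcSet

__all__ = ["CountRaster", "MaskRaster", "cumulative_viewshed", "subtractive_viewshed"]


@dataclass
class CountRaster:
    """Per-cell count of selected towers with line of sight."""

    counts: np.ndarray
    n_selected: int
    valid: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: CRS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.valid = np.asarray(self.valid, dtype=bool)
        inside = self.counts[self.valid]
        if inside.size and (inside.min() < 0 or inside.max() > self.n_selected):
            raise ValueError("counts must lie in [0, n_selected] on valid cells")


@dataclass
class MaskRaster:
    """Boolean result of a subtractive query."""

    mask: np.ndarray
    viewing_names: list[str]
    obstructed_names: list[str]
    valid: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: CRS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.mask & ~self.valid):
            raise ValueError("mask must be false on invalid cells")


def _check_names(pset: PrecalcSet, names: list[str], role: str) -> None:
    unknown = [n for n in names if n not in pset.names]
    if unknown:
        raise KeyError(f"unknown {role} tower(s) {unknown}; available: {pset.names}")


def cumulative_viewshed(pset: PrecalcSet, selected: list[str]) -> CountRaster:
    """Element-wise sum of the selected towers' Boolean viewsheds."""
    if not selected:
        raise ValueError("no towers selected")
    _check_names(pset, selected, "selected")
    counts = np.zeros(pset.shape, dtype=np.int64)
    valid = np.ones(pset.shape, dtype=bool)
    for name in selected:
        vs = pset.raster(name)
        counts += vs.visible
        valid &= vs.valid
    counts[~valid] = 0
    return CountRaster(counts, len(selected), valid, pset.transform, pset.crs)


def subtractive_viewshed(pset: PrecalcSet, viewing: list[str], obstructed: list[str]) -> MaskRaster:
    """Cells seen by every viewing tower and by no obstructed tower."""
    if not viewing:
        raise ValueError("viewing list must be non-empty")
    overlap = set(viewing) & set(obstructed)
    if overlap:
        raise ValueError(f"tower(s) {sorted(overlap)} appear as both viewing and obstructed")
    _check_names(pset, viewing, "viewing")
    _check_names(pset, obstructed, "obstructed")
    mask = np.ones(pset.shape, dtype=bool)
    valid = np.ones(pset.shape, dtype=bool)
    for name in viewing:
        vs = pset.raster(name)
        mask &= vs.visible
        valid &= vs.valid
    for name in obstructed:
        vs = pset.raster(name)
        mask &= ~vs.visible
        valid &= vs.valid
    mask &= valid
    return MaskRaster(mask, list(viewing), list(obstructed), valid, pset.transform, pset.crs)
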