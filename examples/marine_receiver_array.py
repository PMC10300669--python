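"""Acoustic receiver array over an islet-dotted basin.

A 9×10 grid of submerged receivers — 300 m apart, moored 1 m above the
seabed, each with 500 m effective range — covers a 20 m-deep basin with
three small islets.  Tags are modelled 1 m above the seabed.  Islets do two
things: their cells are *invalid* (a target 1 m above a seabed that is
above water makes no sense) and they cast reception shadows — in-range
cells seen by fewer receivers than open water would allow.
"""

import numpy as np

import towershed as ts
from towershed.aquatic import AquaticConfig, HeightMode, aquatic_viewshed, target_elevation_field

basin = ts.make_dem(
    ts.FixtureSpec(
        kind="basin_with_islets", nrows=114, ncols=124, resolution_m=30.0,
        basin_depth_m=-20.0, islet_height_m=2.0, islet_sigma_m=60.0,
        islet_centers=((0.35, 0.45), (0.6, 0.6), (0.75, 0.3)),
    )
)
receivers = ts.grid_receivers(
    9, 10, spacing_m=300.0, height_m=1.0, range_m=500.0,
    origin=(basin.extent.xmin + 420.0, basin.extent.ymax - 420.0),
)
acfg = AquaticConfig(water_level_m=0.0, mode=HeightMode.ABOVE_SEABED, offset_m=1.0)
cfg = ts.SightConfig(curved=False)

counts = np.zeros(basin.values.shape, dtype=int)
for recv in receivers:
    counts += aquatic_viewshed(basin, recv, cfg, acfg).visible

_, valid = target_elevation_field(basin, acfg)
xs, ys = basin.cell_centers_x(), basin.cell_centers_y()
in_range = np.zeros_like(counts)
for recv in receivers:
    rx, ry = recv.xy(basin.crs)
    gx, gy = np.meshgrid(xs - rx, ys - ry)
    in_range += np.hypot(gx, gy) <= 500.0
reachable = valid & (in_range > 0)
shadowed = reachable & (counts < in_range)

print(f"receivers: {len(receivers)} (9×10, 300 m apart, 1 m above seabed, 500 m range)")
print(f"islet (land) cells, marked invalid: {int((basin.values >= 0).sum())}")
print(f"reachable water cells: {int(reachable.sum())}")
print(f"covered by ≥1 receiver: {100 * np.mean(counts[reachable] > 0):.1f} %")
print(f"shadowed (fewer receivers than open water would give): "
      f"{100 * shadowed.sum() / reachable.sum():.1f} %")
print(f"max simultaneous receivers at one cell: {counts.max()}")
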