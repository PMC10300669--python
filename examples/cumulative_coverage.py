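"""Cumulative coverage of a tower array around a hill.

Nine 10 m towers on a 3×3 grid watch a 50 m Gaussian hill.  The cumulative
viewshed counts, for every cell, how many towers have line of sight to a
0.3 m target (a walking, ground-dwelling animal).  Localization by
time-of-arrival needs at least three simultaneous towers, so the ≥3
fraction is the planning number that matters.
"""

import tempfile

import numpy as np

import towershed as ts

dem = ts.make_dem(ts.FixtureSpec(kind="gaussian_hill", nrows=41, ncols=41, resolution_m=30.0))
towers = ts.TowerSet(
    [
        ts.tower_at_cell(dem, r, c, f"T{3 * i + j + 1}", height_m=10.0, max_range_m=700.0)
        for i, r in enumerate([6, 20, 34])
        for j, c in enumerate([6, 20, 34])
    ]
)

with tempfile.TemporaryDirectory() as tmp:
    [pset] = ts.precalculate_set(dem, towers, [0.3], ts.SightConfig(curved=False), tmp)
    counts = ts.cumulative_viewshed(pset, pset.names)

    n = counts.counts[counts.valid]
    print(f"towers: {len(towers)}, grid: {dem.nrows}×{dem.ncols} at {dem.resolution[0]:.0f} m")
    print(f"cells seen by ≥1 tower: {100 * np.mean(n >= 1):.1f} %")
    print(f"cells seen by ≥3 towers (localizable): {100 * np.mean(n >= 3):.1f} %")
    print(f"best-covered cell sees {n.max()} towers")
    ts.write_kmz(counts, f"{tmp}/coverage.kmz")
    print("KMZ overlay written (darker = more towers)")
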