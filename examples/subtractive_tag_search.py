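"""Narrowing a lost-tag search with a subtractive viewshed.

A tag on a fallen bird is still heard by towers T1 and T2 but by no other
tower in the array.  The tag must therefore lie in the area visible from
both T1 and T2 and from none of the others — usually a small fraction of
the study site, small enough to search on foot with a hand-held antenna.
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
    [pset] = ts.precalculate_set(dem, towers, [0.3], ts.SightConfig(), tmp)
    viewing = ["T1", "T2"]
    obstructed = [n for n in pset.names if n not in viewing]
    mask = ts.subtractive_viewshed(pset, viewing, obstructed)

    cell_ha = dem.resolution[0] * dem.resolution[1] / 10_000.0
    n_cells = int(mask.mask.sum())
    total = int(mask.valid.sum())
    print(f"detected by {viewing}, silent at {len(obstructed)} other towers")
    print(f"search area: {n_cells} cells = {n_cells * cell_ha:.1f} ha "
          f"({100 * n_cells / total:.1f} % of the {total * cell_ha:.0f} ha site)")
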