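# towershed

Line-of-sight (LOS) and viewshed analysis for planning and operating
telemetry tower networks and acoustic receiver arrays — the question this
package answers is *which parts of a study site can which receivers
actually see?*

Tracking systems that localize an animal-borne tag from signal
time-of-arrival (reverse-GPS radio arrays, marine acoustic arrays) need
simultaneous detection by several towers, so coverage planning is a
multi-tower visibility problem: cumulative coverage (how many towers see
each point), subtractive queries (seen by towers A and B but by none of the
others — the footprint a partially detected lost tag must lie in), elevated
targets (a perching owl at 5 m is not a lapwing at 0.3 m), and submerged
receivers over bathymetry where islets both invalidate target depths and
cast reception shadows.

## The model

A target at Q is visible from a tower at P when no terrain sample between
them rises strictly above the straight sight line. With terrain elevation
e(d) at ground distance d along the segment (nearest-cell lookup on the
DEM, sampled every half cell by default), tower height h_t and target
height h_q above the local surface, the curved-Earth test lowers every
point by the spherical tangent-plane drop

    δ(d) = d² / (2R),      R = 6 371 000 m by default

(the second-order Taylor term of a sphere falling below its tangent plane;
R is configurable). The sight line runs from A = e(0) + h_t to
B = e(D) − δ(D) + h_q, and the target is visible iff

    e(d) − δ(d) ≤ A + (d/D)·(B − A)   for every interior sample d,

with samples within half a cell of either endpoint excluded so a tower's
own cell never occludes itself. The flat-Earth model is δ ≡ 0. A per-tower
*viewshed* applies this test to every cell center within the tower's
reception range; cumulative and subtractive maps are element-wise sums and
Boolean combinations of the stored per-tower rasters. In aquatic mode the
seabed is the blocking surface, targets are specified either metres above
the seabed or metres below the water surface, and physically impossible
cells (target above the surface, below the seabed, or on land) are marked
*invalid* — distinct from "not visible".

## Worked example

`examples/cumulative_coverage.py` builds a 41×41-cell, 30 m-resolution
Gaussian-hill terrain, places nine 10 m towers with 700 m range on a 3×3
grid, precalculates their viewsheds for a 0.3 m target and prints:

```
towers: 9, grid: 41×41 at 30 m
cells seen by ≥1 tower: 100.0 %
cells seen by ≥3 towers (localizable): 89.9 %
best-covered cell sees 6 towers
```

The ≥3 number is the planning figure: time-of-arrival localization needs at
least three simultaneous detections, so 10 % of this site would detect but
not localize a tag. `examples/subtractive_tag_search.py` continues the
scenario — a tag heard only by T1 and T2 must lie in 20 cells (1.8 ha, 1.2 %
of the site), a feasible ground search. `examples/point_to_point_los.py`
shows the curvature effect (a ground target 11 km away over a flat plain:
visible flat-Earth, blocked curved-Earth) and
`examples/marine_receiver_array.py` runs a 90-receiver submerged grid over
an islet-dotted basin (13.5 % of reachable water is shadowed by islets).

## Command line

The same three-phase workflow from a shell — data entry, preparation,
analysis:

```
towershed fixtures --kind gaussian_hill --out data/          # synthetic DEM + towers
towershed prepare --dem data/dem.tif --towers data/towers.csv \
                  --height 0.3 --height 5 --curved --out sets/
towershed cumulative sets/TransAlt0.3m_Res30 --towers all --out cov.tif
towershed subtract   sets/TransAlt0.3m_Res30 --viewing T1 --viewing T2 \
                  --obstructed all-except --obstructed T1 --obstructed T2 \
                  --format kmz --out search.kmz
towershed los --dem data/dem.tif --from 32.54,35.44,10 --to 32.53,35.46,0.3 \
                  --curved --profile-out profile.csv
```

Set directories are named `TransAlt{height}m_Res{cellsize}` and carry a
JSON manifest (grid geometry, CRS, Earth model and radius, tower table), so
a precalculated set is self-describing and shareable. `prepare` also
accepts a JSON config file (`--config run.json`, keys `dem`, `towers`,
`target_heights`, `curved`, `earth_radius_m`, `sample_step_m`, `out`,
`water_level_m`, `height_mode`); explicit flags override config keys.
Tower CSVs have the header `name,lat,lon,height_m,max_range_m` (WGS-84
degrees; empty range = limited by the DEM extent). Exports are uint8/uint16
GeoTIFFs (invalid = nodata) or KMZ ground overlays.

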