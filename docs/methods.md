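# Methods

## Visibility model

A sight line is tested between a tower at point P (height h_t above the
local surface) and a target at Q (height h_q above the surface, or an
absolute elevation in aquatic mode). The segment P→Q is sampled at fixed
ground-distance spacing; each sample takes the elevation of the cell it
falls in (nearest-cell lookup, cell-center registration, row 0 = north).
The target is visible iff no interior sample's terrain lies **strictly**
above the straight line joining the endpoint elevations. Three rules pin
down the edge cases:

- **Tie rule.** Terrain exactly on the sight line does not block. A
  grazing line over a constant-elevation plain is therefore visible.
- **Endpoint exclusion.** Samples within half the smaller cell dimension
  of either endpoint never block, so a tower's (or target's) own cell
  cannot occlude itself; without this, any tower on a local high point
  would shadow its immediate neighbourhood spuriously.
- **Nodata.** Missing-elevation samples in the interior neither block nor
  invalidate (they are logged); a *target* on a nodata cell makes the LOS
  question undefined and the result is flagged invalid, which is not the
  same as not-visible.

## Earth curvature

The curved-Earth model lowers every sample, and the target endpoint, by
δ(d) = d²/(2R) with the tower as the zero-drop origin — the second-order
Taylor expansion of a sphere dropping below its tangent plane, valid while
d ≪ R (at 50 km the next term is below a millimetre). The blocking
condition e(d) − δ(d) > chord(d) is symmetric under d ↔ D−d for equal
endpoint heights, which the tests verify empirically. R defaults to the
standard mean Earth radius 6 371 000 m and is configurable (any positive
radius, for sensitivity analyses or to reproduce other tools' constants).
Since δ ≥ 0 grows toward the target, the curved viewshed is always a
subset of the flat one; the flat model is exactly δ ≡ 0. Atmospheric
refraction (effective-radius corrections), Fresnel zones and signal
attenuation are out of scope: LOS is a first-order proxy for detectability.

## Sampling parameters

- `sample_step_m` — default half the smaller cell dimension. Half-cell
  sampling cannot step over a cell along the segment; finer steps change
  results only at cell-boundary grazing incidences. The oracle-equivalence
  tests run engine and oracle at a tenth of a cell so both traverse the
  identical sample set.
- `endpoint_exclusion_m` — default half the smaller cell dimension (see
  above); 0 disables self-exclusion.
- Distances are horizontal ground distances (Euclidean in projected CRSs,
  spherical haversine with the configured radius in geographic CRSs), not
  3-D slant distances; at tower-height-to-range ratios of telemetry arrays
  the difference is negligible and the convention matches standard
  viewshed practice. For geographic grids the degree-valued cell size is
  converted to metres at the grid-center latitude when resolving the two
  defaults above.

## Viewsheds, sets and composites

`compute_viewshed` evaluates one LOS per cell center; cells whose center
lies beyond the tower's `max_range_m` are false automatically, and an empty
range means extent-limited. Per-tower Boolean rasters are stored as uint8
GeoTIFFs (1 visible, 0 not visible, 255 invalid/nodata) in a directory
named `TransAlt{h}m_Res{r}` with a JSON manifest recording grid geometry,
CRS, Earth model and radius, sampling parameters and the tower table — the
filename convention is human-readable, the manifest is authoritative.
Everything is deterministic: rewriting a set is bit-identical.

Cumulative maps are element-wise integer sums of selected rasters;
subtractive maps are AND over the viewing set ∧ NOT-OR over the obstructed
set. Validity propagates conservatively (invalid anywhere ⇒ invalid in the
output) so aquatic islet shadows survive composition; naming one tower in
both subtractive roles is rejected as an almost-certain user error rather
than returning the silently empty result.

## Aquatic mode

Over bathymetry the seabed is the blocking surface and the water column is
treated as fully transparent (straight rays; sound-speed refraction,
thermoclines and multipath are out of scope). Target depth conventions:

- `above_seabed`: target = seabed + offset; invalid where that exceeds the
  water level (e.g. 5 m above the seabed in 3 m of water) — boundary
  equality, a target exactly at the surface, is valid;
- `below_surface`: target = water level − offset; invalid where that lies
  below the seabed (boundary equality valid).

Land cells (seabed at or above the water level) are always invalid rather
than not-visible, so they render as opaque shadows in every composite.
Validity is a property of bathymetry + configuration alone, independent of
receiver placement. A receiver on land or protruding above the surface is
an error.

## Synthetic fixtures

The generator produces closed-form surfaces (flat plane, Gaussian hill and
ridge, eastward staircase, islet-dotted basin) evaluated at cell centers,
plus regular receiver grids. The marine demo uses the working conditions
of the hypothetical acoustic array it emulates: 90 receivers in a 9×10 grid,
300 m apart, moored 1 m above the seabed, 500 m effective range, water
level 0. Defaults elsewhere (41×41 cells at 30 m; 10 m towers; 0.3 m and
5 m target heights) reflect a 1 arc-second DEM and the heights of the
ground-dwelling and perching species that motivate elevated viewsheds.
Fixtures default to a projected metre-unit CRS (UTM 36N) so LOS tests are
decoupled from geodesy; one geographic-CRS fixture exercises the haversine
paths. Random islet placement flows through a single integer seed and is
bit-reproducible.

What the fixtures do **not** emulate: real DEM noise and void pixels, land
cover (buildings, vegetation) absent from elevation models, radio
propagation effects, and tides. Passing tests therefore demonstrate the
geometry engine is correct, not that LOS equals detection probability in
the field.

## Verification strategy

The engine is cross-checked cell-for-cell against an independently coded
brute-force oracle (plain per-sample loop, its own floor arithmetic and
distance code, dense cell/10 sampling, same tie/exclusion rules) on five
fixture terrains in both Earth models, and against closed-form hand
evaluations (the 11 km / 2 m tower sight line blocked curved but clear
flat, with a +1.374 m midpoint excess). Property tests cover direction
symmetry at equal heights, curved ⊆ flat containment, monotonicity under
raising either endpoint, range masking, set-algebra identities and
reorder invariance, GeoTIFF/KMZ round trips and end-to-end CLI
determinism. Test problem sizes (31–41 cells per side for oracle
comparisons, a 114×124 basin for the marine demo) keep the dense oracle
tractable while exercising every code path; the engine itself has no grid
size limit and its cost is O(cells × samples-per-line).

## Implementation notes

- GeoTIFF reading/writing is implemented directly on tifffile with the
  four georeferencing tags the format needs (ModelPixelScale,
  ModelTiepoint, GeoKeyDirectory with an EPSG code, GDAL_NODATA);
  rotated/sheared transforms and multi-band rasters are rejected with
  explicit errors.
- Coordinate transforms support WGS-84 and the UTM zones via the classical
  transverse-Mercator series (sub-centimetre within a zone); towers are
  given in WGS-84 lat/lon and projected onto the DEM's CRS on use.
  Ellipsoidal geodesics are deliberately not implemented: the spherical
  haversine is consistent with the spherical curvature model and its error
  is negligible at viewshed ranges.
- KMZ export writes a KML 2.2 ground overlay plus an RGBA PNG at raster
  resolution; counts use a monotone ramp (more towers = darker), invalid
  cells are opaque black, background transparent — all overridable via
  `Palette`.

## Known limitations

Single-band metre-unit rasters only; no mosaicking or DEM acquisition; no
vegetation/building attenuation layers; no automated array-placement
optimization; full recompute when a tower moves; per-cell LOS loops are
pure numpy without parallelism (a 500×500 grid × 10 extent-limited towers
is minutes of work on one CPU).
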