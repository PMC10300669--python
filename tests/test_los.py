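"""Point-to-point LOS: curvature model, profile sampling, blocking rule."""

import math

import numpy as np
import pytest

import towershed as ts
from oracle import los_visible

CURVED = ts.SightConfig(curved=True)
FLAT = ts.SightConfig(curved=False)
R = 6_371_000.0


class TestCurvatureDrop:
    def test_zero_distance(self):
        assert ts.curvature_drop(0.0, CURVED) == 0.0

    @pytest.mark.parametrize(
        "d,expected",
        [(1_000.0, 0.07848), (10_000.0, 7.848)],
    )
    def test_worked_values(self, d, expected):
        assert ts.curvature_drop(d, CURVED) == pytest.approx(expected, rel=1e-3)

    def test_closed_form_across_range(self):
        ds = np.geomspace(1.0, 50_000.0, 200)
        drops = ts.curvature_drop(ds, CURVED)
        assert np.allclose(drops, ds * ds / (2 * R), rtol=1e-9, atol=0)

    def test_quadratic_scaling(self):
        assert ts.curvature_drop(10_000.0, CURVED) == pytest.approx(
            100 * ts.curvature_drop(1_000.0, CURVED), rel=1e-12
        )

    def test_flat_model_is_zero(self):
        assert ts.curvature_drop(25_000.0, FLAT) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ts.curvature_drop(-1.0, CURVED)

    def test_alternative_earth_radius_is_configurable(self):
        cfg = ts.SightConfig(curved=True, earth_radius_m=6_731_000.0)
        assert ts.curvature_drop(10_000.0, cfg) == pytest.approx(1e8 / (2 * 6_731_000.0), rel=1e-12)


class TestSampleProfile:
    def test_flat_terrain_all_zero(self, flat_dem):
        p1 = ts.cell_center(flat_dem, 5, 5)
        p2 = ts.cell_center(flat_dem, 35, 30)
        prof = ts.sample_profile(flat_dem, p1, p2, FLAT)
        assert np.all(prof.terrain == 0)
        assert not prof.any_nodata

    def test_sample_count_rule(self, flat_dem):
        p1 = ts.cell_center(flat_dem, 20, 3)
        p2 = (p1[0] + 1000.0, p1[1])
        prof = ts.sample_profile(flat_dem, p1, p2, ts.SightConfig(sample_step_m=15.0))
        assert len(prof.distances) == 68  # ceil(1000/15) interior partition + endpoints
        assert prof.distances[0] == 0.0
        assert prof.distances[-1] == pytest.approx(1000.0)
        assert np.all(np.diff(prof.distances) > 0)

    def test_ridge_peak_near_midpoint(self, ridge_dem):
        p1 = ts.cell_center(ridge_dem, 20, 0)
        p2 = ts.cell_center(ridge_dem, 20, 80)
        prof = ts.sample_profile(ridge_dem, p1, p2, FLAT)
        mid = prof.total_distance_m / 2
        peak_d = prof.distances[np.argmax(prof.terrain)]
        assert abs(peak_d - mid) <= 30.0  # within one cell of the ridge crest
        assert prof.terrain.max() == pytest.approx(50.0, abs=0.5)

    def test_curved_terrain_equals_terrain_minus_drop(self, flat_dem):
        p1 = ts.cell_center(flat_dem, 5, 5)
        p2 = ts.cell_center(flat_dem, 35, 35)
        prof = ts.sample_profile(flat_dem, p1, p2, CURVED)
        expected = prof.terrain - prof.distances**2 / (2 * R)
        assert np.allclose(prof.terrain_curved, expected, rtol=0, atol=1e-12)

    def test_outside_extent_rejected(self, flat_dem):
        p1 = ts.cell_center(flat_dem, 5, 5)
        with pytest.raises(ValueError, match="outside"):
            ts.sample_profile(flat_dem, p1, (flat_dem.extent.xmax + 10, p1[1]), FLAT)

    def test_profile_csv_export(self, ridge_dem, tmp_path):
        p1 = ts.cell_center(ridge_dem, 20, 0)
        p2 = ts.cell_center(ridge_dem, 20, 80)
        prof = ts.sample_profile(ridge_dem, p1, p2, CURVED, 10.0, 0.3)
        out = tmp_path / "profile.csv"
        prof.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "distance_m,terrain_m,terrain_curved_m,sightline_m"


class TestLineOfSight:
    def test_clear_over_flat_terrain(self, flat_dem):
        p1 = ts.cell_center(flat_dem, 20, 2)
        p2 = ts.cell_center(flat_dem, 20, 36)
        res = ts.line_of_sight(flat_dem, p1, 10.0, p2, 0.3, FLAT)
        assert res.visible and res.valid
        assert res.blocking_distance_m is None

    def test_ridge_blocks_near_midpoint(self, ridge_dem):
        p1 = ts.cell_center(ridge_dem, 20, 2)
        p2 = ts.cell_center(ridge_dem, 20, 78)
        res = ts.line_of_sight(ridge_dem, p1, 10.0, p2, 0.3, FLAT)
        assert not res.visible
        D = res.profile.total_distance_m
        assert abs(res.blocking_distance_m - D / 2) < 0.15 * D

    def test_curvature_blocks_at_eleven_km(self):
        # closed form: at d = 5.5 km the curved terrain exceeds the chord
        # from (0, 2) to (11000, -9.497) by ≈ 1.374 m
        dem = ts.make_dem(ts.FixtureSpec(kind="flat", nrows=5, ncols=380, resolution_m=30.0))
        p1 = ts.cell_center(dem, 2, 2)
        p2 = (p1[0] + 11_000.0, p1[1])
        curved = ts.line_of_sight(dem, p1, 2.0, p2, 0.0, CURVED)
        flat = ts.line_of_sight(dem, p1, 2.0, p2, 0.0, FLAT)
        assert flat.visible
        assert not curved.visible
        d, D = 5_500.0, 11_000.0
        margin = -(d * d) / (2 * R) - (2.0 + (d / D) * (-(D * D) / (2 * R) - 2.0))
        assert margin == pytest.approx(1.374, abs=0.01)
        idx = np.argmin(np.abs(curved.profile.distances - d))
        sampled_margin = curved.profile.terrain_curved[idx] - curved.profile.sightline[idx]
        assert sampled_margin == pytest.approx(margin, abs=0.01)

    def test_tower_cell_does_not_occlude_itself(self, flat_dem):
        vals = flat_dem.values.copy()
        vals[20, 10] = 50.0  # a mast-sized obstacle in the tower's own cell
        dem = ts.DEMGrid(values=vals, transform=flat_dem.transform, crs=flat_dem.crs)
        p1 = ts.cell_center(dem, 20, 10)
        p2 = ts.cell_center(dem, 20, 15)
        res = ts.line_of_sight(dem, p1, 1.0, p2, 1.0, FLAT)
        assert res.visible

    def test_tie_terrain_exactly_on_line_does_not_block(self):
        dem = ts.make_dem(ts.FixtureSpec(kind="flat", nrows=5, ncols=41, value=10.0))
        p1 = ts.cell_center(dem, 2, 2)
        p2 = ts.cell_center(dem, 2, 38)
        res = ts.line_of_sight(dem, p1, 0.0, p2, 0.0, FLAT)
        assert res.visible  # sightline lies exactly on the terrain

    def test_target_on_nodata_cell_flagged_invalid(self, flat_dem):
        mask = flat_dem.nodata_mask.copy()
        mask[20, 30] = True
        dem = ts.DEMGrid(flat_dem.values, flat_dem.transform, flat_dem.crs, nodata_mask=mask)
        res = ts.line_of_sight(dem, ts.cell_center(dem, 20, 2), 10.0, ts.cell_center(dem, 20, 30), 0.3, FLAT)
        assert not res.valid
        assert not res.visible

    def test_interior_nodata_does_not_block(self, flat_dem):
        mask = flat_dem.nodata_mask.copy()
        mask[20, 15:18] = True
        dem = ts.DEMGrid(flat_dem.values, flat_dem.transform, flat_dem.crs, nodata_mask=mask)
        res = ts.line_of_sight(dem, ts.cell_center(dem, 20, 2), 10.0, ts.cell_center(dem, 20, 36), 0.3, FLAT)
        assert res.visible
        assert res.profile.any_nodata

    def test_tower_on_nodata_cell_rejected(self, flat_dem):
        mask = flat_dem.nodata_mask.copy()
        mask[20, 2] = True
        dem = ts.DEMGrid(flat_dem.values, flat_dem.transform, flat_dem.crs, nodata_mask=mask)
        with pytest.raises(ValueError, match="nodata"):
            ts.line_of_sight(dem, ts.cell_center(dem, 20, 2), 10.0, ts.cell_center(dem, 20, 36), 0.3, FLAT)


class TestProperties:
    @pytest.mark.parametrize("cfg", [FLAT, CURVED], ids=["flat", "curved"])
    def test_symmetry_with_equal_heights(self, hill_dem, rng, cfg):
        """Equal endpoint heights ⇒ direction does not matter."""
        for _ in range(100):
            r1, c1, r2, c2 = rng.integers(0, 41, 4)
            if (r1, c1) == (r2, c2):
                continue
            p1 = ts.cell_center(hill_dem, r1, c1)
            p2 = ts.cell_center(hill_dem, r2, c2)
            fwd = ts.line_of_sight(hill_dem, p1, 5.0, p2, 5.0, cfg)
            rev = ts.line_of_sight(hill_dem, p2, 5.0, p1, 5.0, cfg)
            assert fwd.visible == rev.visible

    def test_curved_visible_implies_flat_visible(self, hill_dem, rng):
        for _ in range(100):
            r1, c1, r2, c2 = rng.integers(0, 41, 4)
            p1 = ts.cell_center(hill_dem, r1, c1)
            p2 = ts.cell_center(hill_dem, r2, c2)
            curved = ts.line_of_sight(hill_dem, p1, 8.0, p2, 0.3, CURVED)
            flat = ts.line_of_sight(hill_dem, p1, 8.0, p2, 0.3, FLAT)
            if curved.visible:
                assert flat.visible

    def test_height_monotonicity(self, ridge_dem):
        p1 = ts.cell_center(ridge_dem, 20, 2)
        p2 = ts.cell_center(ridge_dem, 20, 78)
        ladder = [0.0, 2.0, 5.0, 10.0, 30.0, 60.0]
        seen = [ts.line_of_sight(ridge_dem, p1, h, p2, 0.3, FLAT).visible for h in ladder]
        # once visible, raising the tower keeps it visible
        assert seen == sorted(seen)
        seen_t = [ts.line_of_sight(ridge_dem, p1, 10.0, p2, h, FLAT).visible for h in ladder]
        assert seen_t == sorted(seen_t)

    @pytest.mark.parametrize("kind", ["gaussian_hill", "ridge", "staircase"])
    @pytest.mark.parametrize("curved", [False, True], ids=["flat", "curved"])
    def test_agrees_with_dense_oracle_point_pairs(self, kind, curved, rng):
        dem = ts.make_dem(ts.FixtureSpec(kind=kind, nrows=31, ncols=31, resolution_m=30.0))
        step = min(dem.resolution) / 10.0
        cfg = ts.SightConfig(curved=curved, sample_step_m=step)
        for _ in range(40):
            r1, c1, r2, c2 = rng.integers(0, 31, 4)
            p1 = ts.cell_center(dem, r1, c1)
            p2 = ts.cell_center(dem, r2, c2)
            z1 = dem.values[r1, c1] + 8.0
            z2 = dem.values[r2, c2] + 0.3
            expected = los_visible(dem, p1, z1, p2, z2, curved=curved, step=step)
            got = ts.line_of_sight(dem, p1, 8.0, p2, 0.3, cfg)
            assert got.visible == expected
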