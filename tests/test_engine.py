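"""The walking algorithm: step vectors, ray heights, cell assessments,
single-cell walks and full-grid timesteps."""

import math

import numpy as np
import pytest

from gridshade.engine import (assess_object, assess_terrain, ray_height,
                              simulate_timestep, step_vector, terrain_shade,
                              walk_cell)
from gridshade.grids import build_landscape_stack
from gridshade.params import CalibrationParams

from conftest import grid, sun


class TestStepVector:
    @pytest.mark.parametrize("azimuth, v, run, rise", [
        (90.0, 1.0, 1.0, 0.0),        # sun due east
        (0.0, 2.0, 0.0, 2.0),         # sun due north
        (225.0, 1.0, -math.sqrt(0.5), -math.sqrt(0.5)),  # southwest
        (180.0, 1.0, 0.0, -1.0),      # due south
    ])
    def test_directions(self, azimuth, v, run, rise):
        sv = step_vector(azimuth, v)
        assert sv.run == pytest.approx(run, abs=1e-12)
        assert sv.rise == pytest.approx(rise, abs=1e-12)

    def test_length_invariant(self):
        for azimuth in np.linspace(0, 359.9, 37):
            sv = step_vector(float(azimuth), 2.5)
            assert math.hypot(sv.run, sv.rise) == pytest.approx(2.5)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            step_vector(90.0, 0.0)


class TestRayHeight:
    def test_forty_five_degrees(self):
        vrc, ah = ray_height(0.0, 45.0, 10.0)
        assert vrc == pytest.approx(10.0)
        assert ah == pytest.approx(10.0)

    def test_thirty_degrees_from_100m(self):
        _, ah = ray_height(100.0, 30.0, 10.0)
        assert ah == pytest.approx(105.7735, abs=1e-4)

    def test_zero_distance(self):
        assert ray_height(42.0, 30.0, 0.0) == (0.0, 42.0)


class TestAssessments:
    def test_ray_passes_over_object(self):
        assert assess_object(25.0, 0.0, 20.0, 0.4) == 1.0

    def test_ray_penetrates_object(self):
        assert assess_object(10.0, 0.0, 20.0, 0.4) == 0.4

    def test_transmittance_product_rule(self):
        o_ld = assess_object(10, 0, 20, 0.5) * assess_object(12, 0, 20, 0.5)
        assert o_ld == pytest.approx(0.25)

    def test_understory_voxel_selected_below_its_top(self):
        # ray at 3 m, understory top at 5 m: the understory transmits
        assert assess_object(3.0, 0.0, 20.0, 0.4,
                             understory_height=5.0,
                             understory_otm=0.9) == pytest.approx(0.9)
        # ray at 10 m, above the understory: canopy transmits
        assert assess_object(10.0, 0.0, 20.0, 0.4,
                             understory_height=5.0,
                             understory_otm=0.9) == pytest.approx(0.4)

    def test_tr_cali_scales_and_clamps(self):
        assert assess_object(10, 0, 20, 0.4, tr_cali=0.5) == pytest.approx(0.2)
        assert assess_object(10, 0, 20, 0.9, tr_cali=1.2) == 1.0

    @pytest.mark.parametrize("ah, elev, expected", [
        (12.0, 30.0, "penetrated"),
        (12.0, 5.0, "above"),
        (12.0, 12.0, "above"),   # grazing tie does not terminate
    ])
    def test_terrain(self, ah, elev, expected):
        assert assess_terrain(ah, elev) == expected

    def test_terrain_shade_inverse_distance(self):
        assert terrain_shade(1, 0.5) == 0.5
        assert terrain_shade(4, 0.5) == 0.125
        assert terrain_shade(1000, 0.5) < 1e-3

    def test_terrain_shade_needs_a_walked_cell(self):
        with pytest.raises(RuntimeError):
            terrain_shade(0, 0.5)


class TestWalkCell:
    def test_flat_unshaded(self, flat_stack):
        res = walk_cell((4, 4), sun(135.0, 40.0), flat_stack)
        assert res.object_light_fraction == 1.0
        assert res.terrain_shade == 0.0
        assert res.terminated_by in ("edge", "ceiling")

    def test_block_case_hand_derived(self, block_row_stack):
        # ray height at the object center 10 m away = 10 tan30 = 5.77 < 20:
        # penetrates, O_LD = 0.4
        res = walk_cell((0, 5), sun(90.0, 30.0), block_row_stack)
        assert res.object_light_fraction == pytest.approx(0.4)
        assert res.terrain_shade == 0.0

    def test_ridge_case_hand_derived(self, ridge_row_stack):
        # col 6 passes (ray 5.77 above ground 0); col 7 center ray height
        # 11.55 < 30 penetrates after 2 cells: shade = 0.5/2
        res = walk_cell((0, 5), sun(90.0, 30.0), ridge_row_stack,
                        CalibrationParams(gr_cali=0.5))
        assert res.terminated_by == "terrain"
        assert res.cells_walked == 2
        assert res.terrain_shade == pytest.approx(0.25)
        assert res.object_light_fraction == 1.0

    def test_night_precondition(self, flat_stack):
        with pytest.raises(ValueError):
            walk_cell((0, 0), sun(90.0, -3.0), flat_stack)

    def test_result_independent_of_step_length(self, block_row_stack):
        results = [
            walk_cell((0, 5), sun(90.0, 30.0), block_row_stack, v=v)
            for v in (2.5, 1.25, 0.625)
        ]
        assert len({r.object_light_fraction for r in results}) == 1
        assert len({r.terminated_by for r in results}) == 1

    def test_sensor_height_lifts_ray_over_object(self, block_row_stack):
        # from 15 m up, the ray clears the 20 m object (15 + 5.77 > 20)
        res = walk_cell((0, 5), sun(90.0, 30.0), block_row_stack,
                        origin_height_offset=15.0)
        assert res.object_light_fraction == 1.0

    def test_stacked_voxels_select_layer_by_ray_height(self):
        # canopy 20 m (OT 0.4) over an 8 m understory (OT 0.9) at col 6:
        # a low ray (5.77 m at the cell center) crosses the understory,
        # a higher one (10 m) crosses the canopy
        dem = np.zeros((1, 16))
        ndsm = np.zeros((1, 16))
        otm = np.ones((1, 16))
        uh = np.zeros((1, 16))
        uo = np.ones((1, 16))
        ndsm[0, 6], otm[0, 6] = 20.0, 0.4
        uh[0, 6], uo[0, 6] = 8.0, 0.9
        stack = build_landscape_stack(
            dem=grid(dem), ndsm=grid(ndsm), otm=grid(otm),
            understory_height=grid(uh), understory_otm=grid(uo))
        low = walk_cell((0, 5), sun(90.0, 30.0), stack)
        assert low.object_light_fraction == pytest.approx(0.9)
        high = walk_cell((0, 5), sun(90.0, 45.0), stack)
        assert high.object_light_fraction == pytest.approx(0.4)

    def test_nodata_terrain_is_transparent_mid_walk(self):
        dem = np.zeros((1, 16))
        dem[0, 6] = -9999.0
        dem[0, 7] = 30.0
        stack = build_landscape_stack(dem=grid(dem))
        res = walk_cell((0, 5), sun(90.0, 30.0), stack)
        # the nodata cell neither blocks nor terminates; the ridge behind
        # it still intercepts the ray after two walked cells
        assert res.terminated_by == "terrain"
        assert res.cells_walked == 2


class TestSimulateTimestep:
    def test_strip_shadow_geometry(self):
        # 2x8 grid, opaque-ish column at col 2, sun due west at 30 deg:
        # shadow band spans floor(20/tan30/10)=3 cells east of the object
        dem = np.zeros((2, 8))
        ndsm = np.zeros((2, 8))
        otm = np.ones((2, 8))
        ndsm[:, 2] = 20.0
        otm[:, 2] = 0.4
        stack = build_landscape_stack(dem=grid(dem), ndsm=grid(ndsm),
                                      otm=grid(otm))
        res = simulate_timestep(stack, sun(270.0, 30.0))
        for row in range(2):
            np.testing.assert_allclose(
                res.o_ld[row], [1, 1, 1, 0.4, 0.4, 0.4, 1, 1])

    def test_night_grids(self, flat_stack):
        res = simulate_timestep(flat_stack, sun(0.0, -10.0))
        assert res.is_night
        assert np.all(res.o_ld == 1.0)

    def test_all_masked_out_yields_all_nodata(self):
        stack = build_landscape_stack(dem=grid(np.zeros((3, 3))),
                                      mask=grid(np.zeros((3, 3))))
        res = simulate_timestep(stack, sun(90.0, 45.0))
        assert np.all(np.isnan(res.o_ld))

    def test_masked_cells_still_cast_shade(self):
        dem = np.zeros((1, 8))
        ndsm = np.zeros((1, 8))
        otm = np.ones((1, 8))
        ndsm[0, 6] = 20.0
        otm[0, 6] = 0.4
        mask = np.ones((1, 8))
        mask[0, 6] = 0.0  # the object's own cell is outside the AOI
        stack = build_landscape_stack(dem=grid(dem), ndsm=grid(ndsm),
                                      otm=grid(otm), mask=grid(mask))
        res = simulate_timestep(stack, sun(90.0, 30.0))
        assert res.o_ld[0, 5] == pytest.approx(0.4)
        assert np.isnan(res.o_ld[0, 6])

    def test_monotonic_in_transmittance_and_height(self):
        rng = np.random.default_rng(7)
        base_ndsm = np.where(rng.random((10, 10)) < 0.5,
                             rng.uniform(5, 25, (10, 10)), 0.0)
        base_otm = np.where(base_ndsm > 0, rng.uniform(0.2, 0.8, (10, 10)), 1.0)
        dem = np.zeros((10, 10))
        s = sun(240.0, 35.0)

        def o_ld(ndsm, otm):
            stack = build_landscape_stack(dem=grid(dem), ndsm=grid(ndsm),
                                          otm=grid(otm))
            return simulate_timestep(stack, s).o_ld

        ref = o_ld(base_ndsm, base_otm)
        raised_otm = np.minimum(base_otm + 0.1, 1.0)
        assert np.all(o_ld(base_ndsm, raised_otm) >= ref - 1e-12)
        raised_ndsm = base_ndsm + np.where(base_ndsm > 0, 5.0, 0.0)
        assert np.all(o_ld(raised_ndsm, base_otm) <= ref + 1e-12)

    def test_rotational_symmetry_axis_aligned(self):
        rng = np.random.default_rng(11)
        ndsm = np.where(rng.random((12, 12)) < 0.4,
                        rng.uniform(5, 25, (12, 12)), 0.0)
        otm = np.where(ndsm > 0, rng.uniform(0.2, 0.8, (12, 12)), 1.0)
        dem = rng.uniform(0, 5, (12, 12))

        def fields(d, n, o, azimuth):
            stack = build_landscape_stack(dem=grid(d), ndsm=grid(n),
                                          otm=grid(o))
            res = simulate_timestep(stack, sun(azimuth, 35.0))
            return res.o_ld, res.terrain_shade_grid

        # rot90 (counterclockwise in array view) maps east to north
        a_old, t_old = fields(dem, ndsm, otm, 90.0)
        a_rot, t_rot = fields(np.rot90(dem), np.rot90(ndsm), np.rot90(otm),
                              0.0)
        np.testing.assert_allclose(np.rot90(a_old), a_rot, atol=1e-12)
        np.testing.assert_allclose(np.rot90(t_old), t_rot, atol=1e-12)
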