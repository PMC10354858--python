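"""Simulator tests: geometry, plans, dose engine, error injection, noise."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from vmatqa import simulate as sim


class TestDetectorGeometry:
    def test_default_plane_inclinations(self, geometry):
        assert sorted(abs(a) for a in geometry.plane_angles) == [40.0, 50.0]

    def test_central_region_pitch_is_5mm(self, geometry):
        coords = geometry.in_plane[0]
        central = coords[np.max(np.abs(coords), axis=1) <= 30.0]
        # nearest-neighbour spacing inside the central 6x6 cm block
        from scipy.spatial import cKDTree
        d, _ = cKDTree(central).query(central, k=2)
        assert np.allclose(d[:, 1], 5.0)

    def test_peripheral_pitch_is_10mm(self, geometry):
        coords = geometry.in_plane[0]
        outer = coords[np.max(np.abs(coords), axis=1) > 40.0]
        from scipy.spatial import cKDTree
        d, _ = cKDTree(outer).query(outer, k=2)
        assert np.allclose(d[:, 1], 10.0)

    def test_diodes_inside_phantom(self, geometry):
        for k in range(2):
            w = geometry.world[k]
            assert np.all(np.hypot(w[:, 0], w[:, 2])
                          <= geometry.phantom_radius + 1e-9)

    @pytest.mark.parametrize("bad", [
        dict(central_pitch=0.0), dict(outer_pitch=-1.0),
        dict(half_extent=0.0), dict(half_extent=150.0),
        dict(phantom_radius=-5.0),
    ])
    def test_nonphysical_config_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.make_detector_geometry(sim.DetectorConfig(**bad))


class TestSamplePlan:
    def test_same_seed_identical(self):
        p1, p2 = sim.sample_plan(3), sim.sample_plan(3)
        assert p1.prescription_scale == p2.prescription_scale
        for a, b in zip(p1.control_points, p2.control_points):
            assert a.gantry_deg == b.gantry_deg
            assert np.array_equal(a.leaves, b.leaves)

    def test_different_seeds_differ(self):
        p1, p2 = sim.sample_plan(3), sim.sample_plan(4)
        assert any(not np.array_equal(a.leaves, b.leaves)
                   for a, b in zip(p1.control_points, p2.control_points))

    @pytest.mark.parametrize("seed", range(6))
    def test_leaf_order_invariant(self, seed):
        plan = sim.sample_plan(seed)
        for cp in plan.control_points:
            assert np.all(cp.leaves[:, 0] <= cp.leaves[:, 1])
            assert 0.0 <= cp.gantry_deg < 360.0
            assert cp.mu_weight > 0


def _single_cp_plan(a: float, b: float, n_pairs: int = 28,
                    mu: float = 1.0) -> sim.VMATPlan:
    leaves = np.tile([a, b], (n_pairs, 1)).astype(float)
    return sim.VMATPlan([sim.ControlPoint(0.0, mu, leaves)])


class TestComputeDose:
    def test_closed_apertures_leak_only(self, geometry):
        plan = _single_cp_plan(0.0, 0.0)
        grid, _ = sim.compute_dose(plan, geometry)
        engine = sim.DoseEngineParams()
        leak_level = engine.transmission * 1.0  # attenuation only reduces it
        assert grid.values.max() <= leak_level + 1e-12

    def test_linearity_in_mu(self, geometry, small_plan):
        doubled = sim.VMATPlan(
            [sim.ControlPoint(cp.gantry_deg, 2 * cp.mu_weight, cp.leaves)
             for cp in small_plan.control_points],
            small_plan.leaf_pitch, small_plan.prescription_scale)
        g1, _ = sim.compute_dose(small_plan, None)
        g2, _ = sim.compute_dose(doubled, None)
        assert np.allclose(g2.values, 2.0 * g1.values, rtol=0, atol=1e-12)

    def test_open_square_max_on_beam_axis(self):
        # 6x6 cm aperture, single control point at gantry 0: the beam travels
        # along -z, so the maximum must sit within one cell of the beam axis
        # laterally (the dose is flat along y inside the open rows) and the
        # axis column through the isocenter must carry the global maximum.
        plan = _single_cp_plan(-30.0, 30.0)
        grid, _ = sim.compute_dose(plan, None)
        idx = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        ax = grid.axes()
        assert abs(ax[idx[0]]) <= grid.spacing + 1e-9
        assert ax[idx[2]] > 0  # entry side (source at +z)
        i0 = grid.isocenter_index()[0]
        axis_column_max = grid.values[i0, i0, :].max()
        assert axis_column_max >= grid.values.max() * (1 - 1e-9)

    def test_grid_matches_direct_evaluation(self, small_plan):
        # the gridded accumulation and the point-wise evaluator implement the
        # same analytic model; at grid nodes they must agree exactly
        grid, _ = sim.compute_dose(small_plan, None)
        ax = grid.axes()
        nodes = [(3, 40, 50), (44, 44, 44), (20, 60, 30)]
        pts = np.array([[ax[i], ax[j], ax[k]] for i, j, k in nodes])
        direct = sim.dose_at_points(small_plan, pts)
        gridded = np.array([grid.values[i, j, k] for i, j, k in nodes])
        assert np.allclose(direct, gridded, rtol=1e-9)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            sim.compute_dose(sim.VMATPlan([]), None)


class TestInjectError:
    def test_output_plus_scales_by_1p03(self, small_dose, small_plan):
        grid, _ = small_dose
        _, g2 = sim.inject_error(small_plan, grid, sim.ErrorSpec("output_plus"))
        assert np.allclose(g2.values, grid.values * 1.03, rtol=0, atol=1e-12)

    def test_none_is_bitwise_identity(self, small_dose, small_plan):
        grid, _ = small_dose
        _, g2 = sim.inject_error(small_plan, grid, sim.ErrorSpec("none"))
        assert g2 is grid

    def test_unknown_kind_rejected(self, small_dose, small_plan):
        with pytest.raises(ValueError):
            sim.inject_error(small_plan, small_dose[0],
                             sim.ErrorSpec("collimator"))

    def test_mlc_systematic_offsets_all_leaves(self, small_plan):
        plan2 = sim.perturb_plan(small_plan, sim.ErrorSpec("mlc_systematic"))
        for cp, cp2 in zip(small_plan.control_points, plan2.control_points):
            assert np.allclose(cp2.leaves, cp.leaves + 2.0)

    def test_mlc_random_keeps_leaf_order(self, small_plan):
        plan2 = sim.perturb_plan(small_plan, sim.ErrorSpec("mlc_random", seed=9))
        for cp in plan2.control_points:
            assert np.all(cp.leaves[:, 0] <= cp.leaves[:, 1])

    def test_gantry_cw_then_ccw_recovers_field(self, small_plan):
        """Composing the +2 and -2 degree resamples must return to the
        original within twice the single-resample interpolation error,
        measured against the exact rotation of the analytic dose model."""
        grid, _ = sim.compute_dose(small_plan, None)
        spec_cw = sim.ErrorSpec("gantry_cw")
        _, g_cw = sim.inject_error(small_plan, grid, spec_cw)

        # single-resample interpolation error bound over all interior nodes:
        # compare the numeric rotation with the analytic model evaluated at
        # the rotated positions
        ax = grid.axes()
        ii = np.arange(8, len(ax) - 8)
        xg, yg, zg = np.meshgrid(ax[ii], ax[ii], ax[ii], indexing="ij")
        pts = np.column_stack([xg.ravel(), yg.ravel(), zg.ravel()])
        exact = sim.dose_at_points(
            small_plan, sim.error_source_positions(pts, spec_cw))
        sl = np.ix_(ii, ii, ii)
        e_interp = np.abs(g_cw.values[sl].ravel() - exact).max()

        _, g_back = sim.inject_error(small_plan, g_cw,
                                     sim.ErrorSpec("gantry_ccw"))
        delta = np.abs(g_back.values[sl] - grid.values[sl]).max()
        assert delta < 2.0 * e_interp

    def test_setup_shift_moves_field(self, small_dose, small_plan):
        grid, _ = small_dose
        _, g2 = sim.inject_error(small_plan, grid, sim.ErrorSpec("setup_lng"))
        ax = grid.axes()
        # sampling the shifted grid at p equals the original at p + 1 mm
        pts = np.array([[ax[30], ax[40], ax[50]], [ax[50], ax[44], ax[40]]])
        shifted = g2.sample(pts)
        orig = grid.sample(pts + np.array([0.0, 1.0, 0.0]))
        assert np.allclose(shifted, orig, rtol=1e-6, atol=1e-9)


class TestResamplers:
    def test_rotation_matches_scipy_affine(self, smooth_field):
        ax, vals = smooth_field
        deg = 2.0
        mine = sim._rotate_grid_about_y(vals, deg, ax)

        delta = np.radians(deg)
        c, s = np.cos(delta), np.sin(delta)
        # source coords in index space for scipy.ndimage.map_coordinates
        idx = np.arange(31.0)
        x, z = np.meshgrid(idx - 15, idx - 15, indexing="ij")
        xs = (c * x + s * z) + 15
        zs = (-s * x + c * z) + 15
        ref = np.empty_like(vals)
        for j in range(31):
            ref[:, j, :] = ndimage.map_coordinates(
                vals[:, j, :], [xs, zs], order=1, mode="constant")
        interior = (slice(2, -2), slice(None), slice(2, -2))
        assert np.allclose(mine[interior], ref[interior], atol=1e-12)

    def test_shift_matches_scipy(self, smooth_field):
        ax, vals = smooth_field
        shift_mm = (1.0, -1.0, 0.5)
        mine = sim._shift_grid(vals, shift_mm, ax)
        ref = ndimage.shift(vals, [-s / 2.5 for s in shift_mm], order=1,
                            mode="constant", prefilter=False)
        interior = (slice(2, -2),) * 3
        assert np.allclose(mine[interior], ref[interior], atol=1e-12)


class TestSimulateMeasurement:
    def test_zero_noise_is_exact(self, geometry, small_dose):
        _, planar = small_dose
        quiet = sim.NoiseConfig(diode_sd=0, field_sd=0, daily_sd=0,
                                calibration_sd=0)
        out = sim.simulate_measurement(planar, geometry, quiet, seed=1)
        for k in range(2):
            assert np.array_equal(out[k].values, planar[k].values)

    def test_determinism(self, geometry, small_dose):
        _, planar = small_dose
        a = sim.simulate_measurement(planar, geometry, seed=42)
        b = sim.simulate_measurement(planar, geometry, seed=42)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_per_diode_sd_calibration(self, geometry, small_dose):
        """Monte-Carlo: the empirical iid relative noise matches the
        configured per-diode sd within 10% over ~10000 draws."""
        _, planar = small_dose
        cfg = sim.NoiseConfig(diode_sd=0.007, field_sd=0.0, daily_sd=0.0,
                              calibration_sd=0.0)
        rel = []
        for seed in range(20):
            out = sim.simulate_measurement(planar, geometry, cfg, seed=seed)
            for k in range(2):
                keep = planar[k].values > 0.1 * planar[k].values.max()
                rel.append(out[k].values[keep] / planar[k].values[keep] - 1.0)
        rel = np.concatenate(rel)
        assert len(rel) > 10000
        assert abs(rel.std() - 0.007) < 0.1 * 0.007

    def test_negative_sd_rejected(self, geometry, small_dose):
        _, planar = small_dose
        with pytest.raises(ValueError):
            sim.simulate_measurement(planar, geometry,
                                     sim.NoiseConfig(diode_sd=-0.1), seed=0)


class TestGenerateDataset:
    def test_split_exceeding_beams_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_dataset(n_beams=3, split=(2, 1, 1), seed=0)

    def test_counting_split_1_1_1(self):
        ds = sim.generate_dataset(n_beams=3, split=(1, 1, 1), seed=0)
        assert len(ds.by_split("train")) == 1
        assert len(ds.by_split("validation")) == 1
        test = ds.by_split("test")
        assert len(test) == 1 and len(test[0].calc) == 10

    def test_test_beam_conditions_and_planes(self, small_dataset):
        for beam in small_dataset.by_split("test"):
            assert set(beam.calc) == set(sim.ERROR_KINDS)
            for vals in beam.calc.values():
                assert len(vals) == 2
            assert set(beam.plane_fields) == set(sim.ERROR_KINDS)

    def test_bit_identical_regeneration(self, small_dataset):
        ds2 = sim.generate_dataset(n_beams=8, split=(4, 2, 2), seed=11)
        for b1, b2 in zip(small_dataset.beams, ds2.beams):
            assert np.array_equal(b1.measured[0], b2.measured[0])
            for cond in b1.calc:
                assert np.array_equal(b1.calc[cond][0], b2.calc[cond][0])
                assert np.array_equal(b1.calc[cond][1], b2.calc[cond][1])

    def test_manifest_records_provenance(self, small_dataset):
        m = small_dataset.manifest()
        assert m["seed"] == 11 and m["n_beams"] == 8
        assert all("plan_seed" in b for b in m["beams"])
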