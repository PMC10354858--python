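"""DD-map construction, clipping, interpolation and dataset assembly."""

import numpy as np
import pytest

from vmatqa import ddmap, simulate as sim


class TestNormalize:
    def test_basic_division(self):
        out = ddmap.normalize_by_isocenter(np.array([1.0, 2.0]), 2.0)
        assert np.array_equal(out, [0.5, 1.0])

    def test_zero_isocenter_rejected(self):
        with pytest.raises(ValueError):
            ddmap.normalize_by_isocenter(np.array([1.0]), 0.0)

    def test_scale_invariance(self):
        vals = np.array([0.3, 1.1, 2.0])
        a = ddmap.normalize_by_isocenter(vals, 1.7)
        b = ddmap.normalize_by_isocenter(vals * 3.5, 1.7 * 3.5)
        assert np.allclose(a, b)


class TestBuildDDMap:
    def test_equal_inputs_give_zero_map(self, geometry):
        vals = np.linspace(0.2, 1.0, len(geometry.in_plane[0]))
        m = ddmap.build_dd_map(vals, vals, geometry, 0)
        assert np.array_equal(m.values, np.zeros((27, 27)))

    def test_clipping_to_limits(self, geometry):
        calc = np.full(len(geometry.in_plane[0]), 0.5)
        m = ddmap.build_dd_map(calc + 0.35, calc, geometry, 0)
        assert np.all(m.values == 0.2)
        m2 = ddmap.build_dd_map(calc - 0.35, calc, geometry, 0)
        assert np.all(m2.values == -0.2)

    def test_midway_node_linear_interpolation(self, geometry):
        # lattice node (35, 0) sits midway between peripheral diodes (30, 0)
        # and (40, 0); differences 0.0 and 0.10 must interpolate to 0.05
        coords = geometry.in_plane[0]
        calc = np.full(len(coords), 0.5)
        meas = calc.copy()
        target = (np.abs(coords[:, 0] - 40.0) < 1e-9) & (np.abs(coords[:, 1]) < 1e-9)
        assert target.sum() == 1
        meas[target] += 0.10
        m = ddmap.build_dd_map(meas, calc, geometry, 0)
        axis = ddmap.lattice_axis()
        i = int(np.flatnonzero(np.isclose(axis, 35.0))[0])
        j = int(np.flatnonzero(np.isclose(axis, 0.0))[0])
        assert m.values[i, j] == pytest.approx(0.05, abs=1e-12)

    def test_no_smoothing_at_diode_nodes(self, geometry):
        rng = np.random.default_rng(4)
        coords = geometry.in_plane[0]
        calc = np.full(len(coords), 1.0)
        meas = calc + rng.uniform(-0.1, 0.1, size=len(coords))
        m = ddmap.build_dd_map(meas, calc, geometry, 0)
        axis = ddmap.lattice_axis()
        diff = meas - calc
        for i, p in enumerate(axis):
            for j, y in enumerate(axis):
                hit = np.flatnonzero((np.abs(coords[:, 0] - p) < 1e-9)
                                     & (np.abs(coords[:, 1] - y) < 1e-9))
                if len(hit):
                    assert m.values[i, j] == pytest.approx(diff[hit[0]],
                                                           abs=1e-12)

    def test_clipping_idempotent(self, geometry):
        rng = np.random.default_rng(0)
        calc = np.full(len(geometry.in_plane[0]), 0.5)
        meas = calc + rng.uniform(-0.5, 0.5, size=len(calc))
        m = ddmap.build_dd_map(meas, calc, geometry, 0)
        assert np.array_equal(np.clip(m.values, -0.2, 0.2), m.values)

    def test_shape_mismatch_rejected(self, geometry):
        with pytest.raises(ValueError):
            ddmap.build_dd_map(np.zeros(10), np.zeros(11), geometry, 0)


class TestAugmentFlips:
    def _map(self, values):
        return ddmap.DDMap(values, plane_id=1)

    def test_exactly_four_maps(self):
        rng = np.random.default_rng(1)
        out = ddmap.augment_flips(self._map(rng.uniform(-0.2, 0.2, (27, 27))))
        assert len(out) == 4
        assert len({m.values.tobytes() for m in out}) == 4

    def test_symmetric_map_gives_identical_maps(self):
        x = np.add.outer(np.abs(np.arange(27) - 13),
                         np.abs(np.arange(27) - 13)) / 200.0
        out = ddmap.augment_flips(self._map(x))
        for m in out[1:]:
            assert np.array_equal(m.values, out[0].values)

    def test_flip_is_involution(self):
        rng = np.random.default_rng(2)
        m = self._map(rng.uniform(-0.2, 0.2, (27, 27)))
        once = ddmap.augment_flips(m)[1]
        twice = ddmap.augment_flips(once)[1]
        assert np.array_equal(twice.values, m.values)


class TestAssembly:
    def test_counts_small_split(self, small_dataset):
        train, val, cases = ddmap.assemble_vae_datasets(small_dataset)
        assert train.shape == (4 * 2 * 4, 27, 27)   # 4 beams x 2 planes x 4 flips
        assert val.shape == (2 * 2, 27, 27)
        assert len(cases) == 2 * 10
        for c in cases:
            assert {m.plane_id for m in c.maps} == {1, 2}

    def test_missing_condition_raises(self, small_dataset):
        with pytest.raises(KeyError):
            ddmap.beam_case_maps(small_dataset, splits=("test",),
                                 conditions=("leaf_drop",))

    def test_error_free_maps_nearly_plain(self, small_dataset):
        _, _, cases = ddmap.assemble_vae_datasets(small_dataset)
        free = [m.values for c in cases if c.error == "none" for m in c.maps]
        assert np.mean(np.abs(np.stack(free))) < 0.01

    def test_output_error_sign_noise_free(self, geometry):
        """With noise-free measurement, an output+ error inflates the
        calculated dose, so the in-field mean of measured - calculated is
        negative (and positive for output-)."""
        plan = sim.sample_plan(2)
        _, planar = sim.compute_dose(plan, geometry)
        iso = ddmap.measured_isocenter_dose(planar[0].values, geometry)
        m_norm = ddmap.normalize_by_isocenter(planar[0].values, iso)
        for kind, sign in (("output_plus", -1), ("output_minus", 1)):
            f = 1.03 if kind == "output_plus" else 0.97
            c_norm = ddmap.normalize_by_isocenter(planar[0].values * f, iso)
            m = ddmap.build_dd_map(m_norm, c_norm, geometry, 0)
            interior = m.values[9:18, 9:18]
            assert np.sign(interior.mean()) == sign

    def test_output_error_monotone_amplitude(self, geometry):
        """Mean |DD| grows with the output-error magnitude (1, 3, 5 %)."""
        plan = sim.sample_plan(7)
        _, planar = sim.compute_dose(plan, geometry)
        measured = sim.simulate_measurement(planar, geometry, seed=3)
        iso = ddmap.measured_isocenter_dose(measured[0].values, geometry)
        m_norm = ddmap.normalize_by_isocenter(measured[0].values, iso)
        amps = []
        for mag in (0.01, 0.03, 0.05):
            c = ddmap.normalize_by_isocenter(planar[0].values * (1 + mag), iso)
            amps.append(np.abs(ddmap.build_dd_map(m_norm, c, geometry, 0).values).mean())
        assert amps[0] <= amps[1] <= amps[2]

    def test_identity_chain(self, geometry):
        """inject_error(none) + noise-free measurement reproduces the
        calculated planar dose exactly: the DD map is identically zero."""
        plan = sim.sample_plan(9)
        grid, planar = sim.compute_dose(plan, geometry)
        _, grid2 = sim.inject_error(plan, grid, sim.ErrorSpec("none"))
        quiet = sim.NoiseConfig(diode_sd=0, field_sd=0, daily_sd=0,
                                calibration_sd=0)
        measured = sim.simulate_measurement(planar, geometry, quiet, seed=0)
        iso = ddmap.measured_isocenter_dose(measured[0].values, geometry)
        m = ddmap.build_dd_map(
            ddmap.normalize_by_isocenter(measured[0].values, iso),
            ddmap.normalize_by_isocenter(grid2.sample(geometry.world[0]), iso),
            geometry, 0)
        assert np.array_equal(m.values, np.zeros((27, 27)))
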