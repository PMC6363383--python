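"""Compartment model: discretization, parameter assignment, integration."""

import numpy as np
import pytest

from dendrogain import biophysics as bp
from dendrogain import morphology as mo
from dendrogain.morphology import Region

from conftest import passive_config, single_soma


def soma_plus_cable(cable_um: float = 100.0) -> mo.Morphology:
    return mo.Morphology(
        region=np.array([int(Region.SOMA), int(Region.APICAL_DENDRITE)]),
        xyz=np.array([[0.0, 0.0, 0.0], [0.0, cable_um, 0.0]]),
        radius=np.array([10.0, 1.0]),
        parent=np.array([-1, 0]),
    )


# ---------------------------------------------------------------------------
# Discretization and assignment


class TestDiscretize:
    def test_ceiling_division_of_dendrite(self):
        cm = bp.discretize(soma_plus_cable(100.0), max_segment_length=20.0)
        dend = cm.region == int(Region.APICAL_DENDRITE)
        assert int(dend.sum()) == 5
        assert np.allclose(cm.length[dend], 20.0)

    def test_ais_always_25_compartments_of_2_um(self):
        m = mo.attach_axon(soma_plus_cable())
        cm = bp.discretize(m, max_segment_length=100.0)
        ais = cm.region == int(Region.AXON_AIS)
        assert int(ais.sum()) == 25
        assert np.allclose(cm.length[ais], 2.0)
        myelin = cm.region == int(Region.AXON_MYELIN)
        assert int(myelin.sum()) == 21
        assert cm.length[myelin].sum() == pytest.approx(1000.0)

    def test_zero_length_edge_rejected(self):
        m = mo.Morphology(
            region=np.array([1, 3]),
            xyz=np.zeros((2, 3)),
            radius=np.array([10.0, 1.0]),
            parent=np.array([-1, 0]),
        )
        with pytest.raises(bp.DegenerateGeometryError):
            bp.discretize(m)

    def test_parent_before_child_ordering(self, small_tree_model):
        assert np.all(small_tree_model.parent < np.arange(small_tree_model.n))

    def test_halving_segment_length_moves_ap_peak_under_one_percent(self):
        """Spatial-discretization convergence on the AP peak time."""
        morph = mo.attach_axon(
            mo.generate_branched_tree(
                mo.SyntheticTreeSpec(target_tdl=2000.0, target_branch_points=9, seed=3)
            )
        )
        peaks = []
        for seg in (100.0, 50.0):
            model = bp.assign_biophysics(bp.discretize(morph, seg))
            _, st = bp.equilibrate(model, duration=0.5)
            n = int(0.1 / 1e-5)
            tr = bp.simulate(model, current=np.full(n, 400.0), dt=1e-5, state=st)
            assert tr.voltage.max() > 0
            peaks.append(np.argmax(tr.voltage) * tr.dt)
        assert abs(peaks[0] - peaks[1]) / peaks[1] < 0.01


class TestAssign:
    def test_myelin_effective_parameters(self):
        m = mo.attach_axon(soma_plus_cable())
        model = bp.assign_biophysics(bp.discretize(m))
        my = model.region == int(Region.AXON_MYELIN)
        assert np.allclose(model.cm_eff[my], 0.75 / 37.5)  # 0.02 µF/cm²
        assert np.allclose(model.rm_eff[my], 30.3 * 5)  # 151.5 kΩ·cm²
        assert np.allclose(model.gna_density[my], 0.0)
        assert np.allclose(model.gk_density[my], 0.0)

    def test_ais_sodium_density(self):
        m = mo.attach_axon(soma_plus_cable())
        model = bp.assign_biophysics(bp.discretize(m))
        ais = model.region == int(Region.AXON_AIS)
        assert np.allclose(model.gna_density[ais], 8000.0)
        assert np.allclose(model.gk_density[ais], 1500.0)

    def test_spine_factor_on_dendrites(self):
        model = bp.assign_biophysics(bp.discretize(soma_plus_cable()))
        dend = model.region == int(Region.APICAL_DENDRITE)
        assert np.allclose(model.cm_eff[dend] / 0.75, 1.84)
        assert np.allclose(model.rm_eff[dend], 30.3 / 1.84)
        soma = model.region == int(Region.SOMA)
        assert np.allclose(model.cm_eff[soma], 0.75)

    def test_missing_region_density_is_config_error(self):
        cfg_dict = {r: 0.0 for r in Region if r != Region.APICAL_DENDRITE}
        cfg = bp.BiophysicsConfig(gna=cfg_dict, gk=cfg_dict)
        with pytest.raises(bp.ConfigError):
            bp.assign_biophysics(bp.discretize(soma_plus_cable()), cfg)

    def test_invalid_config_values_rejected(self):
        with pytest.raises(bp.ConfigError):
            bp.BiophysicsConfig(cm=-1.0)
        with pytest.raises(bp.ConfigError):
            bp.BiophysicsConfig(spine_factor=0.5)


# ---------------------------------------------------------------------------
# Integration correctness


class TestSolver:
    def test_single_backward_euler_step_matches_dense_solve(self):
        """Independent oracle: assemble the implicit system densely."""
        model = bp.assign_biophysics(bp.discretize(soma_plus_cable(), 25.0),
                                     passive_config())
        dt = 2.5e-5
        dt_ms = dt * 1e3
        cdt, gl, _, _, gax, gdiag_pass = bp._solver_arrays(model, dt_ms)
        n = model.n
        v0 = np.full(n, -60.0)
        A = np.diag(cdt + gdiag_pass)
        for i in range(1, n):
            A[i, model.parent[i]] -= gax[i]
            A[model.parent[i], i] -= gax[i]
        b = cdt * v0 + gl * model.config.e_leak
        expected = np.linalg.solve(A, b)
        trace = bp.simulate(model, dt=dt, duration=2 * dt, v_init=-60.0)
        assert trace.voltage[0] == pytest.approx(expected[0], abs=1e-9)

    def test_passive_membrane_time_constant(self):
        """Closed-form RC oracle: tau = Rm*Cm = 22.7 ms."""
        model = bp.assign_biophysics(bp.discretize(single_soma()), passive_config())
        _, st = bp.equilibrate(model, duration=0.5)
        tau = 30.3 * 0.75  # ms
        dt = 1e-5
        n = int(0.15 / dt)
        trace = bp.simulate(model, current=np.full(n, -20.0), dt=dt, state=st)
        v0 = trace.voltage[0]
        v_inf = trace.voltage[-1]
        v_at_tau = trace.voltage[int(tau * 1e-3 / dt)]
        frac = (v_at_tau - v0) / (v_inf - v0)
        assert frac == pytest.approx(1 - np.exp(-1), rel=0.01)

    def test_leak_only_converges_to_leak_reversal(self):
        model = bp.assign_biophysics(bp.discretize(soma_plus_cable()), passive_config())
        trace = bp.simulate(model, dt=2.5e-5, duration=0.5, v_init=-55.0)
        assert trace.voltage[-1] == pytest.approx(-70.0, abs=1e-3)

    def test_suprathreshold_step_fires_narrow_positive_spike(self, small_tree_model):
        _, st = bp.equilibrate(small_tree_model)
        dt = 1e-5
        n = int(0.2 / dt)
        tr = bp.simulate(small_tree_model, current=np.full(n, 400.0), dt=dt, state=st)
        spikes = bp.detect_spikes(tr)
        assert spikes.n >= 1
        assert tr.voltage.max() > 0.0
        above = tr.voltage > 0.0
        first_up = np.argmax(above)
        width = np.argmin(above[first_up:]) * dt
        assert width < 5e-3

    def test_gating_variables_stay_in_unit_interval(self, small_tree_model):
        _, st = bp.equilibrate(small_tree_model, duration=0.3)
        n = int(0.1 / 2.5e-5)
        _, st2 = bp.simulate(small_tree_model, current=np.full(n, 600.0),
                             dt=2.5e-5, state=st, return_state=True)
        for g in (st2.m, st2.h, st2.n):
            assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_instability_raises_naming_step(self):
        model = bp.assign_biophysics(bp.discretize(single_soma()), passive_config())
        n = int(0.1 / 2.5e-5)
        with pytest.raises(bp.IntegrationError, match="step"):
            bp.simulate(model, current=np.full(n, 5e6), dt=2.5e-5)

    def test_dt_bound_and_length_mismatch(self, small_tree_model):
        with pytest.raises(ValueError):
            bp.simulate(small_tree_model, dt=1e-4, duration=0.01)
        with pytest.raises(ValueError):
            bp.simulate(small_tree_model, current=np.zeros(10), dt=1e-5, duration=1.0)


class TestRestingPotential:
    def test_channel_free_model_rests_at_leak(self):
        model = bp.assign_biophysics(bp.discretize(soma_plus_cable()), passive_config())
        assert bp.measure_resting_potential(model, duration=1.0) == pytest.approx(
            -70.0, abs=1e-3
        )

    def test_rest_independent_of_initial_condition(self, small_tree_model):
        values = [
            bp.equilibrate(small_tree_model, duration=1.0, v_init=v)[0]
            for v in (-80.0, -60.0)
        ]
        assert values[0] == pytest.approx(values[1], abs=0.05)


class TestInputResistance:
    def test_isolated_soma_closed_form(self):
        """Rm / area oracle for a 20 µm x 20 µm cylinder: ~2.41 GΩ."""
        model = bp.assign_biophysics(bp.discretize(single_soma()), passive_config())
        expected = 30.3e3 / (np.pi * 20e-4 * 20e-4) / 1e6  # MΩ
        assert bp.measure_input_resistance(model) == pytest.approx(expected, rel=0.01)

    def test_adding_dendrite_decreases_input_resistance(self):
        soma_only = bp.assign_biophysics(bp.discretize(single_soma()), passive_config())
        with_dend = bp.assign_biophysics(
            bp.discretize(soma_plus_cable(500.0)), passive_config()
        )
        assert bp.measure_input_resistance(with_dend) < bp.measure_input_resistance(
            soma_only
        )

    def test_ohmic_scaling_in_rm(self):
        zero = {r: 0.0 for r in Region}
        r1 = bp.measure_input_resistance(
            bp.assign_biophysics(bp.discretize(single_soma()),
                                 bp.BiophysicsConfig(gna=zero, gk=zero))
        )
        r2 = bp.measure_input_resistance(
            bp.assign_biophysics(bp.discretize(single_soma()),
                                 bp.BiophysicsConfig(rm=60.6, gna=zero, gk=zero))
        )
        assert r2 / r1 == pytest.approx(2.0, rel=0.01)


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        tr = bp.VoltageTrace(dt=1e-4, voltage=np.full(1000, -70.0))
        assert bp.detect_spikes(tr).n == 0

    def test_three_spaced_crossings(self):
        t = np.arange(0, 0.1, 1e-4)
        v = np.full_like(t, -70.0)
        for tc in (0.02, 0.05, 0.08):
            mask = (t >= tc) & (t < tc + 1e-3)
            v[mask] = 20.0
        assert bp.detect_spikes(bp.VoltageTrace(dt=1e-4, voltage=v)).n == 3

    def test_refractory_merges_fast_double_crossings(self):
        t = np.arange(0, 0.02, 1e-4)
        v = np.full_like(t, -70.0)
        v[50:52] = 10.0
        v[55:57] = 10.0  # 0.5 ms later: inside the 2 ms refractory window
        assert bp.detect_spikes(bp.VoltageTrace(dt=1e-4, voltage=v)).n == 1

    @pytest.mark.parametrize("phase", [0.0, 0.3, 0.7])
    def test_subsample_interpolation_accuracy(self, phase):
        """Detected time tracks the analytic crossing to sub-sample error."""
        dt = 1e-4
        f = 20.0
        t = np.arange(0, 0.1, dt) + phase * dt
        v = 50.0 * np.sin(2 * np.pi * f * t)
        spikes = bp.detect_spikes(bp.VoltageTrace(dt=dt, voltage=v))
        # analytic upward zero crossings of sin at t = k/f, shifted to grid origin
        expected = np.array([k / f - phase * dt for k in range(1, 3)])
        expected = expected[(expected > 0) & (expected < 0.1 - dt)]
        k = min(len(expected), spikes.n)
        assert k >= 1
        assert np.all(np.abs(spikes.times[:k] - expected[:k]) < dt)

    def test_strictly_increasing_invariant(self):
        with pytest.raises(ValueError):
            bp.SpikeTrain(times=np.array([0.1, 0.1]))
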