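"""Backward-Euler reaction-diffusion solver: analytic oracles and invariants."""

import numpy as np
import pytest

from calspine import (CalciumState, ConfigurationError, ModelParameters,
                      SolverConfig, StimulationProtocol, bare_cable,
                      default_parameters, simulate, single_spike, step,
                      synaptic_calcium_flux, synaptic_current,
                      two_spine_arrangement)
from calspine.calcium_solver import (build_system_matrix,
                                     current_to_concentration_rate)

EMPTY = StimulationProtocol(spikes={})


class TestSynapticCurrent:
    def test_no_spikes_no_current(self):
        assert synaptic_current(0.123, [], 0.1, 1e-3) == 0.0

    def test_amplitude_at_spike(self):
        assert synaptic_current(0.5, [0.5], 0.1, 1e-3) == pytest.approx(0.1)

    def test_exponential_decay(self):
        assert synaptic_current(0.5 + 1e-3, [0.5], 0.1, 1e-3) == pytest.approx(
            0.1 * np.exp(-1), rel=1e-12)

    def test_causality(self):
        assert synaptic_current(0.499, [0.5], 0.1, 1e-3) == 0.0

    def test_superposition(self):
        t, spikes = 0.02, [0.0, 0.01]
        expected = 0.1 * (np.exp(-20) + np.exp(-10))
        assert synaptic_current(t, spikes, 0.1, 1e-3) == pytest.approx(expected)


class TestCalciumFlux:
    def test_zero_current_zero_flux(self, params):
        assert synaptic_calcium_flux(0.0, params) == 0.0

    def test_unit_conversion_against_si_arithmetic(self, params):
        # 0.11 * 0.1e-12 A / (2 * 96485 C/mol * 0.16464e-15 L) in M/s -> uM/s
        V_s_l = (4 / 3) * np.pi * 0.34 ** 3 * 1e-15
        expected = 0.11 * 0.1e-12 / (2 * 96485.0 * V_s_l) * 1e6
        assert synaptic_calcium_flux(0.1, params) == pytest.approx(expected, rel=1e-12)
        assert synaptic_calcium_flux(0.1, params) == pytest.approx(346.24, abs=0.01)

    def test_linearity(self, params):
        assert synaptic_calcium_flux(0.2, params) == pytest.approx(
            2 * synaptic_calcium_flux(0.1, params), rel=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(Exception):
            current_to_concentration_rate(0.1, 0.0, 2, 96485.0)


class TestStep:
    def test_zero_state_is_fixed_point(self, params, two_spines):
        state = CalciumState.zeros(two_spines)
        out = step(state, np.zeros(2), two_spines, params)
        assert np.all(out.C_d == 0) and np.all(out.C_s == 0)

    def test_uniform_decay_closed_form(self, params):
        # uniform field, no spines: one implicit step divides by (1 + dt/tau)
        arr = bare_cable(10.0)
        cfg = SolverConfig(dt=1e-4)
        state = CalciumState(C_d=np.full(arr.geometry.n_segments, 2.0),
                             C_s=np.zeros(0))
        out = step(state, np.zeros(0), arr, params, cfg)
        expected = 2.0 / (1 + cfg.dt / params.tau_decay)
        np.testing.assert_allclose(out.C_d, expected, rtol=1e-12)

    def test_dt_exceeding_transient_resolution_rejected(self, params, two_spines):
        with pytest.raises(ConfigurationError):
            step(CalciumState.zeros(two_spines), np.zeros(2), two_spines,
                 params, SolverConfig(dt=1e-3))


class TestDiffusionOracles:
    def make_impulse(self, length=80.0, dx=0.5):
        arr = bare_cable(length, dx)
        c0 = np.zeros(arr.geometry.n_segments)
        c0[arr.geometry.n_segments // 2] = 1.0 / dx  # unit mass in uM*um
        return arr, CalciumState(C_d=c0, C_s=np.zeros(0))

    def gaussian(self, arr, t, D):
        x = arr.geometry.centers
        x0 = x[arr.geometry.n_segments // 2]
        return np.exp(-(x - x0) ** 2 / (4 * D * t)) / np.sqrt(4 * np.pi * D * t)

    def test_impulse_matches_greens_function(self):
        p = ModelParameters(tau_decay=1e12)
        arr, state = self.make_impulse()
        cfg = SolverConfig(dt=1e-5, store_every=10 ** 9)
        res = simulate(EMPTY, arr, p, T=0.02, cfg=cfg, initial_state=state)
        ref = self.gaussian(arr, 0.02, p.D)
        assert np.abs(res.C_d[-1] - ref).max() < 0.02 * ref.max()

    def test_impulse_with_decay_matches_damped_gaussian(self):
        p = ModelParameters(tau_decay=0.08)
        arr, state = self.make_impulse()
        cfg = SolverConfig(dt=1e-5, store_every=10 ** 9)
        res = simulate(EMPTY, arr, p, T=0.02, cfg=cfg, initial_state=state)
        ref = self.gaussian(arr, 0.02, p.D) * np.exp(-0.02 / p.tau_decay)
        assert np.abs(res.C_d[-1] - ref).max() < 0.02 * ref.max()

    def test_mass_conserved_without_decay(self):
        p = ModelParameters(tau_decay=1e300)
        arr, state = self.make_impulse(length=40.0)
        cfg = SolverConfig(dt=1e-5, store_every=10 ** 9)
        res = simulate(EMPTY, arr, p, T=0.01, cfg=cfg, initial_state=state)
        total0 = state.C_d.sum() * arr.geometry.dx
        total1 = res.C_d[-1].sum() * arr.geometry.dx
        assert abs(total1 - total0) < 1e-10


class TestCoupledDynamics:
    def test_single_spike_peaks_at_stimulated_spine_first(self, params, two_spines,
                                                          fast_cfg):
        res = simulate(single_spike(0, repetitions=1), two_spines, params,
                       T=0.2, cfg=fast_cfg, plasticity_on=False)
        t_peak = res.times[np.argmax(res.C_s, axis=0)]
        assert res.C_s[:, 0].max() > res.C_s[:, 1].max()
        assert t_peak[0] < t_peak[1]

    def test_nonnegativity_under_stimulation(self, params, two_spines, fast_cfg):
        res = simulate(single_spike(0), two_spines, params, T=4.2, cfg=fast_cfg,
                       plasticity_on=False)
        assert res.C_d.min() >= 0 and res.C_s.min() >= 0

    def test_mirror_symmetry(self, params, fast_cfg):
        arr = two_spine_arrangement()
        proto = single_spike(0, repetitions=1)
        res = simulate(proto, arr, params, T=0.3, cfg=fast_cfg)
        arr_m = arr.mirrored()
        # the mirrored arrangement reverses spine order along the cable
        res_m = simulate(proto, arr_m, params, T=0.3, cfg=fast_cfg)
        np.testing.assert_allclose(res_m.C_d, res.C_d[:, ::-1], atol=1e-10)
        np.testing.assert_allclose(res_m.C_s, res.C_s, atol=1e-10)
        np.testing.assert_allclose(res_m.final_weights, res.final_weights,
                                   atol=1e-10)

    def test_isolated_spine_matches_closed_form_when_diffusion_off(self):
        # D=0 decouples the spine: dC/dt = J0 exp(-t/tau_d) - C/tau_decay
        p = default_parameters("fig2").replace(D=0.0)
        arr = two_spine_arrangement()
        cfg = SolverConfig(dt=5e-6, store_every=10 ** 9)
        res = simulate(single_spike(0, repetitions=1), arr, p, T=0.05,
                       cfg=cfg, plasticity_on=False)
        J0 = synaptic_calcium_flux(p.I0, p)
        a, b = 1.0 / p.tau_decay, 1.0 / p.tau_d
        t = 0.05 - 0.01  # spike occurs at the 10 ms lead-in
        expected = J0 * (np.exp(-a * t) - np.exp(-b * t)) / (b - a)
        assert res.C_s[-1, 0] == pytest.approx(expected, rel=0.01)
        assert res.C_s[-1, 1] == 0.0

    def test_halving_dt_converges(self, params, two_spines):
        # calcium converges at first order; weights inherit extra
        # sensitivity from threshold-crossing times, so their bound is looser
        finals, peaks = [], []
        for dt in (1e-4, 5e-5):
            res = simulate(single_spike(0), two_spines, params, T=4.2,
                           cfg=SolverConfig(dt=dt, store_every=10 ** 9))
            finals.append(res.final_weights)
            res_c = simulate(single_spike(0, repetitions=1), two_spines,
                             params, T=0.2,
                             cfg=SolverConfig(dt=dt, store_every=int(2e-3 / dt)),
                             plasticity_on=False)
            peaks.append(res_c.C_s.max(axis=0))
        assert np.abs(peaks[0] - peaks[1]).max() < 0.02 * peaks[0].max()
        assert np.abs(finals[0] - finals[1]).max() < 1e-2

    def test_volume_corrected_mode_conserves_moles(self):
        # with no decay, total moles (V-weighted concentration) stay constant
        p = ModelParameters(tau_decay=1e300)
        arr = two_spine_arrangement()
        cfg = SolverConfig(dt=1e-4, store_every=10 ** 9,
                           flux_mode="volume-corrected")
        c0 = np.zeros(arr.geometry.n_segments)
        c0[20] = 1.0
        state = CalciumState(C_d=c0, C_s=np.zeros(2))
        res = simulate(EMPTY, arr, p, T=0.05, cfg=cfg, initial_state=state)
        from calspine import compartment_volumes
        V_d, V_s = compartment_volumes(p, arr.geometry.dx)
        total = lambda cd, cs: (cd * V_d).sum() + (cs * V_s).sum()
        assert total(res.C_d[-1], res.C_s[-1]) == pytest.approx(
            total(c0, np.zeros(2)), rel=1e-9)

    def test_column_balance_of_system_matrix(self, params, two_spines):
        # exchange fluxes move "concentration" without loss in plain mode
        A = build_system_matrix(two_spines, params, "plain")
        n = two_spines.geometry.n_segments
        cols = A.sum(axis=0)
        np.testing.assert_allclose(cols, -1.0 / params.tau_decay, rtol=1e-9)

    def test_protocol_outside_duration_rejected(self, params, two_spines):
        with pytest.raises(Exception):
            simulate(single_spike(0), two_spines, params, T=0.5)

    def test_empty_protocol_keeps_weights(self, params, two_spines, fast_cfg):
        res = simulate(EMPTY, two_spines, params, T=0.1, cfg=fast_cfg)
        np.testing.assert_array_equal(res.delta_w, 0.0)


class TestResultExport:
    def test_dataframe_long_format(self, params, two_spines, fast_cfg):
        res = simulate(single_spike(0, repetitions=1), two_spines, params,
                       T=0.05, cfg=fast_cfg)
        df = res.to_dataframe()
        assert set(df.columns) == {"time_s", "compartment", "variable", "value"}
        assert set(df["variable"]) == {"C_d", "C_s", "w"}

    def test_summary_roundtrips_deterministically(self, params, two_spines,
                                                  fast_cfg):
        import json

        runs = [simulate(single_spike(0, repetitions=1), two_spines, params,
                         T=0.05, cfg=fast_cfg).summary() for _ in range(2)]
        assert json.dumps(runs[0], sort_keys=True) == json.dumps(
            runs[1], sort_keys=True)

    def test_hdf5_roundtrip(self, params, two_spines, fast_cfg, tmp_path):
        h5py = pytest.importorskip("h5py")
        res = simulate(single_spike(0, repetitions=1), two_spines, params,
                       T=0.05, cfg=fast_cfg)
        path = tmp_path / "run.h5"
        res.to_hdf5(path)
        with h5py.File(path) as f:
            np.testing.assert_allclose(f["C_s"][...], res.C_s)
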