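"""Network loop: spike detection, recalibration, adaptivity, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from hhetd import (InstabilityError, NetworkConfig, NetworkSimulation,
                   SynapticState, decay_step, detect_spike,
                   etd2_step as etd2, rk2_step as rk2,
                   hh_default, simulate, table1_config)
from hhetd.model import NeuronState
from hhetd.network import build_weights


class TestDetectSpike:
    def test_midpoint_crossing(self):
        assert detect_spike(-51.0, -49.0, 10.0, 0.1, -50.0) == pytest.approx(10.05)

    def test_no_upward_crossing(self):
        assert detect_spike(-49.0, -48.0, 0.0, 0.1, -50.0) is None   # already above
        assert detect_spike(-49.0, -51.0, 0.0, 0.1, -50.0) is None   # downward

    def test_tiny_bracket(self):
        tau = detect_spike(-50.0001, -49.9999, 3.0, 0.277, -50.0)
        assert tau == pytest.approx(3.0 + 0.1385, rel=1e-9)

    def test_ineligible_neuron_is_skipped(self):
        assert detect_spike(-51.0, -49.0, 0.0, 0.1, -50.0, eligible=False) is None

    def test_threshold_at_endpoint_counts(self):
        assert detect_spike(-51.0, -50.0, 0.0, 0.1, -50.0) == pytest.approx(0.1)


def quiet_config(**kw):
    base = dict(n=4, n_exc=3, n_inh=1, S=0.0, f=0.0, nu_hz=0.0,
                dt=0.05, T=5.0, method="rk2", seed=0)
    base.update(kw)
    return NetworkConfig(**base)


class TestQuiescence:
    def test_no_input_no_spikes(self):
        res = simulate(quiet_config())
        assert res.n_spikes == 0

    def test_rest_state_is_stationary(self):
        from hhetd import resting_state
        rest = resting_state(hh_default())
        res = simulate(quiet_config(v0=rest.V, T=10.0))
        assert np.all(np.abs(res.V - rest.V) < 1e-6)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = table1_config(n=20, n_exc=16, n_inh=4, T=200.0, dt=0.05,
                            method="aetd2", seed=3)
        a, b = simulate(cfg), simulate(cfg)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.V, b.V)

    def test_different_seed_differs(self):
        cfg = table1_config(n=20, n_exc=16, n_inh=4, T=200.0, dt=0.05, seed=3)
        a = simulate(cfg)
        b = simulate(replace(cfg, seed=4))
        assert not np.array_equal(a.spike_times, b.spike_times)

    def test_stepwise_equals_single_run(self):
        cfg = table1_config(n=10, n_exc=8, n_inh=2, T=50.0, dt=0.05, seed=5)
        whole = simulate(cfg)
        sim = NetworkSimulation(cfg)
        for _ in range(cfg.n_steps // 100):
            sim.step(100)
        assert np.array_equal(np.asarray(sim.spike_times), whole.spike_times)
        assert np.array_equal(sim.V, whole.V)


class TestAgainstSingleNeuronSteppers:
    @pytest.mark.parametrize("method", ["rk2", "etd2"])
    def test_one_network_step_matches_python_stepper(self, method, syn):
        """Dual-route check: one compiled network step without spikes equals
        the pure-Python per-neuron stepper with analytic conductance decay."""
        cfg = table1_config(n=5, n_exc=4, n_inh=1, T=1.0, dt=0.02,
                            method=method, seed=8, nu_hz=0.0)
        sim = NetworkSimulation(cfg)
        # give the neurons distinct, nonzero synaptic states
        r = np.random.default_rng(0)
        for arr in (sim.syn.G_E, sim.syn.G_I, sim.syn.H_E, sim.syn.H_I):
            arr[:] = r.random(cfg.n) * 0.2
        params = sim.params
        hh_step = rk2 if method == "rk2" else etd2
        expected = []
        for i in range(cfg.n):
            s0 = SynapticState.zeros(1)
            s0.G_E[0] = sim.syn.G_E[i]
            s0.G_I[0] = sim.syn.G_I[i]
            s0.H_E[0] = sim.syn.H_E[i]
            s0.H_I[0] = sim.syn.H_I[i]

            def at(t, s0=s0):
                if t == 0:
                    return s0.G_E[0], s0.G_I[0]
                d = decay_step(s0, t, syn)
                return d.G_E[0], d.G_I[0]

            st = NeuronState(sim.V[i], sim.m[i], sim.h[i], sim.n_gate[i])
            expected.append(hh_step(st, 0.0, cfg.dt, at, params, syn))
        sim.step(1)
        for i, st in enumerate(expected):
            assert sim.V[i] == pytest.approx(st.V, rel=1e-12, abs=1e-12)
            assert sim.m[i] == pytest.approx(st.m, rel=1e-12)
            assert sim.h[i] == pytest.approx(st.h, rel=1e-12)
            assert sim.n_gate[i] == pytest.approx(st.n, rel=1e-12)


class TestConductanceBookkeeping:
    def test_two_neuron_spike_increments_target(self, syn):
        """A spike of neuron 0 at tau adds (S/2) e^{-(t_end-tau)/sigma_dE} to
        every neuron's H_E (all-to-all with self-edge, N = 2)."""
        cfg = NetworkConfig(n=2, n_exc=2, n_inh=0, S=0.2, f=0.0, nu_hz=0.0,
                            dt=0.1, T=1.0, method="rk2", seed=0, v0=-65.0)
        sim = NetworkSimulation(cfg)
        # drive neuron 0 over threshold by hand
        sim.V[0] = -50.001
        sim.syn.G_E[0] = 2.0  # strong drive so it crosses within one step
        G_E_before = sim.syn.G_E.copy()
        H_E_decay = sim.syn.H_E * math.exp(-cfg.dt / syn.sigma_d_E)
        t_new, i_new = sim.step(1)
        assert list(i_new) == [0]
        tau = t_new[0]
        inc = (0.2 / 2) * math.exp(-(cfg.dt - tau) / syn.sigma_d_E)
        assert sim.syn.H_E[1] == pytest.approx(H_E_decay[1] + inc, rel=1e-12)
        assert sim.syn.H_E[0] == pytest.approx(H_E_decay[0] + inc, rel=1e-12)

    def test_final_conductances_equal_event_superposition(self, syn):
        """G/H are linear in the spike events, so the final synaptic state
        must equal the closed-form superposition of every feedforward and
        recurrent spike's kernel — this checks detection/recalibration
        event-count conservation end to end."""
        cfg = table1_config(n=20, n_exc=16, n_inh=4, T=200.0, dt=0.05,
                            method="aetd2", seed=21)
        sim = NetworkSimulation(cfg)
        W, is_exc = sim.W.copy(), sim.is_exc.copy()
        ff = sim.feedforward
        res = sim.run()
        T = res.n_steps * cfg.dt
        n = cfg.n
        HE = np.zeros(n)
        GE = np.zeros(n)
        HI = np.zeros(n)
        GI = np.zeros(n)
        sdE, srE = syn.sigma_d_E, syn.sigma_r_E
        sdI, srI = syn.sigma_d_I, syn.sigma_r_I
        pref_E = sdE * srE / (sdE - srE)
        pref_I = sdI * srI / (sdI - srI)
        for i, times in enumerate(ff.times):
            d = T - times
            HE[i] += cfg.f * np.exp(-d / sdE).sum()
            GE[i] += cfg.f * (pref_E * (np.exp(-d / sdE) - np.exp(-d / srE))).sum()
        for tau, j in zip(res.spike_times, res.spike_neurons):
            d = T - tau
            if is_exc[j]:
                HE += W[:, j] * math.exp(-d / sdE)
                GE += W[:, j] * pref_E * (math.exp(-d / sdE) - math.exp(-d / srE))
            else:
                HI += W[:, j] * math.exp(-d / sdI)
                GI += W[:, j] * pref_I * (math.exp(-d / sdI) - math.exp(-d / srI))
        assert np.allclose(res.syn.H_E, HE, rtol=1e-9, atol=1e-12)
        assert np.allclose(res.syn.G_E, GE, rtol=1e-9, atol=1e-12)
        assert np.allclose(res.syn.H_I, HI, rtol=1e-9, atol=1e-12)
        assert np.allclose(res.syn.G_I, GI, rtol=1e-9, atol=1e-12)

    def test_refractory_bounds_interspike_intervals(self, small_result):
        cfg = small_result.config
        for i in range(cfg.n):
            t = small_result.spike_times[small_result.spike_neurons == i]
            if len(t) > 1:
                assert np.all(np.diff(t) >= cfg.refractory)


class TestAdaptivity:
    def test_zero_stiff_duration_reduces_to_rk2(self):
        base = table1_config(n=20, n_exc=16, n_inh=4, T=300.0, dt=0.05, seed=6)
        rk2_res = simulate(replace(base, method="rk2"))
        ad = simulate(replace(base, method="aetd2", stiff_duration=0.0))
        assert np.array_equal(rk2_res.spike_times, ad.spike_times)
        assert np.array_equal(rk2_res.V, ad.V)
        assert np.all(ad.n_stiff_steps == 0)

    def test_infinite_stiff_duration_is_etd2_after_first_spike(self):
        cfg = table1_config(n=10, n_exc=8, n_inh=2, T=200.0, dt=0.05,
                            method="aetd2", stiff_duration=np.inf, seed=6)
        res = simulate(cfg)
        first = np.full(cfg.n, np.nan)
        for t, i in zip(res.spike_times, res.spike_neurons):
            if np.isnan(first[i]):
                first[i] = t
        for i in range(cfg.n):
            if np.isnan(first[i]):
                assert res.n_stiff_steps[i] == 0
            else:
                # ETD2 from the first step that starts after the spike
                k_detect = int(np.floor(first[i] / cfg.dt))
                assert res.n_stiff_steps[i] == res.n_steps - (k_detect + 1)

    def test_default_window_uses_both_branches(self, small_result):
        spiked = np.unique(small_result.spike_neurons)
        assert len(spiked) > 0
        assert np.all(small_result.n_stiff_steps[spiked] > 0)
        assert np.all(small_result.n_stiff_steps < small_result.n_steps)

    def test_rtm_slope_criterion_marks_stiff_steps(self):
        cfg = NetworkConfig(n=5, n_exc=4, n_inh=1, S=0.1, f=0.1, nu_hz=500.0,
                            dt=0.02, T=300.0, method="aetd2", model="rtm",
                            v0=-67.0, seed=2)
        res = simulate(cfg)
        assert res.n_spikes > 0
        spiked = np.unique(res.spike_neurons)
        assert np.all(res.n_stiff_steps[spiked] > 0)


class TestInstabilityHandling:
    def test_coarse_rk2_aborts_with_diagnostic(self):
        cfg = table1_config(n=10, n_exc=8, n_inh=2, T=500.0, dt=1.0,
                            method="rk2", seed=1)
        with pytest.raises(InstabilityError, match="rk2.*dt=1.0"):
            simulate(cfg)

    def test_coarse_etd2_stays_finite(self):
        # ETD2 at dt = 1 ms is wildly inaccurate but must not blow up
        cfg = table1_config(n=20, n_exc=16, n_inh=4, T=500.0, dt=1.0,
                            method="etd2", seed=1)
        res = simulate(cfg)
        assert np.all(np.isfinite(res.V))


class TestTopology:
    def test_all_to_all_weights(self):
        cfg = table1_config(n=4, n_exc=3, n_inh=1, T=1.0)
        W, is_exc = build_weights(cfg, np.random.default_rng(0))
        assert np.allclose(W, 0.2 / 4)
        assert list(is_exc) == [True, True, True, False]
        W2, _ = build_weights(replace(cfg, include_self=False),
                              np.random.default_rng(0))
        assert np.all(np.diag(W2) == 0)

    def test_random_topology_density_and_seed(self):
        cfg = table1_config(n=100, topology="random", p_connect=0.25, T=1.0)
        rng = np.random.default_rng(0)
        W, _ = build_weights(cfg, np.random.default_rng(0))
        density = (W > 0).mean()
        assert density == pytest.approx(0.25, abs=0.02)
        W2, _ = build_weights(cfg, np.random.default_rng(0))
        assert np.array_equal(W, W2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(n=5, n_exc=3, n_inh=1)
        with pytest.raises(ValueError):
            NetworkConfig(method="rk4")
        with pytest.raises(ValueError):
            NetworkConfig(dt=0.0)
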