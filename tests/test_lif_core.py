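"""Membrane integration, event delivery, closed loop and free-run statistics."""

import numpy as np
import pytest

from shifted_stdp.lif_core import (
    NeuronState,
    deliver_spike,
    free_run_stats,
    initial_weights,
    run_simulation,
    step,
)
from shifted_stdp.params import (
    InputEnsembleConfig,
    NeuronParams,
    PairSTDPParams,
    SynapseParams,
)
from shifted_stdp.spike_gen import EnsembleRealization, SpikeTrain, generate_ensemble
from shifted_stdp.stdp_rules import PairingState, on_post_spike, on_pre_spike


DT = 1e-4


class TestStep:
    def test_rest_is_an_equilibrium(self, neuron, synapses):
        st = NeuronState(v=neuron.v_rest)
        for _ in range(100):
            st, spiked = step(st, neuron, synapses, DT)
            assert not spiked
        assert st.v == pytest.approx(neuron.v_rest, abs=1e-12)

    def test_free_decay_follows_membrane_time_constant(self, neuron, synapses):
        # closed form: V(t) = V0 * exp(-t/tau_m) relative to rest
        st = NeuronState(v=neuron.v_rest + 10.0)
        n = int(round(neuron.tau_m * np.log(2) / DT))
        for _ in range(n):
            st, _ = step(st, neuron, synapses, DT)
        expected = 10.0 * np.exp(-n * DT / neuron.tau_m)
        assert st.v - neuron.v_rest == pytest.approx(expected, rel=1e-9)
        assert st.v - neuron.v_rest == pytest.approx(5.0, rel=1e-2)

    def test_threshold_crossing_resets_to_rest(self, neuron, synapses):
        st = NeuronState(v=neuron.v_threshold + 0.1)
        st, spiked = step(st, neuron, synapses, DT)
        assert spiked
        assert st.v == neuron.v_rest

    def test_coarse_dt_rejected(self, neuron, synapses):
        with pytest.raises(ValueError):
            step(NeuronState(), neuron, synapses, synapses.tau_s)


class TestDeliverSpike:
    def test_zero_weight_is_identity(self, neuron):
        st = NeuronState(v=1.0, g_ex=2.0, g_in=3.0)
        out = deliver_spike(st, "excitatory", 0.0)
        assert (out.v, out.g_ex, out.g_in) == (1.0, 2.0, 3.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            deliver_spike(NeuronState(), "excitatory", -1.0)

    def test_epsp_peak_matches_double_exponential_filter(self, neuron, synapses):
        # analytic peak of w * tau_s/(tau_m-tau_s) * (e^-t/tau_m - e^-t/tau_s)
        w = 1.0
        tau_m, tau_s = neuron.tau_m, synapses.tau_s
        t_star = np.log(tau_m / tau_s) * tau_m * tau_s / (tau_m - tau_s)
        peak_analytic = w * tau_s / (tau_m - tau_s) * (
            np.exp(-t_star / tau_m) - np.exp(-t_star / tau_s)
        )
        st = deliver_spike(NeuronState(), "excitatory", w)
        peak = 0.0
        for _ in range(int(0.1 / 1e-5)):
            st, _ = step(st, neuron, synapses, 1e-5)
            peak = max(peak, st.v - neuron.v_rest)
        assert peak == pytest.approx(peak_analytic, rel=1e-3)

    def test_inhibition_lowers_the_whole_trajectory(self, neuron, synapses):
        base = deliver_spike(NeuronState(), "excitatory", 1.0)
        inh = deliver_spike(base, "inhibitory", 0.5)
        for _ in range(2000):
            base, _ = step(base, neuron, synapses, DT)
            inh, _ = step(inh, neuron, synapses, DT)
            assert inh.v < base.v


def _quiet_ensemble(n_ex, n_in, duration):
    empty = lambda: SpikeTrain(times=np.zeros(0), duration=duration)
    return EnsembleRealization(
        excitatory=[empty() for _ in range(n_ex)],
        inhibitory=[empty() for _ in range(n_in)],
        n_correlated=0,
    )


class TestRunSimulation:
    def test_silent_inputs_and_noop_rule_change_nothing(self, neuron, small_synapses):
        real = _quiet_ensemble(20, 5, 10.0)
        w0 = np.linspace(1, 5, 20)
        rec = run_simulation(real, neuron, small_synapses, None, duration=10.0,
                             weights=w0, seed=0)
        assert len(rec.post_spikes) == 0
        assert np.array_equal(rec.final_weights, w0)

    def test_identical_seeds_reproduce_bit_for_bit(self, neuron, small_synapses,
                                                   small_ensemble):
        rule = PairSTDPParams()
        a = run_simulation(small_ensemble, neuron, small_synapses, rule,
                           duration=20.0, seed=5)
        b = run_simulation(small_ensemble, neuron, small_synapses, rule,
                           duration=20.0, seed=5)
        assert np.array_equal(a.post_spikes.times, b.post_spikes.times)
        assert np.array_equal(a.final_weights, b.final_weights)
        assert np.array_equal(a.snapshots, b.snapshots)

    def test_default_initial_weights_are_uniform_1_to_5(self, neuron, small_synapses,
                                                        small_ensemble):
        rec = run_simulation(small_ensemble, neuron, small_synapses, None,
                             duration=5.0, seed=3)
        assert rec.initial_weights.min() >= 1.0
        assert rec.initial_weights.max() <= 5.0
        big = initial_weights(20_000, seed=1)
        assert big.min() == pytest.approx(1.0, abs=2e-3)
        assert big.max() == pytest.approx(5.0, abs=2e-3)

    def test_constant_weight_drive_spikes_reproducibly(self, neuron, small_synapses,
                                                       small_ensemble):
        # rates high enough to fire the small ensemble
        ens = InputEnsembleConfig(n_excitatory=20, n_inhibitory=5,
                                  rate_excitatory=80.0, rate_inhibitory=10.0)
        rec = run_simulation(ens, neuron, small_synapses, None, duration=30.0,
                             weights=np.full(20, 3.0), seed=7)
        assert rec.postsynaptic_rate > 0

    def test_mismatched_weights_rejected(self, neuron, small_synapses, small_ensemble):
        with pytest.raises(ValueError):
            run_simulation(small_ensemble, neuron, small_synapses, None,
                           duration=5.0, weights=np.ones(3), seed=0)

    def test_dt_refinement_changes_rate_under_two_percent(self, neuron, synapses):
        # same pre-realized inputs, plasticity off, frozen weights
        ens = InputEnsembleConfig()
        real = generate_ensemble(ens, 120.0, seed=11)
        w = np.full(250, 2.8)
        rates = []
        for dt in (1e-4, 5e-5):
            rec = run_simulation(real, neuron, synapses, None, duration=120.0,
                                 dt=dt, weights=w, seed=11)
            rates.append(rec.postsynaptic_rate)
        assert abs(rates[1] - rates[0]) / rates[0] < 0.02

    def test_kernel_matches_event_driven_reference(self, neuron, small_synapses):
        """The numba closed loop reproduces the pure-Python pairing machine.

        A small ensemble is replayed through an explicit step/deliver loop
        with the reference on_pre/on_post updates; final weights must agree
        to numerical precision.
        """
        ens = InputEnsembleConfig(n_excitatory=20, n_inhibitory=5,
                                  rate_excitatory=60.0, rate_inhibitory=20.0)
        duration, dt = 8.0, 1e-4
        real = generate_ensemble(ens, duration, seed=13)
        w0 = initial_weights(20, seed=13)
        rule = PairSTDPParams()

        rec = run_simulation(real, neuron, small_synapses, rule, duration=duration,
                             dt=dt, weights=w0, seed=13)

        # reference loop
        n_steps = int(round(duration / dt))
        events = {}
        for j, tr in enumerate(real.excitatory):
            for b in np.floor(tr.times / dt).astype(int):
                events.setdefault(b, []).append(j)
        in_bins = np.concatenate(
            [np.floor(tr.times / dt).astype(int) for tr in real.inhibitory]
        )
        in_counts = np.bincount(in_bins, minlength=n_steps)
        st = NeuronState()
        pairing = PairingState(20)
        w = w0.copy()
        for i in range(n_steps):
            t = i * dt
            st = deliver_spike(st, "inhibitory",
                               small_synapses.w_inh * in_counts[i]) if in_counts[i] else st
            for j in sorted(events.get(i, [])):
                st = deliver_spike(st, "excitatory", w[j])
                w[j] = max(w[j] + on_pre_spike(pairing, j, t, rule), 0.0)
            st, spiked = step(st, neuron, small_synapses, dt)
            if spiked:
                w = np.maximum(w + on_post_spike(pairing, t, rule), 0.0)
        assert np.allclose(w, rec.final_weights, atol=1e-10)

    def test_superposition_of_subthreshold_responses(self, neuron, small_synapses):
        # linear filter: response(A+B) = response(A) + response(B) without spiking
        duration = 20.0
        realA = generate_ensemble(
            InputEnsembleConfig(n_excitatory=20, n_inhibitory=5,
                                rate_excitatory=5.0, rate_inhibitory=0.0),
            duration, seed=1)
        realB = generate_ensemble(
            InputEnsembleConfig(n_excitatory=20, n_inhibitory=5,
                                rate_excitatory=0.0, rate_inhibitory=20.0),
            duration, seed=2)
        merged = EnsembleRealization(
            excitatory=[SpikeTrain(np.sort(np.concatenate([a.times, b.times])), duration)
                        for a, b in zip(realA.excitatory, realB.excitatory)],
            inhibitory=[SpikeTrain(np.sort(np.concatenate([a.times, b.times])), duration)
                        for a, b in zip(realA.inhibitory, realB.inhibitory)],
            n_correlated=0,
        )
        w = np.full(20, 1.0)
        mA, _ = free_run_stats(realA, neuron, small_synapses, w, duration, seed=0)
        mB, _ = free_run_stats(realB, neuron, small_synapses, w, duration, seed=0)
        mAB, _ = free_run_stats(merged, neuron, small_synapses, w, duration, seed=0)
        assert mAB == pytest.approx(mA + mB, abs=1e-9)


class TestFreeRunStats:
    def test_silent_inputs_give_zero_in_threshold_units(self, neuron, small_synapses):
        real = _quiet_ensemble(20, 5, 5.0)
        mean_v, std_v = free_run_stats(real, neuron, small_synapses,
                                       np.ones(20), 5.0, seed=0)
        assert mean_v == 0.0 and std_v == 0.0

    def test_strong_excitation_is_mean_driven(self, neuron, small_synapses):
        ens = InputEnsembleConfig(n_excitatory=20, n_inhibitory=5,
                                  rate_excitatory=100.0, rate_inhibitory=0.0)
        mean_v, _ = free_run_stats(ens, neuron, small_synapses,
                                   np.full(20, 3.0), 60.0, seed=1)
        assert mean_v > 1.0

    def test_balanced_inhibition_lowers_mean_raises_relative_noise(self, neuron):
        # matched mean drive, more variance with inhibition present
        syn = SynapseParams(n_excitatory=20, n_inhibitory=20, w_inh=3.0)
        quiet = InputEnsembleConfig(n_excitatory=20, n_inhibitory=20,
                                    rate_excitatory=100.0, rate_inhibitory=0.0)
        loud = InputEnsembleConfig(n_excitatory=20, n_inhibitory=20,
                                   rate_excitatory=150.0, rate_inhibitory=50.0)
        m1, s1 = free_run_stats(quiet, neuron, syn, np.full(20, 3.0), 120.0, seed=2)
        m2, s2 = free_run_stats(loud, neuron, syn, np.full(20, 3.0), 120.0, seed=2)
        # shot-noise variance adds with every input stream
        assert m2 < m1 * 1.2
        assert s2 > s1
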