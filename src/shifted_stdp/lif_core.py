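"""Leaky integrate-and-fire neuron with current-based exponential synapses.

The membrane potential (measured relative to rest) obeys

    tau_m dV/dt = -V + g_ex(t) - g_in(t)

where each presynaptic spike makes the corresponding drive jump by its
synaptic strength (mV) and both drives decay with the shared synaptic time
constant tau_s.  When V reaches the threshold theta the neuron spikes and
resets to rest.  Subthreshold dynamics are linear, so the fixed-step update
uses the exact exponential propagator for (V, g) over each dt; the step
size only controls the alignment of spike events to the time grid.

Two entry points matter:

* :func:`run_simulation` — the full closed loop (inputs, neuron, plasticity
  hooks, weight snapshots), backed by a numba kernel;
* :func:`free_run_stats` — the same drive with the spiking mechanism turned
  off and weights frozen, returning the mean and standard deviation of the
  free-running membrane potential in units of the spiking threshold (used
  to distinguish mean-driven from fluctuation-driven operation).

Events falling in the same dt bin are processed presynaptic-first, so a
simultaneous pre/post pair is seen by the pairing logic as dt = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numba import njit

from .params import (
    InputEnsembleConfig,
    JitterParams,
    NeuronParams,
    PairSTDPParams,
    SynapseParams,
    TripletParams,
)
from .spike_gen import EnsembleRealization, SpikeTrain, generate_ensemble

__all__ = [
    "NeuronState",
    "SimulationRecord",
    "step",
    "deliver_spike",
    "run_simulation",
    "free_run_stats",
    "initial_weights",
]

_NEG = -1.0e30  # sentinel for "no event yet"


@dataclass
class NeuronState:
    """Instantaneous neuron state: V relative to rest (mV), drives (mV), time (s)."""

    v: float = 0.0
    g_ex: float = 0.0
    g_in: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v", "g_ex", "g_in", "t"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite neuron state field {name}")
        if self.g_ex < 0 or self.g_in < 0:
            raise ValueError("synaptic drives must be non-negative")


def step(state: NeuronState, neuron: NeuronParams, synapses: SynapseParams, dt: float):
    """Advance the neuron one step of ``dt`` seconds; return (state, spiked).

    Exact exponential update of the linear subthreshold system with the
    drives held to their exponential decay over the step.  If V crosses
    threshold it is reset to rest and ``spiked`` is True.  ``dt`` must
    resolve the synaptic kinetics (dt <= tau_s / 5).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > synapses.tau_s / 5:
        raise ValueError("dt too coarse: require dt <= tau_s / 5")
    if not all(np.isfinite(x) for x in (state.v, state.g_ex, state.g_in)):
        raise FloatingPointError("non-finite neuron state")
    tau_m, tau_s = neuron.tau_m, synapses.tau_s
    em, es = np.exp(-dt / tau_m), np.exp(-dt / tau_s)
    f = tau_s / (tau_m - tau_s) * (em - es)
    v_rel = state.v - neuron.v_rest
    # a state already at threshold fires before integrating
    spiked = bool(v_rel >= neuron.theta)
    if spiked:
        v_rel = 0.0
    v_rel = v_rel * em + (state.g_ex - state.g_in) * f
    if not spiked and v_rel >= neuron.theta:
        spiked = True
        v_rel = 0.0
    return (
        NeuronState(
            v=neuron.v_rest + v_rel,
            g_ex=state.g_ex * es,
            g_in=state.g_in * es,
            t=state.t + dt,
        ),
        spiked,
    )


def deliver_spike(state: NeuronState, synapse_kind: str, weight: float) -> NeuronState:
    """Apply the abrupt drive jump of one presynaptic spike."""
    if weight < 0:
        raise ValueError("synaptic weight must be non-negative")
    if synapse_kind == "excitatory":
        return NeuronState(state.v, state.g_ex + weight, state.g_in, state.t)
    if synapse_kind == "inhibitory":
        return NeuronState(state.v, state.g_ex, state.g_in + weight, state.t)
    raise ValueError("synapse_kind must be 'excitatory' or 'inhibitory'")


@njit(cache=True)
def _kernel(
    n_steps,
    dt,
    ex_bins,
    ex_syn,
    in_bins,
    w,
    tau_m,
    tau_s,
    theta,
    w_inh,
    rule_kind,  # 0 none, 1 pair, 2 jittered, 3 triplet
    ap,
    am,
    taup,
    taud,
    shift,
    sigma,
    a3p,
    a3m,
    taux,
    tauy,
    w_max,
    spiking,
    snap_every_bins,
    snaps,
    post_bins,
    seed,
):
    np.random.seed(seed)
    n_syn = w.size
    em = np.exp(-dt / tau_m)
    es = np.exp(-dt / tau_s)
    f = tau_s / (tau_m - tau_s) * (em - es)
    v = 0.0
    gex = 0.0
    gin = 0.0
    last_pre = np.full(n_syn, _NEG)
    last_post = _NEG
    pe = 0
    pi = 0
    n_post = 0
    n_snap = 0
    v_sum = 0.0
    v2_sum = 0.0
    plastic = rule_kind > 0
    for i in range(n_steps):
        t = i * dt
        while pi < in_bins.size and in_bins[pi] == i:
            gin += w_inh
            pi += 1
        while pe < ex_bins.size and ex_bins[pe] == i:
            j = ex_syn[pe]
            gex += w[j]
            if plastic:
                dw = 0.0
                # adjacent-event pairing: depress only if the most recent
                # event on this synapse is a postsynaptic spike; the triplet
                # extra depression rides on the same pairing
                if last_post > _NEG / 2 and last_post >= last_pre[j]:
                    dtp = last_post - t  # <= 0
                    if rule_kind == 2 and sigma > 0.0:
                        dtp += np.random.normal(0.0, sigma)
                    if dtp > shift:
                        dw += ap * np.exp(-(dtp - shift) / taup)
                    else:
                        dw += -am * np.exp((dtp - shift) / taud)
                    if rule_kind == 3:
                        r_before = np.exp((last_pre[j] - t) / taux) if last_pre[j] > _NEG / 2 else 0.0
                        o_now = np.exp((last_post - t) / tauy)
                        dw -= a3m * o_now * r_before
                if dw != 0.0:
                    wj = w[j] + dw
                    if wj < 0.0:
                        wj = 0.0
                    elif wj > w_max:
                        wj = w_max
                    w[j] = wj
            last_pre[j] = t
            pe += 1
        v = v * em + (gex - gin) * f
        gex *= es
        gin *= es
        if spiking:
            if v >= theta:
                v = 0.0
                if n_post < post_bins.size:
                    post_bins[n_post] = i
                n_post += 1
                if plastic:
                    o_before = 0.0
                    if rule_kind == 3:
                        o_before = (
                            np.exp((last_post - t) / tauy) if last_post > _NEG / 2 else 0.0
                        )
                    for j in range(n_syn):
                        if last_pre[j] > _NEG / 2:
                            dw = 0.0
                            # pair window only for adjacent pre->post events;
                            # the triplet extra potentiation rides on it
                            if last_pre[j] > last_post:
                                dtp = t - last_pre[j]  # >= 0
                                if rule_kind == 2 and sigma > 0.0:
                                    dtp += np.random.normal(0.0, sigma)
                                if dtp > shift:
                                    dw = ap * np.exp(-(dtp - shift) / taup)
                                else:
                                    dw = -am * np.exp((dtp - shift) / taud)
                                if rule_kind == 3:
                                    dw += a3p * o_before * np.exp(-dtp / taux)
                            if dw != 0.0:
                                wj = w[j] + dw
                                if wj < 0.0:
                                    wj = 0.0
                                elif wj > w_max:
                                    wj = w_max
                                w[j] = wj
                last_post = t
        else:
            v_sum += v
            v2_sum += v * v
        if snap_every_bins > 0 and (i + 1) % snap_every_bins == 0:
            if n_snap < snaps.shape[0]:
                for j in range(n_syn):
                    snaps[n_snap, j] = w[j]
                n_snap += 1
    return n_post, n_snap, v_sum, v2_sum


@dataclass
class SimulationRecord:
    """Everything a closed-loop run produced.

    ``snapshot_times`` / ``snapshots`` hold the weight vector at a regular
    cadence (snapshots[k] taken at snapshot_times[k]); ``free_run_stats``
    is only filled by :func:`free_run_stats`.
    """

    post_spikes: SpikeTrain
    snapshot_times: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, n_excitatory)
    initial_weights: np.ndarray
    final_weights: np.ndarray
    seed: int
    dt: float
    duration: float
    config: dict = field(default_factory=dict)
    free_run: Optional[tuple] = None  # (mean_v_over_theta, std_v_over_theta)

    @property
    def postsynaptic_rate(self) -> float:
        return len(self.post_spikes) / self.duration

    def rate_series(self) -> np.ndarray:
        """Postsynaptic firing rate (Hz) in each inter-snapshot window."""
        edges = np.concatenate([[0.0], self.snapshot_times])
        counts = np.histogram(self.post_spikes.times, bins=edges)[0]
        return counts / np.diff(edges)

    def snapshots_to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.snapshots,
            index=pd.Index(self.snapshot_times, name="time_s"),
            columns=[f"w{j}" for j in range(self.snapshots.shape[1])],
        )
        df.to_csv(path)

    def summary(self) -> dict:
        fw = self.final_weights
        out = {
            "duration_s": self.duration,
            "dt_s": self.dt,
            "seed": self.seed,
            "n_post_spikes": len(self.post_spikes),
            "postsynaptic_rate_hz": self.postsynaptic_rate,
            "mean_weight_mv": float(fw.mean()),
            "std_weight_mv": float(fw.std()),
            "config": self.config,
        }
        if self.free_run is not None:
            out["mean_v_over_theta"] = self.free_run[0]
            out["std_v_over_theta"] = self.free_run[1]
        return out

    def summary_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def initial_weights(n: int, seed, low: float = 1.0, high: float = 5.0) -> np.ndarray:
    """Random initial strengths, uniform on [low, high] mV."""
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n)


def _events_to_bins(trains, dt: float, n_steps: int):
    """Merge per-synapse trains into time-sorted (bin, synapse) event arrays."""
    bins_list = []
    syn_list = []
    for j, tr in enumerate(trains):
        b = np.floor(tr.times / dt).astype(np.int64)
        b = b[b < n_steps]
        bins_list.append(b)
        syn_list.append(np.full(b.size, j, dtype=np.int32))
    if bins_list:
        bins = np.concatenate(bins_list)
        syn = np.concatenate(syn_list)
    else:
        bins = np.zeros(0, dtype=np.int64)
        syn = np.zeros(0, dtype=np.int32)
    order = np.argsort(bins, kind="stable")
    return bins[order], syn[order]


Rule = Union[PairSTDPParams, JitterParams, TripletParams, None]


def _rule_scalars(rule: Rule):
    """Flatten a rule object into the kernel's scalar parameters."""
    if rule is None:
        return (0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, np.inf)
    if isinstance(rule, TripletParams):
        p = rule.pair
        return (
            3, p.a_plus, p.a_minus, p.tau_plus, p.tau_minus, p.shift, 0.0,
            rule.a3_plus, rule.a3_minus, rule.tau_x, rule.tau_y,
            p.w_max if p.w_max is not None else np.inf,
        )
    if isinstance(rule, JitterParams):
        p = rule.base
        return (
            2, p.a_plus, p.a_minus, p.tau_plus, p.tau_minus, p.shift, rule.sigma,
            0.0, 0.0, 1.0, 1.0, p.w_max if p.w_max is not None else np.inf,
        )
    if isinstance(rule, PairSTDPParams):
        return (
            1, rule.a_plus, rule.a_minus, rule.tau_plus, rule.tau_minus,
            rule.shift, 0.0, 0.0, 0.0, 1.0, 1.0,
            rule.w_max if rule.w_max is not None else np.inf,
        )
    raise TypeError(f"unknown rule type {type(rule)!r}")


def _run(
    ensemble,
    neuron: NeuronParams,
    synapses: SynapseParams,
    rule: Rule,
    duration: float,
    dt: float,
    snapshot_every: float,
    seed: int,
    weights: Optional[np.ndarray],
    spiking: bool,
) -> SimulationRecord:
    if isinstance(ensemble, InputEnsembleConfig):
        if ensemble.n_excitatory != synapses.n_excitatory:
            raise ValueError("ensemble/synapse excitatory counts disagree")
        if ensemble.n_inhibitory != synapses.n_inhibitory:
            raise ValueError("ensemble/synapse inhibitory counts disagree")
        realization = generate_ensemble(ensemble, duration, seed=seed)
        config = {"ensemble": ensemble.__dict__.copy()}
    elif isinstance(ensemble, EnsembleRealization):
        realization = ensemble
        config = {"ensemble": "pre-realized"}
    else:
        raise TypeError("ensemble must be InputEnsembleConfig or EnsembleRealization")

    n_steps = int(round(duration / dt))
    if weights is None:
        weights = initial_weights(len(realization.excitatory), seed)
    w = np.asarray(weights, dtype=float).copy()
    if w.size != len(realization.excitatory):
        raise ValueError("weights length must equal the number of excitatory inputs")

    ex_bins, ex_syn = _events_to_bins(realization.excitatory, dt, n_steps)
    in_bins, _ = _events_to_bins(realization.inhibitory, dt, n_steps)

    snap_every_bins = int(round(snapshot_every / dt)) if snapshot_every else 0
    n_snaps = n_steps // snap_every_bins if snap_every_bins else 0
    snaps = np.zeros((n_snaps, w.size))
    post_cap = int(duration * 1000) + 10000  # generous: 1 kHz sustained
    post_bins = np.zeros(post_cap, dtype=np.int64)

    (kind, ap, am, taup, taud, shift, sigma, a3p, a3m, taux, tauy, w_max) = _rule_scalars(rule)
    w0 = w.copy()
    n_post, n_snap, v_sum, v2_sum = _kernel(
        n_steps, dt, ex_bins, ex_syn, in_bins, w,
        neuron.tau_m, synapses.tau_s, neuron.theta, synapses.w_inh,
        kind, ap, am, taup, taud, shift, sigma, a3p, a3m, taux, tauy, w_max,
        spiking, snap_every_bins, snaps, post_bins, seed % (2**31 - 1),
    )
    if n_post > post_cap:
        raise RuntimeError(
            f"postsynaptic spike capacity exceeded ({n_post} > {post_cap}); "
            "the run is pathologically fast-spiking"
        )
    post_times = post_bins[:n_post] * dt
    record = SimulationRecord(
        post_spikes=SpikeTrain(times=post_times, duration=duration),
        snapshot_times=(np.arange(n_snap) + 1) * snap_every_bins * dt,
        snapshots=snaps[:n_snap],
        initial_weights=w0,
        final_weights=w,
        seed=seed,
        dt=dt,
        duration=duration,
        config=config,
    )
    if not spiking:
        mean_v = v_sum / n_steps
        var_v = max(v2_sum / n_steps - mean_v**2, 0.0)
        record.free_run = (mean_v / neuron.theta, float(np.sqrt(var_v)) / neuron.theta)
    return record


def run_simulation(
    ensemble,
    neuron: NeuronParams,
    synapses: SynapseParams,
    rule: Rule,
    duration: float,
    dt: float = 1e-4,
    snapshot_every: float = 10.0,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
) -> SimulationRecord:
    """Closed-loop simulation: inputs -> LIF neuron -> plasticity -> weights.

    ``ensemble`` is either an :class:`InputEnsembleConfig` (inputs drawn
    internally from ``seed``) or a pre-realized ensemble.  ``rule`` selects
    the plasticity machine (None freezes the weights).  Weights default to
    the uniform 1-5 mV initialisation.  Identical arguments and seed give
    bit-identical records.
    """
    return _run(ensemble, neuron, synapses, rule, duration, dt, snapshot_every, seed, weights, True)


def free_run_stats(
    ensemble,
    neuron: NeuronParams,
    synapses: SynapseParams,
    frozen_weights: np.ndarray,
    duration: float,
    dt: float = 1e-4,
    seed: int = 0,
):
    """Mean and std of the free-running membrane potential, in threshold units.

    The spike/reset mechanism is disabled and the weights are frozen, so V
    samples the stationary filtered shot noise; values are reported as
    (V - V_rest)/theta, making silent input exactly (0, 0) and > 1 the
    signature of mean-driven operation.
    """
    rec = _run(
        ensemble, neuron, synapses, None, duration, dt, 0.0, seed,
        np.asarray(frozen_weights, dtype=float), False,
    )
    return rec.free_run
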