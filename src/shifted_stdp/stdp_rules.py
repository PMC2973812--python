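"""Event-driven plasticity rules.

Three rules share the nearest-neighbour pairing scheme:

* shifted pair-based STDP — the window boundary between depression and
  potentiation sits at ``dt = shift`` rather than 0, so short-latency
  causal pairings (0 < dt <= shift) depress;
* jittered STDP — an unshifted window evaluated at ``dt + eta`` with
  Gaussian ``eta``, whose jitter-averaged effective window likewise
  depresses short causal intervals;
* shifted triplet STDP — exponential detector traces (one presynaptic
  trace per synapse, one postsynaptic trace) add multi-spike depression
  (pre-post-pre) and potentiation (post-pre-post) terms on top of the
  shifted pair window.

Nearest-neighbour semantics (reduced / adjacent-event pairing): on each
synapse, only *consecutive* events of opposite type pair, and each
adjacency is used exactly once.  A postsynaptic spike potentiates a
synapse only when that synapse's most recent event is a presynaptic spike
(no postsynaptic spike intervened); a presynaptic spike depresses only
when the most recent event is a postsynaptic spike.  This is what makes
the pairing-interval density decay at rate nu_ex + nu_post (no
intervening spike of either train) and keeps the total potentiation
bounded at high postsynaptic rates — the heart of the rate-buffering
property.  A spike with no prior opposite-type partner produces no
update.

These pure-Python machines are the reference implementation used by the
unit tests and by short event-script replays; the simulation kernel in
:mod:`shifted_stdp.lif_core` inlines the same arithmetic for speed and is
tested for equivalence against this module.
"""

from __future__ import annotations

import math

import numpy as np

from .params import JitterParams, PairSTDPParams, TripletParams

__all__ = [
    "window",
    "jittered_delta",
    "effective_window",
    "PairingState",
    "on_pre_spike",
    "on_post_spike",
    "triplet_on_pre",
    "triplet_on_post",
    "apply_bounds",
]


def window(delta_t, params: PairSTDPParams):
    """Pair-based STDP window (mV) at ``delta_t = t_post - t_pre`` (s).

    Potentiation branch ``a_plus * exp(-(dt - d)/tau_plus)`` for
    ``dt > d``; depression branch ``-a_minus * exp((dt - d)/tau_minus)``
    for ``dt <= d``.  The boundary ``dt = d`` belongs to the depression
    branch, so an exactly shift-separated pairing depresses.
    """
    dt = np.asarray(delta_t, dtype=float)
    d = params.shift
    out = np.where(
        dt > d,
        params.a_plus * np.exp(-(dt - d) / params.tau_plus),
        -params.a_minus * np.exp(np.minimum(dt - d, 0.0) / params.tau_minus),
    )
    if np.isscalar(delta_t) or np.ndim(delta_t) == 0:
        return float(out)
    return out


def jittered_delta(delta_t: float, params: JitterParams, rng) -> float:
    """Jittered window: ``window(delta_t + eta)`` with ``eta ~ N(0, sigma^2)``."""
    eta = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
    return window(delta_t + eta, params.base)


def effective_window(delta_t, params: JitterParams, n_points: int = 2001):
    """Jitter-averaged window: Gaussian convolution of the base window.

    Computed by quadrature over the jitter distribution; this is the
    deterministic curve that the Monte-Carlo mean of
    :func:`jittered_delta` converges to.
    """
    if params.sigma == 0:
        return window(delta_t, params.base)
    etas = np.linspace(-6 * params.sigma, 6 * params.sigma, n_points)
    weights = np.exp(-0.5 * (etas / params.sigma) ** 2)
    weights /= weights.sum()
    dt = np.atleast_1d(np.asarray(delta_t, dtype=float))
    vals = np.array([(window(x + etas, params.base) * weights).sum() for x in dt])
    if np.isscalar(delta_t) or np.ndim(delta_t) == 0:
        return float(vals[0])
    return vals


class PairingState:
    """Per-synapse pairing memory and (for the triplet rule) detector traces.

    ``last_pre[j]`` / ``last_post`` record the most recent event times.
    The triplet traces need no stored amplitude: each spike *sets* its
    trace to 1, so the trace value at time t is exactly
    ``exp(-(t - t_last)/tau)``.
    """

    def __init__(self, n_synapses: int):
        self.n_synapses = n_synapses
        self.last_pre = np.full(n_synapses, -np.inf)
        self.last_post = -np.inf
        # processing-order sequence numbers decide adjacency; ties in time
        # (events in the same integration step) follow processing order
        self._seq = 0
        self._pre_seq = np.full(n_synapses, -1, dtype=np.int64)
        self._post_seq = -1
        self._t_latest = -np.inf

    def _check_order(self, t: float) -> int:
        if t < self._t_latest:
            raise ValueError(
                f"event at t={t} precedes an already-processed event at t={self._t_latest}"
            )
        self._t_latest = t
        self._seq += 1
        return self._seq

    def pre_trace(self, j: int, t: float, tau_x: float) -> float:
        """Presynaptic detector r_j at time t (0 if no pre spike yet)."""
        lp = self.last_pre[j]
        return math.exp(-(t - lp) / tau_x) if np.isfinite(lp) else 0.0

    def post_trace(self, t: float, tau_y: float) -> float:
        """Postsynaptic detector o at time t (0 if no post spike yet)."""
        lp = self.last_post
        return math.exp(-(t - lp) / tau_y) if np.isfinite(lp) else 0.0


def on_pre_spike(state: PairingState, synapse_j: int, t: float, params: PairSTDPParams) -> float:
    """Process a presynaptic spike at synapse ``synapse_j``; return dw (mV).

    Pairs with the immediately preceding postsynaptic spike — but only if
    that postsynaptic spike is the most recent event on this synapse (no
    presynaptic spike intervened).  The pairing has dt <= 0, the
    depression branch.  Returns 0 when there is no adjacent opposite-type
    partner.
    """
    seq = state._check_order(t)
    dw = 0.0
    if state._post_seq > state._pre_seq[synapse_j]:
        dw = window(state.last_post - t, params)
    state.last_pre[synapse_j] = t
    state._pre_seq[synapse_j] = seq
    return dw


def on_post_spike(state: PairingState, t: float, params: PairSTDPParams) -> np.ndarray:
    """Process a postsynaptic spike; return the dw vector (mV) over synapses.

    A synapse is updated only when its most recent event is a presynaptic
    spike (its pre arrived after the previous postsynaptic spike), via the
    window at ``dt = t - last_pre[j]``; with a shifted window this is a
    *depression* when ``0 < dt <= shift``.
    """
    seq = state._check_order(t)
    dw = np.zeros(state.n_synapses)
    paired = state._pre_seq > state._post_seq
    if np.any(paired):
        dw[paired] = window(t - state.last_pre[paired], params)
    state.last_post = t
    state._post_seq = seq
    return dw


def triplet_on_pre(state: PairingState, synapse_j: int, t: float, params: TripletParams) -> float:
    """Triplet-rule presynaptic update; returns dw (mV) for synapse j.

    Applies the shifted pair depression against the last postsynaptic
    spike, plus the extra triplet depression ``-a3_minus * o(t) *
    r_j(t^-)`` (pre-pre interval decay through r_j, gated by the
    postsynaptic detector so that a full 2 pre/1 post ensemble is
    required).  Trace values are read before r_j is reset to 1.
    """
    seq = state._check_order(t)
    r_before = state.pre_trace(synapse_j, t, params.tau_x)
    o_now = state.post_trace(t, params.tau_y)
    dw = 0.0
    if state._post_seq > state._pre_seq[synapse_j]:
        dw = window(state.last_post - t, params.pair)
        dw -= params.a3_minus * o_now * r_before
    state.last_pre[synapse_j] = t  # r_j set to 1 at its own spike time
    state._pre_seq[synapse_j] = seq
    return dw


def triplet_on_post(state: PairingState, t: float, params: TripletParams) -> np.ndarray:
    """Triplet-rule postsynaptic update; returns the dw vector (mV).

    Applies the shifted pair window against each synapse's last
    presynaptic spike, plus the extra triplet potentiation ``a3_plus *
    o(t^-) * r_j(t)`` (post-post interval decay through o, gated per
    synapse by its presynaptic detector).  o is read before being reset
    to 1.
    """
    seq = state._check_order(t)
    o_before = state.post_trace(t, params.tau_y)
    dw = np.zeros(state.n_synapses)
    paired = state._pre_seq > state._post_seq
    if np.any(paired):
        dts = t - state.last_pre[paired]
        r_now = np.exp(-dts / params.tau_x)
        dw[paired] = window(dts, params.pair) + params.a3_plus * o_before * r_now
    state.last_post = t  # o set to 1
    state._post_seq = seq
    return dw


def apply_bounds(weights: np.ndarray, params: PairSTDPParams) -> np.ndarray:
    """Clip weights at ``w_min`` (always) and at ``w_max`` when configured."""
    upper = params.w_max if params.w_max is not None else np.inf
    return np.clip(weights, params.w_min, upper)
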