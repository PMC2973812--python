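"""Model parameters and their defaults.

Every quantity is held in SI-flavoured simulation units: seconds for times,
millivolts for voltages and synaptic strengths, hertz for rates.  Synaptic
strengths are expressed directly as the membrane-potential jump they inject
(the membrane resistance is absorbed into the definition), so the excitatory
weights, the inhibitory strength, and the STDP amplitudes all carry mV units.

The defaults describe a single leaky integrate-and-fire neuron driven by
250 excitatory and 200 inhibitory Poisson inputs at 10 Hz each, with
current-based exponential synapses (tau_s = 5 ms) and a pair-based STDP
window whose potentiation/depression boundary is shifted to +2 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "InputEnsembleConfig",
    "PairSTDPParams",
    "JitterParams",
    "TripletParams",
]


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters.

    Voltages are measured relative to rest, so ``v_rest = 0`` and the
    spiking threshold ``v_threshold`` is the depolarisation (mV) needed to
    fire.  On reaching threshold the neuron emits a spike and resets to
    rest; no refractory period is modelled.
    """

    tau_m: float = 20e-3  # membrane time constant (s)
    v_rest: float = 0.0  # resting potential (mV, reference point)
    v_threshold: float = 20.0  # spiking threshold (mV above rest)

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")

    @property
    def theta(self) -> float:
        """Threshold depolarisation relative to rest (mV)."""
        return self.v_threshold - self.v_rest


@dataclass(frozen=True)
class SynapseParams:
    """Current-based exponential synapses.

    Each presynaptic spike makes the corresponding synaptic drive jump by
    the synaptic strength; between spikes both the excitatory and the
    inhibitory drive decay exponentially with the shared time constant
    ``tau_s``.  The inhibitory strength ``w_inh`` is fixed (inhibitory
    synapses are not plastic).
    """

    tau_s: float = 5e-3  # synaptic time constant (s), shared E/I
    w_inh: float = 1.0  # inhibitory synaptic strength (mV)
    n_excitatory: int = 250
    n_inhibitory: int = 200

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.w_inh < 0:
            raise ValueError("w_inh must be non-negative")
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise ValueError("synapse counts must be non-negative")


@dataclass(frozen=True)
class InputEnsembleConfig:
    """Configuration of the presynaptic Poisson ensemble.

    A fraction ``correlated_fraction`` of the excitatory inputs forms a
    group with pairwise zero-lag count correlation ``correlation_coefficient``
    (built by thinning a shared generating train); the rest are independent.
    ``correlation_time_constant`` adds an exponential lag (mean, seconds) to
    each correlated spike, breaking exact synchrony; 0 keeps zero-lag
    correlations.
    """

    n_excitatory: int = 250
    n_inhibitory: int = 200
    rate_excitatory: float = 10.0  # Hz per excitatory input
    rate_inhibitory: float = 10.0  # Hz per inhibitory input
    correlated_fraction: float = 0.0
    correlation_coefficient: float = 0.2
    correlation_time_constant: float = 0.0  # s, mean exponential lag
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_excitatory < 0 or self.rate_inhibitory < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.correlation_coefficient <= 1.0:
            raise ValueError("correlation coefficient must lie in [0, 1]")
        if not 0.0 <= self.correlated_fraction <= 1.0:
            raise ValueError("correlated_fraction must lie in [0, 1]")
        if self.correlation_time_constant < 0:
            raise ValueError("correlation_time_constant must be non-negative")

    @property
    def n_correlated(self) -> int:
        return int(round(self.correlated_fraction * self.n_excitatory))


@dataclass(frozen=True)
class PairSTDPParams:
    """Shifted pair-based STDP window.

    The weight change for a nearest-neighbour pairing with time difference
    ``dt = t_post - t_pre`` is::

        dw =  a_plus  * exp(-(dt - shift) / tau_plus)   for dt >  shift
        dw = -a_minus * exp( (dt - shift) / tau_minus)  for dt <= shift

    ``shift > 0`` moves the potentiation/depression boundary so that a
    presynaptic spike closely followed by a postsynaptic spike (0 < dt <=
    shift) depresses the synapse.  ``shift = 0`` recovers the conventional
    window.  Weights are always clipped at ``w_min = 0``; ``w_max`` is only
    applied when set (used for unshifted comparison runs, which are unstable
    without bounds).
    """

    a_plus: float = 0.25  # mV, max potentiation
    a_minus: float = 0.30  # mV, max depression
    tau_plus: float = 20e-3  # s
    tau_minus: float = 14e-3  # s
    shift: float = 2e-3  # s, window shift (d >= 0)
    w_min: float = 0.0  # mV
    w_max: Optional[float] = None  # mV, only for unshifted comparison runs

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if self.w_max is not None and self.w_max <= self.w_min:
            raise ValueError("w_max must exceed w_min")


@dataclass(frozen=True)
class JitterParams:
    """Jittered (unshifted) STDP window.

    The pairing interval fed to the window is ``dt + eta`` with
    ``eta ~ N(0, sigma^2)`` drawn independently per pairing.  The base
    window has no shift; depression must exceed potentiation in amplitude
    (a_minus > a_plus) while a_plus*tau_plus > a_minus*tau_minus, so the
    jitter-averaged effective window depresses short causal intervals but
    still potentiates on balance.
    """

    sigma: float = 3e-3  # s, std of the Gaussian jitter
    base: PairSTDPParams = field(
        default_factory=lambda: PairSTDPParams(
            a_plus=0.25, a_minus=0.30, tau_plus=20e-3, tau_minus=14e-3, shift=0.0
        )
    )

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.base.shift != 0.0:
            raise ValueError("jittered STDP uses an unshifted base window")


@dataclass(frozen=True)
class TripletParams:
    """Shifted triplet STDP.

    On top of the shifted pair window, a presynaptic detector trace r_j per
    synapse (set to 1 on each presynaptic spike, decaying with tau_x) and a
    single postsynaptic detector o (set to 1 on each postsynaptic spike,
    decaying with tau_y) add multi-spike terms: a pre-post-pre ensemble
    contributes an extra depression up to a3_minus, a post-pre-post ensemble
    an extra potentiation up to a3_plus.  Trace values are read *before*
    they are reset by the triggering spike (the epsilon convention).
    """

    a3_plus: float = 0.25  # mV, max triplet potentiation
    a3_minus: float = 0.25  # mV, max triplet depression
    tau_x: float = 100e-3  # s, presynaptic detector decay
    tau_y: float = 100e-3  # s, postsynaptic detector decay
    pair: PairSTDPParams = field(default_factory=PairSTDPParams)

    def __post_init__(self) -> None:
        if min(self.a3_plus, self.a3_minus, self.tau_x, self.tau_y) <= 0:
            raise ValueError("triplet amplitudes and time constants must be positive")


def with_updates(params, **changes):
    """Return a copy of a frozen params dataclass with fields replaced."""
    return replace(params, **changes)
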