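"""Poisson and correlated-Poisson input spike trains.

Correlated groups are built by the thinning construction: a generating
Poisson train of rate ``rate / c`` is drawn once, and each member train
keeps each generating spike independently with probability ``c``.  Every
member then has rate ``rate`` and every pair of members has zero-lag count
correlation ``c``.  An optional exponential lag (independent draw per spike
per train) converts exact synchrony into temporally smeared correlations;
the mean of the lag distribution is the correlation time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import InputEnsembleConfig

__all__ = [
    "SpikeTrain",
    "poisson_train",
    "correlated_group",
    "apply_exponential_lag",
    "generate_ensemble",
    "EnsembleRealization",
    "trains_to_csv",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times on [0, duration), in seconds."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(~np.isfinite(t)):
                raise ValueError("spike times must be finite")
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted ascending")
            if t[0] < 0 or t[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Empirical rate (Hz)."""
        return self.times.size / self.duration

    def bin_counts(self, bin_width: float) -> np.ndarray:
        """Spike counts in consecutive bins of ``bin_width`` seconds."""
        n_bins = int(np.floor(self.duration / bin_width))
        return np.histogram(self.times, bins=n_bins, range=(0.0, n_bins * bin_width))[0]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def poisson_train(rate: float, duration: float, seed=0) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz on [0, duration) s."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(times=times, duration=duration)


def correlated_group(
    n: int,
    rate: float,
    c: float,
    duration: float,
    seed=0,
    mean_lag: float = 0.0,
    return_clusters: bool = False,
):
    """``n`` Poisson trains of rate ``rate`` with pairwise zero-lag correlation ``c``.

    Thinning: the generating train has rate ``rate / c`` and each member
    keeps each generating spike independently with probability ``c``.  With
    ``c = 0`` the members are independent Poisson trains; with ``c = 1``
    they are all identical to the generating train.

    ``mean_lag`` (s) applies an independent exponential lag to each kept
    spike of each member (see :func:`apply_exponential_lag`).

    When ``return_clusters`` is true, also returns the cluster sizes (the
    number of member trains sharing each generating spike) — the
    bookkeeping used to normalise the causal bump of correlated synapses.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("correlation coefficient must lie in [0, 1]")
    rng = _rng(seed)
    if c == 0.0:
        trains = [poisson_train(rate, duration, rng) for _ in range(n)]
        if mean_lag > 0:
            trains = [apply_exponential_lag(tr, mean_lag, rng) for tr in trains]
        if return_clusters:
            return trains, np.zeros(0, dtype=int)
        return trains

    generating = poisson_train(rate / c, duration, rng)
    keep = rng.random((generating.times.size, n)) < c
    trains = []
    for j in range(n):
        t = generating.times[keep[:, j]]
        tr = SpikeTrain(times=t, duration=duration)
        if mean_lag > 0:
            tr = apply_exponential_lag(tr, mean_lag, rng)
        trains.append(tr)
    if return_clusters:
        return trains, keep.sum(axis=1)
    return trains


def apply_exponential_lag(train: SpikeTrain, mean_lag: float, seed=0) -> SpikeTrain:
    """Shift every spike by an independent Exp(mean_lag) draw (seconds).

    The result is re-sorted; spikes pushed past the train duration are
    dropped (negligible for durations much longer than the lag).
    ``mean_lag = 0`` returns the input unchanged.
    """
    if mean_lag < 0:
        raise ValueError("mean_lag must be non-negative")
    if mean_lag == 0 or train.times.size == 0:
        return train
    rng = _rng(seed)
    shifted = train.times + rng.exponential(mean_lag, size=train.times.size)
    shifted = np.sort(shifted[shifted < train.duration])
    return SpikeTrain(times=shifted, duration=train.duration)


@dataclass
class EnsembleRealization:
    """One realization of the full presynaptic ensemble.

    ``excitatory`` holds one train per excitatory synapse; indices
    ``0 .. n_correlated-1`` belong to the correlated group.  ``inhibitory``
    holds one train per inhibitory synapse.  ``cluster_sizes`` records, for
    each generating spike of the correlated group, how many member trains
    kept it (empty when there is no correlated group).
    """

    excitatory: list
    inhibitory: list
    n_correlated: int
    cluster_sizes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def correlated_indices(self) -> np.ndarray:
        return np.arange(self.n_correlated)

    @property
    def group_labels(self) -> np.ndarray:
        """Boolean mask over excitatory synapses: True = correlated group."""
        lab = np.zeros(len(self.excitatory), dtype=bool)
        lab[: self.n_correlated] = True
        return lab

    @property
    def mean_cluster_size(self) -> float:
        """Average number of correlated-group spikes sharing a generating event."""
        sizes = self.cluster_sizes[self.cluster_sizes > 0]
        return float(sizes.mean()) if sizes.size else 1.0


def generate_ensemble(config: InputEnsembleConfig, duration: float, seed=None) -> EnsembleRealization:
    """Draw the full input ensemble described by ``config`` for ``duration`` s."""
    rng = _rng(config.seed if seed is None else seed)
    n_corr = config.n_correlated
    cluster_sizes = np.zeros(0, dtype=int)
    excitatory: list = []
    if n_corr > 0 and config.correlation_coefficient > 0:
        corr, cluster_sizes = correlated_group(
            n_corr,
            config.rate_excitatory,
            config.correlation_coefficient,
            duration,
            rng,
            mean_lag=config.correlation_time_constant,
            return_clusters=True,
        )
        excitatory.extend(corr)
    else:
        excitatory.extend(
            poisson_train(config.rate_excitatory, duration, rng) for _ in range(n_corr)
        )
    excitatory.extend(
        poisson_train(config.rate_excitatory, duration, rng)
        for _ in range(config.n_excitatory - n_corr)
    )
    inhibitory = [
        poisson_train(config.rate_inhibitory, duration, rng)
        for _ in range(config.n_inhibitory)
    ]
    return EnsembleRealization(
        excitatory=excitatory,
        inhibitory=inhibitory,
        n_correlated=n_corr,
        cluster_sizes=cluster_sizes,
    )


def trains_to_csv(trains, path) -> None:
    """Write trains as two-column CSV (time_s, channel_id)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "channel_id"])
        for ch, tr in enumerate(trains):
            for t in tr.times:
                writer.writerow([f"{t:.6f}", ch])
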