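"""Measurements on simulation output.

Weight-distribution summaries and modality classification, steady-state
detection by moment convergence, interspike-interval regularity, the
causal bump of the pre->post pairing-interval histogram, competition
outcomes between correlated and uncorrelated synapse groups, and
localization of the transition point along a parameter scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .spike_gen import SpikeTrain

__all__ = [
    "WeightDistributionSummary",
    "CompetitionOutcome",
    "CausalBump",
    "summarize_weights",
    "steady_state_reached",
    "classify_modality",
    "isi_cv",
    "causal_bump",
    "competition_outcome",
    "find_transition",
]


@dataclass(frozen=True)
class WeightDistributionSummary:
    moments: tuple  # (m1, m2, m3) raw moments in mV, mV^2, mV^3
    histogram: np.ndarray
    bin_edges: np.ndarray
    modality: str  # unimodal | bimodal | degenerate


@dataclass(frozen=True)
class CompetitionOutcome:
    mean_correlated: float
    mean_uncorrelated: float
    winner: str  # correlated | uncorrelated | tie

    @property
    def difference(self) -> float:
        """Signed difference, correlated minus uncorrelated (mV)."""
        return self.mean_correlated - self.mean_uncorrelated


@dataclass(frozen=True)
class CausalBump:
    """Excess of short-latency causal pairings over the acausal baseline."""

    lags: np.ndarray  # bin centres (s), positive lags
    bump: np.ndarray  # baseline-subtracted density (per s, per pre spike)
    baseline_rate: float  # fitted acausal exponential decay rate (Hz)
    normalization: str  # per-spike | per-cluster

    @property
    def area(self) -> float:
        return float(np.trapezoid(np.maximum(self.bump, 0.0), self.lags))

    @property
    def peak_latency(self) -> float:
        return float(self.lags[int(np.argmax(self.bump))])


def summarize_weights(weights, bounds=None, n_bins: int = 50) -> WeightDistributionSummary:
    w = np.asarray(weights, dtype=float)
    lo = 0.0 if bounds is None else bounds[0]
    hi = w.max() * 1.05 + 1e-12 if bounds is None or bounds[1] is None else bounds[1]
    hist, edges = np.histogram(w, bins=n_bins, range=(lo, hi))
    return WeightDistributionSummary(
        moments=(float(np.mean(w)), float(np.mean(w**2)), float(np.mean(w**3))),
        histogram=hist,
        bin_edges=edges,
        modality=classify_modality(w, bounds=bounds),
    )


def steady_state_reached(
    snapshot_times,
    snapshots,
    post_spikes: SpikeTrain,
    window: float,
    tol: float = 0.02,
) -> bool:
    """True when weight moments and firing rate have stopped drifting.

    Compares the first three raw moments of the weight distribution and the
    postsynaptic rate between the last two non-overlapping windows of
    ``window`` seconds; each must change by less than ``tol`` (relative).
    The k-th moment is compared on the common mV scale (m_k^(1/k)), so the
    tolerance means the same thing for all three; the raw third moment of a
    finite synapse population carries sampling noise several times larger
    than its first-moment equivalent.
    """
    times = np.asarray(snapshot_times, dtype=float)
    snaps = np.asarray(snapshots, dtype=float)
    t_end = times[-1] if times.size else 0.0
    if times.size < 2 or t_end < 2 * window:
        raise ValueError("need snapshots spanning at least two comparison windows")
    m_prev = (times > t_end - 2 * window) & (times <= t_end - window)
    m_last = times > t_end - window
    if not (m_prev.any() and m_last.any()):
        raise ValueError("windows contain no snapshots; lower `window`")

    def moments(mask):
        w = snaps[mask]
        return np.array([
            np.mean(w),
            np.sqrt(np.mean(w**2)),
            np.cbrt(np.mean(w**3)),
        ])

    mom_prev, mom_last = moments(m_prev), moments(m_last)
    rate_prev = np.sum(
        (post_spikes.times > t_end - 2 * window) & (post_spikes.times <= t_end - window)
    ) / window
    rate_last = np.sum(post_spikes.times > t_end - window) / window
    rel_mom = np.abs(mom_last - mom_prev) / np.maximum(np.abs(mom_prev), 1e-12)
    if np.any(rel_mom >= tol):
        return False
    rate_ref = max(rate_prev, 1e-9)
    return bool(abs(rate_last - rate_prev) / rate_ref < tol)


def classify_modality(
    weights,
    bounds=None,
    rel_mode_threshold: float = 0.05,
    bound_mass_threshold: float = 0.10,
) -> str:
    """Label a weight sample unimodal, bimodal (U-shaped) or degenerate.

    Mass piled against *both* active bounds (each more than 10% of synapses
    within 5% of a bound) is the signature of the U-shaped distribution of
    bounded unstable STDP and counts as bimodal directly.  Otherwise the
    sample is kernel-smoothed (Gaussian, Silverman bandwidth) and interior
    modes exceeding 5% of the main mode's density are counted.
    The label is invariant to permutation and uniform rescaling.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 100:
        raise ValueError("need at least 100 weights to classify modality")
    if np.ptp(w) < 1e-12 * max(abs(w).max(), 1.0):
        return "degenerate"
    lo = 0.0 if bounds is None else bounds[0]
    hi = None if bounds is None else bounds[1]
    span = (hi - lo) if hi is not None else np.ptp(w)
    frac_lo = np.mean(w <= lo + 0.05 * span)
    if hi is not None:
        frac_hi = np.mean(w >= hi - 0.05 * span)
        if frac_lo > bound_mass_threshold and frac_hi > bound_mass_threshold:
            return "bimodal"
    scale = np.std(w)
    kde = stats.gaussian_kde(w / scale, bw_method="silverman")
    grid = np.linspace(w.min() / scale, w.max() / scale, 512)
    dens = kde(grid)
    peaks = [
        i
        for i in range(1, grid.size - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if not peaks:
        return "unimodal"
    main = max(dens[peaks])
    # count modes separated by a genuine valley (below 80% of the smaller peak)
    strong = [i for i in peaks if dens[i] > rel_mode_threshold * main]
    n_modes = 1
    for a, b in zip(strong[:-1], strong[1:]):
        valley = dens[a:b + 1].min()
        if valley < 0.8 * min(dens[a], dens[b]):
            n_modes += 1
    return "unimodal" if n_modes == 1 else "bimodal"


def isi_cv(post_spikes: SpikeTrain, min_isis: int = 100) -> float:
    """Coefficient of variation of the interspike intervals.

    0 for perfectly periodic firing; ~1 for Poisson firing.  Small CV is
    the signature of the mean-driven regime, large CV of the
    fluctuation-driven regime.
    """
    isis = np.diff(post_spikes.times)
    if isis.size < min_isis:
        raise ValueError(f"need at least {min_isis} interspike intervals, got {isis.size}")
    return float(np.std(isis) / np.mean(isis))


def _nearest_following_lag(pre_times: np.ndarray, post_times: np.ndarray) -> np.ndarray:
    """Lag from each pre spike to the next post spike, adjacent pairs only.

    A pair is dropped when another spike of the same pre train intervenes,
    so the baseline interval density decays at nu_ex + nu_post (the
    adjacent-event pairing convention of the plasticity rules).
    """
    idx = np.searchsorted(post_times, pre_times, side="right")
    ok = idx < post_times.size
    lag = post_times[idx[ok]] - pre_times[ok]
    t_pre = pre_times[ok]
    next_pre = np.full(t_pre.size, np.inf)
    same = np.flatnonzero(ok)
    has_next = same + 1 < pre_times.size
    next_pre[has_next] = pre_times[same[has_next] + 1]
    return lag[t_pre + lag <= next_pre]


def _nearest_preceding_lag(pre_times: np.ndarray, post_times: np.ndarray) -> np.ndarray:
    """Lag from each pre spike back to the previous post spike (positive),
    adjacent pairs only (no intervening spike of the same pre train)."""
    idx = np.searchsorted(post_times, pre_times, side="left") - 1
    ok = idx >= 0
    lag = pre_times[ok] - post_times[idx[ok]]
    t_pre = pre_times[ok]
    prev_pre = np.full(t_pre.size, -np.inf)
    same = np.flatnonzero(ok)
    has_prev = same - 1 >= 0
    prev_pre[has_prev] = pre_times[same[has_prev] - 1]
    return lag[t_pre - lag >= prev_pre]


def causal_bump(
    pre_trains: Sequence[SpikeTrain],
    post_spikes: SpikeTrain,
    max_lag: float = 50e-3,
    bin_width: float = 0.5e-3,
    cluster_norm: bool = False,
    cluster_size: float = 1.0,
    baseline_window=(5e-3, 50e-3),
) -> CausalBump:
    """Histogram of nearest-neighbour pre->post latencies minus the acausal baseline.

    The baseline is an exponential  a * exp(-r * lag)  fitted to the
    *negative*-lag (pre after post) nearest-neighbour histogram on
    ``baseline_window``; its decay rate estimates nu_ex + nu_post.  The
    positive-lag histogram minus this baseline is the causal bump — the
    excess probability that the presynaptic spike itself evoked the
    postsynaptic one.  With ``cluster_norm`` the bump is divided by the
    average synchronous-cluster size, making correlated-group bumps
    comparable per contributing spike.
    """
    if not pre_trains or len(post_spikes) == 0:
        raise ValueError("need non-empty pre trains and post spikes")
    post = post_spikes.times
    fwd = np.concatenate([_nearest_following_lag(tr.times, post) for tr in pre_trains])
    bwd = np.concatenate([_nearest_preceding_lag(tr.times, post) for tr in pre_trains])
    n_pre = sum(len(tr) for tr in pre_trains)
    edges = np.arange(0.0, max_lag + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h_fwd = np.histogram(fwd, bins=edges)[0] / (n_pre * bin_width)
    h_bwd = np.histogram(bwd, bins=edges)[0] / (n_pre * bin_width)

    lo, hi = baseline_window
    mask = (centers >= lo) & (centers <= hi) & (h_bwd > 0)
    if mask.sum() < 5:
        raise ValueError("not enough acausal counts to fit the baseline")
    coef = np.polyfit(centers[mask], np.log(h_bwd[mask]), 1)
    rate = -coef[0]
    baseline = np.exp(coef[1] + coef[0] * centers)
    bump = h_fwd - baseline
    norm = "per-spike"
    if cluster_norm:
        bump = bump / max(cluster_size, 1.0)
        norm = "per-cluster"
    return CausalBump(lags=centers, bump=bump, baseline_rate=float(rate), normalization=norm)


def competition_outcome(
    weights, group_labels, tie_tolerance: float = 0.05
) -> CompetitionOutcome:
    """Compare mean strengths of the correlated vs uncorrelated groups.

    ``group_labels`` is a boolean mask (True = correlated).  The winner is
    a tie when the relative difference of the group means is below
    ``tie_tolerance``.
    """
    w = np.asarray(weights, dtype=float)
    lab = np.asarray(group_labels, dtype=bool)
    if lab.shape != w.shape:
        raise ValueError("group labels must match the weight vector")
    if not lab.any() or lab.all():
        raise ValueError("both groups must be non-empty")
    mc = float(w[lab].mean())
    mu = float(w[~lab].mean())
    ref = max(abs(mc), abs(mu), 1e-12)
    if abs(mc - mu) / ref < tie_tolerance:
        winner = "tie"
    else:
        winner = "correlated" if mc > mu else "uncorrelated"
    return CompetitionOutcome(mean_correlated=mc, mean_uncorrelated=mu, winner=winner)


def find_transition(x_values, signed_differences) -> float:
    """Interpolated zero crossing of a signed outcome along a scan.

    Requires exactly one sign change across the scan; returns the linearly
    interpolated crossing point.  Raises when the differences never change
    sign ("no transition in scanned range") or change sign more than once.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(signed_differences, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x and difference arrays of length >= 2")
    signs = np.sign(y)
    nz = signs != 0
    changes = [
        i
        for i in range(x.size - 1)
        if nz[i] and nz[i + 1] and signs[i] != signs[i + 1]
    ]
    if not changes:
        raise ValueError("no transition in scanned range")
    if len(changes) > 1:
        raise ValueError("multiple sign changes in scanned range")
    i = changes[0]
    return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
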