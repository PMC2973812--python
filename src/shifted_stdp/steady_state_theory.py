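"""Fokker-Planck steady-state theory for shifted pair-based STDP.

The strength w of one synapse performs a random walk driven by
nearest-neighbour pre/post pairings.  With pairing-interval rate density
R(dt | w) and window W(dt), the drift and diffusion of the walk are

    A(w) = integral W(dt)   R(dt | w) d(dt)
    B(w) = integral W(dt)^2 R(dt | w) d(dt) .

For Poisson pre and post trains the acausal part of R decays as
exp(-lambda |dt|) with lambda = nu_ex + nu_post (adjacent-event pairing:
no intervening spike of either train).  For dt > 0 the synapse adds a
causal bump: a presynaptic spike of strength w transiently raises the
postsynaptic intensity by

    (nu_post * tau_s / mu) * w * K(t),     K(t) = exp(-t/tau_bump)/tau_bump,

the linear-Poisson response gain (the rate responds proportionally to the
time-integrated depolarisation w*tau_s relative to the mean drive mu)
concentrated on the evoked-spike latency scale tau_bump (~2 ms at the
near-threshold operating point; the bump has first-passage character, not
the full EPSP width).  The nearest-neighbour survival factor depletes
later pairings correspondingly.  To first order in w both A and B are
then linear, A(w) = a_A + b_A w (likewise B), and the zero-flux
stationary solution of the Fokker-Planck equation is a shifted gamma
density

    p(w) ~ (a_B + b_B w)^(c-1) * exp(2 b_A w / b_B),
    c = 2 (a_A b_B - a_B b_A) / b_B^2 .

Normalizability requires b_A < 0 (restoring drift: the causal bump of a
strong synapse pushes enough pairings into the depression region) and
c > 0 (which needs a_A > 0, i.e. A+ tau+ sufficiently greater than
A- tau-, the opposite of the conventional unshifted stability condition).
The mean of the gamma form is exactly -a_A / b_A.

The postsynaptic rate depends on the mean weight through the mean-driven
integrate-and-fire rate formula

    nu_post = 1 / (tau_m * ln(mu / (mu - theta))),
    mu = tau_s * (N_E nu_ex w_mean - N_I nu_in w_inh)

(0 when mu <= theta), and the mean weight depends on the rate through the
drift balance; :func:`fixed_point` solves the coupled pair.

Known limitation, stated for honesty: the Poisson-post assumption and the
first-order (fixed-shape) bump underestimate the restoring force that the
simulation's bump sharpening provides, so the analytic rate
underestimates and the analytic distribution is broader than the
simulated one; the analytic mean weight agrees well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, stats

from .params import NeuronParams, PairSTDPParams, SynapseParams

__all__ = [
    "PairingDensityParams",
    "DriftDiffusion",
    "StationaryDistribution",
    "FixedPoint",
    "pairing_intensity",
    "pairing_density",
    "drift_diffusion",
    "drift_at",
    "diffusion_at",
    "stationary_distribution",
    "postsynaptic_rate",
    "mean_input",
    "fixed_point",
    "rate_curve",
]

DEFAULT_TAU_BUMP = 2e-3  # s, evoked-spike latency scale of the causal bump


@dataclass(frozen=True)
class PairingDensityParams:
    """Inputs of the pairing-interval density for a single synapse.

    ``mu`` is the mean free-membrane drive (mV above rest) entering the
    linear-Poisson bump gain; ``tau_bump`` the latency scale of the
    evoked-spike kernel; ``w`` the strength of the synapse whose causal
    bump is being described (0 = pure acausal density).
    """

    nu_ex: float  # Hz, presynaptic rate of this synapse
    nu_post: float  # Hz, postsynaptic rate
    tau_s: float = 5e-3  # s, synaptic time constant (response integral)
    mu: float = 25.0  # mV, mean drive (gain normalisation)
    tau_bump: float = DEFAULT_TAU_BUMP  # s, causal-bump kernel width
    w: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.nu_ex < 0 or self.nu_post < 0:
            raise ValueError("rates must be non-negative")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.mu <= 0 or self.tau_s <= 0 or self.tau_bump <= 0:
            raise ValueError("mu, tau_s, tau_bump must be positive")

    @property
    def lambda_sum(self) -> float:
        """Acausal decay rate: nu_ex + nu_post (Hz)."""
        return self.nu_ex + self.nu_post

    @property
    def bump_gain(self) -> float:
        """Linear-Poisson gain per mV of synaptic strength."""
        return self.nu_post * self.tau_s / self.mu


def pairing_intensity(delta_t, p: PairingDensityParams):
    """Rate density of nearest-neighbour pairings at interval ``delta_t`` (per s^2).

    Full (non-linearised) form: the acausal side is
    nu_ex * nu_post * exp(lambda dt) for dt < 0; for dt > 0 the
    postsynaptic intensity nu(t) = nu_post + g0 w K(t) multiplies the
    survival factor exp(-nu_ex t - nu_post t - g0 w Kc(t)), with
    K(t) = exp(-t/tau_bump)/tau_bump and Kc its integral.
    """
    dt = np.asarray(delta_t, dtype=float)
    lam = p.lambda_sum
    gw = p.bump_gain * p.w
    neg = p.nu_ex * p.nu_post * np.exp(lam * np.minimum(dt, 0.0))
    tpos = np.maximum(dt, 0.0)
    k = np.exp(-tpos / p.tau_bump) / p.tau_bump
    kc = 1.0 - np.exp(-tpos / p.tau_bump)
    pos = p.nu_ex * (p.nu_post + gw * k) * np.exp(-lam * tpos - gw * kc)
    out = np.where(dt < 0, neg, pos)
    if np.ndim(delta_t) == 0:
        return float(out)
    return out


def _intensity_norm(p: PairingDensityParams) -> float:
    lam = p.lambda_sum
    neg_mass = p.nu_ex * p.nu_post / lam
    pos_mass = integrate.quad(
        lambda t: pairing_intensity(t, p), 0.0, 50.0 / max(lam, 1.0), limit=400
    )[0]
    return neg_mass + pos_mass


def pairing_density(delta_t, p: PairingDensityParams):
    """Probability density of nearest-neighbour pairing intervals (per s).

    The normalised version of :func:`pairing_intensity`; for w = 0 it is
    the symmetric two-sided exponential (lambda/2) exp(-lambda |dt|), and
    a positive w adds the causal bump at dt > 0 ("the stronger the
    synapse, the larger the bump").
    """
    return pairing_intensity(delta_t, p) / _intensity_norm(p)


@dataclass(frozen=True)
class DriftDiffusion:
    """Linear drift/diffusion coefficients: A(w)=a_A+b_A w, B(w)=a_B+b_B w.

    Units: A in mV/s, B in mV^2/s, slopes per second.
    """

    a_A: float
    b_A: float
    a_B: float
    b_B: float

    def drift(self, w):
        return self.a_A + self.b_A * np.asarray(w, dtype=float)

    def diffusion(self, w):
        return self.a_B + self.b_B * np.asarray(w, dtype=float)


# --- exact piecewise-exponential integrals -------------------------------
#
# Every coefficient is an integral of  Wpow(t) * exp(-lam t) * phi(t)  over
# t in [0, inf) plus the acausal side, where Wpow is the window (or its
# square) and phi is 1, K(t) or Kc(t) — all sums of exponentials.  The
# helpers integrate c * exp(rho t) exactly over [0, d] and [d, inf).


def _seg(c: float, rho: float, d: float) -> float:
    """integral_0^d c e^{rho t} dt."""
    if d == 0.0:
        return 0.0
    if rho == 0.0:
        return c * d
    return c * (math.exp(rho * d) - 1.0) / rho


def _tail(c: float, rho: float, d: float) -> float:
    """integral_d^inf c e^{rho t} dt (rho < 0)."""
    if rho >= 0:
        raise ValueError("tail integral requires negative exponent")
    return -c * math.exp(rho * d) / rho


def _window_phi_integral(
    amp_p: float, amp_m: float, tau_p: float, tau_m_: float, d: float,
    lam: float, phi_terms,
) -> float:
    """integral_0^inf W(t) e^{-lam t} phi(t) dt for phi = sum c_k e^{rho_k t}.

    W(t) = -amp_m e^{(t-d)/tau_m_} on [0, d], amp_p e^{-(t-d)/tau_p} on (d, inf).
    """
    total = 0.0
    for c_k, rho_k in phi_terms:
        total += _seg(-amp_m * math.exp(-d / tau_m_) * c_k, 1.0 / tau_m_ - lam + rho_k, d)
        total += _tail(amp_p * math.exp(d / tau_p) * c_k, -1.0 / tau_p - lam + rho_k, d)
    return total


def _acausal_neg_integral(amp_p, amp_m, tau_p, tau_m_, d, lam) -> float:
    """integral_{-inf}^0 W(dt) e^{lam dt} d(dt); for d >= 0 only depression."""
    return -amp_m * math.exp(-d / tau_m_) / (lam + 1.0 / tau_m_)


def drift_diffusion(p: PairingDensityParams, stdp: PairSTDPParams) -> DriftDiffusion:
    """Closed-form linear drift/diffusion coefficients.

    a_* collect the acausal pairings (both signs of dt); b_* collect the
    first-order-in-w causal bump minus the nearest-neighbour depletion it
    causes among later pairings.  Valid in the Taylor regime
    bump_gain * w << 1.
    """
    lam = p.lambda_sum
    d = stdp.shift
    one = [(1.0, 0.0)]
    k_kernel = [(1.0 / p.tau_bump, -1.0 / p.tau_bump)]
    kc_kernel = [(1.0, 0.0), (-1.0, -1.0 / p.tau_bump)]
    g0 = p.bump_gain

    def coeffs(amp_p, amp_m, tau_p, tau_m_):
        acausal = p.nu_ex * p.nu_post * (
            _acausal_neg_integral(amp_p, amp_m, tau_p, tau_m_, d, lam)
            + _window_phi_integral(amp_p, amp_m, tau_p, tau_m_, d, lam, one)
        )
        bump = _window_phi_integral(amp_p, amp_m, tau_p, tau_m_, d, lam, k_kernel)
        depl = _window_phi_integral(amp_p, amp_m, tau_p, tau_m_, d, lam, kc_kernel)
        causal = p.nu_ex * g0 * (bump - p.nu_post * depl)
        return acausal, causal

    a_A, b_A = coeffs(stdp.a_plus, stdp.a_minus, stdp.tau_plus, stdp.tau_minus)
    # W^2: amplitudes squared, time constants halved, depression sign positive
    a_B, b_B = coeffs(
        stdp.a_plus**2, -stdp.a_minus**2, stdp.tau_plus / 2.0, stdp.tau_minus / 2.0
    )
    return DriftDiffusion(a_A=a_A, b_A=b_A, a_B=a_B, b_B=b_B)


def drift_at(w: float, p: PairingDensityParams, stdp: PairSTDPParams) -> float:
    """Drift A(w) by direct quadrature of the *full* pairing intensity.

    Independent cross-check of the closed-form linear coefficients.
    """
    from .stdp_rules import window

    pw = PairingDensityParams(p.nu_ex, p.nu_post, p.tau_s, p.mu, p.tau_bump, w)
    lam = pw.lambda_sum
    span = 50.0 / max(lam, 1.0)
    neg = integrate.quad(
        lambda t: window(-t, stdp) * pairing_intensity(-t, pw), 0, span, limit=400
    )[0]
    pos = integrate.quad(
        lambda t: window(t, stdp) * pairing_intensity(t, pw), 0, span,
        limit=400, points=[stdp.shift],
    )[0]
    return neg + pos


def diffusion_at(w: float, p: PairingDensityParams, stdp: PairSTDPParams) -> float:
    """Diffusion B(w) by direct quadrature of the full pairing intensity."""
    from .stdp_rules import window

    pw = PairingDensityParams(p.nu_ex, p.nu_post, p.tau_s, p.mu, p.tau_bump, w)
    lam = pw.lambda_sum
    span = 50.0 / max(lam, 1.0)
    neg = integrate.quad(
        lambda t: window(-t, stdp) ** 2 * pairing_intensity(-t, pw), 0, span, limit=400
    )[0]
    pos = integrate.quad(
        lambda t: window(t, stdp) ** 2 * pairing_intensity(t, pw), 0, span,
        limit=400, points=[stdp.shift],
    )[0]
    return neg + pos


@dataclass(frozen=True)
class StationaryDistribution:
    """Gamma-form stationary weight distribution with stability flags.

    The density is a gamma with shape ``c``, scale ``-b_B / (2 b_A)`` and
    support starting at ``-a_B / b_B`` (slightly negative: the analytic
    form assigns a small probability to negative strengths, which the
    simulations do not allow).  ``stable`` is False when either positivity
    condition fails, in which case the density cannot be normalised
    (runaway strengths).
    """

    dd: DriftDiffusion
    shape: float
    loc: float
    scale: Optional[float]
    stable_drift: bool  # b_A < 0 (with b_B > 0): restoring drift
    stable_shape: bool  # gamma shape c > 0 (needs a_A large enough)
    stable: bool

    @property
    def gamma(self):
        if not self.stable:
            raise ValueError("unstable parameter set: no normalizable density")
        return stats.gamma(a=self.shape, loc=self.loc, scale=self.scale)

    @property
    def mean(self) -> float:
        """Mean weight; equals -a_A/b_A exactly for the gamma form."""
        return -self.dd.a_A / self.dd.b_A

    @property
    def std(self) -> float:
        return float(self.gamma.std())

    def pdf(self, w):
        return self.gamma.pdf(w)

    def truncated_pdf(self, w):
        """Density truncated and renormalised on w >= 0, for comparison
        with simulations (which clip at zero strength)."""
        g = self.gamma
        mass = 1.0 - g.cdf(0.0)
        w = np.asarray(w, dtype=float)
        return np.where(w >= 0, g.pdf(w) / mass, 0.0)

    def truncated_cdf(self, w):
        g = self.gamma
        c0 = g.cdf(0.0)
        w = np.asarray(w, dtype=float)
        return np.clip((g.cdf(np.maximum(w, 0.0)) - c0) / (1.0 - c0), 0.0, 1.0)


def stationary_distribution(dd: DriftDiffusion) -> StationaryDistribution:
    """Zero-flux stationary solution of the Fokker-Planck equation.

    Solving A p = (1/2) d(Bp)/dw with linear A and B gives the shifted
    gamma density described in the module docstring.
    """
    if not all(np.isfinite(x) for x in (dd.a_A, dd.b_A, dd.a_B, dd.b_B)):
        raise ValueError("drift/diffusion coefficients must be finite")
    stable_drift = dd.b_A < 0 and dd.b_B > 0
    if dd.b_B != 0:
        shape = 2.0 * (dd.a_A * dd.b_B - dd.a_B * dd.b_A) / dd.b_B**2
        loc = -dd.a_B / dd.b_B
    else:
        shape, loc = np.nan, np.nan
    stable_shape = bool(np.isfinite(shape) and shape > 0)
    stable = stable_drift and stable_shape
    scale = -dd.b_B / (2.0 * dd.b_A) if stable else None
    return StationaryDistribution(
        dd=dd, shape=float(shape), loc=float(loc), scale=scale,
        stable_drift=bool(stable_drift), stable_shape=stable_shape, stable=stable,
    )


def mean_input(
    w_mean: float, nu_ex: float, nu_in: float,
    neuron: NeuronParams, synapses: SynapseParams,
) -> float:
    """Mean free-membrane drive mu (mV above rest) for mean weight w_mean."""
    return synapses.tau_s * (
        synapses.n_excitatory * nu_ex * w_mean
        - synapses.n_inhibitory * nu_in * synapses.w_inh
    )


def postsynaptic_rate(
    w_mean: float, nu_ex: float, nu_in: float,
    neuron: NeuronParams, synapses: SynapseParams,
) -> float:
    """Mean-driven integrate-and-fire rate (Hz); 0 below threshold."""
    mu = mean_input(w_mean, nu_ex, nu_in, neuron, synapses)
    if mu <= neuron.theta:
        return 0.0
    return 1.0 / (neuron.tau_m * math.log(mu / (mu - neuron.theta)))


@dataclass(frozen=True)
class FixedPoint:
    """Self-consistent steady state: postsynaptic rate and mean weight."""

    nu_post: float  # Hz
    w_mean: float  # mV
    converged: bool
    iterations: int

    def residuals(self, nu_ex, nu_in, neuron, synapses, stdp,
                  tau_bump: float = DEFAULT_TAU_BUMP):
        """(rate residual, drift-balance residual) at the fixed point."""
        r1 = self.nu_post - postsynaptic_rate(self.w_mean, nu_ex, nu_in, neuron, synapses)
        mu = mean_input(self.w_mean, nu_ex, nu_in, neuron, synapses)
        p = PairingDensityParams(nu_ex, self.nu_post, synapses.tau_s, mu, tau_bump)
        dd = drift_diffusion(p, stdp)
        r2 = dd.drift(self.w_mean)
        return r1, r2


def fixed_point(
    nu_ex: float,
    nu_in: float,
    neuron: NeuronParams,
    synapses: SynapseParams,
    stdp: PairSTDPParams,
    tau_bump: float = DEFAULT_TAU_BUMP,
    w_max_bracket: float = 20.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> FixedPoint:
    """Solve the coupled rate/mean-weight steady state.

    The self-consistency residual  w*(w) - w  (w* = drift-balance weight
    at the rate implied by w) changes sign across the root; it is
    bracketed on a grid densified near the mean-driven threshold wall and
    solved by Brent's method.  The drift-balance map is far too steep near
    the root for plain damped iteration; a damped sweep (factor 0.5) is
    kept only as a fallback.  Raises when neither converges.
    """
    from scipy.optimize import brentq

    if nu_ex == 0:
        return FixedPoint(nu_post=0.0, w_mean=0.0, converged=True, iterations=0)

    def resid(wm: float) -> float:
        nu = postsynaptic_rate(wm, nu_ex, nu_in, neuron, synapses)
        if nu <= 0:
            return np.nan
        mu = mean_input(wm, nu_ex, nu_in, neuron, synapses)
        p = PairingDensityParams(nu_ex, nu, synapses.tau_s, mu, tau_bump)
        dd = drift_diffusion(p, stdp)
        if dd.b_A >= 0:
            return np.nan
        return -dd.a_A / dd.b_A - wm

    w_lo = (neuron.theta / synapses.tau_s + synapses.n_inhibitory * nu_in * synapses.w_inh) / (
        synapses.n_excitatory * nu_ex
    )
    ws = np.concatenate([
        np.geomspace(w_lo * 1.00002, w_lo * 1.05, 150),
        np.linspace(w_lo * 1.05, w_lo + w_max_bracket, 400),
    ])
    rs = np.array([resid(w) for w in ws])
    for i in range(ws.size - 1):
        if np.isfinite(rs[i]) and np.isfinite(rs[i + 1]) and rs[i] > 0 and rs[i + 1] < 0:
            w = brentq(resid, ws[i], ws[i + 1], xtol=1e-13)
            nu = postsynaptic_rate(w, nu_ex, nu_in, neuron, synapses)
            return FixedPoint(nu_post=nu, w_mean=float(w), converged=True, iterations=i)
    # damped-iteration fallback
    w = w_lo * 1.01
    for it in range(max_iter):
        r = resid(w)
        if not np.isfinite(r):
            w *= 1.1
            if w > w_lo + w_max_bracket:
                break
            continue
        w_new = w + 0.5 * r
        if not np.isfinite(w_new) or w_new <= 0 or w_new > w_lo + 10 * w_max_bracket:
            break  # diverging iterate: no fixed point in range
        if abs(w_new - w) < tol * max(abs(w), 1e-12):
            nu = postsynaptic_rate(w_new, nu_ex, nu_in, neuron, synapses)
            return FixedPoint(nu_post=nu, w_mean=float(w_new), converged=True, iterations=it)
        w = w_new
    raise RuntimeError(
        f"fixed point did not converge for nu_ex={nu_ex}, nu_in={nu_in}: "
        "no bracketed root and damped iteration failed"
    )


def rate_curve(
    nu_ex_grid,
    nu_in: float,
    neuron: NeuronParams,
    synapses: SynapseParams,
    stdp: PairSTDPParams,
    tau_bump: float = DEFAULT_TAU_BUMP,
):
    """Steady-state postsynaptic rate over a grid of excitatory input rates.

    Returns (rates_hz, mean_weights_mv); entries are NaN where no stable
    fixed point exists.  The curve is non-monotone: rate buffering through
    the sharpening acausal pairing density makes the equilibrated rate
    fall again at high excitatory input rates, and below the peak the
    mean-driven constraint caps the rate.
    """
    rates = np.full(len(nu_ex_grid), np.nan)
    weights = np.full(len(nu_ex_grid), np.nan)
    for i, nx in enumerate(nu_ex_grid):
        try:
            fp = fixed_point(nx, nu_in, neuron, synapses, stdp, tau_bump=tau_bump)
        except RuntimeError:
            continue
        rates[i] = fp.nu_post
        weights[i] = fp.w_mean
    return rates, weights
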