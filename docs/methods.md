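# Methods

## Model

A single leaky integrate-and-fire neuron receives `N_E = 250` excitatory
and `N_I = 200` inhibitory Poisson spike trains.  The membrane potential,
measured relative to rest, obeys

    tau_m dV/dt = -V + g_ex(t) - g_in(t),        tau_m = 20 ms,

with spiking threshold `theta = 20 mV` and reset to rest; no refractory
period.  Synapses are current-based: each presynaptic spike makes the
corresponding drive jump by its strength (mV; the membrane resistance is
absorbed into the weights) and both drives decay with the shared synaptic
time constant `tau_s = 5 ms`.  Inhibitory strengths are fixed at
`w_inh = 1.5 mV`; excitatory strengths are plastic, initialized uniformly
on 1–5 mV, and clipped at zero.  Default input rates are 10 Hz per train
on both populations.

### Pair-based shifted STDP

A pairing with time difference `dt = t_post - t_pre` changes the synapse by

    dw =  A+ exp(-(dt - d)/tau+)   for dt > d
    dw = -A- exp( (dt - d)/tau-)   for dt <= d

with `A+ = 0.25 mV`, `A- = 0.30 mV`, `tau+ = 20 ms`, `tau- = 14 ms` and
window shift `d = 2 ms` by default.  The boundary `dt = d` belongs to the
depression branch, so a presynaptic spike whose evoked postsynaptic spike
follows within the shift depresses the synapse — the mechanism that makes
strong synapses self-limiting.

Pairing is nearest-neighbour in the *adjacent-event* (reduced) sense: on
each synapse only consecutive events of opposite type pair, and each
adjacency is used once.  Two consequences are load-bearing: the
pairing-interval density of independent Poisson trains decays at
`lambda = nu_ex + nu_post` on both sides, and the total potentiation a
synapse can collect saturates as the postsynaptic rate grows (each pre
spike opens at most one potentiation opportunity).  The latter is the
rate-buffering mechanism; with the alternative reading in which every
postsynaptic spike re-pairs with the most recent presynaptic spike,
potentiation grows without bound in the postsynaptic rate and the model
diverges from its own initial conditions.

Simultaneous events within one integration step are processed
presynaptic-first, so a same-step pre/post pair is seen as `dt = 0`
(depression, given the shift).

### Jittered STDP

The unshifted window (`d = 0`) evaluated at `dt + eta`,
`eta ~ N(0, sigma^2)` drawn independently per pairing.  Averaged over the
jitter, the effective window is negative for small positive `dt` whenever
`A- > A+`, acting as an implicit shift whose extent grows with `sigma`;
stability additionally requires `A+ tau+ > A- tau-`.  Both inequalities
hold for the default window, which the jittered rule reuses.

### Shifted triplet STDP

Each synapse carries a presynaptic detector `r_j` (set to 1 at each of its
presynaptic spikes, decaying with `tau_x = 100 ms`); a single postsynaptic
detector `o` behaves symmetrically (`tau_y = 100 ms`).  On an adjacency
pairing the pair window applies as above, plus a triplet term read from
the traces *before* the triggering spike resets them: an extra depression
`-A3- o(t) r_j(t^-)` on a presynaptic spike (2 pre / 1 post ensembles,
decaying with the pre–pre interval) and an extra potentiation
`+A3+ o(t^-) r_j(t)` on a postsynaptic spike (1 pre / 2 post ensembles,
decaying with the post–post interval).  The triplet terms are gated on the
adjacency pairing itself — they are an addition to "the usual pairing
effect", and un-gated trace products are unstable at every amplitude we
tested, because the extra potentiation then scales unboundedly with the
postsynaptic rate.  The representative amplitude is
`A3+ = A3- = 0.05 mV`, chosen (before measuring any transition values) so
the triplet terms perturb rather than dominate the pair rule's operating
point.

### Correlated inputs

A correlated group of `n` trains with pairwise zero-lag correlation `c`
is built by thinning: one generating Poisson train of rate `rate/c`, each
member keeping each spike independently with probability `c`.  Every
member then has the target rate and every pair has count correlation `c`
(measured in 1 ms bins).  An optional exponential lag with mean equal to
the correlation time constant is added per spike per train independently
(a shared draw would preserve exact synchrony); lagged spikes pushed past
the duration are dropped.  The generator records the cluster size of each
generating spike for the per-cluster normalisation of causal-bump
measurements.

## Numerics

Fixed-step integration at `dt = 0.1 ms` with the exact exponential
propagator of the linear subthreshold system (the step size only aligns
events to the grid; halving it changes the firing rate by < 2%).  The
closed loop is a single compiled kernel; the event-driven pure-Python
pairing machines are the reference implementation, and a test replays an
identical event stream through both paths and requires agreement to
1e-10 mV.  A state already at threshold fires before integrating.
Weight snapshots are taken every 10–25 s.

Steady state is declared when the first three weight moments (compared on
a common mV scale, i.e. `m_k^(1/k)`) and the postsynaptic rate each change
by less than 2% between consecutive comparison windows (750–1000 s for
stability classifications).  The raw third moment of a 250-synapse
population fluctuates several percent at stationarity, which is why
moments are compared on the common scale; even window-averaged moments
need ~1000 s windows to sit reliably inside the 2% tolerance.

Modality classification: mass piled against both active bounds (> 10% of
synapses within 5% of each) is bimodal (the U shape of bounded unstable
STDP); otherwise a Gaussian KDE (Silverman bandwidth) counts interior
modes, requiring secondary modes above 5% of the main mode with a genuine
valley between.  Modality is judged on the final snapshot: individual
synapses churn through the bounds (the U shape is a population feature,
not per-synapse bistability), so time-averaged weights wash it out.
Competition group *means*, by contrast, are time-averaged over the last
third of each run, which damps single-realization noise near the
transition.

## Steady-state theory

For one synapse, drift and diffusion are integrals of the window (and its
square) against the pairing-interval rate density.  The acausal part
decays at `lambda = nu_ex + nu_post`; for `dt > 0` a causal bump adds

    (nu_post tau_s / mu) * w * exp(-t/tau_bump)/tau_bump,

the linear-Poisson response gain (rate responds in proportion to the
time-integrated depolarisation `w tau_s` relative to the mean drive `mu`)
concentrated on an evoked-spike latency scale `tau_bump = 2 ms` — the
bump has first-passage character, far narrower than the EPSP.  The
nearest-neighbour survival factor depletes later pairings to first order
in `w`.  Both coefficients are then linear in `w`, and the zero-flux
stationary solution of the Fokker–Planck equation is a shifted gamma
density; normalizability requires the drift slope to be negative and the
gamma shape positive (the latter needs `A+ tau+` sufficiently above
`A- tau-`, opposite to the classical unshifted condition).  The gamma
mean is exactly `-a_A/b_A`.  The postsynaptic rate uses the mean-driven
integrate-and-fire formula `nu = 1/(tau_m ln(mu/(mu - theta)))` with
`mu = tau_s (N_E nu_ex w_mean - N_I nu_in w_inh)`; the coupled
rate/weight system is solved by bracketing the self-consistency residual
and applying Brent's method (the drift-balance map is far too steep near
the root for damped iteration, which is retained only as a fallback).
Every closed-form coefficient is cross-checked against direct quadrature
of the full density (1%), and the gamma solution against a numerically
integrated zero-flux density (2%).

### Known limitations of the theory

The analytic side assumes Poisson postsynaptic statistics and a
fixed-shape first-order causal bump.  The simulated neuron fires
semi-regularly in the mean-driven regime (ISI CV ~ 0.5), which discounts
short-interval depression, and the simulated bump sharpens with synaptic
strength (the essential nonlinear stabilizing effect).  Consequences,
measured at the defaults: the analytic fixed-point rate underestimates
the simulated rate by roughly a factor two; the analytic mean weight
agrees with simulation within ~5%; the analytic distribution is broader
than the simulated one (KS distance ~ 0.2 after truncation to
non-negative strengths); and the analytic rate-curve maximum sits at
~5–6 Hz excitatory input rather than ~10 Hz.  The analytic fixed point
exists for shifts between about 1 and 2.75 ms at default rates; the
shift-scan presets cover that range.

## What the generator does and does not emulate

Inputs are homogeneous Poisson trains with optional pairwise zero-lag
correlations and exponential lag smearing.  Real presynaptic populations
carry rate nonstationarity, higher-order correlation structure and
synapse-specific rates, none of which are modelled; passing tests
therefore demonstrate the plasticity mechanisms under the stated
idealized input statistics, not robustness to natural input ensembles.

## Experiment sizes

Scans run the full 250/200 ensemble, 1500 s of simulated time per grid
point (2500–4000 s for stability classifications), three seeds per
competition point with weights time-averaged over the final 500 s.
Competition outcomes near the anti-Hebbian/Hebbian transition are
bistable-ish across realizations, so transition estimates carry an
uncertainty of roughly one scan step (3 Hz) even with averaging.

## Design choices made where the design was open

* Unstable comparison runs (unshifted or weakly jittered windows) use a
  hard bound `w_max = 8 mV`, placed above the stable rule's weight scale
  so bound pile-up is diagnostic of instability rather than an artifact.
* The transition between competition regimes is defined operationally as
  the interpolated zero crossing of the correlated-minus-uncorrelated
  mean-weight difference along the inhibitory-rate scan (with a 3-point
  moving-average fallback when single-realization noise produces multiple
  crossings).
* The causal-bump baseline is fitted on negative lags in [-50, -5] ms and
  pairing histograms use the same adjacent-event convention as the
  plasticity rules, excluding pairs separated by another spike of the same
  train — without this the baseline decays at `nu_post` rather than
  `nu_ex + nu_post`.
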