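"""Window arithmetic, nearest-neighbour pairing, jitter and triplet traces."""

import numpy as np
import pytest

from shifted_stdp.params import JitterParams, PairSTDPParams, TripletParams
from shifted_stdp.stdp_rules import (
    PairingState,
    apply_bounds,
    effective_window,
    jittered_delta,
    on_post_spike,
    on_pre_spike,
    triplet_on_post,
    triplet_on_pre,
    window,
)


@pytest.fixture
def pair():
    return PairSTDPParams()  # A+=0.25, A-=0.30, tau+=20ms, tau-=14ms, d=2ms


class TestWindow:
    def test_vanishes_at_large_intervals(self, pair):
        assert abs(window(1.0, pair)) < 1e-12
        assert abs(window(-1.0, pair)) < 1e-12

    def test_short_causal_interval_depresses(self, pair):
        # the defining feature of the shifted window
        assert window(1e-3, pair) < 0

    def test_unshifted_boundary_value_is_minus_a_minus(self):
        p = PairSTDPParams(shift=0.0)
        assert window(0.0, p) == pytest.approx(-p.a_minus)

    def test_boundary_belongs_to_depression_branch(self, pair):
        assert window(pair.shift, pair) == pytest.approx(-pair.a_minus)
        # branch continuity on each side of the boundary
        eps = 1e-9
        assert window(pair.shift - eps, pair) == pytest.approx(-pair.a_minus, rel=1e-6)
        assert window(pair.shift + eps, pair) == pytest.approx(pair.a_plus, rel=1e-6)

    def test_causal_potentiation_value(self, pair):
        # pre at 100 ms, post at 110 ms: dt = 10 ms, 8 ms past the shift
        expected = pair.a_plus * np.exp(-8e-3 / pair.tau_plus)
        assert window(10e-3, pair) == pytest.approx(expected)

    def test_acausal_depression_value(self, pair):
        expected = -pair.a_minus * np.exp((-10e-3 - pair.shift) / pair.tau_minus)
        assert window(-10e-3, pair) == pytest.approx(expected)

    def test_vectorized_matches_scalar(self, pair):
        dts = np.array([-5e-3, 0.0, 1e-3, 2e-3, 10e-3])
        vec = window(dts, pair)
        assert np.allclose(vec, [window(t, pair) for t in dts])


def brute_force_adjacent_pairs(events):
    """Oracle: pair consecutive opposite-type events of a single synapse.

    ``events`` is a time-sorted list of (time, kind) with kind 'pre'|'post'.
    Returns the list of signed pairing intervals dt = t_post - t_pre, one
    per adjacency, in event order.
    """
    pairs = []
    for (t0, k0), (t1, k1) in zip(events[:-1], events[1:]):
        if k0 != k1:
            pairs.append(t1 - t0 if k1 == "post" else -(t1 - t0))
    return pairs


class TestNearestNeighbourPairing:
    def test_pre_with_no_prior_post_is_silent(self, pair):
        st = PairingState(3)
        assert on_pre_spike(st, 0, 0.1, pair) == 0.0

    def test_post_with_no_prior_pre_is_zero_vector(self, pair):
        st = PairingState(3)
        assert np.all(on_post_spike(st, 0.1, pair) == 0.0)

    def test_pre_after_post_pairs_at_negative_interval(self, pair):
        st = PairingState(1)
        on_post_spike(st, 0.090, pair)
        dw = on_pre_spike(st, 0, 0.100, pair)
        assert dw == pytest.approx(window(-10e-3, pair))

    def test_second_pre_after_one_post_does_not_re_pair(self, pair):
        # adjacency: post . pre . pre -> only the first pre depresses
        st = PairingState(1)
        on_post_spike(st, 0.050, pair)
        dw1 = on_pre_spike(st, 0, 0.060, pair)
        dw2 = on_pre_spike(st, 0, 0.070, pair)
        assert dw1 == pytest.approx(window(-10e-3, pair))
        assert dw2 == 0.0

    def test_second_post_after_one_pre_does_not_re_pair(self, pair):
        st = PairingState(1)
        on_pre_spike(st, 0, 0.050, pair)
        dw1 = on_post_spike(st, 0.060, pair)
        dw2 = on_post_spike(st, 0.070, pair)
        assert dw1[0] == pytest.approx(window(10e-3, pair))
        assert dw2[0] == 0.0

    def test_out_of_order_events_rejected(self, pair):
        st = PairingState(1)
        on_post_spike(st, 0.5, pair)
        with pytest.raises(ValueError):
            on_pre_spike(st, 0, 0.1, pair)

    def test_arbitrary_scripts_match_brute_force_oracle_hypothesis(self, pair):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(
            st.lists(
                st.tuples(st.floats(0, 10, allow_nan=False), st.booleans()),
                min_size=2, max_size=40,
            )
        )
        def run(script):
            events = sorted((t, "post" if is_post else "pre") for t, is_post in script)
            state = PairingState(1)
            total = 0.0
            for t, kind in events:
                if kind == "pre":
                    total += on_pre_spike(state, 0, t, pair)
                else:
                    total += on_post_spike(state, t, pair)[0]
            expected = sum(window(dt, pair) for dt in brute_force_adjacent_pairs(events))
            assert total == pytest.approx(expected, rel=1e-12, abs=1e-15)

        run()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_scripts_match_brute_force_oracle(self, pair, seed):
        # 50-event random scripts on one synapse, replayed event by event
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 2.0, size=50))
        kinds = rng.choice(["pre", "post"], size=50)
        events = list(zip(times, kinds))

        st = PairingState(1)
        total = 0.0
        for t, k in events:
            if k == "pre":
                total += on_pre_spike(st, 0, t, pair)
            else:
                total += on_post_spike(st, t, pair)[0]
        expected = sum(window(dt, pair) for dt in brute_force_adjacent_pairs(events))
        assert total == pytest.approx(expected, rel=1e-12)


class TestJitteredWindow:
    def test_zero_sigma_reduces_to_plain_window(self, rng):
        jp = JitterParams(sigma=0.0)
        for dt in (-5e-3, 1e-3, 10e-3):
            assert jittered_delta(dt, jp, rng) == window(dt, jp.base)

    def test_effective_window_depresses_short_causal_intervals(self):
        # with A- > A+ the jitter-averaged window is negative just after 0,
        # an implicit shift whose extent grows with the jitter
        def crossing(sigma):
            jp = JitterParams(sigma=sigma)
            dts = np.linspace(0, 3e-3, 301)
            vals = effective_window(dts, jp)
            return dts[np.argmax(vals > 0)]

        jp = JitterParams(sigma=3e-3)
        assert effective_window(0.1e-3, jp) < 0
        assert effective_window(20e-3, jp) > 0
        assert crossing(1e-3) < crossing(2e-3) < crossing(4e-3)

    def test_monte_carlo_mean_matches_gaussian_convolution(self, rng):
        jp = JitterParams(sigma=2e-3)
        dt = 1.5e-3
        draws = np.array([jittered_delta(dt, jp, rng) for _ in range(100_000)])
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(mc - effective_window(dt, jp)) < 3 * se


@pytest.fixture
def triplet():
    return TripletParams(a3_plus=0.05, a3_minus=0.05)


class TestTripletRule:
    def test_isolated_first_pre_changes_nothing_but_sets_trace(self, triplet):
        st = PairingState(2)
        dw = triplet_on_pre(st, 0, 0.1, triplet)
        assert dw == 0.0
        assert st.pre_trace(0, 0.1, triplet.tau_x) == pytest.approx(1.0)

    def test_isolated_first_post_zero_vector_and_sets_trace(self, triplet):
        st = PairingState(2)
        dw = triplet_on_post(st, 0.1, triplet)
        assert np.all(dw == 0.0)
        assert st.post_trace(0.1, triplet.tau_y) == pytest.approx(1.0)

    def test_trace_decays_exponentially_between_events(self, triplet):
        st = PairingState(1)
        triplet_on_pre(st, 0, 0.0, triplet)
        for dt in (0.01, 0.05, 0.2):
            assert st.pre_trace(0, dt, triplet.tau_x) == pytest.approx(
                np.exp(-dt / triplet.tau_x)
            )

    def test_pre_pre_interval_sets_triplet_depression_factor(self, triplet):
        # pre at t0, post, pre at t0+delta: extra depression scales with
        # the pre-trace exp(-delta/tau_x) read before the reset
        delta = 0.030
        base = PairSTDPParams(
            a_plus=triplet.pair.a_plus, a_minus=triplet.pair.a_minus,
            tau_plus=triplet.pair.tau_plus, tau_minus=triplet.pair.tau_minus,
            shift=triplet.pair.shift,
        )
        st = PairingState(1)
        triplet_on_pre(st, 0, 0.0, triplet)
        triplet_on_post(st, 0.020, triplet)
        dw = triplet_on_pre(st, 0, delta, triplet)
        pair_part = window(0.020 - delta, base)
        extra = dw - pair_part
        expected = -triplet.a3_minus * np.exp(-(delta - 0.020) / triplet.tau_y) * np.exp(
            -delta / triplet.tau_x
        )
        assert extra == pytest.approx(expected)

    def test_post_pre_post_exceeds_plain_pre_post(self, triplet):
        # same pre->post pairing, with and without an earlier post
        def net(with_first_post):
            st = PairingState(1)
            if with_first_post:
                triplet_on_post(st, 0.0, triplet)
            triplet_on_pre(st, 0, 0.010, triplet)
            return triplet_on_post(st, 0.020, triplet)[0]

        assert net(True) > net(False)

    def test_post_pre_post_beats_pre_post_pre(self, triplet):
        # matched 10 ms intervals; the post-pre-post ensemble potentiates more
        st1 = PairingState(1)
        total_ppp = triplet_on_post(st1, 0.0, triplet)[0]
        total_ppp += triplet_on_pre(st1, 0, 0.010, triplet)
        total_ppp += triplet_on_post(st1, 0.020, triplet)[0]

        st2 = PairingState(1)
        total_prp = triplet_on_pre(st2, 0, 0.0, triplet)
        total_prp += triplet_on_post(st2, 0.010, triplet)[0]
        total_prp += triplet_on_pre(st2, 0, 0.020, triplet)
        assert total_ppp > total_prp


class TestBounds:
    def test_negative_weights_clip_to_zero(self, pair):
        out = apply_bounds(np.array([-0.1, 0.5]), pair)
        assert np.array_equal(out, [0.0, 0.5])

    def test_no_upper_bound_in_shifted_mode(self, pair):
        out = apply_bounds(np.array([50.0]), pair)
        assert out[0] == 50.0

    def test_upper_bound_applies_when_configured(self):
        p = PairSTDPParams(shift=0.0, w_max=2.0)
        out = apply_bounds(np.array([1.0, 3.0]), p)
        assert np.array_equal(out, [1.0, 2.0])
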