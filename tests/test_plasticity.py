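"""Unit and property tests for the pure plasticity mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from tristdp import (
    NeuromodConfig,
    PairSTDPConfig,
    TraceState,
    apply_post_spike,
    apply_pre_spike,
    clamp_weight,
    decay_trace,
    weight_delta,
    weight_delta_general,
)


def euler_decay(value, elapsed, tau, dt=1e-4):
    """Brute-force Euler integration of ds/dt = -s/tau."""
    steps = int(round(elapsed / dt))
    for _ in range(steps):
        value -= value / tau * dt
    return value


def quad_delta(c, t_c_last, d, t_d_last, t_last, t, tau_c, tau_d):
    """Adaptive quadrature of the weight-drift integrand.

    The integrand decays with rate k = 1/tau_c + 1/tau_d; the domain is
    truncated at 60/k (tail < e^-60) so the adaptive rule cannot converge
    prematurely on an interval vastly longer than the integrand's support.
    """

    def integrand(s):
        return (
            c * d
            * math.exp(-(s - t_c_last) / tau_c)
            * math.exp(-(s - t_d_last) / tau_d)
        )

    k = 1.0 / tau_c + 1.0 / tau_d
    upper = min(t, t_last + 60.0 / k)
    val, _ = quad(integrand, t_last, upper, epsabs=1e-14, epsrel=1e-12, limit=200)
    return val


class TestDecayTrace:
    @pytest.mark.parametrize(
        "value,elapsed,tau,expected",
        [
            (0.73, 0.0, 17.0, 0.73),  # zero elapsed is the identity
            (0.0, 123.0, 5.0, 0.0),  # a zero trace stays zero
            (1.0, 1000.0, 1000.0, math.exp(-1.0)),
        ],
    )
    def test_closed_form(self, value, elapsed, tau, expected):
        assert decay_trace(value, elapsed, tau) == pytest.approx(expected, rel=1e-12)

    def test_matches_fine_step_euler(self):
        assert decay_trace(1.0, 1000.0, 1000.0) == pytest.approx(
            euler_decay(1.0, 1000.0, 1000.0), rel=1e-3
        )

    @pytest.mark.parametrize("elapsed,tau", [(-1.0, 10.0), (1.0, 0.0), (1.0, -5.0)])
    def test_invalid_arguments(self, elapsed, tau):
        with pytest.raises(ValueError):
            decay_trace(1.0, elapsed, tau)

    @given(
        value=st.floats(-10, 10),
        a=st.floats(0, 1000),
        b=st.floats(0, 1000),
        tau=st.floats(0.5, 5000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_semigroup(self, value, a, b, tau):
        two_step = decay_trace(decay_trace(value, a, tau), b, tau)
        one_step = decay_trace(value, a + b, tau)
        assert two_step == pytest.approx(one_step, rel=1e-12, abs=1e-12)


class TestPairSTDPOnEligibility:
    stdp = PairSTDPConfig(a_plus=1.0, a_minus=1.0, tau_plus=10.0, tau_minus=12.0)

    def test_post_spike_samples_decayed_pre_trace(self):
        # pre spike at 1 ms (unit trace), post spike at 3 ms
        pre = TraceState(1.0, 1.0)
        c = apply_post_spike(0.0, 3.0, pre, self.stdp)
        assert c == pytest.approx(math.exp(-2.0 / 10.0), rel=1e-9)
        assert c == pytest.approx(0.818731, abs=1e-6)
        assert pre.value == 1.0 and pre.last_update == 1.0  # not mutated

    def test_zero_pre_trace_leaves_eligibility(self):
        assert apply_post_spike(0.4, 9.0, TraceState(0.0, 2.0), self.stdp) == 0.4

    def test_accumulated_pre_trace(self):
        # two pre spikes 10 ms apart, post 1 ms after the second
        pre = TraceState(0.0, 0.0)
        pre.value = decay_trace(pre.value, 0, 10.0) + 1.0  # spike at 0
        pre.value = decay_trace(pre.value, 10, 10.0) + 1.0  # spike at 10
        pre.last_update = 10.0
        c = apply_post_spike(0.0, 11.0, pre, self.stdp)
        assert c == pytest.approx(math.exp(-1.1) + math.exp(-0.1), rel=1e-12)

    def test_pre_spike_samples_decayed_post_trace(self):
        # post at 3 ms (unit trace), next pre at 15 ms
        c = apply_pre_spike(0.0, 15.0, TraceState(1.0, 3.0), self.stdp)
        assert c == pytest.approx(-math.exp(-1.0), rel=1e-12)

    def test_zero_post_trace_leaves_eligibility(self):
        assert apply_pre_spike(-0.2, 9.0, TraceState(0.0, 2.0), self.stdp) == -0.2

    def test_symmetry_under_amplitude_swap(self):
        asym = PairSTDPConfig(a_plus=0.7, a_minus=0.7, tau_plus=9.0, tau_minus=9.0)
        pot = apply_post_spike(0.0, 8.0, TraceState(1.3, 2.0), asym)
        dep = apply_pre_spike(0.0, 8.0, TraceState(1.3, 2.0), asym)
        assert pot == pytest.approx(-dep, rel=1e-12)


class TestWeightDelta:
    mod = NeuromodConfig(tau_c=1000.0, tau_d=200.0, w_min=-np.inf, w_max=np.inf)

    def test_zero_interval_and_zero_dopamine(self):
        assert weight_delta(1.0, 0.5, 10.0, 10.0, self.mod) == 0.0
        assert weight_delta(3.7, 0.0, 0.0, 5000.0, self.mod) == 0.0

    def test_against_quadrature_example(self):
        dw = weight_delta(1.0, 0.1, 0.0, 100.0, self.mod)
        assert dw == pytest.approx(7.5198, abs=5e-4)
        assert dw == pytest.approx(
            quad_delta(1.0, 0, 0.1, 0, 0, 100, 1000.0, 200.0), rel=1e-10
        )

    def test_many_random_draws_match_quadrature(self, rng):
        for _ in range(300):
            tau_c, tau_d = rng.uniform(1, 5000, 2)
            c, d = rng.uniform(-10, 10, 2)
            interval = rng.uniform(0, 5000)
            mod = NeuromodConfig(tau_c=tau_c, tau_d=tau_d, w_min=-np.inf, w_max=np.inf)
            got = weight_delta(c, d, 0.0, interval, mod)
            want = quad_delta(c, 0, d, 0, 0, interval, tau_c, tau_d)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_linear_in_c_and_d_with_correct_sign(self):
        base = weight_delta(1.0, 0.1, 0.0, 50.0, self.mod)
        assert weight_delta(3.0, 0.1, 0.0, 50.0, self.mod) == pytest.approx(
            3 * base, rel=1e-12
        )
        assert weight_delta(1.0, -0.2, 0.0, 50.0, self.mod) == pytest.approx(
            -2 * base, rel=1e-12
        )
        assert math.copysign(1.0, weight_delta(-2.0, 0.3, 0.0, 50.0, self.mod)) == -1.0

    def test_monotone_in_interval_and_asymptote(self):
        intervals = np.linspace(0, 20_000, 200)
        values = [abs(weight_delta(1.0, 0.1, 0.0, t, self.mod)) for t in intervals]
        assert all(b >= a for a, b in zip(values, values[1:]))
        limit = 1.0 * 0.1 * (1000.0 * 200.0) / 1200.0
        assert values[-1] == pytest.approx(limit, rel=1e-6)

    def test_rejects_reversed_interval(self):
        with pytest.raises(ValueError):
            weight_delta(1.0, 1.0, 10.0, 5.0, self.mod)


class TestWeightDeltaGeneral:
    mod = NeuromodConfig(tau_c=1000.0, tau_d=200.0, w_min=-np.inf, w_max=np.inf)

    def test_reduces_to_common_reference_form(self):
        a = weight_delta_general(0.8, 50.0, -0.3, 50.0, 50.0, 400.0, self.mod)
        b = weight_delta(0.8, -0.3, 50.0, 400.0, self.mod)
        assert a == pytest.approx(b, rel=1e-14)

    def test_zero_eligibility(self):
        assert weight_delta_general(0.0, 0, 5.0, 10, 20, 500, self.mod) == 0.0

    def test_staggered_references_match_quadrature(self, rng):
        for _ in range(300):
            tau_c, tau_d = rng.uniform(1, 5000, 2)
            mod = NeuromodConfig(tau_c=tau_c, tau_d=tau_d, w_min=-np.inf, w_max=np.inf)
            t_c_last = rng.uniform(0, 100)
            t_d_last = rng.uniform(0, 100)
            t_last = 100.0
            t = t_last + rng.uniform(0, 3000)
            c, d = rng.uniform(-10, 10, 2)
            got = weight_delta_general(c, t_c_last, d, t_d_last, t_last, t, mod)
            want = quad_delta(c, t_c_last, d, t_d_last, t_last, t, tau_c, tau_d)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            weight_delta_general(1.0, 120.0, 1.0, 0.0, 100.0, 200.0, self.mod)
        with pytest.raises(ValueError):
            weight_delta_general(1.0, 0.0, 1.0, 0.0, 100.0, 50.0, self.mod)


@pytest.mark.parametrize(
    "w,expected", [(1.0, 1.0), (-0.5, 0.0), (7.2, 5.0), (0.0, 0.0), (5.0, 5.0)]
)
def test_clamp_weight(w, expected):
    mod = NeuromodConfig(w_min=0.0, w_max=5.0)
    assert clamp_weight(w, mod) == expected


@pytest.mark.parametrize(
    "kwargs",
    [
        {"a_plus": 0.0},
        {"tau_plus": -1.0},
        {"tau_minus": 0.0},
    ],
)
def test_stdp_config_rejects_nonpositive(kwargs):
    with pytest.raises(ValueError):
        PairSTDPConfig(**kwargs)


def test_neuromod_config_rejects_bad_values():
    with pytest.raises(ValueError):
        NeuromodConfig(tau_c=-1.0)
    with pytest.raises(ValueError):
        NeuromodConfig(w_min=2.0, w_max=1.0)
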