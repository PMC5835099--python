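"""Pure plasticity mathematics for dopamine-modulated (three-factor) STDP.

The learning rule keeps, per synapse, an *eligibility trace* ``C`` that is
written by ordinary pair-based STDP and decays with time constant ``tau_c``,
and, per post-synaptic neuron, a *dopamine concentration* ``D`` that is
incremented by each dopaminergic spike (by ``d_c``, which may be negative for
punishment) and decays with time constant ``tau_d``.  The synaptic weight
drifts continuously as ``dw/dt = C * D``.  Between events both ``C`` and ``D``
are plain exponentials, so the weight change over an event-free interval has
the closed form implemented by :func:`weight_delta`; this is what makes a
lazy, event-driven implementation possible.

Everything in this module is a pure function of its arguments; simulation
state lives in :mod:`tristdp.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TraceState",
    "PairSTDPConfig",
    "NeuromodConfig",
    "DopamineState",
    "SynapseState",
    "decay_trace",
    "trace_at",
    "add_trace_spike",
    "apply_post_spike",
    "apply_pre_spike",
    "weight_delta",
    "weight_delta_general",
    "clamp_weight",
]


@dataclass
class TraceState:
    """An exponentially decaying spike trace.

    ``value`` is the (dimensionless) trace level referenced to time
    ``last_update`` (ms).  Each spike adds +1 to the trace; traces accumulate
    without saturation, so sampling a partner's trace at spike times realises
    an all-to-all pair interaction with an exponential window.
    """

    value: float = 0.0
    last_update: float = 0.0


@dataclass(frozen=True)
class PairSTDPConfig:
    """Amplitudes and time constants of the pair-based STDP window.

    A causal pre->post pair separated by ``dt`` contributes
    ``a_plus * exp(-dt / tau_plus)`` (potentiation); an anti-causal pair
    contributes ``-a_minus * exp(-dt / tau_minus)`` (depression).
    """

    a_plus: float = 1.0
    a_minus: float = 1.0
    tau_plus: float = 10.0  # ms
    tau_minus: float = 12.0  # ms

    def __post_init__(self) -> None:
        for name in ("a_plus", "a_minus", "tau_plus", "tau_minus"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class NeuromodConfig:
    """Neuromodulation constants and weight bounds.

    ``tau_c`` (ms) is the decay constant of the eligibility trace, ``tau_d``
    (ms) the dopamine re-absorption constant.  Weights (nA for current-based
    synapses) are clamped additively to ``[w_min, w_max]`` after each row
    processing; pass infinities to disable clamping.
    """

    tau_c: float = 1000.0  # ms
    tau_d: float = 200.0  # ms
    w_min: float = 0.0
    w_max: float = math.inf

    def __post_init__(self) -> None:
        if self.tau_c <= 0.0 or self.tau_d <= 0.0:
            raise ValueError("tau_c and tau_d must be strictly positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")


@dataclass
class DopamineState:
    """Dopamine concentration ``D`` referenced to time ``last_update`` (ms).

    ``level`` may be negative (punishment signals use a negative per-spike
    increment ``d_c``).
    """

    level: float = 0.0
    last_update: float = 0.0


@dataclass
class SynapseState:
    """One plastic synapse: weight (nA), eligibility trace and delay (ms)."""

    weight: float
    target: int
    delay: int = 1
    eligibility: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("synaptic delay must be an integer >= 1 ms")


def decay_trace(value: float, elapsed: float, tau: float) -> float:
    """Decay a trace value over ``elapsed`` ms: ``value * exp(-elapsed/tau)``."""
    if tau <= 0.0:
        raise ValueError("tau must be strictly positive")
    if elapsed < 0.0:
        raise ValueError("elapsed must be non-negative")
    if value == 0.0:
        return 0.0
    return value * math.exp(-elapsed / tau)


def trace_at(trace: TraceState, t: float, tau: float) -> float:
    """Sample a trace at time ``t`` >= ``trace.last_update``."""
    return decay_trace(trace.value, t - trace.last_update, tau)


def add_trace_spike(trace: TraceState, t: float, tau: float) -> None:
    """Advance ``trace`` to time ``t`` and add a unit spike increment."""
    trace.value = trace_at(trace, t, tau) + 1.0
    trace.last_update = t


def apply_post_spike(
    c: float, t_post: float, pre_trace: TraceState, cfg: PairSTDPConfig
) -> float:
    """Potentiation step of pair STDP, written to the eligibility trace.

    A post-synaptic spike at ``t_post`` samples the pre-synaptic trace and
    returns ``c + a_plus * s_i(t_post)``.  The pre trace is not mutated.
    """
    sampled = trace_at(pre_trace, t_post, cfg.tau_plus)
    return c + cfg.a_plus * sampled


def apply_pre_spike(
    c: float, t_pre: float, post_trace: TraceState, cfg: PairSTDPConfig
) -> float:
    """Depression step of pair STDP, written to the eligibility trace.

    A pre-synaptic spike at ``t_pre`` samples the post-synaptic trace and
    returns ``c - a_minus * s_j(t_pre)``.  The post trace is not mutated.
    """
    sampled = trace_at(post_trace, t_pre, cfg.tau_minus)
    return c - cfg.a_minus * sampled


def weight_delta(
    c_at_ref: float,
    d_at_ref: float,
    t_ref: float,
    t: float,
    cfg: NeuromodConfig,
) -> float:
    """Closed-form weight change over an event-free interval.

    With both the eligibility trace and the dopamine concentration referenced
    to the same time ``t_ref`` (values ``c_at_ref`` and ``d_at_ref``),
    integrating ``dw/dt = C(t) D(t)`` from ``t_ref`` to ``t`` gives::

        dw = C D / (-(1/tau_c + 1/tau_d))
             * (exp(-(t - t_ref)/tau_c) * exp(-(t - t_ref)/tau_d) - 1)

    which is positive for ``C*D > 0`` and saturates at
    ``C*D*tau_c*tau_d/(tau_c + tau_d)`` as the interval grows.
    """
    if t < t_ref:
        raise ValueError("t must be >= t_ref")
    cd = c_at_ref * d_at_ref
    if cd == 0.0 or t == t_ref:
        return 0.0
    k = 1.0 / cfg.tau_c + 1.0 / cfg.tau_d
    dt = t - t_ref
    return cd / (-k) * (math.exp(-dt / cfg.tau_c) * math.exp(-dt / cfg.tau_d) - 1.0)


def weight_delta_general(
    c_at_tc: float,
    t_c_last: float,
    d_at_td: float,
    t_d_last: float,
    t_last: float,
    t: float,
    cfg: NeuromodConfig,
) -> float:
    """Weight change without the common-reference-time simplification.

    ``c_at_tc`` is the eligibility trace referenced to ``t_c_last`` and
    ``d_at_td`` the dopamine concentration referenced to ``t_d_last``; the
    weight was last brought up to date at ``t_last``.  Reduces exactly to
    :func:`weight_delta` when ``t_c_last == t_d_last == t_last``.
    """
    if t < t_last:
        raise ValueError("t must be >= t_last")
    if t_c_last > t_last or t_d_last > t_last:
        raise ValueError("trace reference times must not exceed t_last")
    cd = c_at_tc * d_at_td
    if cd == 0.0 or t == t_last:
        return 0.0
    k = 1.0 / cfg.tau_c + 1.0 / cfg.tau_d
    upper = math.exp(-(t - t_c_last) / cfg.tau_c) * math.exp(-(t - t_d_last) / cfg.tau_d)
    lower = math.exp(-(t_last - t_c_last) / cfg.tau_c) * math.exp(
        -(t_last - t_d_last) / cfg.tau_d
    )
    return cd / (-k) * (upper - lower)


def clamp_weight(w: float, cfg: NeuromodConfig) -> float:
    """Clamp a weight additively into ``[w_min, w_max]``."""
    return min(max(w, cfg.w_min), cfg.w_max)
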