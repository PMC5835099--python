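"""Current-based leaky integrate-and-fire neurons and spike sources.

The neuron model is the PyNN-style ``IF_curr_exp``: a leaky membrane

    C_m dV/dt = (C_m / tau_m) (v_rest - V) + I_syn_E + I_syn_I + I_offset

driven by excitatory and inhibitory synaptic currents that jump by the
synaptic weight (nA; inhibitory weights are negative) on spike arrival and
decay exponentially with their own time constants.  Integration is an exact
per-step exponential update on the 1 ms grid with the total input current
held constant across each step, which makes trajectories deterministic and
directly comparable with closed forms.

Two parameterisations are bundled as module constants: regular-spiking
excitatory (``RS``) and fast-spiking inhibitory (``FS``) cells, which differ
in refractory period, threshold and offset current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "RS",
    "FS",
    "lif_step",
    "poisson_step",
    "poisson_train",
    "min_superthreshold_amplitude",
    "default_pulse_amplitude",
]


@dataclass(frozen=True)
class LIFParams:
    """IF_curr_exp parameters (capacitance nF, currents nA, times ms, voltages mV)."""

    c_m: float = 0.3
    i_offset: float = 0.0
    tau_m: float = 10.0
    tau_refrac: float = 4.0
    tau_syn_e: float = 1.0
    tau_syn_i: float = 1.0
    v_reset: float = -70.0
    v_rest: float = -65.0
    v_thresh: float = -55.4

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.c_m <= 0:
            raise ValueError("tau_m and c_m must be positive")
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError("require v_reset <= v_rest < v_thresh")

    @property
    def r_m(self) -> float:
        """Membrane resistance tau_m / C_m (MOhm when nF/ms/nA/mV units are used)."""
        return self.tau_m / self.c_m


#: Regular-spiking excitatory cell.
RS = LIFParams(c_m=0.3, i_offset=0.005, tau_m=10.0, tau_refrac=4.0,
               tau_syn_e=1.0, tau_syn_i=1.0, v_reset=-70.0, v_rest=-65.0,
               v_thresh=-55.4)

#: Fast-spiking inhibitory cell (shorter refractory period, lower threshold).
FS = LIFParams(c_m=0.3, i_offset=0.0, tau_m=10.0, tau_refrac=2.0,
               tau_syn_e=1.0, tau_syn_i=1.0, v_reset=-70.0, v_rest=-65.0,
               v_thresh=-56.4)


@dataclass
class LIFState:
    """Dynamic state of one LIF neuron."""

    v: float
    i_syn_e: float = 0.0
    i_syn_i: float = 0.0
    refrac_remaining: int = 0


def lif_step(
    state: LIFState,
    params: LIFParams,
    input_e: float = 0.0,
    input_i: float = 0.0,
    i_ext: float = 0.0,
    dt: float = 1.0,
) -> bool:
    """Advance one neuron by one 1 ms step; returns True if it spiked.

    ``input_e`` / ``input_i`` are the ring-buffer deposits arriving this
    step (added to the synaptic currents before integration); ``i_ext`` is
    extra injected current for this step only (stimulus pulses).  During the
    refractory countdown the membrane is held at ``v_reset`` while synaptic
    currents keep decaying.
    """
    state.i_syn_e += input_e
    state.i_syn_i += input_i
    spiked = False
    if state.refrac_remaining > 0:
        state.refrac_remaining -= 1
        state.v = params.v_reset
    else:
        i_total = state.i_syn_e + state.i_syn_i + params.i_offset + i_ext
        v_inf = params.v_rest + params.r_m * i_total
        state.v = v_inf + (state.v - v_inf) * math.exp(-dt / params.tau_m)
        if state.v >= params.v_thresh:
            spiked = True
            state.v = params.v_reset
            state.refrac_remaining = int(round(params.tau_refrac / dt))
    state.i_syn_e *= math.exp(-dt / params.tau_syn_e)
    state.i_syn_i *= math.exp(-dt / params.tau_syn_i)
    return spiked


def poisson_step(rate: float, dt: float, rng: np.random.Generator) -> bool:
    """One Bernoulli draw of a Poisson source: P(spike) = 1 - exp(-rate dt / 1000)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0.0:
        return False
    return bool(rng.random() < 1.0 - math.exp(-rate * dt / 1000.0))


def poisson_train(
    rate: float, n_steps: int, rng: np.random.Generator, dt: float = 1.0
) -> np.ndarray:
    """Spike step indices of a Poisson source over ``n_steps`` steps."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0.0:
        return np.empty(0, dtype=np.int64)
    p = 1.0 - math.exp(-rate * dt / 1000.0)
    return np.flatnonzero(rng.random(n_steps) < p).astype(np.int64)


def min_superthreshold_amplitude(params: LIFParams, dt: float = 1.0) -> float:
    """Smallest constant current (nA) that lifts a resting cell over threshold
    within a single ``dt`` step."""
    return (params.v_thresh - params.v_rest) / (
        params.r_m * (1.0 - math.exp(-dt / params.tau_m))
    )


def default_pulse_amplitude(params: LIFParams = RS, dt: float = 1.0) -> float:
    """Default stimulus-pulse amplitude: 1.2x the single-step threshold current."""
    return 1.2 * min_superthreshold_amplitude(params, dt)
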