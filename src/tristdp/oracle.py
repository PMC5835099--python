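"""Dense clock-driven integrator of the plasticity dynamics.

Ground truth for verifying the event-driven engine: every synapse is updated
every timestep from externally supplied pre/post/dopamine event streams (no
membrane dynamics).  Within each step the weight drift uses the same
product-of-exponentials closed form as the lazy update, so the integrator is
step-size-exact rather than an Euler approximation — any disagreement with
the event-driven engine isolates an engine bug, not discretisation error.

Intended for small instances only (a hard guard refuses > 10^4 synapses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plasticity import NeuromodConfig, PairSTDPConfig

__all__ = ["DenseState", "dense_step", "simulate_dense", "DenseTrajectory"]

_MAX_SYNAPSES = 10_000


@dataclass
class DenseState:
    """Dense per-synapse and per-neuron state at ``state.time`` (ms)."""

    pre: np.ndarray  # pre entity index per synapse
    tgt: np.ndarray  # target neuron index per synapse
    w: np.ndarray
    c: np.ndarray  # eligibility trace
    s_pre: np.ndarray  # pre trace per entity (decays with tau_plus)
    s_post: np.ndarray  # post trace per neuron (decays with tau_minus)
    d: np.ndarray  # dopamine concentration per neuron (decays with tau_d)
    time: float = 0.0
    by_pre: list = field(default_factory=list)  # synapse indices per pre entity
    by_tgt: list = field(default_factory=list)  # synapse indices per target

    @classmethod
    def create(cls, n_entities: int, n_neurons: int, pre, tgt, w0) -> "DenseState":
        pre = np.asarray(pre, dtype=np.int64)
        tgt = np.asarray(tgt, dtype=np.int64)
        w = np.array(w0, dtype=np.float64, copy=True)
        if pre.size > _MAX_SYNAPSES:
            raise ValueError(
                f"dense integrator refuses {pre.size} synapses (> {_MAX_SYNAPSES}); "
                "use the event-driven engine for large networks"
            )
        return cls(
            pre=pre,
            tgt=tgt,
            w=w,
            c=np.zeros(pre.size),
            s_pre=np.zeros(n_entities),
            s_post=np.zeros(n_neurons),
            d=np.zeros(n_neurons),
            by_pre=[np.flatnonzero(pre == i) for i in range(n_entities)],
            by_tgt=[np.flatnonzero(tgt == j) for j in range(n_neurons)],
        )


def _bounded(mod: NeuromodConfig) -> bool:
    return np.isfinite(mod.w_min) or np.isfinite(mod.w_max)


def dense_step(
    state: DenseState,
    spikes_pre,
    spikes_post,
    dopamine_events,
    stdp: PairSTDPConfig,
    mod: NeuromodConfig,
    dt: float = 1.0,
    mode: str = "neuromod",
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the dense state by one step of width ``dt``.

    Event lists hold the events of the *current* step time: ``spikes_pre`` /
    ``spikes_post`` are entity / neuron indices, ``dopamine_events`` are
    ``(target, d_c)`` pairs.  Order within the step: decay all traces over
    the elapsed step, apply dopamine increments, apply STDP increments
    (sampling traces before this step's spike increments, so simultaneous
    pre/post spikes never pair), clamp rows whose pre entity spiked,
    integrate ``dw/dt = C D`` over the step with the exact closed form, then
    add the spike increments to the traces.

    Returns copies of ``(w, c)`` taken just before the weight drift — the
    values an event-driven row processing at this step's time would report.
    """
    # (1) analytic decay over the preceding step (all traces start at zero,
    # so the spurious decay before the very first step is a no-op)
    state.c *= math.exp(-dt / mod.tau_c)
    state.d *= math.exp(-dt / mod.tau_d)
    state.s_pre *= math.exp(-dt / stdp.tau_plus)
    state.s_post *= math.exp(-dt / stdp.tau_minus)
    # (2) dopamine increments
    for j, d_c in dopamine_events:
        state.d[j] += d_c
    # (3) STDP increments (to C; directly to w in two-factor mode)
    accum = state.c if mode == "neuromod" else state.w
    for j in spikes_post:
        idx = state.by_tgt[j]
        if idx.size:
            accum[idx] += stdp.a_plus * state.s_pre[state.pre[idx]]
    for i in spikes_pre:
        idx = state.by_pre[i]
        if idx.size:
            accum[idx] -= stdp.a_minus * state.s_post[state.tgt[idx]]
    # weight clamping happens at row-processing (pre-spike) times only
    if _bounded(mod):
        for i in spikes_pre:
            idx = state.by_pre[i]
            if idx.size:
                state.w[idx] = np.clip(state.w[idx], mod.w_min, mod.w_max)
    w_at_t = state.w.copy()
    c_at_t = state.c.copy()
    # (4) exact weight drift over the step ahead
    if mode == "neuromod":
        k = 1.0 / mod.tau_c + 1.0 / mod.tau_d
        gain = (1.0 - math.exp(-dt * k)) / k
        state.w += state.c * state.d[state.tgt] * gain
    # (5) spike increments to the traces
    for i in spikes_pre:
        state.s_pre[i] += 1.0
    for j in spikes_post:
        state.s_post[j] += 1.0
    state.time += dt
    return w_at_t, c_at_t


@dataclass
class DenseTrajectory:
    """Per-millisecond records of weights and eligibility traces.

    Values are sampled at each integer step time after that step's STDP
    events but before the subsequent drift — directly comparable to what the
    event-driven engine reports when it processes a row at that time.
    """

    times: np.ndarray
    w: np.ndarray
    c: np.ndarray


def simulate_dense(
    n_entities: int,
    n_neurons: int,
    pre,
    tgt,
    w0,
    duration: int,
    pre_spikes=(),
    post_spikes=(),
    dopamine_events=(),
    stdp: PairSTDPConfig | None = None,
    mod: NeuromodConfig | None = None,
    dt: float = 1.0,
    mode: str = "neuromod",
    record: bool = False,
) -> tuple[DenseState, DenseTrajectory | None]:
    """Clock-driven simulation over scripted event streams.

    Events are ``(time, id)`` pairs — dopamine events ``(time, target,
    d_c)`` — on the integer-ms grid; ``dt`` must divide 1 ms.  The returned
    state is advanced to ``duration``: all traces decayed to the final time,
    weight drift integrated over ``[0, duration)`` and the end-of-run clamp
    applied, matching an event-driven run finalized at ``duration``.
    """
    stdp = stdp or PairSTDPConfig()
    mod = mod or NeuromodConfig()
    steps_per_ms = round(1.0 / dt)
    if abs(steps_per_ms * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide 1 ms exactly")
    n_steps = int(duration) * steps_per_ms

    state = DenseState.create(n_entities, n_neurons, pre, tgt, w0)

    pre_by_step: dict[int, list[int]] = {}
    post_by_step: dict[int, list[int]] = {}
    dopa_by_step: dict[int, list[tuple[int, float]]] = {}
    for t, i in pre_spikes:
        pre_by_step.setdefault(int(t) * steps_per_ms, []).append(int(i))
    for t, j in post_spikes:
        post_by_step.setdefault(int(t) * steps_per_ms, []).append(int(j))
    for t, j, d_c in dopamine_events:
        dopa_by_step.setdefault(int(t) * steps_per_ms, []).append((int(j), float(d_c)))

    traj_t, traj_w, traj_c = [], [], []
    for k in range(n_steps):
        w_at_t, c_at_t = dense_step(
            state,
            pre_by_step.get(k, ()),
            post_by_step.get(k, ()),
            dopa_by_step.get(k, ()),
            stdp,
            mod,
            dt=dt,
            mode=mode,
        )
        if record and k % steps_per_ms == 0:
            traj_t.append(float(k) * dt)
            traj_w.append(w_at_t)
            traj_c.append(c_at_t)

    # decay the traces over the last step to reach exactly `duration`,
    # then apply the end-of-run flush clamp
    state.c *= math.exp(-dt / mod.tau_c)
    state.d *= math.exp(-dt / mod.tau_d)
    state.s_pre *= math.exp(-dt / stdp.tau_plus)
    state.s_post *= math.exp(-dt / stdp.tau_minus)
    state.time = float(duration)
    if _bounded(mod):
        np.clip(state.w, mod.w_min, mod.w_max, out=state.w)

    traj = (
        DenseTrajectory(np.asarray(traj_t), np.asarray(traj_w), np.asarray(traj_c))
        if record
        else None
    )
    return state, traj
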