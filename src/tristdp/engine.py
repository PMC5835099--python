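"""Event-driven synaptic machinery.

Synapses are stored in rows keyed by their pre-synaptic entity (a neuron or
an external spike source) and are brought up to date *lazily*: a row is only
processed when its pre-synaptic entity spikes (and once more at the end of a
run, so that reported weights include pending dopamine-gated drift).  To make
that possible each post-synaptic neuron keeps a history of timestamped
events — its own spikes and incoming dopaminergic spikes — together with the
post trace ``s_j`` and dopamine concentration ``D`` at those times.
Dopaminergic spikes bypass the delay ring buffer entirely: they never
depolarise the target, they are written straight into its history.

Row processing walks the history entries that fell inside the window since
the last processing, alternating closed-form weight integration
(:func:`tristdp.plasticity.weight_delta`) with eligibility-trace updates,
exactly as a clock-driven integrator would accumulate them step by step.

Time is an integer 1 ms grid throughout; within one timestep, dopamine
entries are recorded before post-spike entries, and a spike never pairs with
a simultaneous spike of the other kind (traces are sampled before being
incremented at the same timestamp).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .plasticity import (
    NeuromodConfig,
    PairSTDPConfig,
    SynapseState,
    TraceState,
    add_trace_spike,
    apply_post_spike,
    apply_pre_spike,
    clamp_weight,
    decay_trace,
    trace_at,
    weight_delta,
)

__all__ = [
    "EntryKind",
    "PostHistoryEntry",
    "PostHistory",
    "SynapticRow",
    "RingBuffer",
    "process_row_pair_stdp",
    "process_row_neuromod",
    "finalize_row",
    "EventDrivenPlasticityNetwork",
    "simulate_events",
]


class EntryKind(Enum):
    POST_SPIKE = "post_spike"
    DOPAMINE = "dopamine"


@dataclass(frozen=True)
class PostHistoryEntry:
    """A timestamped post-synaptic event.

    ``s`` is the post trace at ``time`` (including the +1 increment for a
    post spike); ``d`` is the dopamine concentration at ``time`` (including
    the increment for a dopamine entry).
    """

    time: int
    s: float
    d: float
    kind: EntryKind


class PostHistory:
    """Event history of one post-synaptic neuron.

    ``tau_s`` is the post-trace decay constant (the depression window
    ``tau_minus``), ``tau_d`` the dopamine decay constant.  Entries are kept
    sorted; at equal times dopamine entries precede post-spike entries.
    """

    def __init__(self, tau_s: float, tau_d: float) -> None:
        self.tau_s = float(tau_s)
        self.tau_d = float(tau_d)
        self.entries: list[PostHistoryEntry] = []
        self._times: list[int] = []

    def _last(self) -> PostHistoryEntry | None:
        return self.entries[-1] if self.entries else None

    def record_post_spike(self, t: int) -> PostHistoryEntry:
        """Append a post-spike entry: trace decayed to ``t`` plus one."""
        last = self._last()
        if last is None:
            entry = PostHistoryEntry(t, 1.0, 0.0, EntryKind.POST_SPIKE)
        else:
            if t < last.time:
                raise ValueError("post-spike insertion out of order")
            dt = t - last.time
            entry = PostHistoryEntry(
                t,
                decay_trace(last.s, dt, self.tau_s) + 1.0,
                decay_trace(last.d, dt, self.tau_d),
                EntryKind.POST_SPIKE,
            )
        self.entries.append(entry)
        self._times.append(t)
        return entry

    def record_dopamine_spike(self, t: int, d_c: float) -> PostHistoryEntry:
        """Append a dopamine entry: concentration decayed to ``t`` plus ``d_c``.

        ``d_c`` may be negative (punishment).  At equal times dopamine must be
        recorded before the post spike, so inserting after a same-time post
        entry is a contract violation.
        """
        last = self._last()
        if last is None:
            entry = PostHistoryEntry(t, 0.0, float(d_c), EntryKind.DOPAMINE)
        else:
            if t < last.time or (t == last.time and last.kind is EntryKind.POST_SPIKE):
                raise ValueError("dopamine insertion out of order")
            dt = t - last.time
            entry = PostHistoryEntry(
                t,
                decay_trace(last.s, dt, self.tau_s),
                decay_trace(last.d, dt, self.tau_d) + float(d_c),
                EntryKind.DOPAMINE,
            )
        self.entries.append(entry)
        self._times.append(t)
        return entry

    def entries_in(self, t_old: int, t: int) -> list[PostHistoryEntry]:
        """Entries with ``t_old < time <= t`` (half-open left, closed right)."""
        if t_old > t:
            raise ValueError("t_old must be <= t")
        lo = bisect_right(self._times, t_old)
        hi = bisect_right(self._times, t)
        return self.entries[lo:hi]

    def preceding(self, t_old: int) -> PostHistoryEntry | None:
        """The entry immediately at or before ``t_old`` (None if history starts later)."""
        lo = bisect_right(self._times, t_old)
        return self.entries[lo - 1] if lo else None

    def dopamine_at(self, t: int) -> float:
        """Dopamine concentration decayed to ``t`` from the last entry <= t."""
        entry = self.preceding(t)
        if entry is None:
            return 0.0
        return decay_trace(entry.d, t - entry.time, self.tau_d)

    def post_trace_state(self, t: int) -> TraceState:
        """Post trace as a :class:`TraceState` sampled for a pre spike at ``t``.

        A pre spike does not pair with a simultaneous post spike, so an entry
        at exactly ``t`` contributes its value *before* the +1 increment.
        """
        entry = self.preceding(t)
        if entry is None:
            return TraceState(0.0, float(t))
        s = entry.s
        if entry.time == t and entry.kind is EntryKind.POST_SPIKE:
            s -= 1.0
        return TraceState(s, float(entry.time))


@dataclass
class SynapticRow:
    """All outgoing synapses of one pre-synaptic entity.

    ``t_old`` is the time of the last processing of this row; the pre trace
    ``s_i`` and every synapse's eligibility trace are referenced to it.
    """

    pre_index: int
    synapses: list[SynapseState] = field(default_factory=list)
    t_old: int = 0
    pre_trace: TraceState = field(default_factory=TraceState)


class RingBuffer:
    """Circular per-neuron input accumulators indexed by ``timestep % size``.

    Excitatory and inhibitory contributions are kept separate (they drive
    synaptic currents with distinct decay constants); a deposited weight
    lands exactly ``delay`` steps after the processing time, and a slot is
    zeroed when consumed.
    """

    def __init__(self, n_neurons: int, max_delay: int = 1) -> None:
        if max_delay < 1:
            raise ValueError("max_delay must be >= 1")
        self.max_delay = int(max_delay)
        self.size = self.max_delay + 1
        self.exc = np.zeros((self.size, n_neurons))
        self.inh = np.zeros((self.size, n_neurons))

    def deposit(self, w: float, target: int, delay: int, t: int) -> None:
        """Accumulate ``w`` into ``target``'s input slot for step ``t + delay``.

        Negative weights are inhibitory and accumulate separately.
        """
        if not 1 <= delay <= self.max_delay:
            raise ValueError(f"delay {delay} outside [1, {self.max_delay}]")
        slot = (t + delay) % self.size
        if w >= 0.0:
            self.exc[slot, target] += w
        else:
            self.inh[slot, target] += w

    def advance(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Return and clear the (excitatory, inhibitory) inputs for step ``t``."""
        slot = t % self.size
        exc = self.exc[slot].copy()
        inh = self.inh[slot].copy()
        self.exc[slot] = 0.0
        self.inh[slot] = 0.0
        return exc, inh


def process_row_pair_stdp(
    row: SynapticRow,
    t: int,
    histories: Sequence[PostHistory],
    stdp: PairSTDPConfig,
    bounds: NeuromodConfig,
    ring: RingBuffer | None = None,
) -> None:
    """Two-factor row processing: STDP acts directly on the weight.

    For each synapse, every post spike in ``(t_old, t]`` potentiates the
    weight by sampling the pre trace, then the triggering pre spike at ``t``
    depresses it by sampling the post trace; the clamped weight is deposited
    into the ring buffer.  Dopamine entries in the history are ignored.
    """
    if t <= row.t_old:
        raise ValueError("row must be processed at t > t_old")
    for syn in row.synapses:
        history = histories[syn.target]
        w = syn.weight
        for entry in history.entries_in(row.t_old, t):
            if entry.kind is EntryKind.POST_SPIKE:
                w = apply_post_spike(w, entry.time, row.pre_trace, stdp)
        w = apply_pre_spike(w, t, history.post_trace_state(t), stdp)
        w = clamp_weight(w, bounds)
        syn.weight = w
        if ring is not None:
            ring.deposit(w, syn.target, syn.delay, t)
    add_trace_spike(row.pre_trace, t, stdp.tau_plus)
    row.t_old = t


def _walk_neuromod(
    syn: SynapseState,
    row: SynapticRow,
    t: int,
    history: PostHistory,
    stdp: PairSTDPConfig,
    mod: NeuromodConfig,
    *,
    apply_pre: bool,
) -> None:
    """Advance one synapse from ``row.t_old`` to ``t`` (three-factor rule)."""
    t_c = row.t_old
    prev = history.preceding(t_c)
    d = 0.0 if prev is None else decay_trace(prev.d, t_c - prev.time, history.tau_d)
    w = syn.weight
    c = syn.eligibility
    for entry in history.entries_in(t_c, t):
        w += weight_delta(c, d, t_c, entry.time, mod)
        c = decay_trace(c, entry.time - t_c, mod.tau_c)
        if entry.kind is EntryKind.POST_SPIKE:
            c = apply_post_spike(c, entry.time, row.pre_trace, stdp)
        d = entry.d
        t_c = entry.time
    w += weight_delta(c, d, t_c, t, mod)
    c = decay_trace(c, t - t_c, mod.tau_c)
    if apply_pre:
        c = apply_pre_spike(c, t, history.post_trace_state(t), stdp)
    syn.weight = clamp_weight(w, mod)
    syn.eligibility = c


def process_row_neuromod(
    row: SynapticRow,
    t: int,
    histories: Sequence[PostHistory],
    stdp: PairSTDPConfig,
    mod: NeuromodConfig,
    ring: RingBuffer | None = None,
) -> None:
    """Three-factor row processing, triggered by a pre spike at ``t``.

    Per synapse, walks the history entries in ``(t_old, t]`` maintaining a
    reference time and the dopamine level decayed to it, applying the
    closed-form weight drift over each event-free segment; post spikes add
    pair-STDP potentiation to the eligibility trace and dopamine entries
    update the running concentration.  The pre spike finally adds depression
    to the eligibility trace, the clamped weight is deposited into the ring
    buffer, and the row's pre trace and ``t_old`` advance to ``t``.
    """
    if t <= row.t_old:
        raise ValueError("row must be processed at t > t_old")
    for syn in row.synapses:
        _walk_neuromod(syn, row, t, histories[syn.target], stdp, mod, apply_pre=True)
        if ring is not None:
            ring.deposit(syn.weight, syn.target, syn.delay, t)
    add_trace_spike(row.pre_trace, t, stdp.tau_plus)
    row.t_old = t


def finalize_row(
    row: SynapticRow,
    t: int,
    histories: Sequence[PostHistory],
    stdp: PairSTDPConfig,
    mod: NeuromodConfig,
) -> None:
    """Flush pending weight drift up to ``t`` without a pre spike.

    Semantics-preserving: applies outstanding history entries and the final
    dopamine-gated segment, but no depression, no pre-trace increment and no
    ring-buffer deposit.  Used at simulation end (and for mid-run weight
    snapshots) so reported weights include drift up to the flush time.
    """
    if t < row.t_old:
        raise ValueError("cannot finalize into the past")
    if t == row.t_old:
        return
    for syn in row.synapses:
        _walk_neuromod(syn, row, t, histories[syn.target], stdp, mod, apply_pre=False)
    row.pre_trace = TraceState(trace_at(row.pre_trace, t, stdp.tau_plus), float(t))
    row.t_old = t


class EventDrivenPlasticityNetwork:
    """Event-driven plasticity on scripted spike/dopamine streams.

    A reference-grade driver around :class:`SynapticRow` /
    :class:`PostHistory` for networks whose spikes are supplied externally
    (no membrane dynamics).  Events must be fed in non-decreasing time order;
    state persists between calls, so a run can be stopped and resumed at any
    checkpoint with bit-identical results.
    """

    def __init__(
        self,
        n_neurons: int,
        rows: Iterable[SynapticRow],
        stdp: PairSTDPConfig | None = None,
        mod: NeuromodConfig | None = None,
        mode: str = "neuromod",
        max_delay: int = 1,
    ) -> None:
        if mode not in ("neuromod", "pair"):
            raise ValueError("mode must be 'neuromod' or 'pair'")
        self.stdp = stdp or PairSTDPConfig()
        self.mod = mod or NeuromodConfig()
        self.mode = mode
        self.histories = [
            PostHistory(self.stdp.tau_minus, self.mod.tau_d) for _ in range(n_neurons)
        ]
        self.rows = {row.pre_index: row for row in rows}
        self.ring = RingBuffer(n_neurons, max_delay)

    def step_events(
        self,
        t: int,
        pre: Iterable[int] = (),
        post: Iterable[int] = (),
        dopamine: Iterable[tuple[int, float]] = (),
    ) -> None:
        """Apply all events at time ``t``: dopamine, then post spikes, then rows."""
        for neuron, d_c in dopamine:
            self.histories[neuron].record_dopamine_spike(t, d_c)
        for neuron in post:
            self.histories[neuron].record_post_spike(t)
        for entity in pre:
            row = self.rows.get(entity)
            if row is None:  # a pre spike of an entity with no synapses
                continue
            if self.mode == "neuromod":
                process_row_neuromod(row, t, self.histories, self.stdp, self.mod, self.ring)
            else:
                process_row_pair_stdp(row, t, self.histories, self.stdp, self.mod, self.ring)

    def finalize(self, t: int) -> None:
        """Flush every row to time ``t``.

        Three-factor rows integrate their pending dopamine-gated drift; pair
        rows apply pending post-spike potentiation.  No depression term and
        no ring-buffer deposit (there is no pre spike at ``t``).
        """
        if self.mode == "neuromod":
            for row in self.rows.values():
                finalize_row(row, t, self.histories, self.stdp, self.mod)
        else:
            for row in self.rows.values():
                if t <= row.t_old:
                    continue
                for syn in row.synapses:
                    w = syn.weight
                    for entry in self.histories[syn.target].entries_in(row.t_old, t):
                        if entry.kind is EntryKind.POST_SPIKE:
                            w = apply_post_spike(w, entry.time, row.pre_trace, self.stdp)
                    syn.weight = clamp_weight(w, self.mod)
                row.pre_trace = TraceState(
                    trace_at(row.pre_trace, t, self.stdp.tau_plus), float(t)
                )
                row.t_old = t

    def weights(self) -> dict[int, list[float]]:
        return {i: [s.weight for s in row.synapses] for i, row in self.rows.items()}

    def eligibilities(self) -> dict[int, list[float]]:
        return {i: [s.eligibility for s in row.synapses] for i, row in self.rows.items()}


def simulate_events(
    net: EventDrivenPlasticityNetwork,
    duration: int,
    pre_spikes: Iterable[tuple[int, int]] = (),
    post_spikes: Iterable[tuple[int, int]] = (),
    dopamine_events: Iterable[tuple[int, int, float]] = (),
) -> EventDrivenPlasticityNetwork:
    """Drive ``net`` with (time, id) event lists and finalize at ``duration``.

    ``dopamine_events`` are (time, target, d_c) triples.  Events are grouped
    by timestep and applied in the engine's canonical within-step order.
    """
    by_time: dict[int, tuple[list[int], list[int], list[tuple[int, float]]]] = {}

    def slot(t: int):
        return by_time.setdefault(int(t), ([], [], []))

    for t, e in pre_spikes:
        slot(t)[0].append(int(e))
    for t, n in post_spikes:
        slot(t)[1].append(int(n))
    for t, n, d_c in dopamine_events:
        slot(t)[2].append((int(n), float(d_c)))
    for t in sorted(by_time):
        if t > duration:
            break
        pre, post, dopa = by_time[t]
        net.step_events(t, pre=pre, post=post, dopamine=dopa)
    net.finalize(duration)
    return net
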