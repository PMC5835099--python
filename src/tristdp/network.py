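"""Network assembly and simulation driver.

:class:`Network` collects neurons, external spike sources and projections,
then compiles everything into the flat arrays consumed by
:mod:`tristdp.kernel` for one deterministic run.  All randomness (Poisson
trains, stimulus schedules) is pre-generated by the caller and handed in as
event arrays, so identical inputs give bit-identical outputs.

Pre-synaptic entities are numbered with the LIF neurons first
(``0..n_neurons-1``) followed by external sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kernel
from .neurons import LIFParams
from .plasticity import NeuromodConfig, PairSTDPConfig

__all__ = ["Network", "SimResult"]


@dataclass
class SimResult:
    """Outputs of one :meth:`Network.run` call."""

    n_neurons: int
    duration: int
    spike_times: np.ndarray  # ms
    spike_neurons: np.ndarray
    syn_pre: np.ndarray  # pre entity per plastic synapse
    syn_tgt: np.ndarray
    weights: np.ndarray  # final weights, flushed to `duration`
    eligibility: np.ndarray
    initial_weights: np.ndarray
    summary: pd.DataFrame | None = None
    truncated_spikes: bool = False

    def mean_rate(
        self,
        t_start: float = 0.0,
        t_stop: float | None = None,
        neurons: Iterable[int] | None = None,
    ) -> float:
        """Mean firing rate (Hz) per neuron over a time window."""
        t_stop = self.duration if t_stop is None else t_stop
        sel = (self.spike_times >= t_start) & (self.spike_times < t_stop)
        if neurons is not None:
            sel &= np.isin(self.spike_neurons, np.asarray(list(neurons)))
            n = len(set(neurons))
        else:
            n = self.n_neurons
        window_s = (t_stop - t_start) / 1000.0
        if n == 0 or window_s <= 0:
            return float("nan")
        return float(sel.sum()) / n / window_s


def _as_events(events, ncol: int):
    if events is None:
        return np.zeros((0, ncol))
    arr = np.asarray(events, dtype=np.float64)
    if arr.size == 0:
        return np.zeros((0, ncol))
    if arr.ndim != 2 or arr.shape[1] != ncol:
        raise ValueError(f"expected event rows with {ncol} columns")
    return arr


class Network:
    """A network of LIF neurons, external sources and projections."""

    def __init__(
        self,
        neuron_params: Sequence[LIFParams],
        stdp: PairSTDPConfig | None = None,
        mod: NeuromodConfig | None = None,
        max_delay: int = 1,
    ) -> None:
        self.params = list(neuron_params)
        self.n_neurons = len(self.params)
        self.n_sources = 0
        self.stdp = stdp or PairSTDPConfig()
        self.mod = mod or NeuromodConfig()
        self.max_delay = int(max_delay)
        self._plastic: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        self._static: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []

    # -- construction ----------------------------------------------------

    @property
    def n_entities(self) -> int:
        return self.n_neurons + self.n_sources

    def add_sources(self, count: int) -> np.ndarray:
        """Register external spike sources; returns their entity ids."""
        ids = np.arange(self.n_entities, self.n_entities + count, dtype=np.int64)
        self.n_sources += count
        return ids

    def _check(self, pre: int, targets: np.ndarray, delays: np.ndarray) -> None:
        if not 0 <= pre < self.n_entities:
            raise ValueError(f"unknown pre entity {pre}")
        if targets.size and (targets.min() < 0 or targets.max() >= self.n_neurons):
            raise ValueError("synapse target out of range")
        if delays.size and (delays.min() < 1 or delays.max() > self.max_delay):
            raise ValueError(f"delays must lie in [1, {self.max_delay}]")

    def connect_plastic(self, pre: int, targets, weights, delays=1) -> None:
        """Add dopamine-modulated plastic synapses from one pre entity."""
        targets = np.asarray(targets, dtype=np.int64)
        weights = np.broadcast_to(np.asarray(weights, dtype=np.float64), targets.shape).copy()
        delays = np.broadcast_to(np.asarray(delays, dtype=np.int64), targets.shape).copy()
        self._check(pre, targets, delays)
        self._plastic.append((int(pre), targets, weights, delays))

    def connect_static(self, pre: int, targets, weights, delays=1) -> None:
        """Add static synapses (negative weights are inhibitory)."""
        targets = np.asarray(targets, dtype=np.int64)
        weights = np.broadcast_to(np.asarray(weights, dtype=np.float64), targets.shape).copy()
        delays = np.broadcast_to(np.asarray(delays, dtype=np.int64), targets.shape).copy()
        self._check(pre, targets, delays)
        self._static.append((int(pre), targets, weights, delays))

    def _csr(self, conns):
        n_pre = self.n_entities
        counts = np.zeros(n_pre + 1, dtype=np.int64)
        for pre, tgt, _, _ in conns:
            counts[pre + 1] += tgt.size
        ptr = np.cumsum(counts)
        tgt_all = np.zeros(ptr[-1], dtype=np.int64)
        w_all = np.zeros(ptr[-1])
        d_all = np.ones(ptr[-1], dtype=np.int64)
        fill = ptr[:-1].copy()
        for pre, tgt, w, d in conns:
            k = fill[pre]
            tgt_all[k : k + tgt.size] = tgt
            w_all[k : k + tgt.size] = w
            d_all[k : k + tgt.size] = d
            fill[pre] += tgt.size
        return ptr, tgt_all, w_all, d_all

    # -- simulation ------------------------------------------------------

    def run(
        self,
        duration: int,
        *,
        external_spikes=None,  # rows (time_ms, entity)
        forced_spikes=None,  # rows (time_ms, neuron)
        dopamine_events=None,  # rows (time_ms, target, d_c)
        pulses=None,  # rows (time_ms, neuron, amplitude_nA)
        snapshot_times=None,  # ms at which to record weight summaries
        mask_pre=None,  # pre entities defining the summary group
        record_spikes: bool = True,
        history_capacity: int | None = None,
        spike_capacity: int | None = None,
        initial_v: np.ndarray | None = None,
    ) -> SimResult:
        """Simulate ``duration`` ms and return flushed final weights.

        The run is one-shot: the network description itself is not mutated,
        so repeated calls with identical inputs are bit-identical.
        """
        n = self.n_neurons
        n_steps = int(duration)
        par = self.params
        vrest = np.array([p.v_rest for p in par])
        vreset = np.array([p.v_reset for p in par])
        vthresh = np.array([p.v_thresh for p in par])
        ioff = np.array([p.i_offset for p in par])
        rm = np.array([p.r_m for p in par])
        dec_m = np.array([np.exp(-1.0 / p.tau_m) for p in par])
        dec_e = np.array([np.exp(-1.0 / p.tau_syn_e) for p in par])
        dec_i = np.array([np.exp(-1.0 / p.tau_syn_i) for p in par])
        refrac_steps = np.array([int(round(p.tau_refrac)) for p in par], dtype=np.int64)

        v = vrest.copy() if initial_v is None else np.asarray(initial_v, dtype=np.float64).copy()
        isyn_e = np.zeros(n)
        isyn_i = np.zeros(n)
        refrac = np.zeros(n, dtype=np.int64)

        p_ptr, p_tgt, p_w, p_delay = self._csr(self._plastic)
        st_ptr, st_tgt, st_w, st_delay = self._csr(self._static)
        p_c = np.zeros(p_tgt.size)
        w0 = p_w.copy()
        row_t_old = np.zeros(self.n_entities, dtype=np.int64)
        row_s_i = np.zeros(self.n_entities)

        syn_pre = np.repeat(np.arange(self.n_entities), np.diff(p_ptr))

        # reverse adjacency (plastic rows targeting each neuron), for pruning
        rev: list[set[int]] = [set() for _ in range(n)]
        for e, j in zip(syn_pre, p_tgt):
            rev[j].add(int(e))
        rev_ptr = np.zeros(n + 1, dtype=np.int64)
        for j in range(n):
            rev_ptr[j + 1] = rev_ptr[j] + len(rev[j])
        rev_row = np.zeros(rev_ptr[-1], dtype=np.int64)
        for j in range(n):
            rev_row[rev_ptr[j] : rev_ptr[j + 1]] = sorted(rev[j])

        def sorted_events(arr, ncol):
            ev = _as_events(arr, ncol)
            ev = ev[(ev[:, 0] >= 0) & (ev[:, 0] < n_steps)]
            order = np.argsort(ev[:, 0], kind="stable")
            return ev[order]

        ext = sorted_events(external_spikes, 2)
        forced = sorted_events(forced_spikes, 2)
        dopa = sorted_events(dopamine_events, 3)
        pul = sorted_events(pulses, 3)

        snap = (
            np.asarray(sorted(snapshot_times), dtype=np.int64)
            if snapshot_times is not None
            else np.zeros(0, dtype=np.int64)
        )
        snap_mask_mean = np.full(snap.size, np.nan)
        snap_global_mean = np.full(snap.size, np.nan)
        if mask_pre is not None:
            mask_set = set(int(x) for x in mask_pre)
            mask = np.array([int(e) in mask_set for e in syn_pre], dtype=np.bool_)
        else:
            mask = np.zeros(syn_pre.size, dtype=np.bool_)

        if history_capacity is None:
            if n * (n_steps + 2) <= 20_000_000:
                history_capacity = n_steps + 2
            else:
                history_capacity = 8192  # relies on snapshot flushes for compaction
        cap = int(history_capacity)
        hist_t = np.zeros((n, cap), dtype=np.int64)
        hist_s = np.zeros((n, cap))
        hist_d = np.zeros((n, cap))
        hist_kind = np.zeros((n, cap), dtype=np.uint8)
        hist_len = np.zeros(n, dtype=np.int64)

        if spike_capacity is None:
            spike_capacity = int(min(30_000_000, max(1_000_000, n * n_steps // 10)))
        spike_t = np.zeros(spike_capacity if record_spikes else 0, dtype=np.int64)
        spike_n = np.zeros(spike_capacity if record_spikes else 0, dtype=np.int64)

        rb_size = self.max_delay + 1
        rb_exc = np.zeros((rb_size, n))
        rb_inh = np.zeros((rb_size, n))

        ns, status = kernel.simulate_core(
            n_steps,
            v, isyn_e, isyn_i, refrac,
            vrest, vreset, vthresh, ioff, rm, dec_m, dec_e, dec_i, refrac_steps,
            p_ptr, p_tgt, p_delay, p_w, p_c, row_t_old, row_s_i,
            st_ptr, st_tgt, st_delay, st_w,
            ext[:, 0].astype(np.int64), ext[:, 1].astype(np.int64),
            forced[:, 0].astype(np.int64), forced[:, 1].astype(np.int64),
            dopa[:, 0].astype(np.int64), dopa[:, 1].astype(np.int64), dopa[:, 2].copy(),
            pul[:, 0].astype(np.int64), pul[:, 1].astype(np.int64), pul[:, 2].copy(),
            self.stdp.a_plus, self.stdp.a_minus,
            self.stdp.tau_plus, self.stdp.tau_minus,
            self.mod.tau_c, self.mod.tau_d, self.mod.w_min, self.mod.w_max,
            hist_t, hist_s, hist_d, hist_kind, hist_len, rev_ptr, rev_row,
            rb_exc, rb_inh,
            spike_t, spike_n,
            snap, snap_mask_mean, snap_global_mean, mask,
            record_spikes,
        )
        if status == kernel.STATUS_HISTORY_OVERFLOW:
            raise RuntimeError(
                "post-synaptic history overflow; increase history_capacity or "
                "provide snapshot_times so lagging rows get flushed"
            )

        summary = None
        if snap.size:
            summary = pd.DataFrame(
                {
                    "time_ms": snap,
                    "group_mean_nA": snap_mask_mean,
                    "global_mean_nA": snap_global_mean,
                }
            )
        return SimResult(
            n_neurons=n,
            duration=n_steps,
            spike_times=spike_t[:ns].copy(),
            spike_neurons=spike_n[:ns].copy(),
            syn_pre=syn_pre,
            syn_tgt=p_tgt,
            weights=p_w,
            eligibility=p_c,
            initial_weights=w0,
            summary=summary,
            truncated_spikes=status == kernel.STATUS_SPIKES_TRUNCATED,
        )
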