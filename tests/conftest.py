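"""Shared helpers: random plasticity scenarios run through each implementation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from tristdp import (
    EventDrivenPlasticityNetwork,
    NeuromodConfig,
    PairSTDPConfig,
    SynapseState,
    SynapticRow,
    simulate_dense,
    simulate_events,
)
from tristdp.network import Network
from tristdp.neurons import LIFParams


@dataclass
class Scenario:
    """A random small plasticity problem on scripted event streams."""

    n_neurons: int
    n_sources: int
    pre: np.ndarray  # pre entity per synapse
    tgt: np.ndarray
    w0: np.ndarray
    duration: int
    pre_spikes: list  # (t, entity); includes neuron entities' own spikes
    post_spikes: list  # (t, neuron)
    dopamine: list  # (t, neuron, d_c)
    stdp: PairSTDPConfig
    mod: NeuromodConfig

    @property
    def n_entities(self) -> int:
        return self.n_neurons + self.n_sources


def make_scenario(
    rng: np.random.Generator,
    *,
    n_neurons: int = 8,
    n_sources: int = 6,
    n_synapses: int = 60,
    duration: int = 2000,
    pre_rate: float = 0.02,
    post_rate: float = 0.01,
    dopamine_rate: float = 0.004,
    stdp: PairSTDPConfig | None = None,
    mod: NeuromodConfig | None = None,
) -> Scenario:
    n_ent = n_neurons + n_sources
    pre = rng.integers(0, n_ent, n_synapses)
    tgt = rng.integers(0, n_neurons, n_synapses)
    w0 = rng.normal(2.0, 0.5, n_synapses)
    post_spikes = [
        (int(t), j)
        for j in range(n_neurons)
        for t in np.flatnonzero(rng.random(duration) < post_rate)
        if t >= 1
    ]
    # a neuron's own spikes also trigger its outgoing row
    pre_spikes = [(t, j) for (t, j) in post_spikes]
    pre_spikes += [
        (int(t), e)
        for e in range(n_neurons, n_ent)
        for t in np.flatnonzero(rng.random(duration) < pre_rate)
        if t >= 1
    ]
    dopamine = [
        (int(t), j, float(rng.choice([0.1, -0.05])))
        for j in range(n_neurons)
        for t in np.flatnonzero(rng.random(duration) < dopamine_rate)
        if t >= 1
    ]
    return Scenario(
        n_neurons=n_neurons,
        n_sources=n_sources,
        pre=pre,
        tgt=tgt,
        w0=w0,
        duration=duration,
        pre_spikes=sorted(pre_spikes),
        post_spikes=sorted(post_spikes),
        dopamine=sorted(dopamine),
        stdp=stdp or PairSTDPConfig(),
        mod=mod or NeuromodConfig(w_min=-np.inf, w_max=np.inf),
    )


def build_rows(sc: Scenario):
    """Object-level rows plus the synapse-index layout used to read them back."""
    by_pre: dict[int, list[int]] = {}
    for k in range(sc.pre.size):
        by_pre.setdefault(int(sc.pre[k]), []).append(k)
    rows = [
        SynapticRow(
            pre_index=e,
            synapses=[SynapseState(weight=sc.w0[k], target=int(sc.tgt[k])) for k in ks],
        )
        for e, ks in by_pre.items()
    ]
    return rows, by_pre


def run_object_engine(sc: Scenario, mode: str = "neuromod"):
    """Run the object-level event-driven engine; returns (w, c) per synapse."""
    rows, by_pre = build_rows(sc)
    net = EventDrivenPlasticityNetwork(sc.n_neurons, rows, sc.stdp, sc.mod, mode=mode)
    simulate_events(net, sc.duration, sc.pre_spikes, sc.post_spikes, sc.dopamine)
    w = np.empty(sc.pre.size)
    c = np.empty(sc.pre.size)
    for row in net.rows.values():
        for syn, k in zip(row.synapses, by_pre[row.pre_index]):
            w[k] = syn.weight
            c[k] = syn.eligibility
    return w, c


def run_oracle(sc: Scenario, mode: str = "neuromod", record: bool = False):
    state, traj = simulate_dense(
        sc.n_entities,
        sc.n_neurons,
        sc.pre,
        sc.tgt,
        sc.w0,
        sc.duration,
        pre_spikes=sc.pre_spikes,
        post_spikes=sc.post_spikes,
        dopamine_events=sc.dopamine,
        stdp=sc.stdp,
        mod=sc.mod,
        mode=mode,
        record=record,
    )
    return state, traj


def run_kernel_engine(sc: Scenario):
    """Run the flat-array kernel on the same scenario (forced spikes, no LIF)."""
    params = [LIFParams(v_thresh=1e9) for _ in range(sc.n_neurons)]
    net = Network(params, sc.stdp, sc.mod)
    net.add_sources(sc.n_sources)
    _, by_pre = build_rows(sc)
    order = []
    for e in sorted(by_pre):
        net.connect_plastic(e, [int(sc.tgt[k]) for k in by_pre[e]],
                            [sc.w0[k] for k in by_pre[e]])
        order += by_pre[e]
    res = net.run(
        sc.duration,
        external_spikes=[(t, e) for (t, e) in sc.pre_spikes if e >= sc.n_neurons],
        forced_spikes=sc.post_spikes,
        dopamine_events=sc.dopamine,
    )
    w = np.empty(sc.pre.size)
    c = np.empty(sc.pre.size)
    for i, k in enumerate(order):
        w[k] = res.weights[i]
        c[k] = res.eligibility[i]
    return w, c


def max_rel_err(a, b, floor: float = 1e-3) -> float:
    """Worst-case relative error with an absolute floor.

    Values below ``floor`` are compared on the absolute scale ``floor`` (so a
    1e-9 relative bound implies |a-b| < 1e-12 near zero): relative error on
    nearly-fully-decayed traces is dominated by double-precision round-off
    in the O(1) terms that cancelled to produce them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scale = np.maximum(floor, np.maximum(np.abs(a), np.abs(b)))
    return float(np.max(np.abs(a - b) / scale)) if a.size else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)
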