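"""Optional matplotlib figures mirroring the standard experiment panels."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_delay_sweep", "plot_raster", "plot_weight_summary"]


def plot_delay_sweep(sweep, ax=None):
    """Final weight change vs. reinforcement delay (reward and punishment)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for dc, df in sweep.groupby("d_c"):
        label = f"$D_c$ = {dc:+g}"
        ax.plot(df["dopamine_time_ms"], df["delta_w_nA"], marker="o", label=label)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("dopaminergic spike time (ms)")
    ax.set_ylabel(r"$\Delta w$ (nA)")
    ax.legend()
    return ax


def plot_raster(sim, t_start=0, t_stop=None, ax=None, **scatter_kw):
    """Spike raster of a :class:`~tristdp.network.SimResult` window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_stop = sim.duration if t_stop is None else t_stop
    sel = (sim.spike_times >= t_start) & (sim.spike_times < t_stop)
    scatter_kw.setdefault("s", 2)
    scatter_kw.setdefault("color", "k")
    ax.scatter(sim.spike_times[sel], sim.spike_neurons[sel], **scatter_kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_xlim(t_start, t_stop)
    return ax


def plot_weight_summary(summary, ax=None):
    """Mean S1-outgoing vs. network-wide plastic weight over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_min = np.asarray(summary["time_ms"]) / 60_000.0
    ax.plot(t_min, summary["group_mean_nA"], color="green", label="$S_1$ outgoing")
    ax.plot(t_min, summary["global_mean_nA"], color="tab:blue", label="all plastic")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("mean weight (nA)")
    ax.legend()
    return ax
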