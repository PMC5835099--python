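"""Writers and loaders for simulation outputs.

Spike rasters are tab-separated text (``time_ms``, ``neuron_id``,
``population``), weight summaries are CSV (``time_ms``, ``group_mean_nA``,
``global_mean_nA``), full weight snapshots are NPZ containers, and run
manifests are JSON.  All times are integer milliseconds; weights are written
in nA at full double precision so round-trips are exact.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_weight_summary",
    "read_weight_summary",
    "write_weight_snapshot",
    "read_weight_snapshot",
    "write_manifest",
]


def _io_error(path, exc):
    return OSError(f"failed writing {path}: {exc}")


def write_spikes(spike_times, spike_neurons, path, population="main") -> None:
    """Write a spike raster as TSV; events must be time-sorted."""
    t = np.asarray(spike_times, dtype=np.int64)
    n = np.asarray(spike_neurons, dtype=np.int64)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be non-decreasing")
    if np.isscalar(population) or isinstance(population, str):
        pop = np.full(t.size, population, dtype=object)
    else:
        pop = np.asarray(population, dtype=object)
    df = pd.DataFrame({"time_ms": t, "neuron_id": n, "population": pop})
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:  # pragma: no cover
        raise _io_error(path, exc) from exc


def read_spikes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_weight_summary(summary: pd.DataFrame, path) -> None:
    """Write the (time, group mean, global mean) weight log as CSV."""
    cols = ["time_ms", "group_mean_nA", "global_mean_nA"]
    missing = [c for c in cols if c not in summary.columns]
    if missing:
        raise ValueError(f"summary missing columns {missing}")
    try:
        summary[cols].to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover
        raise _io_error(path, exc) from exc


def read_weight_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_weight_snapshot(path, *, syn_pre, syn_tgt, weights, eligibility) -> None:
    """Full per-synapse state in an NPZ container."""
    np.savez(
        path,
        syn_pre=np.asarray(syn_pre, dtype=np.int64),
        syn_tgt=np.asarray(syn_tgt, dtype=np.int64),
        weights=np.asarray(weights, dtype=np.float64),
        eligibility=np.asarray(eligibility, dtype=np.float64),
    )


def read_weight_snapshot(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def write_manifest(path, *, experiment: str, seeds: dict, extra: dict | None = None) -> None:
    """Run manifest: seeds, package/library versions and wall-clock time."""
    import numpy
    from . import __version__

    manifest = {
        "experiment": experiment,
        "seeds": seeds,
        "versions": {"tristdp": __version__, "numpy": numpy.__version__},
        "wall_clock_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
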