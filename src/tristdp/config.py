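"""Experiment configuration: loading, validation and execution.

Configurations are YAML files validated into :class:`ExperimentConfig`
before any simulation starts; unknown keys are rejected and every numeric
field carries units in its name or docstring.  An empty file yields the
default parameterisation (the RS/FS neuron constants and the standard STDP
table).  Three named seed streams (connectivity, stimulus, noise) allow one
source of randomness to be varied at a time.

:func:`run_experiment` executes the configured experiment and writes its
artifacts — rasters, weight summaries, a resolved copy of the configuration
and a run manifest — into an output directory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as tio
from .experiments import (
    build_conditioning_network,
    run_conditioning,
    run_reward_punishment,
    sweep_delay,
)
from .neurons import FS, RS, LIFParams
from .plasticity import NeuromodConfig, PairSTDPConfig

__all__ = ["ExperimentConfig", "load_config", "save_config", "run_experiment"]

logger = logging.getLogger("tristdp")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Seeds(_Strict):
    connectivity: int = 1
    stimulus: int = 2
    noise: int = 3


class STDPSection(_Strict):
    """Pair-STDP window parameters (amplitudes dimensionless, taus in ms)."""

    a_plus: float = Field(1.0, gt=0)
    a_minus: float = Field(1.0, gt=0)
    tau_plus: float = Field(10.0, gt=0)
    tau_minus: float = Field(12.0, gt=0)

    def build(self) -> PairSTDPConfig:
        return PairSTDPConfig(self.a_plus, self.a_minus, self.tau_plus, self.tau_minus)


class NeuromodSection(_Strict):
    """Eligibility/dopamine decay constants (ms) and weight bounds (nA)."""

    tau_c: float = Field(1000.0, gt=0)
    tau_d: float = Field(200.0, gt=0)

    def build(self, w_min: float, w_max: float) -> NeuromodConfig:
        return NeuromodConfig(self.tau_c, self.tau_d, w_min, w_max)


class NeuronSection(_Strict):
    """Optional overrides of the RS/FS LIF parameters."""

    rs: dict = Field(default_factory=dict)
    fs: dict = Field(default_factory=dict)

    def build(self) -> tuple[LIFParams, LIFParams]:
        from dataclasses import replace

        return replace(RS, **self.rs), replace(FS, **self.fs)


class SingleSynapseSection(_Strict):
    d_c: float = 0.1
    delay_min_ms: int = Field(4, ge=4)
    delay_max_ms: int = Field(3000, ge=4)
    n_points: int = Field(30, ge=2)
    w_init_nA: float = 0.0


class RewardPunishmentSection(_Strict):
    n_neurons: int = Field(10, ge=1)
    input_rate_hz: float = Field(50.0, ge=0)
    w_init_nA: float = 1.5
    duration_ms: int = Field(14_000, gt=0)
    reward_dc: float = 0.01
    punish_dc: float = -0.002
    tau_c: float = Field(100.0, gt=0)
    tau_d: float = Field(5.0, gt=0)
    w_max_nA: float = 6.0


class ConditioningSection(_Strict):
    n_total: int = Field(200, ge=40)
    duration_ms: int = Field(600_000, gt=0)
    d_c: float = 0.005
    w_init_nA: float = 0.7
    w_inh_nA: float = -2.0
    w_noise_nA: float = 2.0
    w_max_nA: float = 2.8
    noise_rate_hz: float = Field(10.0, ge=0)
    cadence_ms: int = Field(1000, gt=0)
    contingent: bool = True


class ExperimentConfig(_Strict):
    """Fully validated description of one experiment run."""

    experiment: Literal["single_synapse", "reward_punishment", "conditioning"] = (
        "single_synapse"
    )
    seeds: Seeds = Field(default_factory=Seeds)
    stdp: STDPSection = Field(default_factory=STDPSection)
    neuromod: NeuromodSection = Field(default_factory=NeuromodSection)
    neurons: NeuronSection = Field(default_factory=NeuronSection)
    single_synapse: SingleSynapseSection = Field(default_factory=SingleSynapseSection)
    reward_punishment: RewardPunishmentSection = Field(
        default_factory=RewardPunishmentSection
    )
    conditioning: ConditioningSection = Field(default_factory=ConditioningSection)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self):
        if self.single_synapse.delay_max_ms < self.single_synapse.delay_min_ms:
            raise ValueError("delay_max_ms must be >= delay_min_ms")
        return self


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML configuration (empty file = all defaults)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return ExperimentConfig.model_validate(raw)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def _delay_grid(section: SingleSynapseSection) -> np.ndarray:
    grid = np.unique(
        np.round(
            np.geomspace(section.delay_min_ms, section.delay_max_ms, section.n_points)
        ).astype(int)
    )
    return grid


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Run the configured experiment, writing artifacts into ``out_dir``.

    Returns a small dict of headline numbers (also written to the manifest).
    Identical configuration and seeds produce byte-identical data outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    save_config(cfg, out / "resolved_config.yaml")
    stdp = cfg.stdp.build()
    headline: dict = {}

    if cfg.experiment == "single_synapse":
        grid = _delay_grid(cfg.single_synapse)
        mod = NeuromodConfig(cfg.neuromod.tau_c, cfg.neuromod.tau_d, -np.inf, np.inf)
        frames = []
        for dc in (cfg.single_synapse.d_c, -cfg.single_synapse.d_c):
            df = sweep_delay(grid, dc, w_init=cfg.single_synapse.w_init_nA,
                             stdp=stdp, mod=mod)
            df.insert(0, "d_c", dc)
            frames.append(df)
        import pandas as pd

        sweep = pd.concat(frames, ignore_index=True)
        sweep.to_csv(out / "delay_sweep.csv", index=False)
        reward = frames[0]["delta_w_nA"]
        headline = {
            "peak_reward_delta_w_nA": float(reward.iloc[0]),
            "tail_reward_delta_w_nA": float(reward.iloc[-1]),
        }
        logger.info("delay sweep: peak dw=%+.4f nA, tail dw=%+.4f nA",
                    *headline.values())

    elif cfg.experiment == "reward_punishment":
        s = cfg.reward_punishment
        res = run_reward_punishment(
            n_neurons=s.n_neurons, input_rate_hz=s.input_rate_hz,
            w_init=s.w_init_nA, duration=s.duration_ms,
            reward_dc=s.reward_dc, punish_dc=s.punish_dc,
            tau_c=s.tau_c, tau_d=s.tau_d, w_max=s.w_max_nA,
            seed=cfg.seeds.noise, stdp=stdp,
        )
        tio.write_spikes(res.sim.spike_times, res.sim.spike_neurons,
                         out / "spikes.tsv")
        tio.write_weight_snapshot(
            out / "weights.npz", syn_pre=res.sim.syn_pre, syn_tgt=res.sim.syn_tgt,
            weights=res.sim.weights, eligibility=res.sim.eligibility,
        )
        headline = {
            "baseline_rate_hz": res.baseline_rate_hz,
            "reward_rate_hz": res.reward_rate_hz,
            "punish_rate_hz": res.punish_rate_hz,
        }
        logger.info("rates: baseline=%.2f reward=%.2f punish=%.2f Hz",
                    *headline.values())

    else:  # conditioning
        s = cfg.conditioning
        cnet = build_conditioning_network(
            s.n_total, cfg.seeds.connectivity, w_init=s.w_init_nA,
            w_inh=s.w_inh_nA, w_noise=s.w_noise_nA, w_max=s.w_max_nA, stdp=stdp,
        )
        res = run_conditioning(
            cnet, s.duration_ms, stimulus_seed=cfg.seeds.stimulus,
            noise_seed=cfg.seeds.noise, d_c=s.d_c,
            noise_rate_hz=s.noise_rate_hz, cadence_ms=s.cadence_ms,
            contingent=s.contingent,
        )
        tio.write_weight_summary(res.summary, out / "weight_summary.csv")
        tio.write_spikes(res.sim.spike_times, res.sim.spike_neurons,
                         out / "spikes.tsv")
        tio.write_weight_snapshot(
            out / "weights.npz", syn_pre=res.sim.syn_pre, syn_tgt=res.sim.syn_tgt,
            weights=res.sim.weights, eligibility=res.sim.eligibility,
        )
        headline = {
            "s1_mean_nA": res.s1_mean_nA,
            "global_mean_nA": res.global_mean_nA,
            "separation_nA": res.separation_nA,
        }
        logger.info("conditioning: S1 mean=%.3f nA, global mean=%.3f nA",
                    res.s1_mean_nA, res.global_mean_nA)

    tio.write_manifest(
        out / "manifest.json", experiment=cfg.experiment,
        seeds=cfg.seeds.model_dump(), extra={"headline": headline},
    )
    return headline
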