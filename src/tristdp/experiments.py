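"""Builders and runners for the reinforcement-learning experiments.

Three protocols:

* :func:`run_single_synapse_protocol` — a single causal pre→post pair
  followed by one delayed dopaminergic spike; sweeping the delay maps out
  how the eligibility trace converts delayed reinforcement into weight
  change.
* :func:`run_reward_punishment` — ten LIF neurons driven by independent
  50 Hz Poisson sources through plastic synapses; global reward pulses
  potentiate the drive and later punishment pulses depress it.
* Pavlovian conditioning / credit assignment — a recurrent network of
  80 % regular-spiking and 20 % fast-spiking neurons with 10 % random
  connectivity; overlapping random groups of neurons represent stimuli
  ``S_1..S_Ng``, presented in random order as 1 ms super-threshold current
  pulses, and every ``S_1`` presentation is followed (after a random delay
  of up to one second) by a global dopamine reward.  Synapses out of the
  ``S_1`` group are reliably eligibility-tagged at reward time, so their
  mean weight grows past the network-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Network, SimResult
from .neurons import FS, RS, default_pulse_amplitude, poisson_train
from .plasticity import NeuromodConfig, PairSTDPConfig, SynapseState
from .engine import EventDrivenPlasticityNetwork, SynapticRow, simulate_events

__all__ = [
    "run_single_synapse_protocol",
    "sweep_delay",
    "run_reward_punishment",
    "RewardPunishmentResult",
    "StimulusSchedule",
    "stimulus_schedule",
    "ConditioningNetwork",
    "build_conditioning_network",
    "run_conditioning",
    "ConditioningResult",
    "summarize_weights",
]


# ---------------------------------------------------------------------------
# single-synapse delayed reinforcement
# ---------------------------------------------------------------------------

def run_single_synapse_protocol(
    dopamine_time: int,
    d_c: float = 0.1,
    *,
    w_init: float = 0.0,
    stdp: PairSTDPConfig | None = None,
    mod: NeuromodConfig | None = None,
    horizon: int = 2000,
) -> float:
    """Final weight of one synapse after a delayed reinforcement signal.

    A single pre-synaptic spike at 1 ms drives two post-synaptic neurons to
    fire at 3 ms; one dopaminergic spike of amplitude ``d_c`` (negative for
    punishment) arrives at ``dopamine_time`` (>= 4 ms).  The run is
    finalized ``horizon`` ms after the dopaminergic spike, long enough for
    the gated drift to integrate essentially to completion.  Weight bounds
    are disabled by default so reward and punishment are exact mirrors.
    """
    if dopamine_time < 4:
        raise ValueError("dopamine_time must be >= 4 ms (after the 3 ms post spike)")
    stdp = stdp or PairSTDPConfig()
    mod = mod or NeuromodConfig(w_min=-np.inf, w_max=np.inf)
    pre_entity = 2
    row = SynapticRow(
        pre_index=pre_entity,
        synapses=[SynapseState(weight=w_init, target=j) for j in (0, 1)],
    )
    net = EventDrivenPlasticityNetwork(2, [row], stdp, mod)
    duration = int(dopamine_time) + int(horizon)
    simulate_events(
        net,
        duration,
        pre_spikes=[(1, pre_entity)],
        post_spikes=[(3, 0), (3, 1)],
        dopamine_events=[(int(dopamine_time), 0, d_c), (int(dopamine_time), 1, d_c)],
    )
    return net.rows[pre_entity].synapses[0].weight


def sweep_delay(
    delays,
    d_c: float = 0.1,
    *,
    w_init: float = 0.0,
    stdp: PairSTDPConfig | None = None,
    mod: NeuromodConfig | None = None,
) -> pd.DataFrame:
    """Delay sweep of the single-synapse protocol (one run per data point)."""
    rows = []
    for delay in delays:
        w = run_single_synapse_protocol(
            int(delay), d_c, w_init=w_init, stdp=stdp, mod=mod
        )
        rows.append({"dopamine_time_ms": int(delay), "final_weight_nA": w,
                     "delta_w_nA": w - w_init})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population reward / punishment
# ---------------------------------------------------------------------------

@dataclass
class RewardPunishmentResult:
    sim: SimResult
    baseline_rate_hz: float
    reward_rate_hz: float
    punish_rate_hz: float


def run_reward_punishment(
    *,
    n_neurons: int = 10,
    input_rate_hz: float = 50.0,
    w_init: float = 1.5,
    duration: int = 14_000,
    reward_times=(2000, 3000, 4000),
    reward_dc: float = 0.01,
    punish_times=(8000, 9000, 10_000),
    punish_dc: float = -0.002,
    tau_c: float = 100.0,
    tau_d: float = 5.0,
    w_min: float = 0.0,
    w_max: float = 6.0,
    seed: int = 0,
    with_dopamine: bool = True,
    stdp: PairSTDPConfig | None = None,
) -> RewardPunishmentResult:
    """Reward then punish the synapses driving a small population.

    Each neuron receives one independent Poisson source through a plastic
    synapse (initial weight ``w_init`` nA).  A single dopaminergic source
    projects to every neuron; rewards arrive early in the run, punishments
    later.  Epoch rates are measured at baseline (0-2 s), after the rewards
    (5-8 s) and after the punishments (11-14 s).
    """
    stdp = stdp or PairSTDPConfig()
    mod = NeuromodConfig(tau_c=tau_c, tau_d=tau_d, w_min=w_min, w_max=w_max)
    net = Network([RS] * n_neurons, stdp, mod)
    sources = net.add_sources(n_neurons)
    for j, src in enumerate(sources):
        net.connect_plastic(int(src), [j], w_init)

    rng = np.random.default_rng(seed)
    ext = []
    for src in sources:
        for t in poisson_train(input_rate_hz, duration, rng):
            ext.append((int(t), int(src)))

    dopa = []
    if with_dopamine:
        for t in reward_times:
            dopa += [(int(t), j, reward_dc) for j in range(n_neurons)]
        for t in punish_times:
            dopa += [(int(t), j, punish_dc) for j in range(n_neurons)]

    sim = net.run(duration, external_spikes=ext, dopamine_events=dopa)
    return RewardPunishmentResult(
        sim=sim,
        baseline_rate_hz=sim.mean_rate(0, 2000),
        reward_rate_hz=sim.mean_rate(5000, 8000),
        punish_rate_hz=sim.mean_rate(11_000, 14_000),
    )


# ---------------------------------------------------------------------------
# Pavlovian conditioning / credit assignment
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Stimulus presentations and reward (dopamine) events."""

    stimuli: list  # (time_ms, group_index)
    rewards: list  # (time_ms, d_c)


def stimulus_schedule(
    n_groups: int,
    duration: int,
    seed,
    *,
    interval_ms=(100, 300),
    reward_group: int = 0,
    reward_delay_max: int = 1000,
    d_c: float = 0.01,
    contingent: bool = True,
) -> StimulusSchedule:
    """Random stimulus stream with rewards tied to one group.

    Groups are drawn uniformly with inter-stimulus intervals uniform in
    ``interval_ms``; every presentation of ``reward_group`` is followed by
    exactly one dopaminergic reward after a delay uniform in
    ``(0, reward_delay_max]`` ms.  With ``contingent=False`` the reward
    contingency is destroyed: each presentation (of any group) is rewarded
    with probability ``1/n_groups``, preserving the overall reward rate
    while decorrelating rewards from group identity.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stimuli = []
    rewards = []
    t = int(rng.integers(interval_ms[0], interval_ms[1] + 1))
    while t < duration:
        k = int(rng.integers(n_groups))
        stimuli.append((t, k))
        if contingent:
            rewarded = k == reward_group
        else:
            rewarded = rng.random() < 1.0 / n_groups
        if rewarded:
            t_r = t + int(rng.integers(1, reward_delay_max + 1))
            if t_r < duration:
                rewards.append((t_r, d_c))
        t += int(rng.integers(interval_ms[0], interval_ms[1] + 1))
    return StimulusSchedule(stimuli=stimuli, rewards=rewards)


@dataclass
class ConditioningNetwork:
    """A built conditioning network plus its realized structure."""

    net: Network
    groups: np.ndarray  # (n_groups, group_size) neuron indices
    noise_sources: np.ndarray  # entity id of the noise source of each neuron
    n_total: int
    n_excitatory: int
    n_plastic_synapses: int
    n_static_synapses: int
    seed: int

    @property
    def n_groups(self) -> int:
        return self.groups.shape[0]

    @property
    def group_size(self) -> int:
        return self.groups.shape[1]

    @property
    def n_recurrent_synapses(self) -> int:
        """Recurrent synapses (plastic + inhibitory, excluding noise input)."""
        return self.n_plastic_synapses + self.n_static_synapses


def build_conditioning_network(
    n_total: int,
    seed: int = 0,
    *,
    p_connect: float = 0.1,
    frac_excitatory: float = 0.8,
    w_init: float = 0.7,
    w_inh: float = -2.0,
    w_noise: float = 2.0,
    w_max: float = 2.8,
    stdp: PairSTDPConfig | None = None,
    mod: NeuromodConfig | None = None,
) -> ConditioningNetwork:
    """Build the recurrent conditioning network.

    ``n_total`` neurons split into 80 % regular-spiking (excitatory, plastic
    outgoing synapses) and 20 % fast-spiking (static inhibitory outgoing
    synapses), connected all-to-all with probability ``p_connect`` and no
    self-connections.  ``n_total/10`` stimulus groups of ``n_total/20``
    neurons are sampled with replacement across groups (a neuron may sit in
    several groups) and without replacement within a group.  Every neuron
    additionally gets one private Poisson noise source (static synapse).
    """
    if n_total < 40 or n_total % 20:
        raise ValueError("n_total must be a multiple of 20 and >= 40")
    rng = np.random.default_rng(seed)
    n_exc = int(round(frac_excitatory * n_total))
    params = [RS] * n_exc + [FS] * (n_total - n_exc)
    mod = mod or NeuromodConfig(w_min=0.0, w_max=w_max)
    net = Network(params, stdp or PairSTDPConfig(), mod)

    conn = rng.random((n_total, n_total)) < p_connect
    np.fill_diagonal(conn, False)
    n_plastic = 0
    n_static = 0
    for i in range(n_total):
        targets = np.flatnonzero(conn[i])
        if targets.size == 0:
            continue
        if i < n_exc:
            net.connect_plastic(i, targets, w_init)
            n_plastic += targets.size
        else:
            net.connect_static(i, targets, w_inh)
            n_static += targets.size

    noise_sources = net.add_sources(n_total)
    for j, src in enumerate(noise_sources):
        net.connect_static(int(src), [j], w_noise)

    n_groups = n_total // 10
    group_size = n_total // 20
    groups = np.stack(
        [rng.choice(n_total, size=group_size, replace=False) for _ in range(n_groups)]
    )
    return ConditioningNetwork(
        net=net,
        groups=groups,
        noise_sources=noise_sources,
        n_total=n_total,
        n_excitatory=n_exc,
        n_plastic_synapses=n_plastic,
        n_static_synapses=n_static,
        seed=seed,
    )


@dataclass
class ConditioningResult:
    sim: SimResult
    schedule: StimulusSchedule
    summary: pd.DataFrame
    s1_mean_nA: float
    global_mean_nA: float

    @property
    def separation_nA(self) -> float:
        """Mean S1-outgoing plastic weight minus the global plastic mean."""
        return self.s1_mean_nA - self.global_mean_nA


def run_conditioning(
    cnet: ConditioningNetwork,
    duration: int,
    stimulus_seed: int = 0,
    noise_seed: int = 0,
    *,
    d_c: float = 0.005,
    noise_rate_hz: float = 10.0,
    cadence_ms: int = 1000,
    pulse_amplitude: float | None = None,
    contingent: bool = True,
    record_spikes: bool = True,
) -> ConditioningResult:
    """Run the conditioning experiment on a built network.

    Stimuli are delivered as 1 ms super-threshold current pulses to all
    members of the chosen group; rewards are single dopaminergic spikes of
    amplitude ``d_c`` delivered to every neuron.  Mean plastic weights
    (S1-outgoing vs. network-wide) are logged every ``cadence_ms``.
    """
    amp = default_pulse_amplitude(RS) if pulse_amplitude is None else pulse_amplitude
    schedule = stimulus_schedule(
        cnet.n_groups, duration, stimulus_seed, d_c=d_c, contingent=contingent
    )
    pulses = [
        (t, int(j), amp) for (t, k) in schedule.stimuli for j in cnet.groups[k]
    ]
    dopa = [
        (t, j, dc) for (t, dc) in schedule.rewards for j in range(cnet.n_total)
    ]
    rng_noise = np.random.default_rng(noise_seed)
    ext = []
    for src, j in zip(cnet.noise_sources, range(cnet.n_total)):
        for t in poisson_train(noise_rate_hz, duration, rng_noise):
            ext.append((int(t), int(src)))

    s1_pre = [int(j) for j in cnet.groups[0] if j < cnet.n_excitatory]
    snap = list(range(cadence_ms, duration + 1, cadence_ms))
    sim = cnet.net.run(
        duration,
        external_spikes=ext,
        dopamine_events=dopa,
        pulses=pulses,
        snapshot_times=snap,
        mask_pre=s1_pre,
        record_spikes=record_spikes,
    )
    s1_mean, global_mean, _ = summarize_weights(sim, s1_pre)
    return ConditioningResult(
        sim=sim,
        schedule=schedule,
        summary=sim.summary,
        s1_mean_nA=s1_mean,
        global_mean_nA=global_mean,
    )


def summarize_weights(sim: SimResult, group_pre) -> tuple[float, float, np.ndarray]:
    """Mean plastic weight over synapses whose pre neuron is in ``group_pre``,
    the global plastic mean, and a per-synapse snapshot (flushed weights)."""
    group = set(int(x) for x in group_pre)
    mask = np.array([int(e) in group for e in sim.syn_pre], dtype=bool)
    snapshot = sim.weights.copy()
    group_mean = float(snapshot[mask].mean()) if mask.any() else float("nan")
    return group_mean, float(snapshot.mean()), snapshot
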