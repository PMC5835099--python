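# tristdp

Event-driven simulation of **dopamine-modulated (three-factor) STDP** in
networks of leaky integrate-and-fire neurons, with a dense clock-driven
integrator as a verification oracle and ready-made reinforcement-learning
experiments (delayed single-synapse reinforcement, population
reward/punishment, and Pavlovian conditioning via the distal-reward
mechanism).

## The problem and the rule

Pure spike-timing-dependent plasticity cannot solve the *credit assignment*
(distal reward) problem: when a reward arrives a second after the activity
that caused it, the responsible synapses are no longer active.  The
three-factor rule solves this with a per-synapse *eligibility trace* `C`
that records recent STDP events and decays slowly, and a *dopamine
concentration* `D` incremented by each dopaminergic spike:

```
dC/dt = -C/τ_c + STDP(Δt) δ(t - t_pre/post)
dD/dt = -D/τ_d + D_c Σ δ(t - t_d)
dw/dt = C · D
```

A causal pre→post pair writes `A₊·exp(-Δt/τ₊)` to `C` (an anti-causal pair
subtracts `A₋·exp(-Δt/τ₋)`), but the weight only moves while dopamine is
present; `D_c < 0` implements punishment.  Between events every quantity is
a plain exponential, so the weight change over an event-free interval
`[t₀, t]` has the closed form

```
Δw = C(t₀) D(t₀) / (1/τ_c + 1/τ_d) · (1 − e^{−(t−t₀)(1/τ_c+1/τ_d)})
```

which lets synapses be updated *lazily*: a synaptic row is touched only
when its pre-synaptic neuron spikes.  Post-synaptic spikes and dopaminergic
spikes are kept in a per-neuron event history (dopaminergic spikes bypass
the synaptic delay ring buffer and never depolarise the target), and row
processing replays that history with the closed form between events.  A
dense clock-driven integrator (`tristdp.oracle`) recomputes the same
dynamics every millisecond and the test suite holds the two routes to
1e-9 relative agreement.

Neurons are current-based LIF cells (`IF_curr_exp`) in two flavours:
regular-spiking excitatory (RS) and fast-spiking inhibitory (FS).

## Worked example

Sweep the delay between a causal pre→post pair (pre at 1 ms, posts at 3 ms)
and a single reward spike (`D_c = 0.1`):

```
$ tristdp sweep-delay --min 4 --max 3000 --points 8 --out out
peak_reward_delta_w_nA: 13.6318
tail_reward_delta_w_nA: 0.681407
wrote out/delay_sweep.csv
```

A reward 4 ms after the pair converts the full pair tag
(`e^{-2/10} ≈ 0.819`, decayed to the reward time and integrated against
`D`) into +13.63 nA of weight change; delaying the reward to 3 s leaves
only `e^{-3/1} ≈ 5 %` of that because the eligibility trace has decayed
(τ_c = 1 s).  Punishment (`--dc -0.1`) produces the exact mirror curve.

The same rule at population scale, from Python:

```python
from tristdp.experiments import run_reward_punishment
res = run_reward_punishment(seed=0)
print(res.baseline_rate_hz, res.reward_rate_hz, res.punish_rate_hz)
# 11.0 13.43 12.23
```

Ten neurons driven by 50 Hz Poisson sources fire at ~11 Hz; three reward
spikes potentiate the input synapses and lift the rate to ~13.4 Hz, and
three later punishment spikes pull it back down.  The Pavlovian
conditioning experiment (`tristdp conditioning --n-total 200
--duration-min 10 --seed 1`) stimulates random neuron groups in sequence
and rewards one of them (S1) after a random delay of up to 1 s; the mean
weight of S1's outgoing plastic synapses ends above the network-wide mean.

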