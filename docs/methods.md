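# Methods

## Model

Synaptic plasticity follows the three-factor rule: pair-based STDP writes
to a per-synapse eligibility trace `C` (decay constant `τ_c`), dopaminergic
spikes increment a per-neuron dopamine concentration `D` by `D_c` (decay
`τ_d`, negative increments for punishment), and the weight drifts as
`dw/dt = C·D`.  The STDP window is realised implicitly through
accumulating spike traces: every spike adds +1 to its neuron's trace
(all-to-all pairing, no saturation), and sampling the partner's trace at
spike times yields `A± · exp(−|Δt|/τ±)`.  Weight dependence is additive;
weights are clamped to `[w_min, w_max]` once per row processing (not
per history entry), with `w_min = 0` unless a protocol disables bounds.

Default plasticity constants: `A₊ = A₋ = 1`, `τ₊ = 10 ms`, `τ₋ = 12 ms`,
`τ_c = 1000 ms`, `τ_d = 200 ms`.  The reward/punishment population
experiment overrides `τ_c = 100 ms`, `τ_d = 5 ms`.

Neurons are current-based LIF cells with exponential synaptic currents.
Regular-spiking (RS, excitatory) cells use C_m = 0.3 nF, I_offset =
0.005 nA, τ_m = 10 ms, τ_refrac = 4 ms, τ_syn = 1 ms, V_reset = −70 mV,
V_rest = −65 mV, V_thresh = −55.4 mV; fast-spiking (FS, inhibitory) cells
differ in I_offset = 0, τ_refrac = 2 ms and V_thresh = −56.4 mV.

## Event-driven evaluation

Simulation runs on an integer 1 ms grid.  Each post-synaptic neuron keeps
a history of timestamped events — its own spikes (with the post trace
`s_j`) and incoming dopaminergic spikes (with `D`) — and each pre-synaptic
entity owns a row of synapses with the time `t_old` of its last processing
and its pre trace `s_i`.  When a pre spike arrives, each synapse in the
row walks the history entries in `(t_old, t]`, alternating the closed-form
integral of `C·D` over event-free segments with trace updates; the
resulting weight is deposited into a per-neuron delay ring buffer
(excitatory and inhibitory accumulators kept separate).  Dopaminergic
spikes are written directly into the target's history — they never pass
through the ring buffer and never depolarise the membrane, so any spike
source can act as a dopamine source.

Conventions (all exercised by the test suite):

* **Tie-breaking.**  At equal times, dopamine entries are recorded before
  post-spike entries, and a spike never pairs with a simultaneous spike of
  the other kind — traces are sampled before being incremented at the same
  timestamp.  The depression term of the triggering pre spike is always
  applied last.
* **Laziness and flushes.**  A row whose pre neuron stays silent is never
  processed; a semantics-preserving flush (applied at simulation end and at
  weight-logging times) integrates pending dopamine-gated drift, applies
  pending post-spike terms and advances `t_old` without a depression term
  or a ring-buffer deposit.  Flushing splits decay exponentials into
  multiple factors, which perturbs results only at round-off level.
* **Histories.**  Unbounded in the reference implementation; the fast
  kernel uses fixed-capacity arrays compacted by discarding entries older
  than the minimum `t_old` of any row targeting the neuron (always keeping
  the entry immediately preceding it, which seeds the dopamine level at
  the window start).  Compaction is bitwise invisible.
* **Membrane integration.**  Exact per-step exponential update with the
  total input current held constant over each 1 ms step; refractory
  neurons hold `V = V_reset` while synaptic currents keep decaying.
  Initial voltages default to `V_rest`.
* **Arithmetic.**  Double precision throughout; traces decay smoothly and
  never snap to zero, so quantities that a fixed-point implementation
  would truncate simply become negligibly small.

## Verification

A dense clock-driven integrator updates every synapse every step, using
the same closed form *within* each step, so it is step-size-exact (halving
the step changes nothing beyond 1e-12) and disagreements isolate engine
bugs rather than discretisation.  The suite checks, on random scripted
event streams: engine ≡ oracle to 1e-9 relative (weights and eligibility
traces, at every row-processing time and at the end), the object-level
engine ≡ the compiled kernel bitwise, and the closed-form update ≡
adaptive quadrature to 1e-6 relative over 10⁴ random parameter draws.
Near zero, comparisons switch to an absolute scale (1e-12): relative error
on a trace that has decayed to ~1e-6 of its peak measures double-precision
round-off of the cancelled terms, not algorithmic disagreement.

## Experiments

**Single-synapse delayed reinforcement.**  One pre spike at 1 ms fires two
post neurons at 3 ms; a single dopaminergic spike (`D_c = ±0.1`) arrives
at a delay swept over 4–3000 ms.  Weight bounds are disabled so reward and
punishment are exact mirrors, and each run is finalized 2 s after the
dopamine spike so the gated drift integrates to completion (the remaining
tail is below 1e-5 of the total).  The resulting |Δw| decays as
`exp(−delay/τ_c)`.

**Population reward/punishment.**  Ten RS neurons each receive one 50 Hz
Poisson source through a plastic synapse (initial weight 1.5 nA, bounds
[0, 6] nA); a dopamine source projects to all.  Rewards `D_c = 0.01` at
2, 3, 4 s; punishments `D_c = −0.002` at 8, 9, 10 s; `τ_c = 100 ms`,
`τ_d = 5 ms`.  Epoch rates are measured at 0–2 s, 5–8 s and 11–14 s.  The
single-run punishment effect (~−0.6 Hz) is comparable to rate-estimation
noise on 10 neurons × 3 s, so the headline comparison averages five
replicate runs with independent Poisson seeds.

**Pavlovian conditioning (desk scale).**  `N_T` neurons (80 % RS, 20 % FS)
connect with probability 0.1 (no self-connections); RS axons are plastic,
FS axons are static inhibitory.  `N_T/10` stimulus groups of `N_T/20`
neurons are drawn with replacement across groups and without replacement
within a group; every neuron gets a private 10 Hz Poisson noise source.
Stimuli are presented in random order at uniform 100–300 ms intervals as
1 ms super-threshold current pulses (1.2× the single-step threshold
current from rest, ≈3.63 nA); each presentation of S1 is followed by one
global dopaminergic spike after a delay uniform in (0, 1 s].  Because
synapses out of S1 are reliably eligibility-tagged when rewards arrive,
their mean weight rises above the network-wide plastic mean, which itself
drifts upward (distractor groups presented shortly before a reward are
also tagged).

Parameters the protocol leaves open were calibrated once to put the
`N_T = 200` network in a sparse irregular background regime (~4–8 Hz with weights frozen):
initial plastic weight 0.7 nA, inhibitory weight −2 nA, noise weight
2 nA, `w_max = 2.8` nA, and reward increment `D_c = 0.005` (larger
increments make the per-reward weight kicks so large that the scaled-down
network saturates into a reward-noise-dominated high-rate regime).
Weight summaries (mean over S1-outgoing plastic synapses vs. all plastic
synapses) are logged every second via the flush mechanism.

At this scale the S1 effect is genuinely stochastic: the end-of-run
separation is positive in roughly three quarters of runs (13/15 over
calibration seeds 1–15; somewhat lower in further seed batches), so the
headline check asks for 4 of 5 seeds of the declared study set.  The control experiment rewards a
random presentation with probability `1/N_g` instead of rewarding S1
(same reward rate, contingency destroyed).  Because per-seed group-mean
noise is comparable to the effect and a third of the neurons belong to no
group, the control is evaluated with a within-run statistic: S1's
separation is z-scored against the distribution of all groups'
separations; with the contingency destroyed the median control z-score
stays well below 1.5, whereas a systematic S1 advantage would push it
toward 2 and beyond.

## What the synthetic conditions do and do not show

All inputs are generated internally (Poisson sources, scripted pulses and
dopamine schedules), so passing tests demonstrate the correctness of the
event-driven algorithm and the qualitative reinforcement phenomena — not
quantitative fidelity to any biological preparation.  The desk-scale
conditioning network has 5× weaker stimulus-volley convergence than the
1000-neuron configuration (group size scales with `N_T` but connection
probability is fixed), so its credit-assignment signal-to-noise is
intrinsically lower; the full-scale, hour-long experiment is represented
here only by its construction statistics.

## Known limitations

* Weight clamping per row processing means a weight can transiently exceed
  its bounds inside a processing window; per-entry clamping is not
  provided.
* Dopaminergic delivery is immediate (no dopamine delay), matching the
  direct history insertion; a per-projection dopamine delay would require
  buffering dopaminergic spikes.
* The kernel's spike recording uses a preallocated buffer; pathological
  high-rate runs truncate the raster (flagged on the result) rather than
  grow it.
* Volume transmission (many dopaminergic afferents per synapse) is out of
  scope.
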