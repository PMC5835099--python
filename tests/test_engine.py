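"""Event-driven engine: histories, ring buffer, row processing."""

import math

import numpy as np
import pytest

from tristdp import (
    EntryKind,
    EventDrivenPlasticityNetwork,
    NeuromodConfig,
    PairSTDPConfig,
    PostHistory,
    RingBuffer,
    SynapseState,
    SynapticRow,
    process_row_neuromod,
    process_row_pair_stdp,
    simulate_events,
)
from conftest import make_scenario, run_object_engine, run_oracle, max_rel_err

STDP = PairSTDPConfig()  # A+=A-=1, tau+=10 ms, tau-=12 ms
MOD = NeuromodConfig(w_min=-np.inf, w_max=np.inf)  # tau_c=1000, tau_d=200


class TestPostHistory:
    def new(self):
        return PostHistory(tau_s=12.0, tau_d=200.0)

    def test_first_post_spike(self):
        h = self.new()
        e = h.record_post_spike(5)
        assert (e.time, e.s, e.d, e.kind) == (5, 1.0, 0.0, EntryKind.POST_SPIKE)

    def test_post_trace_accumulates_with_decay(self):
        h = self.new()
        h.record_post_spike(5)
        e = h.record_post_spike(15)
        assert e.s == pytest.approx(math.exp(-10.0 / 12.0) + 1.0, rel=1e-12)

    def test_post_spike_carries_decayed_dopamine(self):
        h = self.new()
        h.record_dopamine_spike(10, 0.1)
        e = h.record_post_spike(110)
        assert e.d == pytest.approx(0.1 * math.exp(-100.0 / 200.0), rel=1e-12)
        assert e.s == 1.0

    def test_first_dopamine_entry(self):
        h = self.new()
        e = h.record_dopamine_spike(10, 0.1)
        assert (e.time, e.s, e.d, e.kind) == (10, 0.0, 0.1, EntryKind.DOPAMINE)

    def test_dopamine_accumulates_with_decay(self):
        h = self.new()
        h.record_dopamine_spike(100, 0.1)
        e = h.record_dopamine_spike(300, 0.1)
        assert e.d == pytest.approx(0.1 * math.exp(-1.0) + 0.1, rel=1e-12)

    def test_negative_increment_for_punishment(self):
        h = self.new()
        e = h.record_dopamine_spike(10, -0.1)
        assert e.d == -0.1

    def test_out_of_order_insertions_rejected(self):
        h = self.new()
        h.record_post_spike(10)
        with pytest.raises(ValueError):
            h.record_post_spike(9)
        with pytest.raises(ValueError):
            # dopamine must precede a post spike recorded at the same time
            h.record_dopamine_spike(10, 0.1)

    def test_window_query_boundaries(self):
        h = self.new()
        for t in (3, 7, 12):
            h.record_post_spike(t)
        assert [e.time for e in h.entries_in(5, 12)] == [7, 12]
        assert h.entries_in(12, 40) == []
        assert h.preceding(5).time == 3
        assert h.preceding(2) is None

    def test_entry_times_non_decreasing(self):
        h = self.new()
        for t in (3, 7, 12):
            h.record_dopamine_spike(t, 0.01)
            h.record_post_spike(t)
        times = [e.time for e in h.entries]
        assert times == sorted(times)
        # within one timestep, the dopamine entry always precedes the post
        for a, b in zip(h.entries, h.entries[1:]):
            if a.time == b.time:
                assert (a.kind, b.kind) != (EntryKind.POST_SPIKE, EntryKind.DOPAMINE)


class TestRingBuffer:
    def test_deposits_accumulate_and_clear(self):
        rb = RingBuffer(n_neurons=3, max_delay=4)
        rb.deposit(1.0, 2, 2, t=10)
        rb.deposit(0.5, 2, 2, t=10)
        rb.deposit(-0.25, 2, 2, t=10)  # inhibitory, kept separate
        exc, inh = rb.advance(12)
        assert exc[2] == 1.5 and inh[2] == -0.25
        exc, inh = rb.advance(12)  # slot was cleared on consumption
        assert exc[2] == 0.0 and inh[2] == 0.0

    def test_delay_one_consumed_next_step(self):
        rb = RingBuffer(2, max_delay=1)
        rb.deposit(2.0, 0, 1, t=5)
        assert rb.advance(5)[0][0] == 0.0
        assert rb.advance(6)[0][0] == 2.0

    def test_delay_out_of_range(self):
        rb = RingBuffer(2, max_delay=3)
        with pytest.raises(ValueError):
            rb.deposit(1.0, 0, 0, t=0)
        with pytest.raises(ValueError):
            rb.deposit(1.0, 0, 4, t=0)

    def test_no_stale_contributions_after_wraparound(self):
        rb = RingBuffer(1, max_delay=3)
        rb.deposit(1.0, 0, 3, t=0)
        assert rb.advance(3)[0][0] == 1.0
        for t in range(4, 12):  # several wraps later the slots stay clean
            assert rb.advance(t)[0][0] == 0.0


class TestRowProcessing:
    def make_row(self, w=1.0):
        return SynapticRow(pre_index=0, synapses=[SynapseState(weight=w, target=0)])

    def test_pair_mode_depression_only_without_post_entries(self):
        row = self.make_row(w=1.0)
        h = PostHistory(12.0, 200.0)
        h.record_post_spike(2)
        net_histories = [h]
        process_row_pair_stdp(row, 5, net_histories, STDP, MOD)
        # first processing at 5: pre trace was 0, only depression applies
        assert row.synapses[0].weight == pytest.approx(
            1.0 - math.exp(-3.0 / 12.0), rel=1e-12
        )
        assert row.t_old == 5 and row.pre_trace.value == 1.0

    def test_pair_mode_causal_potentiation(self):
        row = self.make_row(w=1.0)
        h = PostHistory(12.0, 200.0)
        histories = [h]
        process_row_pair_stdp(row, 1, histories, STDP, MOD)  # pre spike at 1 ms
        h.record_post_spike(3)
        process_row_pair_stdp(row, 20, histories, STDP, MOD)  # next pre at 20 ms
        expected = (
            1.0
            - 0.0  # no depression at t=1
            + math.exp(-2.0 / 10.0)  # post at 3 sampling pre trace from 1
            - math.exp(-17.0 / 12.0)  # pre at 20 sampling post trace from 3
        )
        assert row.synapses[0].weight == pytest.approx(expected, rel=1e-12)

    def test_neuromod_gating_keeps_weight_without_dopamine(self):
        row = self.make_row(w=1.5)
        h = PostHistory(12.0, 200.0)
        histories = [h]
        process_row_neuromod(row, 1, histories, STDP, MOD)
        h.record_post_spike(3)
        process_row_neuromod(row, 20, histories, STDP, MOD)
        assert row.synapses[0].weight == 1.5  # exactly unchanged
        # eligibility accumulated the same pair terms STDP would have applied
        expected_c = math.exp(-2.0 / 10.0) * math.exp(-17.0 / 1000.0) - math.exp(
            -17.0 / 12.0
        )
        assert row.synapses[0].eligibility == pytest.approx(expected_c, rel=1e-12)

    def test_neuromod_reward_after_pair_matches_hand_integration(self):
        # pre at 1 ms, post at 3 ms, dopamine (+0.1) at 4 ms, next pre at 3000 ms
        row = self.make_row(w=0.0)
        h = PostHistory(12.0, 200.0)
        histories = [h]
        process_row_neuromod(row, 1, histories, STDP, MOD)
        h.record_post_spike(3)
        h.record_dopamine_spike(4, 0.1)
        process_row_neuromod(row, 3000, histories, STDP, MOD)
        c4 = math.exp(-2.0 / 10.0) * math.exp(-1.0 / 1000.0)
        k = 1.0 / 1000.0 + 1.0 / 200.0
        expected = c4 * 0.1 / k * (1.0 - math.exp(-k * 2996.0))
        assert row.synapses[0].weight == pytest.approx(expected, rel=1e-12)
        assert expected > 0

    def test_neuromod_linear_in_dopamine_sign(self):
        results = []
        for d_c in (0.1, -0.1):
            row = self.make_row(w=0.0)
            h = PostHistory(12.0, 200.0)
            histories = [h]
            process_row_neuromod(row, 1, histories, STDP, MOD)
            h.record_post_spike(3)
            h.record_dopamine_spike(4, d_c)
            process_row_neuromod(row, 3000, histories, STDP, MOD)
            results.append(row.synapses[0].weight)
        assert results[0] == pytest.approx(-results[1], rel=1e-12)

    def test_processing_requires_forward_time(self):
        row = self.make_row()
        row.t_old = 10
        with pytest.raises(ValueError):
            process_row_neuromod(row, 10, [PostHistory(12.0, 200.0)], STDP, MOD)


class TestEngineInvariants:
    def test_checkpoint_resume_is_bit_identical(self, rng):
        sc = make_scenario(rng, duration=1500)
        w_once, c_once = run_object_engine(sc)

        # same streams, split at an arbitrary checkpoint and resumed
        from conftest import build_rows

        rows, by_pre = build_rows(sc)
        net = EventDrivenPlasticityNetwork(sc.n_neurons, rows, sc.stdp, sc.mod)
        split = 700
        by_time = {}
        for t, e in sc.pre_spikes:
            by_time.setdefault(t, ([], [], []))[0].append(e)
        for t, j in sc.post_spikes:
            by_time.setdefault(t, ([], [], []))[1].append(j)
        for t, j, dc in sc.dopamine:
            by_time.setdefault(t, ([], [], []))[2].append((j, dc))
        for t in sorted(by_time):
            if t <= split:
                net.step_events(t, *by_time[t])
        for t in sorted(by_time):
            if t > split:
                net.step_events(t, *by_time[t])
        net.finalize(sc.duration)
        w_split = np.empty(sc.pre.size)
        c_split = np.empty(sc.pre.size)
        for row in net.rows.values():
            for syn, k in zip(row.synapses, by_pre[row.pre_index]):
                w_split[k] = syn.weight
                c_split[k] = syn.eligibility
        assert np.array_equal(w_once, w_split)
        assert np.array_equal(c_once, c_split)

    def test_silent_dopamine_leaves_weights_exactly_unchanged(self, rng):
        sc = make_scenario(rng, duration=3000)
        sc.dopamine.clear()
        w, _ = run_object_engine(sc)
        assert np.array_equal(w, sc.w0)

    def test_pair_mode_matches_clock_driven_oracle(self, rng):
        for _ in range(3):
            sc = make_scenario(rng, duration=2000, n_synapses=40)
            sc.dopamine.clear()
            w, _ = run_object_engine(sc, mode="pair")
            state, _ = run_oracle(sc, mode="pair")
            assert max_rel_err(w, state.w) < 1e-9

    def test_simulate_events_ignores_events_beyond_duration(self, rng):
        sc = make_scenario(rng, duration=1000)
        sc2 = make_scenario(rng, duration=1000)
        # identical scenario with one extra event past the horizon
        sc2.pre, sc2.tgt, sc2.w0 = sc.pre, sc.tgt, sc.w0
        sc2.pre_spikes = sc.pre_spikes + [(5000, 0)]
        sc2.post_spikes, sc2.dopamine = sc.post_spikes, sc.dopamine
        assert np.array_equal(run_object_engine(sc)[0], run_object_engine(sc2)[0])
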