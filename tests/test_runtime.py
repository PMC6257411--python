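"""Ring buffers, spike pipeline, event-loop semantics, callback priorities
and the accounting-mode throughput measurement."""

import numpy as np
import pytest

from conftest import single_synapse_network
from spinnlite import costmodel, graph, models, netapi, runtime, sources
from spinnlite.runtime import (CallbackEngine, InputSpikeBuffer,
                               RingBufferBank, empirical_max_events)


class TestRingBufferBank:
    def _one(self):
        return RingBufferBank(16, receptors=2)

    def inject_word(self, ring, weight, neuron=12, receptor=1, delay=10):
        ring.inject(np.array([neuron]), np.array([receptor]),
                    np.array([delay]), np.array([weight]))

    def test_worked_word_lands_in_slot_ten(self):
        ring = self._one()
        self.inject_word(ring, 589)
        assert ring.buf[12, 1, 10] == 589

    def test_double_injection_accumulates(self):
        ring = self._one()
        self.inject_word(ring, 589)
        self.inject_word(ring, 589)
        assert ring.buf[12, 1, 10] == 1178

    def test_saturation_pins_at_u16_max_and_counts(self):
        ring = self._one()
        for _ in range(200):
            self.inject_word(ring, 589)
        assert ring.buf[12, 1, 10] == 0xFFFF
        assert ring.saturations > 0
        assert ring.conservation_ok()      # losses appear in the ledger

    def test_consume_zeroes_slot_and_pointer_wraps(self):
        ring = self._one()
        self.inject_word(ring, 100, delay=16)
        for _ in range(16):
            ring.consume()
            ring.advance()
        assert ring.ptr == 0
        assert ring.consumed_total == 100
        assert ring.remaining == 0

    def test_delay_16_is_farthest_slot(self):
        # period 0: timer consumes, then a spike with delay 16 arrives
        ring = self._one()
        ring.consume()
        self.inject_word(ring, 7, delay=16)
        ring.advance()
        consumed_at = []
        for period in range(1, 20):
            if ring.consume().sum():
                consumed_at.append(period)
            ring.advance()
        assert consumed_at == [16]


class TestInputSpikeBuffer:
    def test_overflow_drops_beyond_256(self):
        buf = InputSpikeBuffer()
        accepted = sum(buf.push(k) for k in range(300))
        assert accepted == 256
        assert buf.drops == 44

    def test_drain_empties(self):
        buf = InputSpikeBuffer()
        buf.push(1), buf.push(2)
        assert buf.drain() == [1, 2]
        assert len(buf) == 0


class TestEventLoop:
    def test_empty_core_produces_nothing(self):
        net = netapi.Network()
        net.add_population(graph.Population("p", 1, "lif"))
        net.record("p", "spikes")
        res = netapi.run(net, 10.0, seed=1)
        assert len(res.spikes("p").data) == 0

    def test_zero_duration_gives_empty_recordings(self):
        net = netapi.build_balanced_fixture(1)
        res = netapi.run(net, 0.0, seed=1)
        assert len(res.spikes("excitatory").data) == 0

    def test_constant_drive_with_refractory_fires_every_third_period(self):
        net = netapi.Network()
        net.add_population(graph.Population(
            "p", 1, "lif", models.LifParams(i_offset=20.0, t_r=2.0)))
        net.record("p", "spikes")
        res = netapi.run(net, 12.0, seed=1)
        times = res.spikes("p").data[:, 0]
        assert list(times) == [0.0, 3.0, 6.0, 9.0]

    def test_minimum_transit_time_one_step(self):
        # emission at step 3 with delay 1: membrane moves at step 4, not 3
        net = single_synapse_network(1)
        res = netapi.run(net, 10.0, seed=1)
        v = res.v("tgt").data[:, 0]
        assert np.allclose(v[:5], v[0])       # samples 0..4 = states t0..t4
        assert abs(v[5] - v[0]) > 1e-9        # state after step 4

    def test_identical_seeds_bit_identical_spike_trains(self):
        net = netapi.build_balanced_fixture(3)
        a = netapi.run(net, 300.0, seed=3).spikes("excitatory").data
        b = netapi.run(netapi.build_balanced_fixture(3), 300.0,
                       seed=3).spikes("excitatory").data
        assert a.shape == b.shape
        assert (a == b).all()

    def test_spike_conservation_router_lossless(self):
        """Every emitted key reaches every subscribed core exactly once."""
        net = netapi.build_balanced_fixture(1)
        res = netapi.run(net, 200.0, seed=1)
        m = res.machine
        emitted_deliveries = 0
        for core in m.cores:
            space = m.router.resolve(core.vertex.base_key) \
                if not isinstance(core, runtime.DelayCore) else None
            if space is not None:
                n_subs = len(m.router.subscribers[space])
                emitted_deliveries += core.diag.spikes_emitted * n_subs
        received = sum(c.diag.spikes_received for c in m.cores)
        assert received == emitted_deliveries == m.router.delivered
        assert all(c.diag.unknown_key_drops == 0 for c in m.neuron_cores)

    def test_unknown_key_dropped_and_counted(self):
        net = single_synapse_network(1)
        machine = netapi.build_machine(net, seed=1)
        core = machine.neuron_cores[0]
        core.on_packet_received(0x7FFF0000)
        core.process_pending()
        assert core.diag.unknown_key_drops == 1

    def test_ring_conservation_after_full_run(self):
        net = netapi.build_balanced_fixture(1)
        res = netapi.run(net, 250.0, seed=1)
        assert all(c.ring.conservation_ok() for c in res.machine.neuron_cores)

    def test_accounting_mode_reports_costs_and_no_overruns_when_idle(self):
        net = single_synapse_network(1)
        machine = netapi.build_machine(net, seed=1)
        sim = runtime.Simulator(machine, accounting=True)
        sim.run(20.0)
        core = machine.neuron_cores[0]
        assert core.diag.virtual_us > 0
        assert core.diag.timer_overruns == 0


class TestCallbackEngine:
    DUR = {"timer": 300.0, "packet": 5.0, "user": 5.0, "dma_complete": 50.0}

    def test_packet_preempts_timer_and_runs_to_completion(self):
        eng = CallbackEngine(self.DUR, dma_latency=10.0)
        eng.post(0.0, "timer")
        eng.post(100.0, "packet")
        trace = eng.run()
        timer = next(e for e in trace if e.name == "timer")
        packet = next(e for e in trace if e.name == "packet")
        assert packet.segments == [(100.0, 105.0)]    # never interrupted
        assert timer.preempted
        assert timer.segments[0] == (0.0, 100.0)
        assert timer.end > 300.0                      # suspended time added

    def test_user_event_raised_only_when_pipeline_idle(self):
        # three spikes while the pipeline is busy: a single user event
        eng = CallbackEngine(self.DUR, dma_latency=10.0)
        eng.post(0.0, "packet")
        eng.post(20.0, "packet")       # during DMA wait / processing
        eng.post(30.0, "packet")
        trace = eng.run()
        assert eng.user_events_raised == 1
        assert len([e for e in trace if e.name == "user"]) == 1
        assert len([e for e in trace if e.name == "dma_complete"]) == 3
        assert not eng.pipeline_active

    def test_idle_core_processes_packet_immediately(self):
        eng = CallbackEngine(self.DUR)
        eng.post(40.0, "packet")
        trace = eng.run()
        assert trace[0].segments[0] == (40.0, 45.0)

    def test_priority_minus_one_handled_before_callback_resumes(self):
        eng = CallbackEngine(self.DUR, dma_latency=0.0)
        eng.post(0.0, "timer")
        eng.post(10.0, "packet")
        trace = eng.run()
        packet = next(e for e in trace if e.name == "packet")
        timer = next(e for e in trace if e.name == "timer")
        gap = [s for s in timer.segments if s[0] >= packet.end]
        assert packet.start == 10.0
        assert all(seg_end <= packet.start or seg_start >= packet.end
                   for seg_start, seg_end in timer.segments)
        assert gap, "timer resumes only after the packet callback finished"

    def test_timer_queue_overflow_counted(self):
        eng = CallbackEngine({**self.DUR, "dma_complete": 10_000.0})
        eng.post(0.0, "packet")        # starts a long pipeline callback
        for i in range(20):
            eng.post(100.0 + i, "timer")
        eng.run()
        assert eng.queue_overflows == 5      # queue holds at most 15

    def test_timer_overrun_detected(self):
        eng = CallbackEngine({**self.DUR, "timer": 1500.0})
        eng.post(0.0, "timer")
        eng.post(1000.0, "timer")
        eng.run()
        assert eng.timer_overruns >= 1


class TestEmpiricalThroughput:
    def test_matches_analytic_prediction_at_reference_point(self):
        assert empirical_max_events(128, 1.0) == 5922

    @pytest.mark.parametrize("n, p", [(16, 1.0), (64, 0.25), (255, 0.2),
                                      (512, 0.5)])
    def test_matches_analytic_prediction_within_one_event(self, n, p):
        w = max(1, round(n * p))
        predicted = costmodel.predict_events(n, w / n).events
        assert abs(empirical_max_events(n, p) - predicted) <= 1
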