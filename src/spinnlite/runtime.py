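"""Discrete-event emulation of the per-core callback machinery.

Each emulated core advances its neurons once per *timer period* and
processes incoming spike packets through the pipelined callback chain
(packet-received -> user -> row-processing).  Cores are logical processes
on one global event loop with deterministic tie-breaking (time, then core
index, then phase); the hardware's asynchrony and clock drift are
intentionally not modelled — determinism is a feature for testing.

Per period the loop runs three phases:

1. every core's timer callback (consume the current ring-buffer slot,
   decay synapse state, advance neurons, emit spike keys, record),
2. delivery: every emitted key goes to every subscribed core's input
   spike buffer (lossless router) and the spike-processing pipeline
   drains each buffer into ring-buffer contributions,
3. ring pointers advance one slot.

A spike emitted in period t therefore lands in a slot consumed no earlier
than period t+1 — the minimum spike transit time of one Δt.  Because the
pipeline drains once per period, the 256-entry input-buffer cap applies to
a single period's arrivals.

Two further facilities live here: a virtual-time *accounting* mode pricing
each period's callbacks with :mod:`spinnlite.costmodel` coefficients
(overruns are diagnosed, never fatal), and a :class:`CallbackEngine` that
replays the priority/preemption semantics of the event-driven OS
(priorities −1…2, queues of length 15 for priorities 1 and 2) to produce
instrumented traces.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from . import costmodel, delays as delays_mod, fxp, graph, models, sources, synformat
from .models import EXC, INH

RING_SLOTS = 16
INPUT_BUFFER_ENTRIES = 256


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CoreDiagnostics:
    """Monotone per-core health counters reported at run end."""

    timer_overruns: int = 0
    max_consecutive_overruns: int = 0
    input_buffer_overflows: int = 0
    ring_saturations: int = 0
    unknown_key_drops: int = 0
    spikes_emitted: int = 0
    spikes_received: int = 0
    callback_counts: dict = field(default_factory=dict)
    virtual_us: float = 0.0
    _consecutive: int = 0

    def count(self, callback: str, n: int = 1) -> None:
        self.callback_counts[callback] = self.callback_counts.get(callback, 0) + n

    def note_period_cost(self, cost_us: float, t_p: float) -> None:
        self.virtual_us += cost_us
        if cost_us > t_p:
            self.timer_overruns += 1
            self._consecutive += 1
            self.max_consecutive_overruns = max(self.max_consecutive_overruns,
                                                self._consecutive)
        else:
            self._consecutive = 0

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if not k.startswith("_")}


# ---------------------------------------------------------------------------
# Ring buffers and spike buffers
# ---------------------------------------------------------------------------

class RingBufferBank:
    """Per-neuron, per-receptor circular accumulators of 16-bit weights.

    16 slots per buffer; the shared slot pointer advances once per timer
    period.  Accumulation saturates at 65535 (never wraps); a conservation
    ledger tracks injected vs consumed weight so saturation losses are
    auditable.
    """

    def __init__(self, n: int, receptors: int = 2, slots: int = RING_SLOTS):
        self.n = n
        self.receptors = receptors
        self.slots = slots
        self.buf = np.zeros((n, receptors, slots), dtype=np.int64)
        self.ptr = 0
        self.saturations = 0
        self.injected_total = 0
        self.consumed_total = 0
        self.saturation_loss = 0

    def inject(self, neuron_ids: np.ndarray, receptor: np.ndarray,
               delay_steps: np.ndarray, weights_raw: np.ndarray) -> None:
        """Saturating-add weights into slot ``(ptr + delay) mod slots``.

        Delay 1 is the minimum: the contribution is consumed at the next
        timer period.  Delay 16 lands back on the slot just consumed — the
        farthest future step.
        """
        if len(neuron_ids) == 0:
            return
        slots = (self.ptr + delay_steps) % self.slots
        flat = (neuron_ids * self.receptors + receptor) * self.slots + slots
        np.add.at(self.buf.reshape(-1), flat, weights_raw.astype(np.int64))
        self.injected_total += int(weights_raw.sum())
        over = self.buf > fxp.U16_MAX
        if over.any():
            self.saturations += int(over.sum())
            self.saturation_loss += int((self.buf[over] - fxp.U16_MAX).sum())
            self.buf[over] = fxp.U16_MAX

    def consume(self) -> np.ndarray:
        """Read and zero the current slot; returns raw u16 [n, receptors]."""
        vals = self.buf[:, :, self.ptr].copy()
        self.consumed_total += int(vals.sum())
        self.buf[:, :, self.ptr] = 0
        return vals

    def advance(self) -> None:
        self.ptr = (self.ptr + 1) % self.slots

    @property
    def remaining(self) -> int:
        return int(self.buf.sum())

    def conservation_ok(self) -> bool:
        """Total injected == consumed + saturation losses + still buffered."""
        return (self.injected_total
                == self.consumed_total + self.saturation_loss + self.remaining)


class InputSpikeBuffer:
    """Buffer of up to 256 pending source keys; the 257th arrival within a
    drain interval is dropped and counted."""

    def __init__(self, capacity: int = INPUT_BUFFER_ENTRIES):
        self.capacity = capacity
        self._items: list[int] = []
        self.drops = 0

    def push(self, key: int) -> bool:
        if len(self._items) >= self.capacity:
            self.drops += 1
            return False
        self._items.append(key)
        return True

    def pop(self) -> int:
        return self._items.pop(0)

    def drain(self) -> list[int]:
        items, self._items = self._items, []
        return items

    def __len__(self) -> int:
        return len(self._items)


# ---------------------------------------------------------------------------
# Cores
# ---------------------------------------------------------------------------

class NeuronCore:
    """One machine vertex of LIF or Izhikevich neurons."""

    def __init__(self, vertex: graph.MachineVertex, dt: float, shift: int,
                 rng: np.random.Generator, record: set[str] = frozenset(),
                 v_init_full: np.ndarray | None = None):
        pop = vertex.population
        self._v_init_full = v_init_full
        self.vertex = vertex
        self.dt = dt
        self.shift = shift
        self.kind = pop.kind
        self.n = vertex.size
        self.record = set(record)
        self.diag = CoreDiagnostics()
        self.ring = RingBufferBank(self.n, receptors=2)
        self.input_buffer = InputSpikeBuffer()
        self.synapses = models.SynapseState(self.n, tau_syn=pop.tau_syn, dt=dt)
        self.input_kind = pop.input_kind
        self.e_rev = pop.e_rev
        if pop.kind == "lif":
            params = pop.params or models.LifParams()
            self.fixed = models.LifFixed(params, dt)
            v0 = self._initial_v(pop, params.e_l, rng)
            self.state = models.LifState(fxp.array_to_raw(v0),
                                         np.zeros(self.n, dtype=np.int64))
        elif pop.kind == "izh":
            params = pop.params or models.IzhParams()
            self.fixed = models.IzhFixed(params, dt)
            v0 = self._initial_v(pop, params.c, rng)
            u0 = params.b * np.asarray(v0, dtype=float)
            self.state = models.IzhState(fxp.array_to_raw(v0),
                                         fxp.array_to_raw(u0))
        else:
            raise ValueError(f"not a neuron kind: {pop.kind}")
        self.i_offset_raw = self.fixed.i_offset_raw
        # incoming lookup structures, filled by the machine builder
        self.mpt = synformat.MasterPopulationTable()
        self.matrices: dict[int, np.ndarray] = {}       # address -> uint32 words
        self.row_true_len: dict[int, np.ndarray] = {}   # address -> words/row
        self.v_trace: list[np.ndarray] = []
        self.spike_steps: list[tuple[int, int]] = []    # (step, local id)
        if "v" in self.record:
            self.v_trace.append(self._v_float())

    def _initial_v(self, pop: graph.Population, default: float,
                   rng: np.random.Generator) -> np.ndarray:
        if self._v_init_full is not None:
            # the builder draws initial state once per population, so the
            # realisation is independent of how the population partitions
            return self._v_init_full[self.vertex.lo:self.vertex.hi + 1]
        init = pop.v_init if pop.v_init is not None else default
        if isinstance(init, graph.Distribution):
            full = init.sample(rng, pop.size)
            return full[self.vertex.lo:self.vertex.hi + 1]
        return np.full(self.n, float(init))

    def _v_float(self) -> np.ndarray:
        return fxp.raw_to_float(self.state.v_raw)

    def timer(self, step: int) -> list[int]:
        """Advance all neurons one period; returns emitted spike keys.

        Order matches the reference callback: synapse shaping consumes the
        current ring slot atomically, then each non-refractory neuron is
        advanced and threshold-tested, then recordings are appended for the
        new timestep.
        """
        self.diag.count("timer_callback")
        ring_raw = self.ring.consume().T                    # [receptor, n] u16
        self.synapses.decay_and_consume(
            fxp.decode_ring_raw(ring_raw, self.shift))
        i_receptor = models.input_type_convert(
            self.synapses.i_raw, self.state.v_raw, self.input_kind, self.e_rev)
        i_total = fxp.add_raw(fxp.sub_raw(i_receptor[EXC], i_receptor[INH]),
                              self.i_offset_raw)
        if self.kind == "lif":
            fired = models.lif_update(self.state, self.fixed, i_total)
        else:
            fired = models.izh_update_rk2(self.state, self.fixed, i_total)
        fired_ids = np.nonzero(fired)[0]
        keys = [self.vertex.key_for(int(i)) for i in fired_ids]
        self.diag.spikes_emitted += len(keys)
        if "spikes" in self.record:
            self.spike_steps.extend((step, int(i)) for i in fired_ids)
        if "v" in self.record:
            self.v_trace.append(self._v_float())
        return keys

    def on_packet_received(self, key: int) -> None:
        """Append the key to the input spike buffer (drop + count on
        overflow); pipeline activation is handled by the drain phase."""
        self.diag.count("packet_received_callback")
        self.diag.spikes_received += 1
        if not self.input_buffer.push(key):
            self.diag.input_buffer_overflows += 1

    def process_pending(self) -> list[int]:
        """Drain the spike-processing pipeline: every buffered key is looked
        up through the master population table and its row(s) processed into
        ring-buffer contributions.  Returns the per-spike synaptic word
        counts (used by accounting mode)."""
        word_counts: list[int] = []
        for key in self.input_buffer.drain():
            self.diag.count("spike_pipeline_callback")
            try:
                entry, addresses = self.mpt.lookup_with_entry(key)
            except KeyError:
                self.diag.unknown_key_drops += 1
                continue
            local = key & ~entry.mask & 0xFFFFFFFF
            words = 0
            for addr_entry in addresses:
                words += self.process_row(addr_entry.address, int(local))
            word_counts.append(words)
        self.diag.ring_saturations = self.ring.saturations
        return word_counts

    def process_row(self, address: int, pre_local: int) -> int:
        """Decode one synaptic row and saturating-add every word's weight
        into slot ``(ptr + delay) mod 16`` of its neuron/receptor buffer.
        A delay field of 0 decodes to the effective 16-step delay."""
        mat = self.matrices[address]
        if pre_local >= mat.shape[0]:
            raise ValueError(
                f"corrupt row: presynaptic id {pre_local} out of range for "
                f"matrix at {address:#x}")
        true_len = int(self.row_true_len[address][pre_local])
        if true_len == 0:
            return 0
        words = mat[pre_local, :true_len].astype(np.int64)
        weights = words >> 16
        nid = words & 0xFF
        stype = (words >> 8) & 1
        dfield = (words >> 9) & 0xF
        eff_delay = np.where(dfield == 0, RING_SLOTS, dfield)
        if (nid >= self.n).any():
            raise ValueError("corrupt row: target neuron id out of range")
        self.ring.inject(nid, stype, eff_delay, weights)
        return true_len


class SourceCore:
    """A spike-source vertex (Poisson or spike-source array)."""

    def __init__(self, vertex: graph.MachineVertex, dt: float,
                 seed_seq: np.random.SeedSequence,
                 record: set[str] = frozenset()):
        pop = vertex.population
        self.vertex = vertex
        self.diag = CoreDiagnostics()
        self.record = set(record)
        self.spike_steps: list[tuple[int, int]] = []
        self.v_trace: list[np.ndarray] = []
        if pop.kind == "poisson":
            config = pop.params
            if not isinstance(config, sources.PoissonSourceConfig):
                config = sources.PoissonSourceConfig(
                    rates=np.full(pop.size, float(config)), dt=dt)
            self.source = sources.PoissonSource(config, seed_seq)
            self._step = self._poisson_step
        elif pop.kind == "spike_array":
            schedule = pop.params
            if not isinstance(schedule, sources.SpikeArraySchedule):
                raise ValueError("spike_array population needs a schedule")
            self.schedule = schedule
            self._step = self._array_step
        else:
            raise ValueError(f"not a source kind: {pop.kind}")

    def _poisson_step(self, step: int) -> list[int]:
        counts = self.source.step()
        keys = []
        for unit in np.nonzero(counts)[0]:
            keys.extend([self.vertex.key_for(int(unit))] * int(counts[unit]))
        return keys

    def _array_step(self, step: int) -> list[int]:
        return [self.vertex.key_for(int(u))
                for u in self.schedule.units_at(step)]

    def timer(self, step: int) -> list[int]:
        self.diag.count("timer_callback")
        keys = self._step(step)
        self.diag.spikes_emitted += len(keys)
        if "spikes" in self.record:
            mask_id = ~self.vertex.mask & 0xFFFFFFFF
            self.spike_steps.extend((step, key & mask_id) for key in keys)
        return keys


class DelayCore:
    """A delay-extension vertex wrapped as a core on the event loop."""

    def __init__(self, vertex: graph.MachineVertex,
                 ext: delays_mod.DelayExtensionVertex):
        self.vertex = vertex
        self.ext = ext
        self.diag = CoreDiagnostics()
        self.input_buffer = InputSpikeBuffer()

    def on_packet_received(self, key: int) -> None:
        self.diag.count("packet_received_callback")
        self.diag.spikes_received += 1
        if not self.input_buffer.push(key):
            self.diag.input_buffer_overflows += 1

    def register_pending(self, step: int) -> None:
        """Timer-side half of the spike counter: incoming spikes of this
        period are registered against their release steps."""
        for key in self.input_buffer.drain():
            local = key & ~self.vertex.mask & 0xFFFFFFFF
            self.ext.receive(int(local), step)

    def timer(self, step: int) -> list[int]:
        self.diag.count("timer_callback")
        keys = self.ext.step(step)
        self.diag.spikes_emitted += len(keys)
        return keys


# ---------------------------------------------------------------------------
# Router and machine container
# ---------------------------------------------------------------------------

class Router:
    """Lossless delivery of emitted keys to subscribed cores.

    Key spaces (base, mask) are registered at build time; delivery resolves
    a key to its unique space by masked comparison.  An emitted key with no
    registered space is a build defect, so it raises.
    """

    def __init__(self):
        self.spaces: list[tuple[int, int]] = []        # (base, mask)
        self.subscribers: list[list] = []
        self.delivered = 0

    def add_space(self, base: int, mask: int) -> int:
        self.spaces.append((base, mask))
        self.subscribers.append([])
        return len(self.spaces) - 1

    def subscribe(self, space_id: int, core) -> None:
        if core not in self.subscribers[space_id]:
            self.subscribers[space_id].append(core)

    def resolve(self, key: int) -> int:
        for i, (base, mask) in enumerate(self.spaces):
            if (key & mask) == base:
                return i
        raise KeyError(f"unroutable key {key:#010x}")

    def deliver(self, key: int) -> int:
        space = self.resolve(key)
        targets = self.subscribers[space]
        for core in targets:
            core.on_packet_received(key)
        self.delivered += len(targets)
        return len(targets)


@dataclass
class Machine:
    """A fully-built machine graph ready to simulate."""

    dt: float
    t_p: float
    shift: int
    cores: list                      # deterministic order = core index
    router: Router
    vertices: dict = field(default_factory=dict)     # label -> MachineVertex list
    manifest: dict = field(default_factory=dict)

    @property
    def neuron_cores(self) -> list[NeuronCore]:
        return [c for c in self.cores if isinstance(c, NeuronCore)]

    def cores_for(self, label: str) -> list:
        return [c for c in self.cores
                if getattr(c.vertex.population, "label", None) == label]

    def diagnostics(self) -> dict:
        return {f"core_{i}_{type(c).__name__}": c.diag.as_dict()
                for i, c in enumerate(self.cores)}


class Simulator:
    """Global event loop over all cores of a built machine.

    ``accounting=True`` prices every period's callbacks with the supplied
    cost coefficients and diagnoses timer overruns (virtual cost > t_p);
    overruns are counted, never fatal.  Deterministic given the build seed:
    identical seeds give bit-identical spike trains.
    """

    def __init__(self, machine: Machine, accounting: bool = False,
                 coeffs: costmodel.CostCoefficients | None = None):
        self.machine = machine
        self.accounting = accounting
        self.coeffs = coeffs or costmodel.LIF_COEFFS
        self.steps_run = 0

    def run(self, duration_ms: float) -> None:
        m = self.machine
        n_steps = int(round(duration_ms / m.dt))
        for _ in range(n_steps):
            self.step()

    def step(self) -> None:
        m = self.machine
        t = self.steps_run
        emitted: list[int] = []
        for core in m.cores:
            emitted.extend(core.timer(t))
        for key in emitted:
            m.router.deliver(key)
        for core in m.cores:
            if isinstance(core, DelayCore):
                core.register_pending(t)
        for core in m.cores:
            if isinstance(core, NeuronCore):
                word_counts = core.process_pending()
                if self.accounting:
                    self._account(core, word_counts)
        for core in m.cores:
            if isinstance(core, NeuronCore):
                core.ring.advance()
        self.steps_run += 1

    def _account(self, core: NeuronCore, word_counts: list[int]) -> None:
        """Price one period: neuron update plus the drained pipeline, with
        the first and last spikes at their own profiled rates."""
        c = self.coeffs
        cost = c.m_n * core.n + c.c_n
        k = len(word_counts)
        if k >= 1:
            cost += c.m_s_f * word_counts[0] + c.c_s_f
        if k >= 2:
            cost += c.m_s_l * word_counts[-1] + c.c_s_l
        for w in word_counts[1:-1]:
            cost += c.m_s_s * w + c.c_s_s
        core.diag.note_period_cost(cost, self.coeffs.t_p)


# ---------------------------------------------------------------------------
# Callback priority engine (instrumented traces)
# ---------------------------------------------------------------------------

PRIORITIES = {"packet": -1, "dma_complete": 0, "user": 0, "timer": 2}
QUEUE_LIMIT = 15


@dataclass
class TraceEntry:
    """One executed callback: scheduling time plus execution segments (a
    gap between segments means the callback was suspended by a
    higher-priority one)."""

    name: str
    priority: int
    scheduled: float
    segments: list[tuple[float, float]] = field(default_factory=list)

    @property
    def start(self) -> float:
        return self.segments[0][0]

    @property
    def end(self) -> float:
        return self.segments[-1][1]

    @property
    def preempted(self) -> bool:
        return len(self.segments) > 1


class _Frame:
    __slots__ = ("entry", "remaining", "seg_start")

    def __init__(self, entry: TraceEntry, duration: float, now: float):
        self.entry = entry
        self.remaining = duration
        self.seg_start = now


class CallbackEngine:
    """Virtual-time replay of the event-driven OS callback semantics.

    Priorities: packet-received −1 (single FIQ handler, preempts
    everything), user and row-processing 0 (preempt 1 and 2, never queued —
    a 0 arriving while a 0 runs is held pending), timer 2 (queued, queue
    length 15 with overflow counted).  Spike keys flow through a real
    :class:`InputSpikeBuffer`; the user event is raised only when the
    pipeline is inactive.  Durations are per callback kind, in µs.
    """

    def __init__(self, durations: dict[str, float], dma_latency: float = 0.0):
        self.durations = dict(durations)
        self.dma_latency = dma_latency
        self.events: list[tuple[float, int, str]] = []
        self._seq = 0
        self.trace: list[TraceEntry] = []
        self.buffer = InputSpikeBuffer()
        self.pipeline_active = False
        self.queue_overflows = 0
        self.user_events_raised = 0
        self.timer_overruns = 0
        self._timer_times: list[float] = []

    def post(self, time: float, kind: str) -> None:
        if kind == "timer":
            self._timer_times.append(time)
        heapq.heappush(self.events, (time, self._seq, kind))
        self._seq += 1

    # -- engine -------------------------------------------------------------

    def run(self) -> list[TraceEntry]:
        stack: list[_Frame] = []              # running callback last
        queued: list[tuple[float, str]] = []  # priorities 1-2
        held: list[tuple[float, str]] = []    # arrived priority-0, blocked
        now = 0.0

        def start(kind: str, sched: float, t: float) -> None:
            entry = TraceEntry(kind, PRIORITIES[kind], sched)
            self.trace.append(entry)
            stack.append(_Frame(entry, self.durations[kind], t))

        def preempt_and_start(kind: str, sched: float, t: float) -> None:
            frame = stack[-1]
            frame.entry.segments.append((frame.seg_start, t))
            frame.remaining -= t - frame.seg_start
            start(kind, sched, t)

        while self.events or stack or queued or held:
            # promote a held priority-0 event as soon as it may run
            if held and (not stack or stack[-1].entry.priority > 0):
                sched, kind = held.pop(0)
                if stack:
                    preempt_and_start(kind, sched, now)
                else:
                    start(kind, sched, max(now, sched))
                    now = max(now, sched)
                continue
            t_next = self.events[0][0] if self.events else float("inf")
            if stack:
                frame = stack[-1]
                finish = now + frame.remaining
                if finish <= t_next:
                    frame.entry.segments.append((frame.seg_start, finish))
                    now = finish
                    stack.pop()
                    if stack:
                        stack[-1].seg_start = now
                    self._complete(frame.entry, now)
                    continue
                t, _, kind = heapq.heappop(self.events)
                now_t = max(now, t)
                prio = PRIORITIES[kind]
                if prio < frame.entry.priority:
                    preempt_and_start(kind, t, now_t)
                    now = now_t
                elif prio >= 1:
                    if len(queued) >= QUEUE_LIMIT:
                        self.queue_overflows += 1
                    else:
                        queued.append((t, kind))
                else:
                    held.append((t, kind))
                continue
            # idle core: next event or queued callback
            if self.events and (not queued or t_next <= now):
                t, _, kind = heapq.heappop(self.events)
                now = max(now, t)
                if PRIORITIES[kind] >= 1:
                    queued.append((t, kind))
                else:
                    start(kind, t, now)
                continue
            if queued:
                queued.sort(key=lambda q: (PRIORITIES[q[1]], q[0]))
                sched, kind = queued.pop(0)
                now = max(now, sched)
                start(kind, sched, now)
        self._check_overruns()
        return self.trace

    def _complete(self, entry: TraceEntry, now: float) -> None:
        if entry.name == "packet":
            self.buffer.push(0)
            if not self.pipeline_active:
                # raise the software user event; mark the pipeline active at
                # raise time so concurrent packets do not double-raise
                self.pipeline_active = True
                self.user_events_raised += 1
                self.post(now, "user")
        elif entry.name == "user":
            if len(self.buffer):
                self.buffer.pop()
            self.post(now + self.dma_latency, "dma_complete")
        elif entry.name == "dma_complete":
            if len(self.buffer):
                self.buffer.pop()
                self.post(now + self.dma_latency, "dma_complete")
            else:
                self.pipeline_active = False

    def _check_overruns(self) -> None:
        """A timer callback still executing when the next timer event was
        due is an overrun — the realtime-budget diagnostic."""
        timers = [e for e in self.trace if e.name == "timer"]
        deadlines = sorted(self._timer_times)
        for entry in timers:
            later = [d for d in deadlines if d > entry.scheduled]
            if later and entry.end > later[0]:
                self.timer_overruns += 1


# ---------------------------------------------------------------------------
# Accounting-mode throughput measurement
# ---------------------------------------------------------------------------

def empirical_max_events(n: int, p: float,
                         coeffs: costmodel.CostCoefficients | None = None,
                         shift: int = fxp.DEFAULT_SHIFT) -> int:
    """Measure the maximum synaptic events one core can absorb in a timer
    period by feeding spikes through a real ring buffer until the virtual
    clock exhausts ``t_p``.

    The virtual clock accrues word-granularly: a row of W words in pipeline
    regime r costs ``m_r`` per word plus ``c_r / W`` amortised per word, so
    a row interrupted by the period boundary contributes exactly the words
    it processed.  The pipeline's first and last spikes are priced at their
    own rates (their full rows are processed); everything in between at the
    subsequent-spike rate.  Returns the number of synaptic words (= events)
    processed.
    """
    coeffs = coeffs or costmodel.LIF_COEFFS
    w = max(1, round(n * p))
    ring = RingBufferBank(n)
    weight = 1                                    # one ring LSB per event
    targets = np.arange(w, dtype=np.int64) % n
    receptor = np.zeros(w, dtype=np.int64)
    delay = np.ones(w, dtype=np.int64)
    weights = np.full(w, weight, dtype=np.int64)

    neuron_cost = coeffs.m_n * n + coeffs.c_n
    first_cost = coeffs.m_s_f * w + coeffs.c_s_f
    last_cost = coeffs.m_s_l * w + coeffs.c_s_l
    budget = coeffs.t_p - neuron_cost - first_cost - last_cost
    if budget < 0:
        return 0
    # first and last pipeline spikes: full rows through the ring buffer
    ring.inject(targets, receptor, delay, weights)
    ring.inject(targets, receptor, delay, weights)
    events = 2 * w

    per_word = coeffs.m_s_s + coeffs.c_s_s / w
    k = 0
    # 1e-9 µs tie tolerance: floating accumulation vs the exact budget edge
    while (k + 1) * per_word <= budget + 1e-9:
        i = k % w
        ring.inject(targets[i:i + 1], receptor[i:i + 1], delay[i:i + 1],
                    weights[i:i + 1])
        k += 1
    if not ring.conservation_ok():
        raise AssertionError("ring-buffer conservation ledger violated")
    return events + k
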