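"""User-facing network builder, machine assembly, fixtures and results.

The front end is a PyNN-flavoured subset (populations, projections,
connectors) rather than a PyNN backend plug-in: a :class:`Network` is
described declaratively, compiled by :func:`build_machine` into cores,
routing-key spaces and bit-exact synaptic structures, and executed by
:class:`spinnlite.runtime.Simulator`.  Every run is reproducible
bit-for-bit from (config, seed): all randomness flows from one seed
sequence, and the on-core arithmetic is integer-only (floats enter only
host-side precomputation, which is quantised).

Also here: the random balanced network fixture (500 excitatory + 125
inhibitory LIF neurons, 250-unit 50 Hz Poisson background, spike-source
-array stimulus at t = 1 s), YAML config loading, the run manifest, and
CSV/JSON output writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import costmodel, delays as delays_mod, fxp, graph, models, runtime, sources
from .graph import ConnectorSpec, Distribution, Population, Projection
from .synformat import AddressListEntry, matrix_from_rows

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Network description
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Declarative network description (the application graph)."""

    dt: float = 1.0                  # ms
    t_p: float = 1000.0              # µs budget per timer period
    shift: int | None = None         # ring-buffer shift; None -> automatic
    max_per_core: int = graph.DEFAULT_MAX_NEURONS_PER_CORE
    balanced_partition: bool = False
    charge_compensation: bool = True
    populations: list[Population] = field(default_factory=list)
    projections: list[Projection] = field(default_factory=list)
    records: dict[str, set[str]] = field(default_factory=dict)

    def add_population(self, pop: Population) -> Population:
        if any(p.label == pop.label for p in self.populations):
            raise ValueError(f"duplicate population label {pop.label!r}")
        self.populations.append(pop)
        return pop

    def connect(self, projection: Projection) -> Projection:
        labels = {p.label for p in self.populations}
        for end in (projection.pre, projection.post):
            if end not in labels:
                raise ValueError(f"unknown population {end!r} in projection")
        post = self.population(projection.post)
        if post.kind not in graph.NEURON_KINDS:
            raise ValueError("projection target must be a neuron population")
        self.projections.append(projection)
        return projection

    def population(self, label: str) -> Population:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    def record(self, label: str, variable: str) -> None:
        if variable not in ("spikes", "v"):
            raise ValueError("recordable variables are 'spikes' and 'v'")
        self.records.setdefault(label, set()).add(variable)

    def max_weight(self) -> float:
        """Largest configured weight magnitude (for automatic shift choice)."""
        best = 0.0
        for proj in self.projections:
            w = proj.weight
            if isinstance(w, Distribution):
                hi = abs(w.high) if w.kind.startswith("uniform") \
                    else abs(w.mean) + 3 * w.sd
            else:
                hi = abs(float(w))
            best = max(best, hi)
        return best


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    dt: float
    t_p: float
    duration: float
    seed: int
    shift: int
    partition_policy: str
    recording: dict
    format_version: int = FORMAT_VERSION

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Machine assembly
# ---------------------------------------------------------------------------

def _delay_split(delay_steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised stage/residual split of per-synapse delays."""
    stages = (delay_steps - 1) // delays_mod.STAGE_SIZE
    residual = delay_steps - delays_mod.STAGE_SIZE * stages
    return stages, residual


def build_machine(network: Network, seed: int) -> runtime.Machine:
    """Compile a network description into a ready-to-run machine.

    Deterministic: partitioning, key allocation, connectivity realisation
    and initial-state draws all derive from ``seed``.  Projection delays
    beyond 16 timesteps automatically insert a delay-extension core per
    presynaptic machine vertex; delays beyond 144 are a configuration
    error raised here, at build time.
    """
    shift = network.shift
    if shift is None:
        shift = fxp.select_shift(max(network.max_weight(), fxp.ACCUM_EPS))

    root = np.random.SeedSequence(seed)
    pop_seqs = {p.label: s for p, s in
                zip(network.populations, root.spawn(len(network.populations)))}
    proj_seqs = root.spawn(len(network.projections))

    # --- partition and allocate keys ---------------------------------------
    allocator = graph.KeyAllocator()
    vertices: dict[str, list[graph.MachineVertex]] = {}
    for pop in network.populations:
        vs = graph.partition(pop, network.max_per_core,
                             network.balanced_partition)
        for v in vs:
            allocator.allocate(v)
        vertices[pop.label] = vs

    # --- create cores -------------------------------------------------------
    router = runtime.Router()
    cores: list = []
    core_of_vertex: dict[int, object] = {}
    space_of_vertex: dict[int, int] = {}
    for pop in network.populations:
        record = network.records.get(pop.label, set())
        pop_rng = np.random.default_rng(pop_seqs[pop.label])
        v_init_full = None
        if pop.kind in graph.NEURON_KINDS and isinstance(pop.v_init,
                                                         Distribution):
            v_init_full = pop.v_init.sample(pop_rng, pop.size)
        for v in vertices[pop.label]:
            v.core = len(cores)
            space_of_vertex[id(v)] = router.add_space(v.base_key, v.mask)
            if pop.kind in graph.NEURON_KINDS:
                core = runtime.NeuronCore(v, network.dt, shift, pop_rng,
                                          record, v_init_full=v_init_full)
            else:
                core = runtime.SourceCore(v, network.dt,
                                          pop_seqs[pop.label], record)
            cores.append(core)
            core_of_vertex[id(v)] = core

    # --- realise projections into per-edge, per-stage blocks ----------------
    # contributions[target vertex][(source key space)] -> list of
    #   (projection, stage, block restricted to that stage)
    contributions: dict[int, dict[tuple[int, int], list]] = {}
    delay_needs: dict[int, dict[int, set[int]]] = {}   # pre vertex -> {local: stages}

    for proj, proj_seq in zip(network.projections, proj_seqs):
        pre_vs = vertices[proj.pre]
        post_vs = vertices[proj.post]
        edges = graph.machine_edges(pre_vs, post_vs, proj)
        edge_seqs = proj_seq.spawn(len(edges))
        for edge, edge_seq in zip(edges, edge_seqs):
            rng = np.random.default_rng(edge_seq)
            block = graph.realize_block(edge, rng, network.dt)
            if (block.delay_steps > delays_mod.MAX_EXTENDED_DELAY).any():
                bad = int(block.delay_steps.max())
                raise ValueError(
                    f"projection {proj.pre}->{proj.post}: delay {bad} "
                    f"timesteps exceeds delay extension limit of "
                    f"{delays_mod.MAX_EXTENDED_DELAY}")
            stages, residuals = _delay_split(block.delay_steps)
            tgt = contributions.setdefault(id(edge.post), {})
            for stage in np.unique(stages):
                sel = stages == stage
                sub = graph.RealizedBlock(block.pre_local[sel],
                                          block.post_local[sel],
                                          block.weight[sel],
                                          residuals[sel])
                tgt.setdefault((id(edge.pre), int(stage)), []).append(
                    (proj, edge, sub))
                if stage > 0:
                    needs = delay_needs.setdefault(id(edge.pre), {})
                    for local in np.unique(sub.pre_local):
                        needs.setdefault(int(local), set()).add(int(stage))

    # --- delay-extension cores and stage key spaces --------------------------
    all_vertices = [v for vs in vertices.values() for v in vs]
    vertex_by_id = {id(v): v for v in all_vertices}
    stage_keys: dict[tuple[int, int], tuple[int, int]] = {}
    delay_core_of: dict[int, runtime.DelayCore] = {}
    for pre_id, needs in delay_needs.items():
        pre_v = vertex_by_id[pre_id]
        config = delays_mod.DelayStageConfig(
            pre_v.size, {n: tuple(sorted(s)) for n, s in needs.items()})
        bases = {}
        for stage in config.stages_used:
            base, mask = allocator.allocate_block(pre_v.size)
            stage_keys[(pre_id, stage)] = (base, mask)
            bases[stage] = base
            router.add_space(base, mask)
        ext = delays_mod.DelayExtensionVertex(config, bases)
        dcore = runtime.DelayCore(pre_v, ext)
        cores.append(dcore)
        delay_core_of[pre_id] = dcore
        router.subscribe(space_of_vertex[pre_id], dcore)

    # --- per-target tables, matrices, subscriptions --------------------------
    for tgt_id, by_space in contributions.items():
        tgt_core: runtime.NeuronCore = core_of_vertex[tgt_id]
        address_cursor = 0
        for (pre_id, stage), items in sorted(
                by_space.items(),
                key=lambda kv: (vertex_by_id[kv[0][0]].base_key, kv[0][1])):
            pre_v = vertex_by_id[pre_id]
            if stage == 0:
                base, mask = pre_v.base_key, pre_v.mask
                router.subscribe(space_of_vertex[pre_id], tgt_core)
            else:
                base, mask = stage_keys[(pre_id, stage)]
                space_id = router.spaces.index((base, mask))
                router.subscribe(space_id, tgt_core)
            addresses = []
            for proj, edge, block in items:
                scale = 1.0
                post_pop = edge.post.population
                if (network.charge_compensation and post_pop.kind == "lif"
                        and post_pop.input_kind == "current"):
                    tau = post_pop.tau_syn[proj.synapse_type]
                    scale = models.charge_compensation(tau, network.dt)
                rows = graph.block_to_rows(block, pre_v.size,
                                           proj.synapse_type, shift,
                                           weight_scale=scale)
                mat = matrix_from_rows(rows)
                true_len = np.asarray([r.n_static for r in rows],
                                      dtype=np.int64)
                tgt_core.matrices[address_cursor] = mat
                tgt_core.row_true_len[address_cursor] = true_len
                addresses.append(AddressListEntry(
                    local=0, address=address_cursor,
                    row_length=min(mat.shape[1], 0xFF)))
                address_cursor += max(4, mat.shape[0] * mat.shape[1] * 4
                                      + 12 * mat.shape[0])
                address_cursor = -(-address_cursor // 4) * 4
            tgt_core.mpt.add(base, mask, addresses)

    manifest = {
        "format_version": FORMAT_VERSION,
        "dt": network.dt,
        "t_p": network.t_p,
        "shift": shift,
        "seed": seed,
        "partition_policy": ("balanced" if network.balanced_partition
                             else "greedy"),
        "vertices": [
            {"label": v.label, "population": v.population.label,
             "slice": [v.lo, v.hi], "base_key": v.base_key, "mask": v.mask,
             "core": v.core, "kind": v.population.kind}
            for v in all_vertices
        ],
        "delay_vertices": [
            {"source": vertex_by_id[pre_id].label,
             "stages": sorted(dcore.ext.config.stages_used)}
            for pre_id, dcore in delay_core_of.items()
        ],
    }
    return runtime.Machine(dt=network.dt, t_p=network.t_p, shift=shift,
                           cores=cores, router=router, vertices=vertices,
                           manifest=manifest)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class RecordedData:
    """A labelled recording; ``enabled`` is False when the variable was not
    selected for recording (data is then empty by construction)."""

    enabled: bool
    data: np.ndarray


@dataclass
class Results:
    machine: runtime.Machine
    network: Network
    duration: float
    seed: int

    def spikes(self, label: str) -> RecordedData:
        """Recorded spikes of a population as an array of rows
        (time_ms, global neuron id), sorted by time then id."""
        enabled = "spikes" in self.network.records.get(label, set())
        rows = []
        for core in self.machine.cores_for(label):
            for step, local in getattr(core, "spike_steps", []):
                rows.append((step * self.machine.dt, core.vertex.lo + local))
        rows.sort()
        data = np.asarray(rows, dtype=float).reshape(-1, 2)
        return RecordedData(enabled, data)

    def v(self, label: str) -> RecordedData:
        """Membrane trace [n_samples, population size]; one sample per Δt
        plus the initial state (duration/Δt + 1 samples)."""
        enabled = "v" in self.network.records.get(label, set())
        cores = [c for c in self.machine.cores_for(label)
                 if isinstance(c, runtime.NeuronCore)]
        if not enabled or not cores:
            return RecordedData(enabled, np.empty((0, 0)))
        data = np.hstack([np.asarray(c.v_trace) for c in cores])
        return RecordedData(enabled, data)

    def rate_hz(self, label: str, t_lo: float = 0.0,
                t_hi: float | None = None) -> float:
        """Mean per-neuron firing rate of a population over [t_lo, t_hi) ms."""
        t_hi = self.duration if t_hi is None else t_hi
        spk = self.spikes(label).data
        n = self.network.population(label).size
        window_s = (t_hi - t_lo) * 1e-3
        if window_s <= 0 or n == 0:
            return 0.0
        in_win = (spk[:, 0] >= t_lo) & (spk[:, 0] < t_hi) if len(spk) else []
        return float(np.sum(in_win)) / (n * window_s)

    def diagnostics(self) -> dict:
        return self.machine.diagnostics()

    def manifest(self) -> RunManifest:
        return RunManifest(
            dt=self.machine.dt, t_p=self.machine.t_p, duration=self.duration,
            seed=self.seed, shift=self.machine.shift,
            partition_policy=self.machine.manifest["partition_policy"],
            recording={k: sorted(v) for k, v in self.network.records.items()})


def run(network: Network, duration_ms: float, seed: int,
        accounting: bool = False) -> Results:
    """Build and execute a network; returns recordings + diagnostics."""
    machine = build_machine(network, seed)
    sim = runtime.Simulator(machine, accounting=accounting)
    sim.run(duration_ms)
    return Results(machine, network, duration_ms, seed)


# ---------------------------------------------------------------------------
# The random balanced network fixture
# ---------------------------------------------------------------------------

#: fixture constants not fixed by the reference description; chosen once to
#: give a stable, active asynchronous regime (see docs/methods.md)
FIXTURE_INH_WEIGHT = 0.8        # nA
FIXTURE_TAU_SYN = (5.0, 5.0)    # ms (excitatory, inhibitory)
FIXTURE_STIM_WEIGHT = 0.5       # nA
FIXTURE_P_CONNECT = 0.2
FIXTURE_DELAY = Distribution("uniform_int", low=1, high=14)


def build_balanced_fixture(seed: int = 1,
                           record_v: bool = False) -> Network:
    """The random balanced network: 500 excitatory + 125 inhibitory
    current-based LIF neurons with mutual and recurrent 20% projections,
    250 Poisson units providing 50 Hz background, and a 25-unit
    spike-source-array stimulus into the excitatory population at t = 1 s.

    Excitatory membrane potentials initialise uniformly between reset and
    threshold.  Partitioned at 255 neurons/core this network occupies 5
    machine vertices.
    """
    lif = models.LifParams(tau_m=20.0, r_m=20.0, e_l=-65.0, v_theta=-50.0,
                           v_reset=-65.0, t_r=5.0)
    net = Network()
    net.add_population(Population(
        "excitatory", 500, "lif", lif,
        v_init=Distribution("uniform", low=lif.v_reset, high=lif.v_theta),
        tau_syn=FIXTURE_TAU_SYN))
    net.add_population(Population(
        "inhibitory", 125, "lif", lif, v_init=lif.e_l,
        tau_syn=FIXTURE_TAU_SYN))
    net.add_population(Population(
        "poisson_source", 250, "poisson",
        sources.PoissonSourceConfig(rates=np.full(250, 50.0), dt=net.dt)))
    stim_times = [[1000.0 + i] for i in range(25)]
    net.add_population(Population(
        "stimulus", 25, "spike_array",
        sources.SpikeArraySchedule(stim_times, dt=net.dt)))

    p = FIXTURE_P_CONNECT
    conn = lambda: ConnectorSpec("fixed_probability", p_connect=p)
    net.connect(Projection("poisson_source", "excitatory", conn(),
                           weight=0.06, delay=1.0))
    net.connect(Projection("excitatory", "excitatory", conn(),
                           weight=0.06, delay=FIXTURE_DELAY))
    net.connect(Projection("excitatory", "inhibitory", conn(),
                           weight=0.06, delay=FIXTURE_DELAY))
    net.connect(Projection("inhibitory", "excitatory", conn(),
                           weight=FIXTURE_INH_WEIGHT, delay=FIXTURE_DELAY,
                           receptor="inhibitory"))
    net.connect(Projection("inhibitory", "inhibitory", conn(),
                           weight=FIXTURE_INH_WEIGHT, delay=FIXTURE_DELAY,
                           receptor="inhibitory"))
    net.connect(Projection("stimulus", "excitatory",
                           ConnectorSpec("fixed_probability", p_connect=0.5),
                           weight=FIXTURE_STIM_WEIGHT, delay=1.0))
    net.record("excitatory", "spikes")
    net.record("inhibitory", "spikes")
    if record_v:
        net.record("excitatory", "v")
    return net


# ---------------------------------------------------------------------------
# Config files and output writers
# ---------------------------------------------------------------------------

def _parse_value(v):
    if isinstance(v, dict) and "kind" in v:
        return Distribution(**v)
    return v


def network_from_dict(cfg: dict) -> Network:
    net = Network(
        dt=float(cfg.get("dt", 1.0)),
        t_p=float(cfg.get("t_p", 1000.0)),
        shift=cfg.get("shift"),
        max_per_core=int(cfg.get("max_per_core",
                                 graph.DEFAULT_MAX_NEURONS_PER_CORE)),
        balanced_partition=bool(cfg.get("balanced_partition", False)),
        charge_compensation=bool(cfg.get("charge_compensation", True)),
    )
    for p in cfg.get("populations", []):
        kind = p["kind"]
        params = p.get("params")
        if kind == "lif" and params is not None:
            params = models.LifParams(**params)
        elif kind == "izh" and params is not None:
            params = models.IzhParams(**params)
        elif kind == "poisson":
            rates = params.get("rates") if isinstance(params, dict) else params
            params = sources.PoissonSourceConfig(
                rates=np.broadcast_to(np.atleast_1d(rates),
                                      (p["size"],)).copy(),
                dt=net.dt)
        elif kind == "spike_array":
            if isinstance(params, dict) and "spike_times_csv" in params:
                params = sources.schedule_from_csv(params["spike_times_csv"],
                                                   dt=net.dt)
            else:
                times = params["spike_times"] if isinstance(params, dict) \
                    else params
                params = sources.SpikeArraySchedule(times, dt=net.dt)
        pop = Population(p["label"], int(p["size"]), kind, params,
                         v_init=_parse_value(p.get("v_init")),
                         tau_syn=tuple(p.get("tau_syn", (5.0, 5.0))),
                         input_kind=p.get("input_kind", "current"),
                         e_rev=tuple(p["e_rev"]) if p.get("e_rev") else None)
        net.add_population(pop)
        for var in p.get("record", []):
            net.record(p["label"], var)
    for pr in cfg.get("projections", []):
        conn = ConnectorSpec(**pr["connector"])
        net.connect(Projection(pr["pre"], pr["post"], conn,
                               weight=_parse_value(pr["weight"]),
                               delay=_parse_value(pr.get("delay", 1.0)),
                               receptor=pr.get("receptor", "excitatory")))
    return net


def load_config(path) -> tuple[Network, dict]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return network_from_dict(cfg), cfg


def write_spikes_csv(results: Results, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ms,population,neuron_id\n")
        for pop in results.network.populations:
            rec = results.spikes(pop.label)
            if not rec.enabled:
                continue
            for t, nid in rec.data:
                fh.write(f"{t:g},{pop.label},{int(nid)}\n")


def write_v_csv(results: Results, label: str, path) -> None:
    rec = results.v(label)
    data = rec.data
    with open(path, "w") as fh:
        fh.write("time_ms," + ",".join(f"n{i}" for i in range(data.shape[1]))
                 + "\n")
        for i, row in enumerate(data):
            fh.write(f"{i * results.machine.dt:g},"
                     + ",".join(f"{v:.6f}" for v in row) + "\n")


def write_diagnostics_json(results: Results, path) -> None:
    with open(path, "w") as fh:
        json.dump(results.diagnostics(), fh, indent=2, default=str)


def write_manifest(results: Results, path) -> None:
    with open(path, "w") as fh:
        json.dump(results.manifest().as_dict(), fh, indent=2)
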