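"""Application-graph construction and partitioning into machine vertices.

A network description (populations joined by projections) is first viewed
as an *application graph*; each population is then partitioned into
*machine vertices* — contiguous slices small enough to run on one core
(≤ 255 neurons by default, matching the 8-bit neuron-id field of the
synaptic word) — and each projection into *machine edges* between vertex
pairs.  Connectors are partition-aware: a one-to-one connector only needs
edges between slice-overlapping vertex pairs, while probabilistic and
all-to-all connectors need the full bipartite edge set.

Each machine vertex receives a base routing key aligned to the next power
of two at or above its neuron count; the mask is the complement of the
neuron-id field.  This guarantees non-overlapping masked key spaces and
lets a spike key be decomposed as ``base | local_neuron_id``.

Connectivity is realised host-side (per machine edge, from per-edge
spawned RNG streams) and stored; rows are padded and encoded through
:mod:`spinnlite.synformat`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import synformat
from .synformat import EXCITATORY, INHIBITORY, Synapse, SynapticRow

DEFAULT_MAX_NEURONS_PER_CORE = 255

NEURON_KINDS = ("lif", "izh")
SOURCE_KINDS = ("poisson", "spike_array")


# ---------------------------------------------------------------------------
# Description types
# ---------------------------------------------------------------------------

@dataclass
class Distribution:
    """Seeded parameter distribution for weights or delays.

    kinds: ``uniform`` (low, high), ``uniform_int`` (low, high inclusive),
    ``normal`` (mean, sd).  Sampling always goes through an explicit
    numpy Generator so realisations are reproducible.
    """

    kind: str
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size)
        if self.kind == "uniform_int":
            return rng.integers(int(self.low), int(self.high), size,
                                endpoint=True).astype(float)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


ParamValue = "float | Distribution"


@dataclass
class Population:
    """A homogeneous group of neurons or source units."""

    label: str
    size: int
    kind: str                      # lif | izh | poisson | spike_array
    params: object = None          # LifParams / IzhParams / source config
    v_init: "object" = None        # float or Distribution (neuron kinds)
    tau_syn: tuple[float, ...] = (5.0, 5.0)   # ms per receptor (exc, inh)
    input_kind: str = "current"    # current | conductance
    e_rev: tuple[float, ...] | None = None    # reversal potentials (conductance)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("population size must be positive")
        if self.kind not in NEURON_KINDS + SOURCE_KINDS:
            raise ValueError(f"unknown population kind {self.kind!r}")


@dataclass
class ConnectorSpec:
    """kind: one_to_one | fixed_probability | all_to_all | from_list."""

    kind: str
    p_connect: float | None = None
    pairs: Sequence[tuple[int, int]] | None = None   # from_list (pre, post)

    def __post_init__(self) -> None:
        if self.kind == "fixed_probability":
            if self.p_connect is None or not 0.0 <= self.p_connect <= 1.0:
                raise ValueError("fixed_probability requires p_connect in [0,1]")
        elif self.kind == "from_list":
            if self.pairs is None:
                raise ValueError("from_list requires pairs")
        elif self.kind not in ("one_to_one", "all_to_all"):
            raise ValueError(f"unknown connector kind {self.kind!r}")


@dataclass
class Projection:
    """A directed bundle of synapses between two populations."""

    pre: str
    post: str
    connector: ConnectorSpec
    weight: object               # float (nA / µS) or Distribution
    delay: object = 1.0          # ms; float or Distribution
    receptor: str = "excitatory"

    @property
    def synapse_type(self) -> int:
        return INHIBITORY if self.receptor == "inhibitory" else EXCITATORY


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass
class MachineVertex:
    """A population slice executable on a single core."""

    population: Population
    index: int                   # slice index within the population
    lo: int
    hi: int                      # inclusive
    base_key: int | None = None
    mask: int | None = None
    core: int | None = None

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    @property
    def label(self) -> str:
        return f"{self.population.label}[{self.index}]"

    def global_ids(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def key_for(self, local_id: int) -> int:
        return self.base_key | local_id


def partition(population: Population,
              max_per_core: int = DEFAULT_MAX_NEURONS_PER_CORE,
              balanced: bool = False) -> list[MachineVertex]:
    """Split a population into contiguous machine vertices.

    Greedy by default (all slices at ``max_per_core`` except the last);
    ``balanced=True`` spreads neurons evenly over the same vertex count.
    """
    if not 1 <= max_per_core <= 256:
        raise ValueError("max_per_core must be in [1, 256]")
    n = population.size
    n_vertices = -(-n // max_per_core)          # ceil
    sizes = []
    if balanced:
        base, extra = divmod(n, n_vertices)
        sizes = [base + (1 if i < extra else 0) for i in range(n_vertices)]
    else:
        remaining = n
        for _ in range(n_vertices):
            take = min(max_per_core, remaining)
            sizes.append(take)
            remaining -= take
    vertices, lo = [], 0
    for i, size in enumerate(sizes):
        vertices.append(MachineVertex(population, i, lo, lo + size - 1))
        lo += size
    return vertices


class KeyAllocator:
    """Sequential routing-key allocation with power-of-two alignment.

    Each vertex's block is aligned to the next power of two ≥ its size, so
    masked key spaces never overlap and ``mask = ~(align - 1)``.
    """

    def __init__(self) -> None:
        self._next = 0

    def allocate(self, vertex: MachineVertex, size: int | None = None) -> None:
        size = vertex.size if size is None else size
        align = 1
        while align < size:
            align <<= 1
        base = -(-self._next // align) * align
        vertex.base_key = base
        vertex.mask = (~(align - 1)) & 0xFFFFFFFF
        self._next = base + align

    def allocate_block(self, size: int) -> tuple[int, int]:
        """Allocate an anonymous key block (used for delay-stage keys)."""
        align = 1
        while align < size:
            align <<= 1
        base = -(-self._next // align) * align
        self._next = base + align
        return base, (~(align - 1)) & 0xFFFFFFFF


# ---------------------------------------------------------------------------
# Machine edges
# ---------------------------------------------------------------------------

@dataclass
class MachineEdge:
    pre: MachineVertex
    post: MachineVertex
    projection: Projection


def _one_to_one_overlaps(pre: MachineVertex, post: MachineVertex) -> bool:
    return pre.lo <= post.hi and post.lo <= pre.hi


def machine_edges(pre_vertices: Sequence[MachineVertex],
                  post_vertices: Sequence[MachineVertex],
                  projection: Projection) -> list[MachineEdge]:
    """Connector-aware machine-edge generation.

    one_to_one: edges only between slice-overlapping vertex pairs.
    fixed_probability / all_to_all: full bipartite edge set.
    from_list: only vertex pairs with at least one listed connection.
    """
    kind = projection.connector.kind
    edges = []
    for pre in pre_vertices:
        for post in post_vertices:
            if kind == "one_to_one":
                keep = _one_to_one_overlaps(pre, post)
            elif kind == "from_list":
                keep = any(pre.lo <= i <= pre.hi and post.lo <= j <= post.hi
                           for i, j in projection.connector.pairs)
            else:
                keep = True
            if keep:
                edges.append(MachineEdge(pre, post, projection))
    return edges


# ---------------------------------------------------------------------------
# Synapse realisation
# ---------------------------------------------------------------------------

@dataclass
class RealizedBlock:
    """Realised connections of one machine edge, in local coordinates."""

    pre_local: np.ndarray
    post_local: np.ndarray
    weight: np.ndarray           # nA / µS, before encoding
    delay_steps: np.ndarray      # timesteps, >= 1

    @property
    def n_synapses(self) -> int:
        return len(self.pre_local)


def _sample(value, rng: np.random.Generator, size: int) -> np.ndarray:
    if isinstance(value, Distribution):
        return value.sample(rng, size)
    return np.full(size, float(value))


def realize_block(edge: MachineEdge, rng: np.random.Generator,
                  dt: float = 1.0) -> RealizedBlock:
    """Draw the connection pattern for one machine edge.

    Bernoulli draws per pre/post pair for fixed-probability connectors;
    deterministic patterns otherwise.  Weights and delays come from the
    projection's scalars or seeded distributions; delays are quantised to
    whole timesteps with a minimum of 1.
    """
    conn = edge.projection.connector
    n_pre, n_post = edge.pre.size, edge.post.size
    if conn.kind == "one_to_one":
        lo = max(edge.pre.lo, edge.post.lo)
        hi = min(edge.pre.hi, edge.post.hi)
        ids = np.arange(lo, hi + 1)
        pre_local, post_local = ids - edge.pre.lo, ids - edge.post.lo
    elif conn.kind == "all_to_all":
        pre_local, post_local = np.divmod(np.arange(n_pre * n_post), n_post)
    elif conn.kind == "fixed_probability":
        draws = rng.random((n_pre, n_post)) < conn.p_connect
        pre_local, post_local = np.nonzero(draws)
    elif conn.kind == "from_list":
        pairs = [(i - edge.pre.lo, j - edge.post.lo)
                 for i, j in conn.pairs
                 if edge.pre.lo <= i <= edge.pre.hi
                 and edge.post.lo <= j <= edge.post.hi]
        pre_local = np.asarray([p for p, _ in pairs], dtype=np.int64)
        post_local = np.asarray([q for _, q in pairs], dtype=np.int64)
    else:  # pragma: no cover - ConnectorSpec validates kinds
        raise ValueError(conn.kind)

    n = len(pre_local)
    weights = np.abs(_sample(edge.projection.weight, rng, n))
    delays_ms = _sample(edge.projection.delay, rng, n)
    delay_steps = np.maximum(1, np.rint(delays_ms / dt)).astype(np.int64)
    return RealizedBlock(np.asarray(pre_local, dtype=np.int64),
                         np.asarray(post_local, dtype=np.int64),
                         weights, delay_steps)


def block_to_rows(block: RealizedBlock, n_pre: int, synapse_type: int,
                  shift: int, weight_scale: float = 1.0,
                  max_row_length: int | None = None) -> list[SynapticRow]:
    """Encode a realised block into padded static rows, one per presynaptic
    neuron (empty rows for unconnected ones).  ``weight_scale`` applies the
    charge-compensation factor where enabled."""
    per_pre: list[list[Synapse]] = [[] for _ in range(n_pre)]
    for p, q, w, d in zip(block.pre_local, block.post_local,
                          block.weight, block.delay_steps):
        per_pre[int(p)].append(Synapse(int(q), float(w) * weight_scale,
                                       int(d), synapse_type))
    if max_row_length is None:
        max_row_length = max((len(s) for s in per_pre), default=0)
    return [synformat.build_row(s, shift, max_row_length) for s in per_pre]


def realize_synapses(edge: MachineEdge, seed: int, shift: int,
                     dt: float = 1.0,
                     weight_scale: float = 1.0) -> list[SynapticRow]:
    """Realise one machine edge end-to-end: sample connections, quantise
    delays, encode weights and pad rows.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    block = realize_block(edge, rng, dt)
    return block_to_rows(block, edge.pre.size, edge.projection.synapse_type,
                         shift, weight_scale)
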