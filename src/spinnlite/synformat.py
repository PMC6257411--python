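"""Bit-exact synaptic data structures.

A spike travels the machine as a bare 32-bit routing key (address-event
representation).  The receiving core resolves that key through two lookup
structures and a block of encoded synapse words:

master population table --> address list --> synaptic matrix rows

* A **static synaptic word** packs one synapse into 32 bits: the top 16 bits
  hold the unsigned ring-buffer weight, the bottom 8 bits the postsynaptic
  neuron id, bit 8 the synapse type (0 excitatory / 1 inhibitory), bits 9-12
  the 4-bit delay field and bits 13-15 padding.
* A **synaptic row** holds all synapses of one presynaptic neuron within one
  projection, split into dynamic-plastic / fixed-plastic / static regions
  behind three size headers.  A row is either all-static or all-plastic.
* The **master population table** maps a masked source key to a slice of the
  **address list**, whose packed 4-byte entries locate each projection's
  matrix and give its padded row length.

The 4-bit delay field stores ``delay mod 16``: configured delays span
[1, 16] timesteps on-core, so a stored field of 0 means an effective delay
of 16 (delay 0 is rejected at configuration time).  ``decode_static_word``
returns the raw field value; use :func:`effective_delay` to recover the
timestep count.

All binary serialisations are little-endian.
"""

from __future__ import annotations

import struct
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .fxp import encode_weight

EXCITATORY = 0
INHIBITORY = 1

NEURON_ID_BITS = 8
NEURON_ID_MASK = 0xFF
TYPE_BIT = 8
DELAY_SHIFT = 9
DELAY_FIELD_MASK = 0xF
PADDING_SHIFT = 13
WEIGHT_SHIFT = 16

#: maximum delay handled inside the synaptic row (4-bit field, 16 slots)
MAX_ON_CORE_DELAY = 16

MPT_ENTRY_BYTES = 12
ADDRESS_ENTRY_BYTES = 4

MATRIX_MAGIC = 0x534E4C4D  # "SNLM"
MATRIX_VERSION = 1


class StaticWordFields(NamedTuple):
    weight_raw: int
    neuron_id: int
    synapse_type: int
    delay: int          # raw 4-bit field value (0 encodes an effective 16)


def effective_delay(delay_field: int) -> int:
    """Map the stored 4-bit delay field to timesteps (field 0 -> 16)."""
    return delay_field if delay_field > 0 else MAX_ON_CORE_DELAY


def encode_static_word(weight_raw: int, neuron_id: int, synapse_type: int,
                       delay: int) -> int:
    """Pack one static synapse into a 32-bit word.

    ``delay`` is the configured delay in timesteps, in [1, 16]; it is stored
    modulo 16.  ``weight_raw`` is the already shift-scaled unsigned 16-bit
    integer from :func:`spinnlite.fxp.encode_weight`.
    """
    if not 0 <= weight_raw <= 0xFFFF:
        raise ValueError(f"weight_raw out of 16-bit range: {weight_raw}")
    if not 0 <= neuron_id <= NEURON_ID_MASK:
        raise ValueError(f"neuron_id out of 8-bit range: {neuron_id}")
    if synapse_type not in (EXCITATORY, INHIBITORY):
        raise ValueError(f"synapse_type must be 0 or 1, got {synapse_type}")
    if not 1 <= delay <= MAX_ON_CORE_DELAY:
        raise ValueError(
            f"delay {delay} outside on-core range [1, {MAX_ON_CORE_DELAY}]; "
            "longer delays require the delay-extension path (spinnlite.delays)"
        )
    return ((weight_raw << WEIGHT_SHIFT)
            | ((delay & DELAY_FIELD_MASK) << DELAY_SHIFT)
            | (synapse_type << TYPE_BIT)
            | neuron_id)


def decode_static_word(word: int, lint: bool = False) -> StaticWordFields:
    """Unpack a 32-bit static synaptic word into its fields.

    Padding bits (13-15) are ignored; with ``lint=True`` nonzero padding
    raises instead (useful when auditing foreign matrix dumps).
    """
    if not 0 <= word <= 0xFFFFFFFF:
        raise ValueError(f"word out of 32-bit range: {word}")
    if lint and (word >> PADDING_SHIFT) & 0x7:
        raise ValueError(f"nonzero padding bits in word {word:#010x}")
    return StaticWordFields(
        weight_raw=word >> WEIGHT_SHIFT,
        neuron_id=word & NEURON_ID_MASK,
        synapse_type=(word >> TYPE_BIT) & 1,
        delay=(word >> DELAY_SHIFT) & DELAY_FIELD_MASK,
    )


# ---------------------------------------------------------------------------
# Synaptic rows
# ---------------------------------------------------------------------------

@dataclass
class Synapse:
    """Host-side description of one synapse before encoding."""

    target: int          # postsynaptic neuron id local to the target vertex
    weight: float        # nA (current) or µS (conductance); magnitude
    delay: int           # timesteps, already quantised; [1, 16] on-core
    synapse_type: int = EXCITATORY


@dataclass
class SynapticRow:
    """One presynaptic neuron's block of synapses for one projection.

    ``static_words`` hold encoded 32-bit synapses for static projections;
    plastic projections instead populate ``plastic_dynamic`` (presynaptic
    event history plus per-synapse structures, opaque 32-bit words) and
    ``fixed_plastic`` (16-bit half-words matching the lower half of a static
    word).  A row never mixes the two.  Rows are padded to the projection's
    maximum row length with all-zero words which decode to weight 0 and are
    therefore inert.
    """

    static_words: list[int] = field(default_factory=list)
    plastic_dynamic: list[int] = field(default_factory=list)
    fixed_plastic: list[int] = field(default_factory=list)
    padded_length: int = 0

    def __post_init__(self) -> None:
        if self.static_words and (self.plastic_dynamic or self.fixed_plastic):
            raise ValueError("a row contains only either static or plastic data")
        self.padded_length = max(self.padded_length, len(self.static_words),
                                 len(self.fixed_plastic))

    @property
    def is_plastic(self) -> bool:
        return bool(self.plastic_dynamic or self.fixed_plastic)

    @property
    def n_static(self) -> int:
        return len(self.static_words)

    def to_bytes(self) -> bytes:
        """Serialise: 3 header words then the three regions, little-endian.

        Headers give (in 32-bit words / half-word counts): dynamic-plastic
        region size, fixed-plastic half-word count, static word count.
        Fixed-plastic half-words pack two per 32-bit word; an odd count
        leaves one empty 16-bit half-slot.  Static padding words are
        emitted so every serialised row has the projection's padded length.
        """
        n_static = self.padded_length if not self.is_plastic else 0
        out = struct.pack("<III", len(self.plastic_dynamic),
                          len(self.fixed_plastic), n_static)
        out += b"".join(struct.pack("<I", w) for w in self.plastic_dynamic)
        halves = list(self.fixed_plastic)
        if len(halves) % 2:
            halves.append(0)          # empty half-slot for odd target counts
        out += struct.pack(f"<{len(halves)}H", *halves)
        if not self.is_plastic:
            words = self.static_words + [0] * (self.padded_length - self.n_static)
            out += struct.pack(f"<{len(words)}I", *words)
        return out

    @classmethod
    def from_bytes(cls, data: bytes) -> "SynapticRow":
        n_dyn, n_fixed, n_static = struct.unpack_from("<III", data, 0)
        off = 12
        dyn = list(struct.unpack_from(f"<{n_dyn}I", data, off))
        off += 4 * n_dyn
        n_half_padded = n_fixed + (n_fixed % 2)
        fixed = list(struct.unpack_from(f"<{n_half_padded}H", data, off)[:n_fixed])
        off += 2 * n_half_padded
        static = list(struct.unpack_from(f"<{n_static}I", data, off))
        return cls(static_words=static, plastic_dynamic=dyn,
                   fixed_plastic=fixed, padded_length=max(n_static, n_fixed))

    def byte_length(self) -> int:
        halves = len(self.fixed_plastic) + len(self.fixed_plastic) % 2
        n_static = self.padded_length if not self.is_plastic else 0
        return 12 + 4 * len(self.plastic_dynamic) + 2 * halves + 4 * n_static


def build_row(synapses: Sequence[Synapse], shift: int,
              max_row_length: int | None = None) -> SynapticRow:
    """Encode one presynaptic neuron's synapses into a padded static row.

    Words are sorted by target neuron id; unconnected presynaptic neurons
    yield an empty row padded to ``max_row_length``.  Delays beyond 16
    timesteps are a configuration error here — they must be split by the
    delay-extension planner first.
    """
    for syn in synapses:
        if syn.delay > MAX_ON_CORE_DELAY:
            raise ValueError(
                f"synaptic delay {syn.delay} exceeds the 16-timestep on-core "
                "limit; route this projection through the delay-extension "
                "planner (spinnlite.delays.plan_delay)"
            )
        if syn.delay < 1:
            raise ValueError("synaptic delay must be >= 1 timestep")
        if syn.target > NEURON_ID_MASK:
            raise ValueError(f"target neuron id {syn.target} exceeds 255")
    words = [
        encode_static_word(encode_weight(s.weight, shift), s.target,
                           s.synapse_type, s.delay)
        for s in sorted(synapses, key=lambda s: s.target)
    ]
    padded = max_row_length if max_row_length is not None else len(words)
    if len(words) > padded:
        raise ValueError("row exceeds the projection's maximum row length")
    return SynapticRow(static_words=words, padded_length=padded)


# ---------------------------------------------------------------------------
# Master population table and address list
# ---------------------------------------------------------------------------

class AddressListEntry(NamedTuple):
    """One projection's matrix location, packed into a single 32-bit word:
    1 location-flag bit (fast local vs shared memory), 23-bit word-aligned
    address and 8-bit maximum row length."""

    local: int           # 1 = matrix resident in fast local memory
    address: int         # byte offset of the matrix's first row (word aligned)
    row_length: int      # padded synapses per presynaptic neuron

    def pack(self) -> int:
        if self.address % 4:
            raise ValueError("matrix address must be word aligned")
        if self.address >> 2 >= 1 << 23:
            raise ValueError("address exceeds the 23-bit word-aligned field")
        if not 0 <= self.row_length <= 0xFF:
            raise ValueError("row length exceeds 8 bits")
        return ((self.local & 1) << 31) | ((self.address >> 2) << 8) | self.row_length

    @classmethod
    def unpack(cls, word: int) -> "AddressListEntry":
        return cls(local=(word >> 31) & 1,
                   address=((word >> 8) & ((1 << 23) - 1)) << 2,
                   row_length=word & 0xFF)


class MasterPopulationEntry(NamedTuple):
    key: int             # 32-bit base key (already masked)
    mask: int            # 32-bit mask
    start: int           # 16-bit index of the first address-list row
    count: int           # 16-bit number of address-list rows (projections)


@dataclass
class MasterPopulationTable:
    """Masked-key lookup from incoming spike key to address-list rows.

    Entries are kept sorted by key so lookups can binary-search; masked key
    spaces must not overlap (checked at build time).  Entry size is 12 bytes,
    address-list entries 4 bytes.
    """

    entries: list[MasterPopulationEntry] = field(default_factory=list)
    address_list: list[AddressListEntry] = field(default_factory=list)

    def add(self, key: int, mask: int,
            addresses: Sequence[AddressListEntry]) -> None:
        if key & ~mask & 0xFFFFFFFF:
            raise ValueError("entry key has bits outside its mask")
        for e in self.entries:
            common = e.mask & mask
            if (e.key & common) == (key & common):
                raise ValueError(
                    f"masked key space {key:#x}/{mask:#x} overlaps existing "
                    f"entry {e.key:#x}/{e.mask:#x}")
        start = len(self.address_list)
        self.address_list.extend(addresses)
        self.entries.append(MasterPopulationEntry(key, mask, start, len(addresses)))
        self.entries.sort(key=lambda e: e.key)
        self._keys = [e.key for e in self.entries]

    def lookup(self, key: int) -> list[AddressListEntry]:
        """Binary search for the unique entry with ``key & mask == entry.key``
        and return its address-list slice.  Raises :class:`KeyError` for an
        unknown source key (callers drop the spike and count it)."""
        entries = self.entries
        if entries:
            i = bisect_right(self._keys, key) - 1
            if i >= 0:
                e = entries[i]
                if (key & e.mask) == e.key:
                    return self.address_list[e.start:e.start + e.count]
        raise KeyError(f"unknown source key {key:#010x}")

    def lookup_with_entry(self, key: int) -> tuple[MasterPopulationEntry,
                                                   list[AddressListEntry]]:
        """Like :meth:`lookup` but also returns the matched entry (whose mask
        recovers the source-local neuron id from the key)."""
        entries = self.entries
        if entries:
            i = bisect_right(self._keys, key) - 1
            if i >= 0:
                e = entries[i]
                if (key & e.mask) == e.key:
                    return e, self.address_list[e.start:e.start + e.count]
        raise KeyError(f"unknown source key {key:#010x}")

    def lookup_linear(self, key: int) -> list[AddressListEntry]:
        """Linear-scan reference lookup (oracle for the binary search)."""
        for e in self.entries:
            if (key & e.mask) == e.key:
                return self.address_list[e.start:e.start + e.count]
        raise KeyError(f"unknown source key {key:#010x}")

    def footprint_bytes(self) -> int:
        return table_footprint_bytes(len(self.entries), len(self.address_list))

    def to_bytes(self) -> bytes:
        out = struct.pack("<II", len(self.entries), len(self.address_list))
        for e in self.entries:
            out += struct.pack("<IIHH", e.key, e.mask, e.start, e.count)
        for a in self.address_list:
            out += struct.pack("<I", a.pack())
        return out

    @classmethod
    def from_bytes(cls, data: bytes) -> "MasterPopulationTable":
        n_e, n_a = struct.unpack_from("<II", data, 0)
        off = 8
        table = cls()
        entries = []
        for _ in range(n_e):
            key, mask, start, count = struct.unpack_from("<IIHH", data, off)
            entries.append(MasterPopulationEntry(key, mask, start, count))
            off += MPT_ENTRY_BYTES
        addresses = []
        for _ in range(n_a):
            (word,) = struct.unpack_from("<I", data, off)
            addresses.append(AddressListEntry.unpack(word))
            off += ADDRESS_ENTRY_BYTES
        table.entries = entries
        table.address_list = addresses
        table._keys = [e.key for e in entries]
        return table


def table_footprint_bytes(n_vertices: int, n_address_rows: int) -> int:
    """Bytes used by the lookup structures: 12 per master-population entry
    (one per source vertex) plus 4 per packed address-list row."""
    if n_vertices < 0 or n_address_rows < 0:
        raise ValueError("counts must be non-negative")
    return MPT_ENTRY_BYTES * n_vertices + ADDRESS_ENTRY_BYTES * n_address_rows


# ---------------------------------------------------------------------------
# Synaptic matrix dumps
# ---------------------------------------------------------------------------

def write_matrix(path, rows: Sequence[SynapticRow], shift: int) -> None:
    """Versioned little-endian binary dump of a synaptic matrix.

    Header: magic, version, shift, row count, padded row length (words).
    The shift is recorded so dumps are self-describing.
    """
    row_len = max((r.padded_length for r in rows), default=0)
    with open(path, "wb") as fh:
        fh.write(struct.pack("<IIIII", MATRIX_MAGIC, MATRIX_VERSION, shift,
                             len(rows), row_len))
        for row in rows:
            fh.write(row.to_bytes())


def read_matrix(path) -> tuple[list[SynapticRow], int]:
    with open(path, "rb") as fh:
        magic, version, shift, n_rows, _row_len = struct.unpack("<IIIII",
                                                                fh.read(20))
        if magic != MATRIX_MAGIC:
            raise ValueError("not a spinnlite synaptic matrix dump")
        if version != MATRIX_VERSION:
            raise ValueError(f"unsupported matrix dump version {version}")
        data = fh.read()
    rows = []
    off = 0
    for _ in range(n_rows):
        row = SynapticRow.from_bytes(data[off:])
        rows.append(row)
        off += row.byte_length()
    return rows, shift


def rows_to_json(rows: Sequence[SynapticRow]) -> list[dict]:
    """Row-level debugging export: decoded fields per static word."""
    out = []
    for i, row in enumerate(rows):
        words = [decode_static_word(w)._asdict() for w in row.static_words]
        out.append({"row": i, "plastic": row.is_plastic,
                    "padded_length": row.padded_length, "static": words})
    return out


def matrix_from_rows(rows: Sequence[SynapticRow]) -> np.ndarray:
    """Stack static rows into a dense uint32 word matrix for the runtime.

    Padding words are zero (weight 0) and therefore inert when processed.
    """
    row_len = max((r.padded_length for r in rows), default=0)
    mat = np.zeros((len(rows), row_len), dtype=np.uint32)
    for i, row in enumerate(rows):
        if row.is_plastic:
            raise ValueError("plastic rows are parsed but not executable")
        if row.static_words:
            mat[i, :len(row.static_words)] = row.static_words
    return mat
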