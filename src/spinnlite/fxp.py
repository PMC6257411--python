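"""Emulation of ISO/IEC TR 18037 ``accum`` (s16.15) fixed-point arithmetic.

The neuromorphic cores emulated by this package have no floating-point
hardware; every on-"core" quantity (membrane potential in mV, synaptic
current in nA, conductance in µS, decay factors) is a signed 32-bit integer
interpreted as ``raw / 2**15``.  This module provides

* a scalar :class:`Accum` value type with the saturation/wrap semantics of
  the hardware type (wrap-around on overflow, underflow-to-zero below
  ``2**-15``),
* vectorised helpers (``mul_raw``, ``add_raw`` …) operating on int64 numpy
  arrays of raw values, used by the neuron solvers,
* the shift-based conversion between 16-bit ring-buffer integers and accum
  weights (``encode_weight`` / ``decode_ring_value``), and
* host-side precomputation of exponential decay factors.

Weights are scaled by ``2**(15 - shift)`` before being written as unsigned
16-bit integers into synaptic matrices; a left-shift by ``shift`` recovers
the accum value at run time.  With the default ``shift = 6`` the
least-significant ring-buffer bit is worth ``2**-9`` nA and the top bit
region reaches ``2**7 = 128``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

FRAC_BITS = 15
SCALE = 1 << FRAC_BITS          # 32768
RAW_BITS = 32
RAW_MOD = 1 << RAW_BITS
RAW_HALF = 1 << (RAW_BITS - 1)

#: smallest representable positive accum value, 2**-15
ACCUM_EPS = 2.0 ** -FRAC_BITS
#: largest representable accum value, (2**31 - 1) / 2**15
ACCUM_MAX = (RAW_HALF - 1) / SCALE

#: default ring-buffer shift (worked-example value; see select_shift)
DEFAULT_SHIFT = 6
#: ring-buffer slots saturate at the unsigned 16-bit ceiling
U16_MAX = 0xFFFF


@dataclass
class FxpDiagnostics:
    """Counters for silent fixed-point events (wraps never raise)."""

    mul_wraps: int = 0
    add_wraps: int = 0

    def reset(self) -> None:
        self.mul_wraps = 0
        self.add_wraps = 0


#: module-level diagnostics used by scalar Accum arithmetic
diagnostics = FxpDiagnostics()


def _wrap32(raw):
    """Two's-complement wrap of an integer (or int64 array) into 32 bits."""
    return (raw + RAW_HALF) % RAW_MOD - RAW_HALF


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def to_raw(value: float) -> int:
    """Quantise a host-side double to the nearest raw s16.15 value (wraps)."""
    return _wrap32(_round_half_away(value * SCALE))


def from_raw(raw: int) -> float:
    return raw / SCALE


@dataclass(frozen=True)
class Accum:
    """A signed 16.15 fixed-point scalar; ``value = raw / 2**15``.

    Addition and subtraction of in-range operands are exact; overflow wraps
    (two's complement) and is counted in :data:`diagnostics`.  Multiplication
    rounds the discarded 15 bits to nearest (ties away from zero); any
    product whose exact magnitude is below ``2**-15`` underflows to zero.
    """

    raw: int

    @classmethod
    def from_float(cls, value: float) -> "Accum":
        return cls(to_raw(value))

    def __float__(self) -> float:
        return self.raw / SCALE

    @property
    def value(self) -> float:
        return self.raw / SCALE

    def __add__(self, other: "Accum") -> "Accum":
        raw = self.raw + other.raw
        wrapped = _wrap32(raw)
        if wrapped != raw:
            diagnostics.add_wraps += 1
        return Accum(wrapped)

    def __sub__(self, other: "Accum") -> "Accum":
        raw = self.raw - other.raw
        wrapped = _wrap32(raw)
        if wrapped != raw:
            diagnostics.add_wraps += 1
        return Accum(wrapped)

    def __mul__(self, other: "Accum") -> "Accum":
        return accum_mul(self, other)

    def __neg__(self) -> "Accum":
        return Accum(_wrap32(-self.raw))

    def __lt__(self, other: "Accum") -> bool:
        return self.raw < other.raw

    def __le__(self, other: "Accum") -> bool:
        return self.raw <= other.raw

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Accum({self.raw / SCALE!r})"


ACCUM_ZERO = Accum(0)
ACCUM_ONE = Accum(SCALE)


def accum_mul(a: Accum, b: Accum) -> Accum:
    """Fixed-point multiply: ``(a.raw * b.raw) >> 15`` with nearest rounding.

    Results with exact magnitude below ``2**-15`` underflow to zero; results
    beyond the 32-bit range wrap silently (diagnostics counter incremented).
    """
    prod = a.raw * b.raw            # exact: value * 2**30
    mag = abs(prod)
    if 0 < mag < SCALE:             # |exact| < 2**-15 -> underflow to zero
        return ACCUM_ZERO
    q = (mag + (1 << (FRAC_BITS - 1))) >> FRAC_BITS
    raw = q if prod >= 0 else -q
    wrapped = _wrap32(raw)
    if wrapped != raw:
        diagnostics.mul_wraps += 1
    return Accum(wrapped)


# ---------------------------------------------------------------------------
# Vectorised raw-array arithmetic (int64 arrays holding 32-bit raw values)
# ---------------------------------------------------------------------------

def mul_raw(a, b):
    """Element-wise s16.15 multiply on int64 raw arrays (or scalars).

    Same rounding/underflow/wrap semantics as :func:`accum_mul`; wraps are
    silent here (the per-element count is not tracked in the hot path).
    """
    prod = np.asarray(a, dtype=np.int64) * np.asarray(b, dtype=np.int64)
    mag = np.abs(prod)
    q = (mag + (1 << (FRAC_BITS - 1))) >> FRAC_BITS
    q[mag < SCALE] = 0              # underflow-to-zero
    return _wrap32(np.where(prod >= 0, q, -q))


def add_raw(a, b):
    """Element-wise wrapping s16.15 add on int64 raw arrays."""
    return _wrap32(np.asarray(a, dtype=np.int64) + np.asarray(b, dtype=np.int64))


def sub_raw(a, b):
    return _wrap32(np.asarray(a, dtype=np.int64) - np.asarray(b, dtype=np.int64))


def array_to_raw(values) -> np.ndarray:
    """Quantise a float array to raw s16.15 (nearest, ties away from zero)."""
    v = np.asarray(values, dtype=np.float64)
    raw = np.sign(v) * np.floor(np.abs(v) * SCALE + 0.5)
    return _wrap32(raw.astype(np.int64))


def raw_to_float(raw) -> np.ndarray:
    return np.asarray(raw, dtype=np.float64) / SCALE


# ---------------------------------------------------------------------------
# Ring-buffer weight codec
# ---------------------------------------------------------------------------

def max_weight(shift: int) -> float:
    """Largest weight encodable at a given shift: ``65535 * 2**(shift-15)``."""
    return U16_MAX * 2.0 ** (shift - FRAC_BITS)


def encode_weight(weight: float, shift: int) -> int:
    """Host-side weight encoding: scale by ``2**(15-shift)``, round to nearest
    (ties away from zero) and return the unsigned 16-bit raw integer.

    Raises :class:`ValueError` for weights outside ``[0, max_weight(shift)]``;
    inhibitory weights are stored as magnitudes (the sign lives in the
    synapse-type bit of the synaptic word).
    """
    if not 0 <= shift <= 15:
        raise ValueError(f"shift must be in [0, 15], got {shift}")
    raw = _round_half_away(weight * 2.0 ** (FRAC_BITS - shift))
    if raw < 0 or raw > U16_MAX:
        raise ValueError(
            f"weight {weight} not representable with shift {shift}; "
            f"maximum representable weight is {max_weight(shift)}"
        )
    return raw


def decode_ring_value(raw: int, shift: int) -> Accum:
    """Convert a 16-bit ring-buffer integer to accum: ``raw * 2**(shift-15)``.

    Exact — the left-shifted raw always fits the accum fraction.
    """
    if not 0 <= raw <= U16_MAX:
        raise ValueError(f"ring-buffer raw value out of range: {raw}")
    return Accum(raw << shift)


def decode_ring_raw(raw, shift: int):
    """Vectorised ring->accum conversion returning int64 raw values."""
    return np.asarray(raw, dtype=np.int64) << shift


def select_shift(max_configured_weight: float, headroom_bits: int = 4) -> int:
    """Automatic shift selection: the smallest shift such that the largest
    configured weight is representable with ``headroom_bits`` bits of
    accumulation headroom left in the 16-bit slot.

    An explicit shift in the run configuration always wins over this rule.
    """
    limit = U16_MAX >> headroom_bits
    for shift in range(16):
        if _round_half_away(max_configured_weight * 2.0 ** (FRAC_BITS - shift)) <= limit:
            return shift
    raise ValueError(
        f"weight {max_configured_weight} too large for any shift with "
        f"{headroom_bits} bits of headroom"
    )


def precompute_decay(tau: float, dt: float) -> Accum:
    """Host-side precomputation of ``exp(-dt/tau)`` quantised to accum.

    Exponentials are expensive on-core, so decay constants are evaluated in
    double precision on the host and loaded as fixed-point constants.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return Accum.from_float(math.exp(-dt / tau))
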