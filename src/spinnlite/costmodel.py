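"""Analytic synaptic-event throughput model and memory-footprint accounting.

Realtime execution gives a core a fixed virtual budget ``t_p`` (µs, 1000
for a 1 ms timestep) per timer period.  Updating ``n`` neurons costs
``m_n·n + c_n``; processing a spike that targets ``nP`` neurons costs a
per-word slope plus a fixed overhead, with distinct coefficients for the
first, subsequent and last spikes of an active pipeline (profiled on the
original hardware; shipped here as presets).  The predicted number of
synaptic events (spike × target pairs) per period is::

    E_s = nP * ( (t_p - (m_n n + c_n) - (m_sf nP + c_sf) - (m_sl nP + c_sl))
                 / (m_ss nP + c_ss)  +  2 )

where the ``+2`` (inside the bracket, multiplied by nP) restores the first
and last spikes whose costs were subtracted explicitly.  Reported event
counts are floored to whole events.

The DTCM footprint accounting mirrors the same core layout: 16 two-byte
ring-buffer slots per neuron per receptor, per-neuron model parameters,
the 12-byte master-population / 4-byte address-list lookup entries, spike
buffers and a fixed OS allowance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synformat import table_footprint_bytes

#: default timer period, µs (1 ms timestep at realtime)
DEFAULT_T_P = 1000.0


@dataclass(frozen=True)
class CostCoefficients:
    """Profiled cost-model parameters, all in µs.

    ``m_*`` are slopes (per neuron or per synaptic word), ``c_*`` fixed
    offsets; ``_f``/``_s``/``_l`` refer to the first, subsequent and last
    spikes of an active processing pipeline.
    """

    m_n: float          # µs / neuron, state update
    c_n: float          # µs, fixed neuron-update overhead
    m_s_f: float        # µs / synaptic word, first spike of pipeline
    c_s_f: float
    m_s_s: float        # µs / synaptic word, subsequent spikes
    c_s_s: float
    m_s_l: float        # µs / synaptic word, last spike
    c_s_l: float
    t_p: float = DEFAULT_T_P

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.m_n, self.c_n, self.m_s_f, self.c_s_f,
                               self.m_s_s, self.c_s_s, self.m_s_l,
                               self.c_s_l, self.t_p)):
            raise ValueError("cost coefficients must be non-negative")


#: profiled preset for current-based LIF neurons with static synapses
LIF_COEFFS = CostCoefficients(m_n=1.015, c_n=3.235,
                              m_s_f=0.126, c_s_f=6.567,
                              m_s_s=0.115, c_s_s=3.96,
                              m_s_l=0.115, c_s_l=2.48)

#: Izhikevich preset: costlier neuron update, spike terms shared with LIF
IZK_COEFFS = replace(LIF_COEFFS, m_n=1.450, c_n=3.231)


@dataclass(frozen=True)
class EventPrediction:
    events: int            # floored whole synaptic events per period
    exact: float           # un-floored model value
    headroom: bool         # False when the neuron update alone exceeds t_p

    def __int__(self) -> int:
        return self.events


def predict_events(n: int, p: float,
                   coeffs: CostCoefficients = LIF_COEFFS) -> EventPrediction:
    """Predicted synaptic events per timer period for ``n`` neurons per core
    and connection probability ``p``.

    Returns events = 0 with ``headroom=False`` when the neuron update leaves
    no spike-processing time.
    """
    if n <= 0 or p <= 0:
        return EventPrediction(0, 0.0, True)
    np_ = n * p
    neuron = coeffs.m_n * n + coeffs.c_n
    if neuron >= coeffs.t_p:
        return EventPrediction(0, 0.0, False)
    first = coeffs.m_s_f * np_ + coeffs.c_s_f
    last = coeffs.m_s_l * np_ + coeffs.c_s_l
    denom = coeffs.m_s_s * np_ + coeffs.c_s_s
    if denom <= 0:
        raise ValueError("subsequent-spike cost must be positive")
    exact = np_ * ((coeffs.t_p - neuron - first - last) / denom + 2.0)
    exact = max(exact, 0.0)
    return EventPrediction(int(exact), exact, True)


def sweep(coeffs: CostCoefficients = LIF_COEFFS,
          n_range=range(16, 513, 16),
          p_range=(0.05, 0.1, 0.2, 0.3, 0.5, 1.0)) -> pd.DataFrame:
    """Prediction grid over neurons-per-core and connection probability.

    Returns a tidy DataFrame with columns n, P, events, exact, plus a
    per-P ``argmax`` flag marking the n that maximises throughput.
    """
    records = []
    for p in p_range:
        for n in n_range:
            pred = predict_events(n, p, coeffs)
            records.append({"n": n, "P": p, "events": pred.events,
                            "exact": pred.exact})
    df = pd.DataFrame.from_records(records)
    df["argmax"] = False
    for p in p_range:
        sel = df["P"] == p
        if df.loc[sel, "events"].max() > 0:
            df.loc[df.loc[sel, "events"].idxmax(), "argmax"] = True
    return df


def argmax_n(p: float, coeffs: CostCoefficients = LIF_COEFFS,
             n_range=range(16, 513)) -> int:
    """Neurons-per-core maximising predicted events at fixed P (grid search)."""
    return max(n_range, key=lambda n: predict_events(n, p, coeffs).exact)


# ---------------------------------------------------------------------------
# DTCM footprint accounting
# ---------------------------------------------------------------------------

RING_SLOTS = 16
RING_SLOT_BYTES = 2
INPUT_SPIKE_BUFFER_BYTES = 256 * 4       # 256 pending 32-bit keys
DMA_BUFFER_BYTES = 2 * 256 * 4           # double-buffered maximum-length row
OS_ALLOWANCE_BYTES = 6 * 1024            # system libraries (fixed allowance)
STACK_BYTES = 2 * 1024

#: per-neuron parameter+state bytes by neuron model.  The LIF figure (56 B)
#: reproduces the reference core layout (14.28 kB at 255 neurons); the
#: Izhikevich figure is this package's estimate for its own state layout.
MODEL_BYTES_PER_NEURON = {"lif": 56, "izh": 64}


@dataclass(frozen=True)
class FootprintReport:
    """DTCM byte accounting for one neuron core."""

    ring_buffers: int
    neuron_params: int
    lookup_tables: int
    spike_buffers: int
    recording: int
    os_allowance: int

    @property
    def total(self) -> int:
        return (self.ring_buffers + self.neuron_params + self.lookup_tables
                + self.spike_buffers + self.recording + self.os_allowance)


def ring_buffer_bytes(n: int, receptors: int = 2) -> int:
    """16 two-byte slots per neuron per receptor."""
    return n * receptors * RING_SLOTS * RING_SLOT_BYTES


def footprint(n: int, receptors: int = 2, model: str = "lif",
              n_source_vertices: int = 0, n_address_rows: int = 0,
              recording_bytes: int = 0) -> FootprintReport:
    """Assemble the DTCM footprint report for a core simulating ``n``
    neurons with the given lookup-table sizes."""
    return FootprintReport(
        ring_buffers=ring_buffer_bytes(n, receptors),
        neuron_params=n * MODEL_BYTES_PER_NEURON[model],
        lookup_tables=table_footprint_bytes(n_source_vertices, n_address_rows),
        spike_buffers=INPUT_SPIKE_BUFFER_BYTES + DMA_BUFFER_BYTES,
        recording=recording_bytes,
        os_allowance=OS_ALLOWANCE_BYTES + STACK_BYTES,
    )
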