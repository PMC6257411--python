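"""Spike-source applications: Poisson generators and spike-source arrays.

Source vertices run alongside neuron cores, driven by the same timer
events, and only ever emit packets.  Two kinds are provided:

* **Poisson source** — each unit fires as an independent Poisson process at
  its mean rate.  Units with an expected count of at most one spike per
  timestep (``rate·Δt ≤ 1``) run in the *slow* regime: after each spike an
  inter-spike interval is drawn in whole timesteps and counted down.  Two
  ISI families are available: ``geometric`` (default; per-step hazard
  ``rate·Δt``, which keeps the mean rate exact for all ``rate·Δt ≤ 1`` and
  agrees with the fast regime at the boundary) and ``exponential`` (an
  exponential draw rounded to ≥ 1 Δt, which under-produces spikes as
  ``rate·Δt`` approaches 1 — retained as the documented approximation).
  Faster units run in the *fast* regime: a Poisson count
  ``~ Poisson(rate·Δt)`` is drawn each step and that many packets emitted
  (the hardware intersperses them with random delays inside the period;
  functionally only the count matters, the spacing enters cost accounting
  only).
* **Spike-source array** — units emit at prescribed times, quantised to the
  Δt grid (duplicates collapse with a warning).

Every unit has its own child RNG stream spawned from the run seed, so
trains are independent across units yet bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class PoissonSourceConfig:
    """Configuration of one Poisson source population (per-unit rates)."""

    rates: np.ndarray            # Hz, one per unit (scalar broadcast ok)
    dt: float = 1.0              # ms
    regime_threshold: float = 1.0   # expected spikes per Δt separating regimes
    isi_family: str = "geometric"   # slow-regime ISI: geometric | exponential

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")
        if self.isi_family not in ("geometric", "exponential"):
            raise ValueError("isi_family must be geometric or exponential")

    def regimes(self) -> np.ndarray:
        """Boolean per unit: True where the fast regime applies
        (expected spikes per timestep above the threshold)."""
        return self.rates * self.dt * 1e-3 > self.regime_threshold


class PoissonSource:
    """Stateful Poisson spike generator for one source vertex."""

    def __init__(self, config: PoissonSourceConfig,
                 seed_seq: np.random.SeedSequence,
                 cache_matrix_hint: bool = False):
        self.config = config
        n = len(config.rates)
        # one child stream per unit: independence across units by construction
        self.rngs = [np.random.default_rng(s) for s in seed_seq.spawn(n)]
        self.fast = config.regimes()
        self.lam = config.rates * config.dt * 1e-3   # expected spikes / step
        self.countdown = np.zeros(n, dtype=np.int64)
        # DTCM-caching of matrices for fast sources is a functional no-op;
        # the flag is retained for cost accounting.
        self.cache_matrix_hint = cache_matrix_hint
        for i in range(n):
            if not self.fast[i] and config.rates[i] > 0:
                self.countdown[i] = self._draw_isi(i)

    def _draw_isi(self, unit: int) -> int:
        """Slow-regime inter-spike interval in whole timesteps (≥ 1).

        geometric: per-step hazard ``min(rate·Δt, 1)`` — exact mean rate.
        exponential: continuous draw rounded to the grid — slightly slow
        near the regime boundary (documented approximation).
        """
        if self.config.isi_family == "geometric":
            p = min(1.0, self.lam[unit])
            return int(self.rngs[unit].geometric(p))
        isi_ms = self.rngs[unit].exponential(1000.0 / self.config.rates[unit])
        return max(1, int(round(isi_ms / self.config.dt)))

    def step(self) -> np.ndarray:
        """Advance one timestep; returns the spike count per unit."""
        counts = np.zeros(len(self.lam), dtype=np.int64)
        for i, rng in enumerate(self.rngs):
            if self.config.rates[i] == 0:
                continue
            if self.fast[i]:
                counts[i] = rng.poisson(self.lam[i])
            else:
                self.countdown[i] -= 1
                if self.countdown[i] <= 0:
                    counts[i] = 1
                    self.countdown[i] = self._draw_isi(i)
        return counts


def poisson_slow_step(source: PoissonSource) -> np.ndarray:
    """Single slow-regime step (ISI countdown); see :meth:`PoissonSource.step`."""
    return source.step()


def poisson_fast_step(source: PoissonSource) -> np.ndarray:
    """Single fast-regime step (Poisson count); see :meth:`PoissonSource.step`."""
    return source.step()


# ---------------------------------------------------------------------------
# Spike-source array
# ---------------------------------------------------------------------------

@dataclass
class SpikeArraySchedule:
    """Per-unit sorted spike times (ms), quantised to the Δt grid."""

    spike_times: Sequence[Sequence[float]]
    dt: float = 1.0
    _steps: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._steps = []
        for unit, times in enumerate(self.spike_times):
            steps = np.rint(np.asarray(sorted(times), dtype=float)
                            / self.dt).astype(np.int64)
            unique = np.unique(steps)
            if len(unique) != len(steps):
                warnings.warn(
                    f"spike-source-array unit {unit}: duplicate spike times "
                    "after Δt quantisation collapsed", stacklevel=2)
            self._steps.append(unique)

    @property
    def n_units(self) -> int:
        return len(self._steps)

    def units_at(self, step: int) -> np.ndarray:
        """Unit ids emitting a spike at timestep ``step``."""
        return np.asarray([u for u, s in enumerate(self._steps)
                           if np.isin(step, s)], dtype=np.int64)


def array_step(schedule: SpikeArraySchedule, step: int) -> np.ndarray:
    """Spikes of a spike-source array at one timestep (unit ids)."""
    return schedule.units_at(step)


def schedule_from_csv(path, dt: float = 1.0) -> SpikeArraySchedule:
    """Load a spike-source-array schedule from CSV rows ``unit,time_ms``."""
    import csv

    per_unit: dict[int, list[float]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or row[0] == "unit":
                continue
            unit, t = int(row[0]), float(row[1])
            per_unit.setdefault(unit, []).append(t)
    n = max(per_unit, default=-1) + 1
    return SpikeArraySchedule([per_unit.get(i, []) for i in range(n)], dt=dt)
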