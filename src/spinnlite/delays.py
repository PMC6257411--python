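"""Delay-extension vertices for synaptic delays beyond 16 timesteps.

The synaptic row's 4-bit delay field and the 16-slot ring buffer cap
on-core delays at 16 Δt.  Longer delays are realised by routing the spike
through a *delay extension* vertex on an adjacent core: the spike is held
there for a whole number of 16-timestep *stages* and then re-emitted under
a stage-specific key; the residual delay (1–16 timesteps) is encoded in
the synaptic row reached through that key.  The postsynaptic core's master
population table therefore carries one entry for the direct path plus one
per delay stage, and an extended-delay spike costs two packets.

Supported total delays span 17–144 timesteps (8 stages of 16 plus a
16-step residual); the 144 ceiling is the platform's printed limit
(memory-constrained on the original hardware) and is enforced as stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: ring-buffer slot count = timesteps per delay stage
STAGE_SIZE = 16
#: maximum number of delay stages
MAX_STAGES = 8
#: largest supported end-to-end delay in timesteps
MAX_EXTENDED_DELAY = MAX_STAGES * STAGE_SIZE + STAGE_SIZE  # 144


def plan_delay(total_delay_ts: int) -> tuple[int, int]:
    """Split a total delay into (stages, residual).

    ``total = 16·stages + residual`` with residual in [1, 16]; stages = 0
    means the delay fits on-core and no extension vertex is needed.
    """
    if total_delay_ts < 1:
        raise ValueError("delay must be at least 1 timestep")
    if total_delay_ts > MAX_EXTENDED_DELAY:
        raise ValueError(
            f"delay {total_delay_ts} timesteps exceeds delay extension limit "
            f"of {MAX_EXTENDED_DELAY}")
    stages = (total_delay_ts - 1) // STAGE_SIZE
    residual = total_delay_ts - STAGE_SIZE * stages
    return stages, residual


@dataclass
class DelayStageConfig:
    """Preprocessed per-presynaptic-neuron delay staging for one vertex.

    ``stages_by_neuron`` maps each presynaptic local id to the distinct
    stage counts (≥ 1) its synapses need; each stage in use gets its own
    re-emission key block and its own row in the postsynaptic master
    population table.
    """

    source_size: int
    stages_by_neuron: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        for stages in self.stages_by_neuron.values():
            if any(not 1 <= s <= MAX_STAGES for s in stages):
                raise ValueError(f"stage counts must lie in [1, {MAX_STAGES}]")

    @property
    def stages_used(self) -> tuple[int, ...]:
        return tuple(sorted({s for stages in self.stages_by_neuron.values()
                             for s in stages}))

    def stages_for(self, local_id: int) -> tuple[int, ...]:
        return self.stages_by_neuron.get(local_id, ())


@dataclass
class DelayExtensionVertex:
    """Runtime state of a delay-extension core.

    A *spike counter* registers (receipt time, presynaptic neuron) for each
    incoming spike; the timer callback releases each registered spike
    exactly ``16·stage`` timesteps after receipt, re-emitted under the
    per-stage key ``stage_base_keys[stage] | local_id``.
    """

    config: DelayStageConfig
    stage_base_keys: dict[int, int]      # stage count -> base key
    # pending[(release_step)] -> list of (stage, local_id)
    pending: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def receive(self, local_id: int, step: int) -> None:
        """Register an incoming spike (receipt period ``step``): schedule one
        release per stage the source neuron participates in."""
        for stage in self.config.stages_for(local_id):
            release = step + STAGE_SIZE * stage
            self.pending.setdefault(release, []).append((stage, local_id))

    def step(self, step: int) -> list[int]:
        """Re-emit all spikes whose stage delay has elapsed at this period."""
        keys = []
        for stage, local_id in self.pending.pop(step, []):
            keys.append(self.stage_base_keys[stage] | local_id)
        return keys


def delay_vertex_step(vertex: DelayExtensionVertex, step: int) -> list[int]:
    """Functional alias for :meth:`DelayExtensionVertex.step`."""
    return vertex.step(step)
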