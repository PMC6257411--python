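# Methods

This note records the models spinnlite implements, the numerical
conventions it fixes where the emulated platform's behaviour is
under-specified, what the synthetic networks do and do not emulate, and
the known limitations.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Fixed-point conventions (`spinnlite.fxp`)

All on-core state is s16.15 ("accum"): a signed 32-bit integer worth
`raw / 2**15`, smallest positive value `2**-15 ≈ 3.05e-5`, largest
`65535.999969...`.  Addition/subtraction are exact in range and wrap in
two's complement beyond it (counted in diagnostics, never raised).
Multiplication computes `(a.raw * b.raw) >> 15` with **round-to-nearest,
ties away from zero** on the discarded bits; any product whose exact
magnitude is below `2**-15` underflows to zero.  Nearest rounding was
chosen over truncation because it keeps long integrations unbiased; its
one visible artifact is a decay stall: iterating `V ← A − λ(A − V)`
freezes once `λ·d` rounds back to `d`, i.e. within `0.5/(1−λ)` quanta of
the fixed point (≈10 quanta ≈ 0.3 mV for τ=20 ms, Δt=1 ms).  The test
suite asserts exactly this band.  The rounding mode of the original
hardware's multiply is not documented; ours is a documented choice, not a
claim of bit-parity.

Weights are encoded host-side as `round(w · 2**(15−shift))` (ties away
from zero — forced by the reference example `1.15·512 = 588.8 → 589`)
into unsigned 16-bit ring-buffer integers, and decoded by a left shift.
The global default `shift = 6`; an automatic rule (smallest shift giving
the largest configured weight ≥4 bits of accumulation headroom) applies
when the configuration does not fix one, and an explicit value always
wins.  Decay factors `e^(−Δt/τ)` are computed in double precision on the
host and quantised once.

## Synaptic structures (`spinnlite.synformat`)

Static word layout (32 bits): weight in bits 16–31, delay field in bits
9–12, synapse type in bit 8 (0 excitatory / 1 inhibitory), neuron id in
bits 0–7, padding in 13–15.  The 4-bit delay field stores `delay mod 16`;
since configured delays span [1, 16] on-core, a stored 0 means an
effective 16 and delay 0 is rejected at configuration time.  `decode`
returns the raw field (so the all-zero padding word decodes to zeroes and
is inert when processed).

Rows carry three header words (dynamic-plastic size, fixed-plastic
half-word count, static word count); a row is all-static or all-plastic;
plastic half-words pack two per 32-bit word with an empty half-slot for
odd target counts; rows are padded to the projection's maximum row
length.  Plastic regions are parsed and serialised but never interpreted
— plasticity rules are out of scope.  All dumps are little-endian with a
versioned header recording the shift.

Master-population-table entries are 12 bytes (key, mask, 16-bit start,
16-bit count), address-list entries 4 bytes (1 flag bit, 23-bit
word-aligned address, 8-bit row length) — the only packing consistent
with 84 bytes for 5 entries + 6 rows.  Keys are allocated per machine
vertex at the next power of two ≥ its size, mask = complement of the
neuron-id field; this guarantees non-overlapping masked spaces and makes
binary search valid (verified against a linear-scan oracle).

## Neuron models (`spinnlite.models`)

LIF uses exact exponential integration assuming the input current is
constant over the step; to keep per-spike charge equal to the exact
solution, weights are pre-multiplied host-side by
`(τ_syn/Δt)(1 − e^(−Δt/τ_syn))` (toggleable, default on, applied at
matrix-generation time).  Units: mV, nA, MΩ, µS, ms — chosen so
biological magnitudes sit comfortably inside the accum range.  The
refractory countdown is `floor(t_r/Δt)` whole timesteps, decremented
during the update; LIF threshold is strict (`V > V_θ`).

Izhikevich advances with the explicit RK-2 midpoint rule applied to
`dv/dt = 0.04v² + 5v + 140 − u + I`, `du/dt = a(bv − u)`, with
`θ = 140 + I − u` evaluated once per stage.  The cutoff `v ≥ V_θ` is
tested on the entry state: a state at/above cutoff is reset
(`v ← c`, `u ← u + d` exactly) instead of integrated.  Three rate
constants (0.04, `b`, `a·h`) are held as pre-scaled constants with 20
fractional bits: at s16.15 the quantisation of 0.04 alone shifts `dv/dt`
by ~0.04 at v = −65, which would swamp the integrator's own error.  The
operation ordering documented here is this package's; no claim of
bit-parity with any compiled original is made.

Oracle tracking is regime-dependent, and the tests state it that way:
the fixed-point spike **count** over 1000 steps matches the
double-precision midpoint oracle at every tested drive, but **spike
times within ±1 step** hold only for strongly-driven regular spiking
(I ≥ 15 with the standard a=0.02, b=0.2, c=−65, d=8 set).  At slow-ramp
drives the discretised system is phase-sensitive: the recovery-variable
kick acquired during the overshoot step depends discontinuously on the
crossing phase, so nearby trajectories diverge exponentially (~×2 per
spike) and no fixed-point state width can stay within one step over that
horizon.  This is a property of the discretised model, not an
implementation defect.

The `additional_input` component (intrinsic currents with a
notify-on-spike hook) ships as an interface with a null implementation.

## Runtime semantics (`spinnlite.runtime`)

Cores are logical processes on one global loop with deterministic
ordering (time, then core index, then phase: timers → delivery/pipeline →
ring-pointer advance).  Hardware asynchrony and clock drift are
deliberately absent — determinism is a feature.  A spike emitted in
period `t` with delay `d` is injected at slot `(ptr + d) mod 16` and
consumed at period `t + d`; delay 1 is the minimum ("pointer + delay",
minimum transit of one Δt), delay 16 lands on the slot just consumed.
Ring slots saturate at 65535 (never wrap) and a conservation ledger
(injected = consumed + saturation losses + buffered) is checked in tests.
Because the functional pipeline drains once per period, the 256-entry
input-buffer cap applies to one period's arrivals; the within-period
interleaving of callbacks (priorities −1…2, preemption, queue length 15,
user-event raising only when the pipeline is idle) is replayed by the
instrumented `CallbackEngine`, which tests use to verify the preemption
scenarios and overrun detection.

"Realtime" is reinterpreted as the budget check *virtual cost ≤ t_p*:
accounting mode prices each period's callbacks with the cost-model
coefficients and counts overruns (never fatal).  Throughput measurement
(`empirical_max_events`) feeds spikes through a real ring buffer with a
word-granular virtual clock in which a row's fixed overhead is amortised
uniformly over its words; a row cut off by the period boundary therefore
contributes exactly the words it processed.  This granularity choice is
what makes the measurement commensurable with the analytic model to ±1
event; per-spike (non-amortised) charging would differ by up to
`c_ss·nP/(m_ss·nP + c_ss)` events at the boundary.

DMA latency is zero in functional mode and a cost term only in
accounting mode.  Delay-extension vertices hold spikes for
`16·stages` periods and re-emit under per-stage keys; residual delays
live in the stage's synaptic rows; the supported range is 17–144 (8
stages + 16 residual, the platform's printed ceiling, enforced at build
time), and an extended spike costs two packets.

## Synthetic networks (`spinnlite.netapi`)

The balanced fixture is 500 excitatory + 125 inhibitory current-based
LIF neurons (τ_m 20 ms, R_m 20 MΩ, E_l = V_reset = −65 mV, V_θ = −50 mV,
t_r 5 ms), 20% connection probability throughout, excitatory weights
0.06 nA, 250 Poisson units at 50 Hz into the excitatory population, a
25-unit spike-source array firing once at t = 1 s (weight 0.5 nA,
p = 0.5), uniform delays 1–14 ms, excitatory membranes initialised
uniformly between reset and threshold.  Constants the reference
description leaves open (inhibitory weight 0.8 nA, τ_syn 5 ms, the
stimulus pattern) are this package's choices, made once to yield a
stable, sustained asynchronous regime (~20 Hz excitatory) with a visible
stimulus response; comparisons against the original hardware raster are
qualitative only.  What passing fixture tests show: lossless routing,
exact delay semantics, fixed-point stability and reproducibility at
desk scale — not quantitative agreement with any hardware run, whose
oscillation frequency and rates depend on the unpublished constants.

Poisson sources: the slow regime (expected ≤1 spike per step) draws ISIs
in whole timesteps; the default family is geometric with per-step hazard
`rate·Δt`, which keeps the mean rate exact for every sub-boundary rate
and agrees with the fast regime (per-step Poisson counts) at the
boundary.  The rounded-exponential family is retained as an option; it
under-produces by ~26% at the boundary and is therefore not the default.
Each unit has its own child RNG stream spawned from the run seed.

## Problem sizes

Test and acceptance workloads are sized for a single-CPU desk run: the
fixture runs 5 s of model time (~15 s wall), the delay sweep covers all
144 configured delays with one-synapse networks, the throughput grid
spans n ∈ {16…512} × P ∈ {0.05…1}, and source statistics use 200 seeded
2 s runs.  These sizes are the package's own choices for its reference
suite.

## Known limitations

* No hardware timing: DMA/SDRAM contention, router silicon, multi-chip
  links, clock drift and energy are not modelled; cost accounting is at
  callback granularity with profiled coefficients taken as given.
* Plasticity rule evaluation, routing-table compression, host streaming
  of recordings, and placement onto chip geometry are out of scope.
* The partitioner's resource model is neuron-count only; DTCM footprints
  are reported, not enforced.
* Functional-mode pipelines drain once per period (see above), so
  sustained >256-spikes-per-period loads drop differently than a real
  continuously-draining pipeline would.
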