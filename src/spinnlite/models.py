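"""Component-structured neuron and synapse models on s16.15 state.

A neuron application is assembled from five components, mirroring the
modular C framework of the emulated platform:

* ``synapse_type`` — per-receptor exponential current shaping, fed from the
  ring buffers once per timestep,
* ``input_type``  — current- or conductance-based conversion of synaptic
  state into neuron input current,
* ``neuron_model`` — sub-threshold update and refractory dynamics (LIF via
  exact exponential integration; Izhikevich via an RK-2 midpoint step),
* ``threshold_type`` — static threshold comparison,
* ``additional_input`` — hook for intrinsic currents (null implementation
  shipped; the interface exists for extension).

All state is held as int64 numpy arrays of raw s16.15 values so a whole
sub-population advances per timer period with vectorised fixed-point
arithmetic.  Units: membrane potentials in mV, currents in nA, resistances
in MΩ (so R_m·I is mV), conductance weights in µS — chosen to keep
biological magnitudes inside the accum range.

LIF sub-threshold dynamics (exact integration, assuming the input current
is constant over the step)::

    V_{t+1} = A - e^{-Δt/τ_m} (A - V_t),   A = E_l + R_m I_{t+Δt}

with V -> V_reset and a refractory countdown of t_r timesteps when
V > V_θ.  Synaptic currents decay exponentially between spikes with a step
change on arrival::

    I_{t+1} = I_t e^{-Δt/τ_syn} + Σ_j w_ij δ(t - t_j)

To keep the total charge injected per spike equal to that of the exact
solution, weights are pre-multiplied on the host by
``(τ_syn/Δt)(1 - e^{-Δt/τ_syn})`` (toggleable, default on).

The Izhikevich model ``dv/dt = 0.04v² + 5v + 140 - u + I``,
``du/dt = a(bv - u)`` is advanced with the explicit RK-2 midpoint rule,
with reset ``v <- c, u <- u + d`` when ``v ≥ V_θ``.  The fixed-point
operation ordering is the straightforward midpoint evaluation documented
here; bit-parity with any particular compiled binary is not claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import fxp
from .fxp import (ACCUM_ONE, Accum, _wrap32, add_raw, array_to_raw, mul_raw,
                  precompute_decay, sub_raw, to_raw)

EXC = 0
INH = 1
RECEPTOR_NAMES = ("excitatory", "inhibitory")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class LifParams:
    """Current-based leaky integrate-and-fire parameters.

    ``r_m`` is in MΩ-equivalents so that ``r_m * I[nA]`` is mV.  ``t_r`` is
    the refractory period in ms; it is floored to whole timesteps at
    compile time.
    """

    tau_m: float = 20.0      # membrane time constant, ms
    r_m: float = 20.0        # membrane resistance, MΩ
    e_l: float = -65.0       # resting potential, mV
    v_theta: float = -50.0   # threshold, mV
    v_reset: float = -65.0   # reset potential, mV
    t_r: float = 5.0         # refractory period, ms
    i_offset: float = 0.0    # background current, nA

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_reset > self.v_theta:
            raise ValueError("v_reset must not exceed v_theta")
        if self.t_r < 0:
            raise ValueError("t_r must be non-negative")


@dataclass
class IzhParams:
    """Izhikevich model constants (dimensionless a, b, c, d; v/u in the
    model's native mV-like scale).  ``h`` is the integration step = Δt."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_theta: float = 30.0    # firing cutoff
    i_offset: float = 0.0

    def __post_init__(self) -> None:
        pass


# ---------------------------------------------------------------------------
# Synapse state (per receptor exponential shaping)
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    """Per-neuron, per-receptor synaptic input state ``I_syn`` with its
    precomputed decay factor ``e^{-Δt/τ_syn}`` (one value per receptor)."""

    n: int
    tau_syn: tuple[float, ...] = (5.0, 5.0)
    dt: float = 1.0
    i_raw: np.ndarray = field(init=False)        # [receptor, neuron]
    decay_raw: np.ndarray = field(init=False)    # [receptor]

    def __post_init__(self) -> None:
        decays = [precompute_decay(tau, self.dt).raw for tau in self.tau_syn]
        if any(not 0 < d < fxp.SCALE for d in decays):
            raise ValueError("synaptic decay must satisfy 0 < decay < 1")
        self.decay_raw = np.asarray(decays, dtype=np.int64)
        self.i_raw = np.zeros((len(self.tau_syn), self.n), dtype=np.int64)

    @property
    def n_receptors(self) -> int:
        return len(self.tau_syn)

    def decay_and_consume(self, ring_input_raw: np.ndarray) -> None:
        """Advance one timestep: ``I <- I·decay + ring_input`` per receptor.

        ``ring_input_raw`` is the decoded (accum raw) content of the current
        timestep's ring-buffer slot, shape [receptor, neuron].  The caller
        guarantees the interrupt-masking contract: no spike-processing
        callback mutates the consumed slot while this runs.
        """
        self.i_raw = add_raw(mul_raw(self.i_raw, self.decay_raw[:, None]),
                             ring_input_raw)


def synapse_decay_and_consume(state: SynapseState,
                              ring_input_raw: np.ndarray) -> SynapseState:
    """Functional wrapper over :meth:`SynapseState.decay_and_consume`."""
    state.decay_and_consume(ring_input_raw)
    return state


def charge_compensation(tau_syn: float, dt: float) -> float:
    """Host-side weight pre-decay factor ``(τ/Δt)(1 - e^{-Δt/τ})``.

    Compensates the constant-current-over-step assumption of the exponential
    membrane update so the charge delivered per spike matches the exact
    continuous solution.  Applied at synaptic-matrix generation time.
    """
    return tau_syn / dt * (1.0 - math.exp(-dt / tau_syn))


# ---------------------------------------------------------------------------
# Input types
# ---------------------------------------------------------------------------

@dataclass
class CurrentInput:
    """Current-based input: synaptic state is already a current (identity)."""

    kind: str = "current"

    def convert(self, i_syn_raw: np.ndarray, v_raw: np.ndarray) -> np.ndarray:
        return i_syn_raw


@dataclass
class ConductanceInput:
    """Conductance-based input: ``I = g (E_rev - V)`` per receptor."""

    e_rev: tuple[float, ...]      # reversal potential per receptor, mV
    kind: str = "conductance"

    def convert(self, g_raw: np.ndarray, v_raw: np.ndarray) -> np.ndarray:
        e_rev_raw = array_to_raw(self.e_rev)[:, None]
        return mul_raw(g_raw, sub_raw(e_rev_raw, v_raw[None, :]))


def input_type_convert(i_syn_raw: np.ndarray, v_raw: np.ndarray,
                       kind: str = "current",
                       e_rev: tuple[float, ...] | None = None) -> np.ndarray:
    """Convert synaptic state into input current per receptor."""
    if kind == "current":
        return CurrentInput().convert(i_syn_raw, v_raw)
    if kind == "conductance":
        if e_rev is None:
            raise ValueError(
                "conductance-based input requires a reversal potential per "
                "receptor (configuration error)")
        return ConductanceInput(e_rev=e_rev).convert(i_syn_raw, v_raw)
    raise ValueError(f"unknown input type {kind!r}")


# ---------------------------------------------------------------------------
# Threshold
# ---------------------------------------------------------------------------

def threshold_static(v_raw, v_theta_raw, strict: bool = True):
    """Static threshold comparison on raw values.

    LIF fires on the strict ``V > V_θ``; the Izhikevich reset uses the
    non-strict ``v ≥ V_θ`` (``strict=False``).
    """
    v = np.asarray(v_raw)
    return v > v_theta_raw if strict else v >= v_theta_raw


# ---------------------------------------------------------------------------
# Additional-input hook (null implementation)
# ---------------------------------------------------------------------------

class NullAdditionalInput:
    """Intrinsic-current interface: per-step update plus notify-on-spike.

    The shipped implementation contributes nothing; the hooks are the
    extension point for voltage-dependent intrinsic currents.
    """

    def update(self, v_raw: np.ndarray) -> np.ndarray:
        return np.zeros_like(v_raw)

    def notify_spike(self, fired: np.ndarray) -> None:
        return None


# ---------------------------------------------------------------------------
# LIF neuron
# ---------------------------------------------------------------------------

@dataclass
class LifState:
    """Membrane potential (raw accum) plus refractory countdown per neuron."""

    v_raw: np.ndarray
    refractory: np.ndarray       # timesteps remaining, int64

    @classmethod
    def zeros(cls, n: int, v_init: float) -> "LifState":
        return cls(np.full(n, to_raw(v_init), dtype=np.int64),
                   np.zeros(n, dtype=np.int64))


class LifFixed:
    """LIF parameters compiled to raw fixed-point constants for a given Δt."""

    def __init__(self, params: LifParams, dt: float):
        self.params = params
        self.dt = dt
        self.decay_raw = precompute_decay(params.tau_m, dt).raw
        self.e_l_raw = to_raw(params.e_l)
        self.v_theta_raw = to_raw(params.v_theta)
        self.v_reset_raw = to_raw(params.v_reset)
        self.r_m_raw = to_raw(params.r_m)
        self.i_offset_raw = to_raw(params.i_offset)
        self.t_r_steps = int(params.t_r / dt)     # floor to whole timesteps


def lif_update(state: LifState, fixed: LifFixed,
               i_total_raw: np.ndarray) -> np.ndarray:
    """Advance all LIF neurons one timestep; returns the fired mask.

    Refractory neurons only decrement their countdown.  Non-refractory
    neurons apply the exponential-integration update and the strict
    threshold test; firing neurons reset and start the countdown.
    """
    refractory = state.refractory > 0
    state.refractory[refractory] -= 1
    active = ~refractory

    a_raw = add_raw(fixed.e_l_raw, mul_raw(fixed.r_m_raw, i_total_raw))
    v_new = sub_raw(a_raw, mul_raw(fixed.decay_raw, sub_raw(a_raw, state.v_raw)))
    state.v_raw = np.where(active, v_new, state.v_raw)

    fired = active & threshold_static(state.v_raw, fixed.v_theta_raw, strict=True)
    state.v_raw[fired] = fixed.v_reset_raw
    state.refractory[fired] = fixed.t_r_steps
    return fired


def lif_update_float(v: float, params: LifParams, i_total: float,
                     dt: float) -> float:
    """Double-precision reference of the sub-threshold LIF update (oracle)."""
    a = params.e_l + params.r_m * i_total
    return a - math.exp(-dt / params.tau_m) * (a - v)


# ---------------------------------------------------------------------------
# Izhikevich neuron (RK-2 midpoint)
# ---------------------------------------------------------------------------

@dataclass
class IzhState:
    v_raw: np.ndarray
    u_raw: np.ndarray

    @classmethod
    def init(cls, n: int, v: float, u: float) -> "IzhState":
        return cls(np.full(n, to_raw(v), dtype=np.int64),
                   np.full(n, to_raw(u), dtype=np.int64))


class IzhFixed:
    def __init__(self, params: IzhParams, dt: float):
        if dt <= 0:
            raise ValueError("h (= dt) must be positive")
        self.params = params
        self.h = dt
        self.a_raw = to_raw(params.a)
        self.b_raw = to_raw(params.b)
        self.c_raw = to_raw(params.c)
        self.d_raw = to_raw(params.d)
        self.v_theta_raw = to_raw(params.v_theta)
        self.i_offset_raw = to_raw(params.i_offset)
        self.h_raw = to_raw(dt)
        self.h_half_raw = to_raw(dt / 2.0)
        # small rate constants are held pre-scaled at 20 fractional bits:
        # at s16.15 the quadratic coefficient alone would move dv/dt by
        # ~0.04 at v = -65, and the ~5e-4 relative error in a and b
        # accumulates into multi-step spike-phase drift over long runs
        self.k004_hp = round(0.04 * (1 << 20))
        self.b_hp = round(params.b * (1 << 20))
        self.ah_hp = round(params.a * dt * (1 << 20))
        self.ah_half_hp = round(params.a * dt / 2.0 * (1 << 20))
        self.k5_raw = to_raw(5.0)
        self.k140_raw = to_raw(140.0)


def _mul_hp(x_raw, c_hp: int, frac_bits: int = 20):
    """Multiply an s16.15 raw by a pre-scaled higher-precision constant
    (``c_hp = round(c * 2**frac_bits)``), rounding back to the accum grid."""
    prod = np.asarray(x_raw, dtype=np.int64) * c_hp
    mag = np.abs(prod)
    q = (mag + (1 << (frac_bits - 1))) >> frac_bits
    return _wrap32(np.where(prod >= 0, q, -q))


def _izh_dv(fix: IzhFixed, v_raw, theta_raw):
    # 0.04 v^2 + 5 v + theta, with theta = 140 + I - u computed once
    v2 = mul_raw(v_raw, v_raw)
    return add_raw(add_raw(_mul_hp(v2, fix.k004_hp),
                           mul_raw(fix.k5_raw, v_raw)), theta_raw)


def _izh_recovery_drive(fix: IzhFixed, v_raw, u_raw):
    # b v - u  (the a and h factors fold into one pre-scaled constant)
    return sub_raw(_mul_hp(v_raw, fix.b_hp), u_raw)


def izh_update_rk2(state: IzhState, fixed: IzhFixed,
                   i_total_raw: np.ndarray) -> np.ndarray:
    """One explicit RK-2 midpoint step of the Izhikevich system, fixed point.

    The non-strict cutoff ``v ≥ V_θ`` is tested on the entry state: a state
    at or above cutoff is reset (``v <- c``, ``u <- u + d`` — u grows by
    exactly d) instead of being integrated, so a spike is registered on the
    step after the crossing.  Sub-cutoff states take one midpoint step with
    θ = 140 + I - u evaluated once per stage.  Returns the fired mask.
    """
    v, u = state.v_raw, state.u_raw
    fired = threshold_static(v, fixed.v_theta_raw, strict=False)

    theta = add_raw(fixed.k140_raw, sub_raw(i_total_raw, u))
    dv = _izh_dv(fixed, v, theta)
    v_mid = add_raw(v, mul_raw(fixed.h_half_raw, dv))
    u_mid = add_raw(u, _mul_hp(_izh_recovery_drive(fixed, v, u),
                               fixed.ah_half_hp))
    theta_mid = add_raw(fixed.k140_raw, sub_raw(i_total_raw, u_mid))
    v_new = add_raw(v, mul_raw(fixed.h_raw, _izh_dv(fixed, v_mid, theta_mid)))
    u_new = add_raw(u, _mul_hp(_izh_recovery_drive(fixed, v_mid, u_mid),
                               fixed.ah_hp))

    state.v_raw = np.where(fired, fixed.c_raw, v_new)
    state.u_raw = np.where(fired, add_raw(u, fixed.d_raw), u_new)
    return fired


def izh_update_float(v: float, u: float, params: IzhParams, i_total: float,
                     h: float) -> tuple[float, float, bool]:
    """Double-precision textbook RK-2 midpoint step of the Izhikevich system
    (the oracle against which the fixed-point path is validated).  Uses the
    same entry-state cutoff convention as :func:`izh_update_rk2`."""
    if v >= params.v_theta:
        return params.c, u + params.d, True

    def f(v_, u_):
        return 0.04 * v_ * v_ + 5.0 * v_ + 140.0 - u_ + i_total

    def g(v_, u_):
        return params.a * (params.b * v_ - u_)

    v_mid = v + h / 2.0 * f(v, u)
    u_mid = u + h / 2.0 * g(v, u)
    v_new = v + h * f(v_mid, u_mid)
    u_new = u + h * g(v_mid, u_mid)
    return v_new, u_new, False
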