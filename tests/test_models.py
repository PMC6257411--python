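"""Neuron and synapse dynamics on fixed-point state vs double oracles."""

import math

import numpy as np
import pytest

from spinnlite import fxp, models
from spinnlite.models import (EXC, INH, IzhFixed, IzhParams, IzhState,
                              LifFixed, LifParams, LifState, SynapseState,
                              input_type_convert, izh_update_float,
                              izh_update_rk2, lif_update, lif_update_float,
                              threshold_static)

#: maximum tolerated fixed-point drift of the LIF membrane over 1000 steps,
#: in mV; justified empirically (observed drift is well below this)
LIF_TRAJECTORY_TOL_MV = 0.05


def make_lif(n=1, **kw):
    params = LifParams(**kw)
    fixed = LifFixed(params, dt=1.0)
    state = LifState(np.full(n, fxp.to_raw(params.e_l), dtype=np.int64),
                     np.zeros(n, dtype=np.int64))
    return params, fixed, state


class TestLif:
    def test_resting_state_is_fixed_point(self):
        _, fixed, state = make_lif()
        fired = lif_update(state, fixed, np.zeros(1, dtype=np.int64))
        assert not fired.any()
        assert fxp.raw_to_float(state.v_raw)[0] == -65.0

    def test_single_step_against_closed_form(self):
        # V=-65, E_l=-65, R_m*I = 15 mV, tau_m=20: V -> -65 + 15(1-e^-1/20)
        params, fixed, state = make_lif(v_theta=0.0)
        i_raw = np.array([fxp.to_raw(0.75)], dtype=np.int64)
        lif_update(state, fixed, i_raw)
        expect = -65.0 + 15.0 * (1 - math.exp(-1 / 20.0))
        assert abs(fxp.raw_to_float(state.v_raw)[0] - expect) < 0.01

    def test_monotone_approach_to_steady_state(self):
        params, fixed, state = make_lif(v_theta=100.0)
        i_raw = np.array([fxp.to_raw(0.5)], dtype=np.int64)
        target = params.e_l + params.r_m * 0.5
        prev = -math.inf
        for _ in range(400):
            lif_update(state, fixed, i_raw)
            v = fxp.raw_to_float(state.v_raw)[0]
            assert v >= prev
            prev = v
        assert abs(prev - target) < 0.01

    def test_zero_input_decay_is_monotone(self):
        """With zero input and V > E_l the membrane decays monotonically
        toward rest.  Round-to-nearest decay admits a stall a few quanta
        above E_l (where decay*d rounds back to d, d < 0.5/(1-decay)); the
        trajectory must still be non-increasing and settle inside that
        band — about 0.3 mV here."""
        _, fixed, state = make_lif(v_theta=100.0)
        state.v_raw[:] = fxp.to_raw(-55.0)
        zeros = np.zeros(1, dtype=np.int64)
        decay = fixed.decay_raw / (1 << 15)
        stall_band = 0.5 / (1.0 - decay)
        prev = state.v_raw[0]
        for _ in range(2000):
            lif_update(state, fixed, zeros)
            v = state.v_raw[0]
            assert v <= prev
            if prev - fixed.e_l_raw > stall_band:
                assert v < prev
            prev = v
        assert prev - fixed.e_l_raw <= stall_band

    def test_trajectory_tracks_double_precision_oracle(self):
        """1000 driven steps: fixed-point membrane stays within the repo
        tolerance of the double-precision exponential-integration update."""
        params, fixed, state = make_lif(v_theta=100.0)  # no firing
        rng = np.random.default_rng(11)
        v_ref = params.e_l
        worst = 0.0
        for step in range(1000):
            i_na = float(rng.uniform(0.0, 0.6))
            i_raw = np.array([fxp.to_raw(i_na)], dtype=np.int64)
            # the core sees the quantised current, the oracle the same value
            i_seen = fxp.raw_to_float(i_raw)[0]
            lif_update(state, fixed, i_raw)
            v_ref = lif_update_float(v_ref, params, i_seen, dt=1.0)
            worst = max(worst, abs(fxp.raw_to_float(state.v_raw)[0] - v_ref))
        assert worst <= LIF_TRAJECTORY_TOL_MV

    def test_held_above_threshold_fires_every_third_period(self):
        # drive strong enough to cross threshold in one step from reset;
        # with t_r = 2 the neuron fires every 3rd period
        params, fixed, state = make_lif(v_theta=-50.0, t_r=2.0)
        i_raw = np.array([fxp.to_raw(20.0)], dtype=np.int64)
        spikes = [i for i in range(12) if lif_update(state, fixed, i_raw)[0]]
        assert spikes == [0, 3, 6, 9]

    def test_refractory_emits_no_spikes_for_exactly_t_r(self):
        params, fixed, state = make_lif(t_r=5.0)
        i_raw = np.array([fxp.to_raw(20.0)], dtype=np.int64)
        spikes = [i for i in range(30)
                  if lif_update(state, fixed, i_raw)[0]]
        gaps = np.diff(spikes)
        assert (gaps == 6).all()       # t_r silent periods + firing period


class TestSynapseState:
    def test_zero_stays_zero(self):
        syn = SynapseState(1)
        syn.decay_and_consume(np.zeros((2, 1), dtype=np.int64))
        assert (syn.i_raw == 0).all()

    def test_step_change_on_arrival(self):
        syn = SynapseState(1, tau_syn=(5.0, 5.0), dt=1.0)
        inject = np.zeros((2, 1), dtype=np.int64)
        inject[EXC, 0] = fxp.to_raw(1.150390625)
        syn.decay_and_consume(inject)
        assert fxp.raw_to_float(syn.i_raw[EXC])[0] == 1.150390625

    def test_five_decay_steps_reach_e_minus_one(self):
        syn = SynapseState(1, tau_syn=(5.0, 5.0), dt=1.0)
        syn.i_raw[EXC, 0] = fxp.to_raw(1.0)
        zeros = np.zeros((2, 1), dtype=np.int64)
        for _ in range(5):
            syn.decay_and_consume(zeros)
        assert fxp.raw_to_float(syn.i_raw[EXC])[0] == pytest.approx(
            math.exp(-1.0), abs=1e-3)

    def test_charge_compensation_factor(self):
        factor = models.charge_compensation(5.0, 1.0)
        assert factor == pytest.approx(5.0 * (1 - math.exp(-0.2)))
        assert 0 < factor < 1


class TestInputType:
    def test_current_identity(self):
        i = np.array([[fxp.to_raw(0.7)], [0]], dtype=np.int64)
        out = input_type_convert(i, np.zeros(1, dtype=np.int64), "current")
        assert (out == i).all()

    def test_conductance_zero_driving_force(self):
        g = np.array([[fxp.to_raw(0.5)], [0]], dtype=np.int64)
        v = np.array([fxp.to_raw(-70.0)], dtype=np.int64)
        out = input_type_convert(g, v, "conductance", e_rev=(-70.0, -70.0))
        assert (out == 0).all()

    def test_conductance_product(self):
        # g=0.5 µS, E_rev=0, V=-70 mV -> 35 nA-equivalent
        g = np.array([[fxp.to_raw(0.5)], [0]], dtype=np.int64)
        v = np.array([fxp.to_raw(-70.0)], dtype=np.int64)
        out = input_type_convert(g, v, "conductance", e_rev=(0.0, 0.0))
        assert fxp.raw_to_float(out[EXC])[0] == pytest.approx(35.0, abs=1e-3)

    def test_missing_reversal_potential_is_config_error(self):
        with pytest.raises(ValueError, match="reversal potential"):
            input_type_convert(np.zeros((2, 1), dtype=np.int64),
                               np.zeros(1, dtype=np.int64), "conductance")


class TestThreshold:
    def test_lif_strict_at_threshold(self):
        theta = fxp.to_raw(-50.0)
        assert not threshold_static(theta, theta, strict=True)
        assert threshold_static(theta + 1, theta, strict=True)

    def test_izh_non_strict_at_cutoff(self):
        theta = fxp.to_raw(30.0)
        assert threshold_static(theta, theta, strict=False)


class TestIzhikevich:
    def make(self, v=-65.0, u=-13.0, **kw):
        params = IzhParams(**kw)
        fixed = IzhFixed(params, dt=1.0)
        state = IzhState.init(1, v, u)
        return params, fixed, state

    def test_equilibrium_state_unchanged(self):
        # at v=-65, u=-13: dv/dt = 0 requires I = 3; du/dt = 0 since u = b*v*...
        # (a(bv-u)=0.02(-13+13)=0)
        params, fixed, state = self.make()
        i_raw = np.array([fxp.to_raw(3.0)], dtype=np.int64)
        izh_update_rk2(state, fixed, i_raw)
        assert abs(fxp.raw_to_float(state.v_raw)[0] + 65.0) < 0.005
        assert abs(fxp.raw_to_float(state.u_raw)[0] + 13.0) < 0.005

    def test_single_step_matches_midpoint_oracle(self):
        params, fixed, state = self.make()
        i_raw = np.array([fxp.to_raw(10.0)], dtype=np.int64)
        izh_update_rk2(state, fixed, i_raw)
        v_ref, u_ref, fired = izh_update_float(-65.0, -13.0, params, 10.0, 1.0)
        assert not fired
        assert abs(fxp.raw_to_float(state.v_raw)[0] - v_ref) <= 2.0 ** -9
        assert abs(fxp.raw_to_float(state.u_raw)[0] - u_ref) <= 2.0 ** -9

    def test_reset_applies_exactly_c_and_d(self):
        params, fixed, state = self.make(v=40.0, u=-13.0)
        fired = izh_update_rk2(state, fixed, np.zeros(1, dtype=np.int64))
        assert fired.all()
        assert fxp.raw_to_float(state.v_raw)[0] == params.c
        assert fxp.raw_to_float(state.u_raw)[0] == pytest.approx(
            -13.0 + params.d, abs=1e-4)

    def run_both(self, i_const: float, n_steps: int = 1000):
        params, fixed, state = self.make()
        i_raw = np.array([fxp.to_raw(i_const)], dtype=np.int64)
        fp_spikes, oracle_spikes = [], []
        v, u = -65.0, -13.0
        for step in range(n_steps):
            if izh_update_rk2(state, fixed, i_raw)[0]:
                fp_spikes.append(step)
            v, u, fired = izh_update_float(v, u, params, i_const, 1.0)
            if fired:
                oracle_spikes.append(step)
        return np.asarray(fp_spikes), np.asarray(oracle_spikes)

    @pytest.mark.parametrize("i_const", [6.0, 10.0, 15.0, 20.0])
    def test_spike_count_matches_oracle_over_1000_steps(self, i_const):
        """The spike count over 1000 regular-spiking steps equals the
        double-precision midpoint oracle's at every tested drive."""
        fp, oracle = self.run_both(i_const)
        assert len(fp) > 5
        assert len(fp) == len(oracle)

    def test_spike_times_track_oracle_in_driven_regime(self):
        """Spike times within ±1 step of the oracle over 1000 steps.

        Checked in a strongly-driven regime (I = 15): there the reset
        overshoot is consistent between crossings and quantisation noise
        stays bounded.  In slow-ramp regimes the discretised map amplifies
        state-precision noise exponentially (the recovery-variable kick at
        reset depends discontinuously on crossing phase), so ±1 tracking
        over this horizon is not attainable there for any fixed-point
        state width — only the count is robust (previous test).
        """
        fp, oracle = self.run_both(15.0)
        assert len(fp) == len(oracle) > 20
        assert np.max(np.abs(fp - oracle)) <= 1
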