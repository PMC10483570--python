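"""Unit tests for the nine step kernels: frozen single-step arithmetic,
threshold/reset semantics, parameter validation and the stated dynamical
invariants (fixed points, gating bounds, refractory separation)."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikebench as sb
from spikebench.models import (AdExParams, IzhParams, NeuronState, NLIFParams,
                               SimulationGrid, adex_step, hh_step, ifsfa_step,
                               izh_step, lif_step, nlif_step, qif_step,
                               srm_step, theta_step)

G = SimulationGrid(dt=0.1)


class TestSingleStepArithmetic:
    """Frozen single-step values, computed independently by hand."""

    def test_lif_rest_is_fixed_point(self, bench_models):
        m = bench_models["LIF"]
        state, spiked = m.step(NeuronState(V=0.0), 0.0, G)
        assert state.V == 0.0 and not spiked

    def test_lif_subthreshold_decay(self, bench_models):
        m = bench_models["LIF"]
        state, spiked = m.step(NeuronState(V=0.5), 0.0, G)
        assert state.V == pytest.approx(0.4875, abs=1e-15)
        assert not spiked

    def test_lif_spike_and_reset(self, bench_models):
        # candidate 0.99 + (-0.99 + 10)/4 * 0.1 = 1.21525 >= 1 -> spike
        m = bench_models["LIF"]
        state, spiked = m.step(NeuronState(V=0.99), 10.0, G)
        assert spiked and state.V == 0.0

    def test_nlif_spike_applies_alpha_map(self):
        # post-step potential 2.0 with V_th=1, alpha=0.5 -> V' = 0 + 0.5*(2-1)
        p = NLIFParams(tau=4.0, V_th=1.0, V_reset=0.0, V_init=0.0,
                       alpha=0.5, beta=0.5)
        g1 = SimulationGrid(dt=1e-12)  # negligible integration, isolates the map
        state, spiked = nlif_step(NeuronState(V=2.0), 0.0, g1, p, "A")
        assert spiked and state.V == pytest.approx(0.5, abs=1e-9)

    def test_nlif_subthreshold_beta_leak(self):
        p = NLIFParams(tau=4.0, V_th=1.0, V_reset=0.0, V_init=0.0,
                       alpha=0.5, beta=0.5)
        g1 = SimulationGrid(dt=1e-12)
        state, spiked = nlif_step(NeuronState(V=0.5), 0.0, g1, p, "A")
        assert not spiked and state.V == pytest.approx(0.25, abs=1e-9)

    def test_adex_at_boundary_decays_without_spike(self):
        # dV/dt = (-1 + 0 - 0.5 + 1)/4 = -0.125 -> V' = 0.9875, no spike
        p = AdExParams(tau_m=4.0, V_reset=0.1, V_init=0.1, V_rheo=0.5,
                       Delta_T=1.0, V_spike=1.0)
        state, spiked = adex_step(NeuronState(V=1.0), 0.0, G, p, "A")
        assert state.V == pytest.approx(0.9875, abs=1e-15)
        assert not spiked

    def test_adex_strong_drive_spikes_within_window(self):
        p = AdExParams(tau_m=4.0, V_reset=0.1, V_init=0.1, V_rheo=0.5,
                       Delta_T=1.0, V_spike=1.0)
        state = NeuronState(V=0.1)
        spiked = False
        for _ in range(100):
            state, spiked = adex_step(state, 10.0, G, p, "A")
            if spiked:
                break
        assert spiked

    def test_ifsfa_rest_is_joint_fixed_point(self, bench_models):
        m = bench_models["IFSFA"]
        state, spiked = m.step(NeuronState(V=m.params.V_rest, w=0.0), 0.0, G)
        assert state.V == m.params.V_rest and state.w == 0.0 and not spiked

    def test_ifsfa_post_spike_adaptation_increment(self, bench_models):
        m = bench_models["IFSFA"]
        # force a spike with a huge current; w jumps by b on the spike step
        state, spiked = m.step(NeuronState(V=0.9, w=0.2), 1000.0, G)
        assert spiked
        w_pre = 0.2 + (m.params.A * (0.9 - m.params.V_rest) - 0.2) / m.params.tau_w * 0.1
        assert state.w == pytest.approx(w_pre + m.params.b, abs=1e-15)

    def test_ifsfa_variant_b_floor_at_rest(self, trace_models):
        m = trace_models["IFSFA"]
        state, _ = m.step(NeuronState(V=m.params.V_r - 30.0, w=500.0), 0.0,
                          SimulationGrid(dt=m.dt))
        assert state.V >= m.params.V_r

    def test_theta_sinusoid_peaks_at_quarter_phase(self):
        # phi = pi/2, t = 0: the sinusoidal current equals its amplitude
        m = sb.make_model("ThetaNeuron", "A",
                          {"tau_m": 4.0, "V_th": 1.0, "V_reset": 0.0,
                           "V_init": 0.0, "I_theta_max": 2.0, "f_theta": 1.0,
                           "phi": math.pi / 2})
        state, _ = theta_step(NeuronState(V=0.0), 0.0, G, m.params, "A", t=0.0)
        assert state.V == pytest.approx((0.0 + 2.0) / 4.0 * 0.1, abs=1e-15)

    def test_theta_variant_b_fixed_point(self, trace_models):
        # V* = (V_r + g*theta)/(1 + g) = (-70 + 1.5*(-50))/2.5 = -58
        m = trace_models["ThetaNeuron"]
        p = m.params
        v_star = (p.V_r + p.g * p.theta) / (1.0 + p.g)
        assert v_star == pytest.approx(-58.0)
        state = NeuronState(V=-70.0)
        g = SimulationGrid(dt=m.dt)
        for _ in range(5000):
            state, _ = m.step(state, 0.0, g)
        assert state.V == pytest.approx(v_star, abs=1e-9)

    def test_izh_constant_term_forces_immediate_spike(self, bench_models):
        # dv/dt ~ 140 at v=u=0 -> v' = 14 >= 0.8 -> spike, reset to c, u += d
        m = bench_models["Izhikevich"]
        state, spiked = izh_step(NeuronState(V=0.0, u=0.0), 0.0, G, m.params, "A")
        assert spiked
        assert state.V == pytest.approx(m.params.c)
        assert state.u == pytest.approx(m.params.d, abs=1e-15)

    def test_izh_recovery_nullcline(self):
        p = IzhParams(a=0.02, b=0.2, c=0.1, d=0.06, V_peak=1e9,
                      U_init=0.0, V_init=0.0)
        state, _ = izh_step(NeuronState(V=0.0, u=0.0), -140.0, G, p, "A")
        assert state.u == 0.0  # b*v - u = 0 at the origin

    def test_srm_synaptic_decay(self):
        # s = 1, tau_s = 10, dt = 0.1 -> s' = 0.99
        m = sb.make_model("SRM", "A", {"tau_s": 10.0, "tau_r": 10.0,
                                       "V_th": 1.0, "V_reset": 0.0, "V_init": 0.0})
        state, _ = srm_step(NeuronState(V=0.0, s=1.0, r=0.0), 0.0, G, m.params, "A")
        assert state.s == pytest.approx(0.99, abs=1e-15)

    def test_srm_spike_increments_synaptic_variables(self, bench_models):
        m = bench_models["SRM"]
        # drive the membrane over threshold with a strongly negative input
        # (the input current enters the SRM membrane with a negative sign)
        state, spiked = m.step(NeuronState(V=0.9, s=0.5, r=0.5), -100.0,
                               SimulationGrid(dt=m.dt))
        assert spiked
        assert state.V == m.params.V_reset
        sc = 0.5 + (-0.5 / m.params.tau_s + 0.5) * 0.1
        rc = 0.5 + (-0.5 / m.params.tau_r) * 0.1
        assert state.s == pytest.approx(sc + 1.0, abs=1e-15)
        assert state.r == pytest.approx(rc + 1.0, abs=1e-15)

    def test_qif_quadratic_single_step(self, bench_models):
        # dV/dt = (-1 + 0.5)/4 = -0.125 at V=1, I=0 -> V' = 0.9875
        m = bench_models["QIF"]
        state, spiked = qif_step(NeuronState(V=1.0), 0.0, G, m.params, "C")
        assert state.V == pytest.approx(0.9875, abs=1e-15)
        assert not spiked


class TestThresholdAndErrors:
    def test_tie_at_threshold_spikes(self):
        # exact equality with the threshold emits a spike (>= comparison)
        m = sb.make_model("LIF", "A", {"tau": 4.0, "V_th": 1.0, "V_reset": 0.0,
                                       "V_init": 0.0})
        # choose I so the candidate equals V_th exactly: V + (I)/4*0.1 = 1
        state, spiked = m.step(NeuronState(V=0.0), 40.0, G)
        assert spiked and state.V == 0.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_input_rejected(self, bench_models, bad):
        with pytest.raises(sb.NumericalOverflowError):
            bench_models["LIF"].step(NeuronState(V=bad), 0.0, G)
        with pytest.raises(sb.NumericalOverflowError):
            bench_models["LIF"].step(NeuronState(V=0.0), bad, G)

    def test_adex_exponential_overflow_is_a_spike(self):
        p = AdExParams(tau_m=4.0, V_reset=0.0, V_init=0.0, V_rheo=0.5,
                       Delta_T=1e-3, V_spike=1e6)
        # exponent 1000/1e-3 overflows the double range; the divergence is the
        # spike and the reset keeps the state finite
        state, spiked = adex_step(NeuronState(V=1e6 + 1.0), 0.0, G, p, "A")
        assert spiked and state.V == 0.0
        assert math.isfinite(state.V)

    def test_make_model_rejects_invariant_violations(self):
        with pytest.raises(sb.ConfigError):
            sb.make_model("LIF", "A", {"tau": -1.0, "V_th": 1.0,
                                       "V_reset": 0.0, "V_init": 0.0})
        with pytest.raises(sb.ConfigError):
            sb.make_model("NLIF", "A", {"tau": 4.0, "V_th": 1.0, "V_reset": 0.0,
                                        "V_init": 0.0, "beta": 1.5})

    def test_make_model_unknown_name(self):
        with pytest.raises(sb.ConfigError):
            sb.make_model("perceptron", "A", "table3")

    def test_inapplicable_parameter_rejected(self):
        # a field that belongs to another model family has no meaning here
        with pytest.raises(sb.ConfigError):
            sb.make_model("LIF", "A", {"tau": 4.0, "V_th": 1.0, "V_reset": 0.0,
                                       "V_init": 0.0, "C_m": 1.0})
        with pytest.raises(sb.ConfigError):
            sb.make_model("LIF", "A", "table3", g_Na=120.0)

    @pytest.mark.parametrize("name", sb.MODEL_NAMES)
    def test_regimes_build_every_model(self, name):
        for regime in sb.REGIMES:
            model = sb.make_model(name, params_source=regime)
            state = model.init_state()
            new, spiked = model.step(state, 0.0, SimulationGrid(dt=model.dt))
            assert isinstance(spiked, bool)


class TestDynamicalInvariants:
    ZERO_REST = ["LIF", "NLIF", "QIF", "IFSFA", "ThetaNeuron", "SRM"]

    @pytest.mark.parametrize("name", ZERO_REST)
    def test_zero_rest_is_exactly_preserved(self, bench_models, name):
        """V = 0 with zero input is an exact fixed point over 10,000 steps."""
        m = bench_models[name]
        state = dataclasses.replace(m.init_state(), V=0.0, w=0.0, s=0.0, r=0.0)
        g = SimulationGrid(dt=m.dt)
        for _ in range(10_000):
            state, spiked = m.step(state, 0.0, g)
            assert not spiked
        assert state.V == 0.0

    def test_hh_rest_stable_and_silent(self):
        """At the canonical resting equilibrium the benchmark HH drifts less
        than 1 mV over 1,000 steps and never crosses a 0 mV detection level."""
        m = sb.make_model("HH", params_source="table3", V_detect=0.0)
        state = m.init_state()
        g = SimulationGrid(dt=m.dt)
        for _ in range(1000):
            state, spiked = m.step(state, 0.0, g)
            assert not spiked
            assert abs(state.V + 65.0) < 1.0

    @given(st.lists(st.floats(min_value=-50.0, max_value=50.0),
                    min_size=1, max_size=200))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_hh_gating_bounds(self, currents):
        """n, m, h stay in [0, 1] under arbitrary bounded input sequences."""
        m = sb.make_model("HH", params_source="table3", V_detect=0.0)
        state = m.init_state()
        g = SimulationGrid(dt=m.dt)
        for I in currents:
            state, _ = m.step(state, I, g)
            for gate in (state.n, state.m, state.h):
                assert 0.0 <= gate <= 1.0

    def test_refractory_separation_qif_b(self, trace_models):
        m = trace_models["QIF"]
        grid = SimulationGrid(dt=m.dt, n_steps=2000)
        rec = sb.run_trace(m, sb.StimulusProtocol("constant", 30.0, grid))
        gaps = np.diff(rec.spike_steps)
        assert len(rec.spike_steps) >= 2
        assert gaps.min() >= m.refractory_steps

    def test_izh_b_refractory_hold(self, trace_models):
        m = trace_models["Izhikevich"]
        grid = SimulationGrid(dt=m.dt, n_steps=4000)
        rec = sb.run_trace(m, sb.StimulusProtocol("constant", 20.0, grid))
        gaps = np.diff(rec.spike_steps)
        assert len(rec.spike_steps) >= 2
        assert gaps.min() >= m.refractory_steps
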