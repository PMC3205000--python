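"""Unit and property tests for the neuron model and its integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from knobsim.model import (
    HHParameters,
    SimulationTrace,
    StimulusProtocol,
    SimulationDiverged,
    build_lut,
    detect_spikes,
    gating_step,
    rest_state,
    sigmoid_inf,
    simulate,
    voltage_step,
)

finite_mV = st.floats(min_value=-120, max_value=60)


class TestSigmoid:
    @pytest.mark.parametrize("V,mu,s,expected", [
        (-40.0, -40.0, 5.0, 0.5),                      # midpoint
        (-35.0, -40.0, 5.0, 1 / (1 + math.exp(-1))),   # one slope unit above
        (-35.0, -40.0, -5.0, 1 / (1 + math.exp(1))),   # negative slope flips it
    ])
    def test_closed_form_values(self, V, mu, s, expected):
        assert sigmoid_inf(V, mu, s) == pytest.approx(expected, rel=1e-12)

    @given(V=finite_mV, mu=finite_mV, d=st.floats(min_value=0.01, max_value=50),
           s=st.floats(min_value=0.5, max_value=20))
    def test_symmetry_about_midpoint(self, V, mu, d, s):
        assert sigmoid_inf(mu + d, mu, s) + sigmoid_inf(mu - d, mu, s) == pytest.approx(1.0)

    @given(mu=finite_mV, s=st.floats(min_value=0.5, max_value=20),
           v1=finite_mV, v2=finite_mV)
    def test_monotonic_increasing_for_positive_slope(self, mu, s, v1, v2):
        if abs(v1 - v2) < 1e-6:  # below float resolution of the sigmoid
            return
        lo, hi = sorted([v1, v2])
        a, b = sigmoid_inf(lo, mu, s), sigmoid_inf(hi, mu, s)
        assert a <= b
        if 1e-12 < a and b < 1 - 1e-12:  # strict away from float saturation
            assert a < b

    def test_bounded_in_unit_interval_at_extremes(self):
        assert sigmoid_inf(1e4, -40, 5) == 1.0
        assert sigmoid_inf(-1e4, -40, 5) == 0.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_rejects_nonfinite_input(self, bad):
        with pytest.raises(ValueError):
            sigmoid_inf(bad, -40.0, 5.0)
        with pytest.raises(ValueError):
            sigmoid_inf(-40.0, bad, 5.0)

    def test_rejects_zero_slope(self):
        with pytest.raises(ValueError):
            sigmoid_inf(-40.0, -40.0, 0.0)


class TestGatingStep:
    def test_fixed_point(self):
        assert gating_step(0.3, 0.3, tau=5.0, dt=0.1) == 0.3

    def test_hand_evaluated_update(self):
        # x + dt (x_inf - x)/tau = 0 + 0.1 * 1 / 10
        assert gating_step(0.0, 1.0, tau=10.0, dt=0.1) == pytest.approx(0.01)

    def test_clamps_at_boundary_when_dt_exceeds_tau(self):
        assert gating_step(1.0, 0.0, tau=0.05, dt=0.1) == 0.0

    @pytest.mark.parametrize("tau,dt", [(0.0, 0.1), (-1.0, 0.1), (5.0, 0.0), (5.0, -0.1)])
    def test_rejects_nonpositive_tau_or_dt(self, tau, dt):
        with pytest.raises(ValueError):
            gating_step(0.5, 0.5, tau=tau, dt=dt)

    @given(x=st.floats(min_value=0, max_value=1),
           x_inf=st.floats(min_value=0, max_value=1),
           tau=st.floats(min_value=0.01, max_value=100),
           dt=st.floats(min_value=0.001, max_value=10))
    def test_output_stays_in_unit_interval(self, x, x_inf, tau, dt):
        assert 0.0 <= gating_step(x, x_inf, tau, dt) <= 1.0


class TestVoltageStep:
    def test_no_currents_leaves_voltage_unchanged(self):
        p = HHParameters(gL=0.0)
        assert voltage_step(-62.3, 0.0, 0.0, 0.0, p, dt=0.1) == -62.3

    def test_leak_only_long_step_reaches_rest(self):
        p = HHParameters()
        out = voltage_step(0.0, 0.0, 0.0, 0.0, p, dt=1e9)
        assert out == pytest.approx(p.E_L, abs=1e-3)

    def test_matches_closed_form_update(self):
        p = HHParameters()  # C_m=1, gL=0.3, E_L=-54.4
        V, I, dt = -65.0, 10.0, 0.1
        expected = (1.0 * V / dt + 0.3 * -54.4 + I) / (1.0 / dt + 0.3)
        assert voltage_step(V, 0.0, 0.0, I, p, dt) == pytest.approx(expected, rel=1e-14)

    @given(V=finite_mV, gNa=st.floats(min_value=0, max_value=200),
           gK=st.floats(min_value=0, max_value=100),
           dt=st.floats(min_value=1e-3, max_value=10))
    def test_zero_current_output_within_reversal_hull(self, V, gNa, gK, dt):
        p = HHParameters()
        lo = min(p.E_Na, p.E_K, p.E_L, V)
        hi = max(p.E_Na, p.E_K, p.E_L, V)
        out = voltage_step(V, gNa, gK, 0.0, p, dt)
        assert lo - 1e-9 <= out <= hi + 1e-9

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            voltage_step(-65.0, 0.0, 0.0, 0.0, HHParameters(), dt=0.0)


class TestSimulate:
    def test_rest_is_fixed_point_for_passive_membrane(self, passive_params):
        p = passive_params
        proto = StimulusProtocol(I_amp=0.0)
        trace = simulate(p, proto, V0=p.E_L)
        assert np.all(trace.V == p.E_L)

    def test_trace_length_and_time_axis(self, default_params):
        proto = StimulusProtocol(dt=0.1, duration=300.0)
        trace = simulate(default_params, proto)
        assert len(trace.V) == 3001
        assert trace.t[0] == 0.0
        assert np.all(np.diff(trace.t) > 0)

    def test_passive_step_matches_rc_closed_form(self, passive_params):
        # during the stimulus V relaxes toward E_L + I/gL with tau = C_m/gL
        p = passive_params
        proto = StimulusProtocol(dt=0.05, I_amp=6.0)
        trace = simulate(p, proto, V0=p.E_L)
        tau = p.C_m / p.gL
        mask = (trace.t >= proto.t_on) & (trace.t < proto.t_off)
        t_rel = trace.t[mask] - proto.t_on
        expected = p.E_L + (proto.I_amp / p.gL) * (1 - np.exp(-t_rel / tau))
        dev = np.abs(trace.V[mask] - expected)
        assert dev.max() / (proto.I_amp / p.gL) < 0.01

    def test_monotone_relaxation_during_passive_step(self, passive_params):
        p = passive_params
        proto = StimulusProtocol(I_amp=6.0)
        trace = simulate(p, proto, V0=p.E_L)
        mask = (trace.t >= proto.t_on) & (trace.t < proto.t_off)
        assert np.all(np.diff(trace.V[mask]) >= 0)
        assert trace.V[mask][-1] < p.E_L + proto.I_amp / p.gL

    def test_regular_preset_spikes_inside_window(self, default_params):
        proto = StimulusProtocol(I_amp=10.0)
        trace = simulate(default_params, proto)
        in_window = [s for s in trace.spike_times if proto.t_on <= s <= proto.t_off]
        assert len(in_window) >= 5

    def test_bit_identical_reruns(self, default_params, default_protocol):
        a = simulate(default_params, default_protocol)
        b = simulate(default_params, default_protocol)
        assert np.array_equal(a.V, b.V) and np.array_equal(a.m, b.m)

    def test_gating_stays_bounded_without_clamping(self, default_params):
        # dt below every time constant: the clamp must never engage
        proto = StimulusProtocol(dt=0.1, I_amp=10.0)
        trace = simulate(default_params, proto)
        assert trace.clamp_hits == 0
        for g in (trace.m, trace.h, trace.n):
            assert g.min() >= 0.0 and g.max() <= 1.0

    def test_voltage_stays_within_reversal_hull_without_stimulus(self, default_params):
        p = default_params
        proto = StimulusProtocol(I_amp=0.0)
        trace = simulate(p, proto, V0=-65.0)
        lo = min(p.E_Na, p.E_K, p.E_L)
        hi = max(p.E_Na, p.E_K, p.E_L)
        assert trace.V.min() >= lo and trace.V.max() <= hi

    def test_step_halving_converges(self):
        # subthreshold parameter set: truncation error shrinks as dt halves
        p = HHParameters(gNa_max=30.0, gK_max=20.0)
        errs = []
        for dt in (0.1, 0.05, 0.025):
            a = simulate(p, StimulusProtocol(dt=dt, I_amp=2.0))
            b = simulate(p, StimulusProtocol(dt=dt / 2, I_amp=2.0))
            errs.append(np.abs(a.V - b.V[::2]).max())
        assert errs[0] > errs[1] > errs[2]

    def test_implicit_update_stable_where_explicit_diverges(self, default_params):
        # stiff setting: dt = 10 ms with full spike conductances
        p = default_params
        proto = StimulusProtocol(dt=10.0, duration=300.0, I_amp=10.0)
        trace = simulate(p, proto)  # implicit: must stay finite
        assert np.all(np.isfinite(trace.V))

        # same equations with a fully explicit voltage update blow up
        V = -65.0
        m = sigmoid_inf(V, p.mu_m, p.s_m)
        h = sigmoid_inf(V, p.mu_h, p.s_h)
        n = sigmoid_inf(V, p.mu_n, p.s_n)
        diverged = False
        for i in range(proto.n_steps):
            t = i * proto.dt
            m = gating_step(m, sigmoid_inf(V, p.mu_m, p.s_m), p.tau_m, proto.dt)
            h = gating_step(h, sigmoid_inf(V, p.mu_h, p.s_h), p.tau_h, proto.dt)
            n = gating_step(n, sigmoid_inf(V, p.mu_n, p.s_n), p.tau_n, proto.dt)
            gNa = p.gNa_max * m ** 3 * h
            gK = p.gK_max * n ** 4
            I = proto.current(t)
            dV = (-gNa * (V - p.E_Na) - gK * (V - p.E_K)
                  - p.gL * (V - p.E_L) + I) / p.C_m
            V = V + proto.dt * dV
            if not math.isfinite(V) or abs(V) > 1e6:
                diverged = True
                break
        assert diverged

    def test_lut_evaluation_close_to_exact(self, default_params, default_protocol):
        exact = simulate(default_params, default_protocol)
        tabulated = simulate(default_params, default_protocol, use_lut=True)
        # spike count is preserved; voltages agree closely between spikes
        assert len(exact.spike_times) == len(tabulated.spike_times)

    def test_divergence_reports_step_index(self):
        p = HHParameters(gNa_max=0.0, gK_max=0.0, gL=0.0, C_m=1e-300)
        proto = StimulusProtocol(dt=0.1, duration=1.0, I_amp=1e308,
                                 t_on=0.0, t_off=1.0)
        with pytest.raises((SimulationDiverged, OverflowError)):
            simulate(p, proto, V0=0.0)


class TestRestState:
    def test_rest_is_self_consistent(self, default_params):
        state = rest_state(default_params)
        p = default_params
        gNa = p.gNa_max * state.m ** 3 * state.h
        gK = p.gK_max * state.n ** 4
        balance = (gNa * p.E_Na + gK * p.E_K + p.gL * p.E_L) / (gNa + gK + p.gL)
        assert state.V == pytest.approx(balance, abs=1e-6)

    def test_passive_rest_is_leak_reversal(self, passive_params):
        assert rest_state(passive_params).V == pytest.approx(passive_params.E_L)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 10, 0.1)
        V = np.full_like(t, -65.0)
        trace = SimulationTrace(t=t, V=V, m=V * 0, h=V * 0, n=V * 0)
        assert detect_spikes(trace) == []

    def test_triangle_wave_crossings_at_known_samples(self):
        t = np.arange(8, dtype=float)
        V = np.array([-10.0, 10.0, -10.0, -5.0, 5.0, 15.0, -10.0, -10.0])
        trace = SimulationTrace(t=t, V=V, m=V * 0, h=V * 0, n=V * 0)
        assert detect_spikes(trace, threshold=0.0) == [1.0, 4.0]

    def test_sample_exactly_at_threshold_counts_once(self):
        t = np.arange(4, dtype=float)
        V = np.array([-1.0, 0.0, 0.5, -1.0])
        trace = SimulationTrace(t=t, V=V, m=V * 0, h=V * 0, n=V * 0)
        assert detect_spikes(trace, threshold=0.0) == [1.0]


class TestLookupTable:
    def test_midpoint_preserved(self):
        lut = build_lut(-40.0, 5.0)
        assert lut(-40.0) == pytest.approx(0.5, abs=1e-4)

    def test_dense_grid_error_below_tolerance(self):
        from knobsim.model import sigmoid_inf
        lut = build_lut(-40.0, 5.0, n_points=2048)
        V = np.linspace(-100, 50, 30011)
        dev = np.abs(lut(V) - sigmoid_inf(V, -40.0, 5.0))
        assert dev.max() <= 1e-4

    def test_clamps_outside_range(self):
        lut = build_lut(-40.0, 5.0, v_min=-100, v_max=50)
        assert lut(-200.0) == lut(-100.0)
        assert lut(100.0) == lut(50.0)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            build_lut(-40.0, 5.0, n_points=1)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(tau_m=0.0), dict(tau_h=-1.0), dict(s_m=0.0),
        dict(gNa_max=-1.0), dict(C_m=0.0),
    ])
    def test_parameter_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            HHParameters(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        dict(dt=0.0), dict(dt=400.0), dict(t_on=-1.0),
        dict(t_on=260.0, t_off=250.0), dict(t_off=301.0),
    ])
    def test_protocol_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            StimulusProtocol(**kwargs)
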