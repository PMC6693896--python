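"""Membrane, synapse and cable dynamics against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isnsim.errors import (
    InvalidParameterError,
    NumericalInstabilityError,
    TopologyError,
)
from isnsim.model_core import (
    CableModel,
    ExpIFParams,
    HHPointParams,
    SynapseParams,
    cable_axial_conductances,
    cable_step,
    decay_synapse,
    exp_if_derivative,
    hh_ionic_current,
    hh_steady_state_gates,
    hh_step,
)
from isnsim.synthetic import make_ball_and_stick


class TestExpIFDerivative:
    def test_leak_fixed_point(self):
        p = ExpIFParams(Delta_T=0.0)
        assert exp_if_derivative(p.E_L, p) == pytest.approx(0.0)

    def test_zero_driving_force_at_excitatory_reversal(self):
        # a synapse reversing at 0 mV carries no current when V = 0 mV
        p = ExpIFParams(Delta_T=0.0, V_cut=10.0)
        for g in (0.5, 5.0, 50.0):
            with_syn = exp_if_derivative(0.0, p, [(g, 0.0)])
            without = exp_if_derivative(0.0, p)
            assert with_syn == pytest.approx(without)

    def test_hand_evaluated_oracle(self):
        # independent term-by-term arithmetic evaluation of the formula
        p = ExpIFParams(C=200.0, g_L=10.0, E_L=-70.0, V_T=-50.0, Delta_T=2.0)
        V = -60.0
        leak = 10.0 * (-70.0 - (-60.0))            # -100 pA
        spike = 10.0 * 2.0 * np.exp((-60.0 + 50.0) / 2.0)
        expected = (leak + spike) / 200.0
        assert exp_if_derivative(V, p) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        p = ExpIFParams()
        with pytest.raises(InvalidParameterError):
            exp_if_derivative(np.nan, p)
        with pytest.raises(InvalidParameterError):
            exp_if_derivative(-60.0, p, [(-1.0, 0.0)])

    @given(
        C=st.floats(50.0, 500.0),
        g_L=st.floats(2.0, 50.0),
        v0=st.floats(-90.0, -40.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_membrane_time_constant_is_C_over_gL(self, C, g_L, v0):
        # dimensional coherence: relaxation of the passive membrane
        # toward E_L proceeds with time constant C/g_L in ms
        p = ExpIFParams(C=C, g_L=g_L, Delta_T=0.0, V_cut=0.0, V_reset=-90.0)
        tau = p.tau_m
        dt = tau / 2000.0
        v = v0
        for _ in range(2000):  # integrate exactly one time constant
            v += dt * exp_if_derivative(v, p)
        expected = p.E_L + (v0 - p.E_L) * np.exp(-1.0)
        assert v == pytest.approx(expected, abs=0.02 + 1e-3 * abs(v0 - p.E_L))

    def test_subthreshold_closed_form(self):
        # V(t) = V_inf + (V0 - V_inf) exp(-t/tau) under constant current
        p = ExpIFParams(Delta_T=0.0)
        I = 150.0
        v_inf = p.E_L + I / p.g_L
        dt, T = 0.01, 100.0
        v = p.E_L
        n = int(T / dt)
        for _ in range(n):
            v += dt * exp_if_derivative(v, p, I_inj=I)
        expected = v_inf + (p.E_L - v_inf) * np.exp(-T / p.tau_m)
        assert abs(v - expected) < 0.1

    def test_reversal_clamping_monotone(self):
        # a dominant inhibitory conductance pulls V monotonically to E_syn
        p = ExpIFParams(Delta_T=0.0)
        g_inh, e_inh = 1000.0 * p.g_L, -75.0
        v, dt = p.E_L, 0.001
        path = [v]
        for _ in range(5000):
            v += dt * exp_if_derivative(v, p, [(g_inh, e_inh)])
            path.append(v)
        path = np.asarray(path)
        assert np.all(np.diff(path) <= 1e-12)
        assert path[-1] == pytest.approx(e_inh, abs=0.1)

    def test_param_invariants(self):
        with pytest.raises(InvalidParameterError):
            ExpIFParams(C=-1.0)
        with pytest.raises(InvalidParameterError):
            ExpIFParams(V_cut=-60.0, V_T=-50.0)
        with pytest.raises(InvalidParameterError):
            SynapseParams(E_syn=0.0, tau_syn=-5.0, w=0.1)


class TestDecaySynapse:
    def test_zero_stays_zero(self):
        assert decay_synapse(0.0, 3.7, 5.0) == 0.0

    def test_one_time_constant(self):
        assert decay_synapse(1.0, 5.0, 5.0) == pytest.approx(np.exp(-1.0))

    @given(
        g0=st.floats(0.0, 10.0),
        tau=st.floats(0.5, 20.0),
        k=st.integers(1, 50),
        dt=st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_semigroup_matches_closed_form(self, g0, tau, k, dt):
        g = g0
        for _ in range(k):
            g = decay_synapse(g, dt, tau)
        assert g == pytest.approx(g0 * np.exp(-k * dt / tau), rel=1e-9, abs=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(InvalidParameterError):
            decay_synapse(1.0, 0.1, -1.0)


class TestHHStep:
    def test_passive_leak_fixed_point(self):
        p = HHPointParams(gbar_Na=0, gbar_Kd=0, gbar_M=0, gbar_CaL=0)
        state = (p.E_leak, 0.0, 1.0, 0.0, 0.0, 0.0)
        out = hh_step(state, p, 0.025)
        assert out[0] == pytest.approx(p.E_leak, abs=1e-9)

    def test_gates_converge_to_steady_state_under_clamp(self):
        p = HHPointParams()
        v_clamp = -40.0
        state = [v_clamp, 0.2, 0.8, 0.2, 0.1, 0.1]
        for _ in range(200000):  # 5 s at fixed V
            out = hh_step(tuple(state), p, 0.025)
            state = [v_clamp] + list(out[1:])
        expected = hh_steady_state_gates(v_clamp, p)
        for got, want in zip(state[1:], expected):
            assert got == pytest.approx(float(want), abs=1e-4)

    def test_strong_step_spikes_only_with_sodium(self):
        prot_steps = 20000  # 500 ms at dt=0.025
        for gna, should_spike in ((5000.0, True), (0.0, False)):
            p = HHPointParams(gbar_Na=gna)
            state = (p.E_leak,) + hh_steady_state_gates(p.E_leak, p)
            state = tuple(float(np.asarray(s)) for s in state)
            peak = -100.0
            for _ in range(prot_steps):
                state = hh_step(state, p, 0.025, I_inj=300.0)
                peak = max(peak, state[0])
            assert (peak >= 0.0) == should_spike

    def test_gate_bounds_enforced(self):
        p = HHPointParams()
        with pytest.raises(NumericalInstabilityError):
            hh_step((-60.0, 1.5, 0.5, 0.5, 0.5, 0.5), p, 0.025)
        with pytest.raises(InvalidParameterError):
            hh_step((-60.0, 0.5, 0.5, 0.5, 0.5, 0.5), p, 0.2)

    def test_gates_stay_bounded_during_firing(self):
        p = HHPointParams()
        state = (p.E_leak,) + tuple(
            float(np.asarray(g)) for g in hh_steady_state_gates(p.E_leak, p)
        )
        for k in range(40000):
            state = hh_step(state, p, 0.025, I_inj=250.0)
            for g in state[1:]:
                assert 0.0 <= g <= 1.0


class TestCable:
    def test_single_compartment_matches_point_update(self):
        m = CableModel([20.0], [20.0], [-1])
        C = m.capacitance_pF()[0]
        gl = m.g_leak_nS()[0]
        v0 = -60.0
        v_new, _ = cable_step(m, np.array([v0]), 0.1)
        # backward-Euler point update: (C/dt) v' + gl v' = (C/dt) v + gl E
        expected = (C / 0.1 * v0 + gl * m.e_pas) / (C / 0.1 + gl)
        assert v_new[0] == pytest.approx(expected, rel=1e-12)

    def test_uniform_rest_is_invariant(self, ball_stick):
        v = np.full(ball_stick.n_comp, ball_stick.e_pas)
        for _ in range(100):
            v, _ = cable_step(ball_stick, v, 0.1)
        assert np.allclose(v, ball_stick.e_pas, atol=1e-9)

    def test_axial_charge_conservation_two_compartments(self):
        # without leak, axial redistribution conserves total charge
        m = CableModel([10.0, 10.0], [2.0, 2.0], [-1, 0], g_pas=0.0,
                       spherical_root=False)
        C = m.capacitance_pF()
        v = np.array([-60.0, -80.0])
        q0 = float((C * v).sum())
        for _ in range(200):
            v, _ = cable_step(m, v, 0.1)
        assert float((C * v).sum()) == pytest.approx(q0, rel=1e-9)
        assert v[0] == pytest.approx(v[1], abs=1e-6)  # equilibration

    def test_ball_and_stick_input_resistance_analytic(self):
        # steady soma voltage under constant current vs the sealed-end
        # finite-cable solution R = 1/(G_soma + tanh(L)/R_inf)
        m = make_ball_and_stick(soma_diam=20.0, dend_len=500.0, dend_diam=2.0,
                                n_comp=100)
        Rm = 1.0 / m.g_pas
        d_cm, l_cm = 2e-4, 500e-4
        lam = np.sqrt((d_cm / 4.0) * (Rm / m.Ra))
        r_i = 4.0 * m.Ra / (np.pi * d_cm ** 2)
        R_inf = r_i * lam
        G_cable = np.tanh(l_cm / lam) / R_inf
        G_soma = m.g_pas * np.pi * (20e-4) ** 2
        R_in = 1.0 / (G_soma + G_cable)
        I = 100.0  # pA
        v_pred = m.e_pas + I * 1e-12 * R_in * 1e3
        v = np.full(m.n_comp, m.e_pas)
        inj = np.zeros(m.n_comp)
        inj[0] = I
        for _ in range(4000):
            v, _ = cable_step(m, v, 5.0, I_inj=inj)
        deflection = v[0] - m.e_pas
        assert deflection == pytest.approx(v_pred - m.e_pas, rel=0.01)

    def test_clamp_current_nulls_synapse_at_its_reversal(self):
        # whole cell resting at the synapse's reversal: the conductance
        # has zero driving force everywhere and cannot alter the current
        m = make_ball_and_stick(n_comp=20, e_pas=-75.0)
        g = np.zeros(m.n_comp)
        g[5] = 2.0
        v = np.full(m.n_comp, -75.0)
        _, i_without = cable_step(m, v, 0.1, clamp=(0, -75.0))
        _, i_with = cable_step(m, v, 0.1, g_syn=[(g, -75.0)], clamp=(0, -75.0))
        assert i_without == pytest.approx(0.0, abs=1e-9)
        assert i_with == pytest.approx(0.0, abs=1e-9)

    def test_topology_validation(self):
        with pytest.raises(TopologyError):
            CableModel([10, 10], [2, 2], [-1, 5])
        with pytest.raises(InvalidParameterError):
            CableModel([10, -1], [2, 2], [-1, 0])

    def test_axial_conductance_symmetry(self, ball_stick):
        g = cable_axial_conductances(ball_stick)
        assert g[0] == 0.0
        assert np.all(g[1:] > 0)
        # interior dendritic couplings are identical for equal segments
        assert np.allclose(g[2:], g[2])
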