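"""Membrane potential maps and Hodgkin-Huxley dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from rosvgic.electrophysiology import (
    LINEAR_VM_INTERCEPT,
    MembraneParams,
    MembraneState,
    hh_gating_rates,
    hh_rest_potential,
    integrate_hh,
    linear_vm,
    membrane_rhs,
    quasi_steady_vm,
    trpv_activation,
    trpv_current,
)


def _oracle_hh_rhs(t, y, g_Na, g_K, g_L, E_Na, E_K, E_L, I=0.0):
    """Independent textbook HH right-hand side (squid-axon rates),
    written from scratch as the reference for the implementation."""
    V, m, h, n = y
    am = 0.1 * (V + 40) / (1 - np.exp(-(V + 40) / 10)) if abs(V + 40) > 1e-9 else 1.0
    bm = 4.0 * np.exp(-(V + 65) / 18)
    ah = 0.07 * np.exp(-(V + 65) / 20)
    bh = 1.0 / (1 + np.exp(-(V + 35) / 10))
    an = 0.01 * (V + 55) / (1 - np.exp(-(V + 55) / 10)) if abs(V + 55) > 1e-9 else 0.1
    bn = 0.125 * np.exp(-(V + 65) / 80)
    dV = (-g_Na * m**3 * h * (V - E_Na) - g_K * n**4 * (V - E_K)
          - g_L * (V - E_L) + I)
    return [dV, am * (1 - m) - bm * m, ah * (1 - h) - bh * h, an * (1 - n) - bn * n]


class TestGatingRates:
    def test_alpha_m_removable_singularity(self):
        a_m = hh_gating_rates(-40.0)[0]
        assert a_m == pytest.approx(1.0, rel=1e-6)

    def test_alpha_n_removable_singularity(self):
        a_n = hh_gating_rates(-55.0)[4]
        assert a_n == pytest.approx(0.1, rel=1e-6)

    def test_rates_nonnegative_and_match_direct_evaluation(self):
        v = np.linspace(-100, 60, 321)
        rates = hh_gating_rates(v)
        for r in rates:
            assert np.all(np.asarray(r) >= 0)
        # away from singularities, compare with the plain formulas
        mask = (np.abs(v + 40) > 0.5) & (np.abs(v + 55) > 0.5)
        vm = v[mask]
        direct_am = 0.1 * (vm + 40) / (1 - np.exp(-(vm + 40) / 10))
        np.testing.assert_allclose(rates[0][mask], direct_am, rtol=1e-10)

    def test_m_inf_monotone_increasing(self):
        v = np.linspace(-80, 0, 161)
        a_m, b_m = hh_gating_rates(v)[:2]
        m_inf = a_m / (a_m + b_m)
        assert np.all(m_inf > 0) and np.all(m_inf < 1)
        assert np.all(np.diff(m_inf) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hh_gating_rates(np.nan)


class TestMembraneRhs:
    def test_isolated_membrane_has_zero_drift(self):
        p = MembraneParams(g_L=0.0)
        st_ = MembraneState(Vm=-50.0, m=0.2, h=0.5, n=0.3)
        dV = membrane_rhs(st_, p, g_Na=0.0, g_K=0.0)[0]
        assert dV == 0.0

    def test_capacitor_law(self):
        # 1 uA/cm2 into 1 uF/cm2 charges at 1 mV/ms
        p = MembraneParams(g_L=0.0)
        st_ = MembraneState(Vm=-70.0, m=0.0, h=1.0, n=0.0)
        dV = membrane_rhs(st_, p, g_Na=0.0, g_K=0.0, I_ROS=1.0)[0]
        assert dV == pytest.approx(1.0)

    def test_nonfinite_input_rejected(self):
        p = MembraneParams()
        st_ = MembraneState(Vm=-70.0, m=0.1, h=0.5, n=0.3)
        with pytest.raises(ValueError):
            membrane_rhs(st_, p, g_Na=np.inf, g_K=36.0)

    def test_relaxes_to_stable_rest_matching_oracle(self):
        """Classic conductances relax to a stable rest; the trajectory must
        agree with an independently coded textbook integration."""
        p = MembraneParams()
        t, V, m, h, n = integrate_hh(p, 120.0, 36.0, duration_ms=80.0, v0=-65.0,
                                     t_eval=np.linspace(0, 80, 801))
        rest = V[-1]
        assert -75.0 < rest < -60.0
        late = V[t > 40.0]
        assert np.ptp(late) < 1.0  # within +-1 mV once settled
        # independent oracle
        y0 = [-65.0, m[0], h[0], n[0]]
        sol = solve_ivp(
            _oracle_hh_rhs, (0, 80), y0, args=(120.0, 36.0, 0.3, 60.0, -90.0, -54.4),
            method="LSODA", rtol=1e-10, atol=1e-12, t_eval=np.linspace(0, 80, 801),
        )
        np.testing.assert_allclose(V, sol.y[0], atol=0.05)

    def test_rest_potential_solver_agrees_with_integration(self):
        p = MembraneParams()
        v_rest = hh_rest_potential(p, 120.0, 36.0)
        _, V, *_ = integrate_hh(p, 120.0, 36.0, duration_ms=100.0, v0=v_rest)
        assert V[-1] == pytest.approx(v_rest, abs=0.1)


class TestQuasiSteadyVm:
    def test_single_conductance_returns_its_reversal(self):
        assert quasi_steady_vm(0, 0, 0.3, 60, -90, -54.4) == pytest.approx(-54.4)

    def test_symmetric_two_point_mean(self):
        assert quasi_steady_vm(1.0, 1.0, 0.0, 60.0, -90.0, 0.0) == pytest.approx(-15.0)

    def test_classic_weighted_mean(self):
        v = quasi_steady_vm(120.0, 36.0, 0.3, 60.0, -90.0, -54.4)
        assert v == pytest.approx(25.232, abs=0.01)  # hand-evaluated

    def test_all_zero_conductance_raises(self):
        with pytest.raises(ValueError):
            quasi_steady_vm(0.0, 0.0, 0.0, 60.0, -90.0, -54.4)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_uniform_conductance_scaling(self, scale):
        v1 = quasi_steady_vm(120.0, 36.0, 0.3, 60.0, -90.0, -54.4)
        v2 = quasi_steady_vm(120.0 * scale, 36.0 * scale, 0.3 * scale,
                             60.0, -90.0, -54.4)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_increasing_gna_depolarizes(self):
        gnas = np.linspace(0, 120, 25)
        vs = [quasi_steady_vm(g, 36.0, 0.3, 60.0, -90.0, -54.4) for g in gnas]
        assert np.all(np.diff(vs) > 0)


class TestLinearVm:
    def test_intercept_at_zero_expression(self):
        assert linear_vm(0.0, 0.0, 45.0, 15.0) == -75.0
        assert LINEAR_VM_INTERCEPT == -75.0

    def test_full_sodium_reaches_activation_threshold(self):
        assert linear_vm(1.0, 0.0, 45.0, 15.0) == pytest.approx(-30.0)

    def test_full_potassium_hyperpolarizes(self):
        assert linear_vm(0.0, 1.0, 45.0, 15.0) == pytest.approx(-90.0)

    def test_out_of_range_expression_rejected(self):
        with pytest.raises(ValueError):
            linear_vm(1.2, 0.0, 45.0, 15.0)
        with pytest.raises(ValueError):
            linear_vm(0.0, -0.1, 45.0, 15.0)

    def test_monotone_in_both_arguments(self):
        g = np.linspace(0, 1, 11)
        v_na = linear_vm(g, 0.3 * np.ones_like(g), 45.0, 15.0)
        v_k = linear_vm(0.3 * np.ones_like(g), g, 45.0, 15.0)
        assert np.all(np.diff(v_na) > 0)
        assert np.all(np.diff(v_k) < 0)


class TestTrpv:
    def test_closed_channel_passes_no_current(self):
        assert trpv_current(-70.0, 0.0, 2.0, 120.0) == 0.0

    def test_zero_driving_force(self):
        assert trpv_current(120.0, 1.0, 2.0, 120.0) == 0.0

    def test_inward_positive_at_rest(self):
        assert trpv_current(-70.0, 1.0, 2.0, 120.0) == pytest.approx(380.0)

    def test_activation_bounds_and_thermal_arm(self):
        ros = np.linspace(0, 0.3, 61)
        act = trpv_activation(ros)
        assert np.all((act >= 0) & (act <= 1))
        assert trpv_activation(0.0, T=45.0) == pytest.approx(1.0)  # heat alone
        assert trpv_activation(0.0, T=37.0) < 1e-6

    def test_activation_out_of_range_rejected_by_current(self):
        with pytest.raises(ValueError):
            trpv_current(-70.0, 1.5, 2.0, 120.0)


class TestGatingBoundsProperty:
    @given(
        i_stim=st.floats(min_value=-20.0, max_value=200.0),
        g_na=st.floats(min_value=0.0, max_value=150.0),
        g_k=st.floats(min_value=0.0, max_value=40.0),
        v0=st.floats(min_value=-90.0, max_value=0.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_gating_variables_stay_in_unit_interval(self, i_stim, g_na, g_k, v0):
        p = MembraneParams()
        _, V, m, h, n = integrate_hh(
            p, g_na, g_k, duration_ms=20.0, v0=v0,
            I_stim=lambda t: i_stim, rtol=1e-8, atol=1e-10,
        )
        # slack at the integrator's error tolerance
        for g in (m, h, n):
            assert np.all(g >= -1e-6) and np.all(g <= 1 + 1e-6)


class TestParamValidation:
    def test_reversal_potential_ordering_enforced(self):
        with pytest.raises(ValueError):
            MembraneParams(E_K=-40.0)  # would violate E_K < E_L

    def test_negative_capacitance_rejected(self):
        with pytest.raises(ValueError):
            MembraneParams(C_m=0.0)
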