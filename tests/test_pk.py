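"""Two-compartment pharmacokinetics: closed form, ODE oracle, rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from epperm.pk import PKParams, bateman, civ_profile, fit_pk, solve_two_compartment


def ode_oracle(params: PKParams, tau: np.ndarray) -> np.ndarray:
    """Independent stiff ODE integration of the compartment cascade."""

    def rhs(_, y):
        m_orb, m_iv = y
        return [-params.k_a * m_orb, params.k_a * m_orb - params.k_e * m_iv]

    sol = solve_ivp(
        rhs, (0.0, float(tau.max())), [params.dose, 0.0], t_eval=tau,
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    return sol.y[1]


class TestClosedForm:
    def test_initial_condition_zero(self):
        assert bateman(np.array([0.0]), PKParams())[0] == 0.0
        assert bateman(np.array([-50.0]), PKParams())[0] == 0.0

    def test_no_clearance_total_uptake(self):
        p = PKParams(k_a=0.02, k_e=0.0, dose=3.0)
        assert bateman(np.array([1e6]), p)[0] == pytest.approx(3.0, rel=1e-8)

    def test_peak_time(self):
        # argmax on a 0.01 s grid agrees with the analytic ln(ka/ke)/(ka-ke)
        p = PKParams(k_a=0.02, k_e=0.001)
        tau = np.arange(0.0, 600.0, 0.01)
        grid_peak = tau[np.argmax(bateman(tau, p))]
        assert grid_peak == pytest.approx(157.7, abs=0.05)
        assert p.t_peak == pytest.approx(grid_peak, abs=0.01)

    def test_confluent_limit_is_continuous(self):
        tau = np.linspace(0.0, 500.0, 64)
        near = bateman(tau, PKParams(k_a=0.01, k_e=0.01 * (1 - 1e-7)))
        conf = bateman(tau, PKParams(k_a=0.01, k_e=0.01))
        np.testing.assert_allclose(near, conf, rtol=1e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ka=st.floats(1e-4, 0.5),
        ratio=st.floats(1e-3, 0.99),
        dose=st.floats(0.1, 10.0),
    )
    def test_matches_ode_oracle_and_mass_bound(self, ka, ratio, dose):
        p = PKParams(k_a=ka, k_e=ka * ratio, dose=dose)
        tau = np.linspace(1.0, 5.0 / p.k_e if p.k_e else 1e4, 40)
        m = bateman(tau, p)
        assert np.all(m >= 0) and np.all(m <= dose * (1 + 1e-9))
        np.testing.assert_allclose(m, ode_oracle(p, tau), rtol=1e-6, atol=1e-9 * dose)

    def test_unimodal_when_cleared(self):
        p = PKParams(k_a=0.02, k_e=5e-4)
        m = bateman(np.linspace(0.5, 8000.0, 2000), p)
        sign_changes = np.count_nonzero(np.diff(np.sign(np.diff(m))) != 0)
        assert sign_changes == 1  # exactly one interior maximum

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            PKParams(k_a=np.nan)
        with pytest.raises(ValueError):
            PKParams(k_a=-0.1)


class TestSolutionAndProfile:
    def test_solution_matches_profile_pointwise(self):
        p = PKParams(v_blood=2.0)
        t = np.linspace(0.0, 2000.0, 101)
        sol = solve_two_compartment(p, t, t_fd=300.0)
        c = civ_profile(p, 300.0)
        np.testing.assert_array_equal(sol.c_iv, c(t))
        assert np.all(sol.c_iv[t < 300.0] == 0.0)
        np.testing.assert_array_equal(sol.m_iv, sol.c_iv * p.v_blood)


class TestFit:
    def test_noiseless_recovery_within_1pct(self, norm_trace, schedule):
        t2, y2 = norm_trace.phase("II")
        fitted, resid = fit_pk(t2, y2, schedule.t_fd)
        assert fitted.k_a == pytest.approx(0.02, rel=0.01)
        assert fitted.k_e == pytest.approx(5e-4, rel=0.01)
        assert resid < 1e-8

    def test_requires_post_peak_samples(self):
        p = PKParams()
        t = np.linspace(310.0, 430.0, 25)  # all on the rise
        y = bateman(t - 300.0, p)
        with pytest.raises(ValueError, match="past the peak"):
            fit_pk(t, y, 300.0)

    def test_requires_rise_samples(self):
        p = PKParams()
        t = np.linspace(600.0, 1000.0, 21)  # all past the peak
        y = bateman(t - 300.0, p)
        with pytest.raises(ValueError, match="rise"):
            fit_pk(t, y, 300.0)

    def test_gain_invariance(self, norm_trace, schedule):
        t2, y2 = norm_trace.phase("II")
        a, _ = fit_pk(t2, y2, schedule.t_fd)
        b, _ = fit_pk(t2, 37.5 * y2, schedule.t_fd)
        assert a.k_a == pytest.approx(b.k_a, rel=1e-6)
        assert a.k_e == pytest.approx(b.k_e, rel=1e-6)
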