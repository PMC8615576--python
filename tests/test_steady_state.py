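"""Steady-state solver and time-course integration."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ptmcycle import (
    FullParameters,
    MMParameters,
    MMState,
    full_rhs,
    initial_condition,
    mm_rhs,
    simulate_time_course,
    solve_steady_state,
)
from ptmcycle.steady_state import SteadyStateError, _integrate_to_steady


class TestInitialCondition:
    def test_basal_state_is_synthesis_over_degradation(self):
        assert initial_condition(MMParameters()).as_tuple() == (100.0, 0.0)
        st = initial_condition(FullParameters(Ytot=100.0), "full")
        assert st.as_tuple() == (100.0, 0.0, 0.0, 0.0)

    def test_no_finite_basal_state_without_degradation(self):
        with pytest.raises(ValueError, match="k3=0"):
            initial_condition(MMParameters(k3=0.0))

    def test_closed_cycle_requires_and_uses_total(self):
        p = MMParameters(k0=0.0, k3=0.0, k4=0.0)
        with pytest.raises(ValueError, match="total"):
            initial_condition(p)
        assert initial_condition(p, total=100.0).as_tuple() == (100.0, 0.0)


class TestSolveSteadyState:
    def test_no_kinase_gives_basal_state(self):
        res = solve_steady_state(MMParameters())
        assert res.converged and res.method == "root"
        assert res.state.as_tuple() == pytest.approx((100.0, 0.0))

    def test_intermediate_kinase_matches_independent_bisection(self):
        """Independent oracle: with equal turnover rates R + Rp = 100, so the
        modification balance 10(100-Rp)/(110-Rp) = 10 Rp/(10+Rp) + 0.01 Rp
        is a scalar equation solved here by plain bisection."""
        def balance(Rp):
            return (10.0 * (100.0 - Rp) / (110.0 - Rp)
                    - 10.0 * Rp / (10.0 + Rp) - 0.01 * Rp)

        expected_Rp = brentq(balance, 0.0, 100.0, xtol=1e-13)
        res = solve_steady_state(MMParameters(X=1.0))
        assert res.state.Rp == pytest.approx(expected_Rp, rel=1e-9)
        assert res.state.R == pytest.approx(100.0 - expected_Rp, rel=1e-9)
        # coarse magnitude frozen from the oracle
        assert res.state.as_tuple() == pytest.approx((57.53, 42.47), abs=0.01)

    def test_equal_turnover_keeps_total_substrate_constant(self):
        for X in (0.1, 1.0, 10.0):
            st = solve_steady_state(MMParameters(X=X)).state
            assert st.Rtot == pytest.approx(100.0, rel=1e-10)

    def test_turnover_balance_at_steady_state(self):
        """Synthesis equals total degradation: k0 = k3 R + k4 Rp."""
        p = MMParameters(X=2.0, k4=0.003)
        st = solve_steady_state(p).state
        assert p.k3 * st.R + p.k4 * st.Rp == pytest.approx(p.k0, rel=1e-8)

    def test_full_model_turnover_balance_includes_complexes(self):
        p = FullParameters(Xtot=5.0, Ytot=100.0, k4=0.001)
        st = solve_steady_state(p, "full").state
        drain = p.k3 * (st.R + st.RX) + p.k4 * (st.Rp + st.RpY)
        assert drain == pytest.approx(p.k0, rel=1e-8)
        assert st.RX <= p.Xtot and st.RpY <= p.Ytot

    def test_closed_cycle_conserves_supplied_total(self):
        p = MMParameters(k0=0.0, k3=0.0, k4=0.0, X=1.0)
        with pytest.raises(ValueError, match="total"):
            solve_steady_state(p)
        st = solve_steady_state(p, total=100.0).state
        assert st.Rtot == pytest.approx(100.0, rel=1e-12)
        assert max(abs(d) for d in mm_rhs(st, p)) < 1e-8

    @pytest.mark.parametrize("model", ["mm", "full"])
    def test_root_and_integration_agree(self, model):
        """The algebraic root and the long-time integrated state coincide for
        random parameter draws within 10x of the defaults."""
        rng = np.random.default_rng(20211741)
        n_draws = 20 if model == "mm" else 6
        for _ in range(n_draws):
            factors = 10.0 ** rng.uniform(-1, 1, size=7)
            if model == "mm":
                p = MMParameters(k0=factors[0], k1=10 * factors[1],
                                 Km1=10 * factors[2], k2=10 * factors[3],
                                 Km2=10 * factors[4], k3=0.01 * factors[5],
                                 k4=0.01 * factors[6],
                                 X=float(10 ** rng.uniform(-1, 1)))
            else:
                p = FullParameters(k0=factors[0], k1b=90 * factors[1],
                                   k2b=90 * factors[2], k1c=10 * factors[3],
                                   k2c=10 * factors[4], k3=0.01 * factors[5],
                                   k4=0.01 * factors[6],
                                   Xtot=float(10 ** rng.uniform(-1, 1)))
            res = solve_steady_state(p, model)
            y0 = np.array(initial_condition(p, model).as_tuple())
            y_int, _ = _integrate_to_steady(p, model, y0)
            np.testing.assert_allclose(np.array(res.state.as_tuple()), y_int,
                                       rtol=1e-6, atol=1e-9)

    def test_unbounded_growth_detected(self):
        # k3=0 and phosphorylation capacity below synthesis+recycling: R grows
        with pytest.raises(SteadyStateError, match="without bound"):
            solve_steady_state(MMParameters(k3=0.0, X=0.05))


class TestTimeCourse:
    def test_constant_trajectory_at_basal_state(self):
        tc = simulate_time_course(MMParameters(), "mm", MMState(100.0, 0.0),
                                  t_end=100.0, reporting_grid=50)
        np.testing.assert_allclose(tc.values[:, 0], 100.0, rtol=1e-7)
        np.testing.assert_allclose(tc.values[:, 1], 0.0, atol=1e-9)

    def test_total_substrate_constant_under_equal_turnover(self):
        tc = simulate_time_course(MMParameters(X=1.0), "mm", MMState(100.0, 0.0),
                                  t_end=1e3, reporting_grid=200)
        rtot = tc.values.sum(axis=1)
        np.testing.assert_allclose(rtot, 100.0, rtol=1e-6)

    def test_trajectories_remain_nonnegative(self):
        tc = simulate_time_course(MMParameters(X=10.0, k4=1.0), "mm",
                                  MMState(100.0, 0.0), t_end=1e3,
                                  reporting_grid=200)
        assert tc.values.min() >= -1e-9
        tcf = simulate_time_course(FullParameters(Xtot=10.0, Ytot=100.0),
                                   "full", None, t_end=1e3, reporting_grid=200)
        assert tcf.values.min() >= -1e-9
        # complexes never exceed the enzyme totals
        assert tcf.values[:, 2].max() <= 10.0 + 1e-9
        assert tcf.values[:, 3].max() <= 100.0 + 1e-9

    def test_settles_to_steady_state(self):
        p = MMParameters(X=1.0)
        tc = simulate_time_course(p, "mm", MMState(100.0, 0.0), t_end=1e4)
        assert tc.settled
        res = solve_steady_state(p)
        np.testing.assert_allclose(tc.values[-1], res.state.as_tuple(),
                                   rtol=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="t_end"):
            simulate_time_course(MMParameters(), "mm", MMState(1, 0), t_end=0.0)
        with pytest.raises(ValueError, match="increasing"):
            simulate_time_course(MMParameters(), "mm", MMState(1, 0),
                                 t_end=10.0, reporting_grid=[0.0, 2.0, 1.0])
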