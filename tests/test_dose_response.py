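"""Dose grids, steady-state scans and the linear total-substrate relations."""

import numpy as np
import pytest

from ptmcycle import (
    DoseGrid,
    DoseResponseCurve,
    FullParameters,
    MMParameters,
    flux_profile,
    rtot_linearity_check,
    scan_dose_response,
)
from ptmcycle.steady_state import SteadyStateError


class TestDoseGrid:
    def test_geometric_grid_points(self):
        g = DoseGrid("X", 1.0, 1.0201, 1.0)
        np.testing.assert_allclose(g.values(), [1.0, 1.01, 1.0201], rtol=1e-12)

    def test_grid_spans_bounds(self):
        v = DoseGrid("X", 1e-2, 1e2, 1.0).values()
        assert v[0] == 1e-2
        assert v[-1] == pytest.approx(100.0, rel=0.01)
        np.testing.assert_allclose(np.diff(np.log(v)), np.log(1.01), rtol=1e-9)

    @pytest.mark.parametrize("kw", [
        {"lower": 0.0, "upper": 1.0}, {"lower": 2.0, "upper": 1.0},
        {"lower": 1.0, "upper": 2.0, "step_percent": 0.0}])
    def test_invalid_grids_rejected(self, kw):
        with pytest.raises(ValueError):
            DoseGrid("X", **kw)


class TestScan:
    def test_baseline_monotonicity(self, baseline_curve):
        """The modified form rises and the unmodified form falls with kinase."""
        assert np.all(np.diff(baseline_curve.outputs["Rp"]) > 0)
        assert np.all(np.diff(baseline_curve.outputs["R"]) < 0)
        np.testing.assert_allclose(
            baseline_curve.outputs["Rtot_free"],
            baseline_curve.outputs["R"] + baseline_curve.outputs["Rp"],
            rtol=1e-12)

    def test_background_at_zero_kinase(self, baseline_curve):
        assert baseline_curve.background_at_zero
        assert baseline_curve.background["R"] == pytest.approx(100.0)
        assert baseline_curve.background["Rp"] == 0.0
        assert baseline_curve.background["flux_k3"] == pytest.approx(1.0)

    def test_background_at_lower_bound_for_other_axes(self):
        c = scan_dose_response(MMParameters(X=1.0), "mm",
                               DoseGrid("k0", 0.1, 0.2, 5.0),
                               readouts=("R", "Rp"))
        assert not c.background_at_zero
        assert c.background["R"] == pytest.approx(c.outputs["R"][0], rel=1e-9)

    def test_unknown_axis_and_readout_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            scan_dose_response(MMParameters(), "mm", DoseGrid("Xtot", 1, 2, 50))
        with pytest.raises(ValueError, match="readout"):
            scan_dose_response(MMParameters(), "mm", DoseGrid("X", 1, 2, 50),
                               readouts=("RXY",))

    def test_stabilized_plateau_reaches_synthesis_over_k4(self, stabilized_curve):
        """Stabilizing Rp tenfold raises the total-substrate plateau to
        k0/k4 = 1000, a 10-fold increase over the basal level 100."""
        rtot = stabilized_curve.outputs["Rtot_free"]
        assert rtot[-1] == pytest.approx(1000.0, rel=1e-2)
        assert stabilized_curve.background["Rtot_free"] == pytest.approx(100.0)

    def test_warm_start_independence(self):
        """Scanning with warm starts equals solving every point cold: the
        deterministic models are monostable, so there is no hysteresis."""
        from ptmcycle import solve_steady_state

        p = FullParameters(Ytot=100.0, k4=0.001)
        grid = DoseGrid("Xtot", 1e-2, 1e2, 10.0)
        warm = scan_dose_response(p, "full", grid, readouts=("R", "Rp"))
        for dose, R, Rp in zip(warm.doses, warm.outputs["R"],
                               warm.outputs["Rp"]):
            cold = solve_steady_state(p.with_(Xtot=float(dose)), "full").state
            assert cold.R == pytest.approx(R, rel=1e-8, abs=1e-10)
            assert cold.Rp == pytest.approx(Rp, rel=1e-8, abs=1e-10)

    def test_nonmonotonic_free_substrate_with_comparable_enzyme(self):
        """With phosphatase comparable to substrate and a strongly stabilized
        modified form, titration into complexes makes free R+Rp fall and the
        growing substrate pool later makes it rise again."""
        c = scan_dose_response(FullParameters(Ytot=100.0, k4=0.0001), "full",
                               DoseGrid("Xtot", 1e-2, 1e2, 1.0),
                               readouts=("Rtot_free",))
        rt = c.outputs["Rtot_free"]
        imin = int(np.argmin(rt))
        assert 0 < imin < len(rt) - 1
        assert rt[-1] > rt[imin] * 1.001


class TestFluxProfile:
    def test_flux_balance_and_dominance(self, baseline_curve):
        df = flux_profile(baseline_curve)
        np.testing.assert_allclose(df["flux_k3"] + df["flux_k4"], 1.0,
                                   rtol=1e-8)
        # at saturating kinase the cycle fluxes dwarf the turnover fluxes;
        # their gap is exactly the Rp turnover flux: flux_k1 - flux_k2 = k4 Rp
        last = df.iloc[-1]
        gap = last["flux_k1"] - last["flux_k2"]
        assert gap == pytest.approx(
            0.01 * baseline_curve.outputs["Rp"][-1], abs=1e-8)
        assert last["flux_k2"] > 5 * max(last["flux_k3"], last["flux_k4"])
        assert last["flux_k1"] > 10 * max(last["flux_k3"], last["flux_k4"])

    def test_missing_flux_columns_rejected(self):
        c = scan_dose_response(MMParameters(), "mm", DoseGrid("X", 1, 2, 50),
                               readouts=("R", "Rp"))
        with pytest.raises(ValueError, match="flux"):
            flux_profile(c)


class TestRtotLinearity:
    def test_arithmetic_of_the_linear_relation(self):
        """With k3=0.01, k4=0.001 the relation predicts
        Rtot = 100 + 0.9*Rp, e.g. 145 at Rp=50."""
        c = DoseResponseCurve.from_arrays(
            [1.0, 2.0, 4.0], {"R": [95.0, 95.0, 95.0], "Rp": [50.0, 50.0, 50.0]},
            params=MMParameters(k4=0.001), model_variant="mm")
        res = rtot_linearity_check(c)
        np.testing.assert_allclose(res.eq_rp_residuals, 145.0 - 145.0,
                                   atol=1e-12)

    def test_equal_turnover_collapses_to_constant_total(self, baseline_curve):
        res = rtot_linearity_check(baseline_curve)
        np.testing.assert_allclose(
            baseline_curve.outputs["Rtot_free"], 100.0, rtol=1e-9)
        assert res.max_abs_residual < 1e-6

    def test_residuals_vanish_on_solver_output(self, stabilized_curve):
        res = rtot_linearity_check(stabilized_curve)
        assert res.max_abs_residual < 1e-6
        assert not res.skipped

    def test_degenerate_rates_skip_the_affected_relation(self):
        c = scan_dose_response(MMParameters(k4=0.0, X=1.0), "mm",
                               DoseGrid("Km1", 1.0, 2.0, 10.0),
                               readouts=("R", "Rp"))
        res = rtot_linearity_check(c)
        assert any("k4=0" in s for s in res.skipped)
        assert res.eq_r_residuals is None
        assert np.max(np.abs(res.eq_rp_residuals)) < 1e-6
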