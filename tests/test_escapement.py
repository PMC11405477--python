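"""Optimal escapement: closed forms, root-finding, yield-loss ordering."""

import math

import numpy as np
import pytest

from escapefit.escapement import (EscapementPolicy, EscapementProblem,
                                  b60_boundary_growth_rate,
                                  crossing_growth_rate, equilibrium_yield,
                                  escapement_fraction, optimal_escapement,
                                  relative_yield)
from escapefit.models import GrowthParams, Model, growth_derivative

from .oracles import grid_optimal_escapement

R_GRID = [1.1, 1.7, 3.0, 9.0]


def _policy(model, r, k=1.0, rho=1.0) -> EscapementPolicy:
    return optimal_escapement(EscapementProblem(GrowthParams(model, r, k), rho))


class TestClosedForms:
    def test_beverton_holt_r4(self):
        assert _policy("beverton_holt", 4.0).s_star == pytest.approx(1 / 3)

    def test_hockey_stick_boundary_r(self):
        """r = 5/3 is exactly where the Hockey-Stick target hits 0.6 k."""
        assert _policy("hockey_stick", 5 / 3).s_star == pytest.approx(0.6)

    @pytest.mark.parametrize("r", np.linspace(1.01, 10.0, 25))
    def test_beverton_holt_simplification(self, r):
        """(sqrt(r)-1)/(r-1) == 1/(1+sqrt(r)) algebraically."""
        assert _policy("beverton_holt", r).fraction_of_k == pytest.approx(
            1.0 / (1.0 + math.sqrt(r)), abs=1e-12)

    def test_limits_at_slow_growth(self):
        """Both smooth models approach s*/k = 1/2 as r -> 1+."""
        for model in ("beverton_holt", "ricker"):
            assert _policy(model, 1.0001).fraction_of_k == pytest.approx(
                0.5, abs=1e-3)

    def test_crossing_growth_rate_closed_form(self):
        assert crossing_growth_rate() == pytest.approx(
            (3 + math.sqrt(5)) / 2, abs=1e-12)

    def test_b60_boundary_closed_form(self):
        assert b60_boundary_growth_rate() == pytest.approx(5 / 3, abs=1e-12)


class TestReedCondition:
    @pytest.mark.parametrize("r", R_GRID)
    def test_ricker_root_satisfies_reed_condition(self, r):
        p = GrowthParams("ricker", r, 1.0)
        s = optimal_escapement(EscapementProblem(p)).s_star
        assert growth_derivative(p, s) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("model", list(Model))
    @pytest.mark.parametrize("r", R_GRID)
    def test_escapement_maximizes_surplus(self, model, r):
        """Reed's condition == surplus maximization at rho = 1."""
        s_opt = _policy(model, r).s_star
        s_grid = grid_optimal_escapement(model.value, r, 1.0, n=10 ** 5)
        assert s_opt == pytest.approx(s_grid, abs=2e-4)

    def test_discounted_beverton_holt(self):
        """General rho: f'(s*) = 1/rho."""
        p = GrowthParams("beverton_holt", 4.0, 1.0)
        s = optimal_escapement(EscapementProblem(p, rho=0.9)).s_star
        assert growth_derivative(p, s) == pytest.approx(1 / 0.9, rel=1e-10)

    def test_discounted_hockey_stick_unsupported(self):
        with pytest.raises(NotImplementedError):
            optimal_escapement(EscapementProblem(
                GrowthParams("hockey_stick", 2.0, 1.0), rho=0.9))

    def test_invalid_discount_factor(self):
        with pytest.raises(ValueError):
            EscapementProblem(GrowthParams("ricker", 2.0, 1.0), rho=1.5)


class TestEscapementCurves:
    def test_hockey_stick_fraction_strictly_decreasing(self):
        r = np.linspace(1.05, 10.0, 200)
        frac = escapement_fraction("hockey_stick", r)
        assert np.all(np.diff(frac) < 0)

    @pytest.mark.parametrize("model,lo", [("beverton_holt", 0.2402),
                                          ("ricker", 0.3394)])
    def test_smooth_models_stay_just_below_half(self, model, lo):
        """s*/k stays in a narrow band below 1/2 for all r in (1, 10].

        The lower edges are the dense-grid minima (attained at r = 10):
        1/(1 + sqrt(10)) = 0.24025 for Beverton-Holt and 0.33941 for
        Ricker — growth rate barely moves these targets.
        """
        r = np.linspace(1.001, 10.0, 300)
        frac = escapement_fraction(model, r)
        assert np.all(frac >= lo) and np.all(frac <= 0.5)

    def test_hockey_stick_more_conservative_below_crossing(self):
        rc = crossing_growth_rate()
        for r, more_conservative in [(rc - 0.05, True), (rc + 0.05, False)]:
            hs = _policy("hockey_stick", r).s_star
            bh = _policy("beverton_holt", r).s_star
            assert (hs > bh) == more_conservative


class TestYield:
    @pytest.mark.parametrize("r", R_GRID)
    def test_hockey_stick_optimal_yield(self, r):
        k = 2.0
        p = GrowthParams("hockey_stick", r, k)
        assert equilibrium_yield(p, k / r) == pytest.approx(k * (r - 1) / r)

    @pytest.mark.parametrize("r", R_GRID)
    def test_beverton_holt_optimal_yield(self, r):
        k = 2.0
        p = GrowthParams("beverton_holt", r, k)
        s = k / (1 + math.sqrt(r))
        expected = k * (math.sqrt(r) - 1) / (math.sqrt(r) + 1)
        assert equilibrium_yield(p, s) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model", list(Model))
    def test_no_surplus_at_carrying_capacity(self, model):
        assert equilibrium_yield(GrowthParams(model, 2.0, 1.0), 1.0) == \
            pytest.approx(0.0, abs=1e-14)

    def test_escapement_above_k_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_yield(GrowthParams("ricker", 2.0, 1.0), 1.5)


class TestRelativeYield:
    def test_correct_model_achieves_full_yield(self):
        for model in Model:
            p = GrowthParams(model, 1.7, 1.0)
            assert relative_yield(p, model) == pytest.approx(1.0)

    def test_hockey_stick_policy_under_beverton_holt_truth(self):
        """k(r-1)^2/(r(2r-1)) over k(sqrt r - 1)/(sqrt r + 1) at r=1.7."""
        got = relative_yield(GrowthParams("beverton_holt", 1.7, 1.0),
                             "hockey_stick")
        r = 1.7
        expected = ((r - 1) ** 2 / (r * (2 * r - 1))) / \
            ((math.sqrt(r) - 1) / (math.sqrt(r) + 1))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.9106, abs=2e-4)

    def test_beverton_holt_policy_under_hockey_stick_truth(self):
        """f_H is linear below its corner, so the ratio is r/(1+sqrt r)."""
        got = relative_yield(GrowthParams("hockey_stick", 1.7, 1.0),
                             "beverton_holt")
        assert got == pytest.approx(1.7 / (1 + math.sqrt(1.7)), rel=1e-12)
        assert got == pytest.approx(0.7379, abs=2e-4)

    def test_wrong_model_never_beats_right_model(self):
        for r in np.linspace(1.05, 9.5, 40):
            for true_m in Model:
                for pol_m in Model:
                    ry = relative_yield(GrowthParams(true_m, r, 1.0), pol_m)
                    assert ry <= 1.0 + 1e-12

    def test_hockey_stick_rule_is_safer_mistake_on_dominance_region(self):
        """Using the Hockey-Stick rule under Beverton-Holt truth loses less
        catch than the reverse over most moderate growth rates.

        Closed forms give the exact dominance region: the two loss curves
        (r-1)^2 (sqrt r + 1) / (r (2r-1)(sqrt r - 1)) and r/(1 + sqrt r)
        cross at r = 1.24234, and coincide at 1 where the two policies
        merge (r = (3+sqrt 5)/2).  Below the lower crossing the ordering
        reverses: the Hockey-Stick target approaches k and its yield
        under Beverton-Holt truth vanishes like 4(r-1).
        """
        for r in np.linspace(1.2424, 2.61, 120):
            hs_under_bh = relative_yield(
                GrowthParams("beverton_holt", r, 1.0), "hockey_stick")
            bh_under_hs = relative_yield(
                GrowthParams("hockey_stick", r, 1.0), "beverton_holt")
            assert hs_under_bh >= bh_under_hs

    def test_ordering_reverses_for_very_slow_growth(self):
        r = 1.05
        assert relative_yield(GrowthParams("beverton_holt", r, 1.0),
                              "hockey_stick") < \
            relative_yield(GrowthParams("hockey_stick", r, 1.0),
                           "beverton_holt")
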