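"""Closed-form Jacobian/Hessian against independent oracles."""

import numpy as np
import pytest

from sucrokin import (
    FluxParameters,
    InvertaseParameters,
    MetabolicState,
    ParameterScenario,
    UndefinedElasticityError,
    analytic_hessian,
    analytic_jacobian,
    derivative_report,
    finite_difference_oracle,
    metabolic_functions,
    scaled_elasticity,
)
from sucrokin.derivatives import hessian_entries, jacobian_entries
from conftest import random_states


class TestFiniteDifferenceOracle:
    def test_constant_function_has_zero_derivatives(self):
        state = MetabolicState(1.0, 2.0, 3.0)
        assert np.allclose(finite_difference_oracle(lambda x: 4.2, state, 1), 0.0)
        assert np.allclose(finite_difference_oracle(lambda x: 4.2, state, 2), 0.0)

    def test_polynomial_gradient_and_hessian(self):
        state = MetabolicState(3.0, 1.0, 1.0)
        f = lambda x: x[0] ** 2
        grad = finite_difference_oracle(f, state, 1)
        assert grad[0] == pytest.approx(6.0, rel=1e-6)
        hess = finite_difference_oracle(f, state, 2)
        assert hess[0, 0] == pytest.approx(2.0, rel=1e-4)

    def test_boundary_state_uses_one_sided_scheme(self, scenario):
        # gradient evaluable at a zero concentration without leaving the orthant
        state = MetabolicState(0.0, 0.0, 0.0)
        f = lambda x: float(
            metabolic_functions(scenario, MetabolicState.from_array(np.maximum(x, 0)))[0]
        )
        grad = finite_difference_oracle(f, state, 1)
        jac = analytic_jacobian(scenario, state)
        assert grad == pytest.approx(jac[0], rel=1e-4, abs=1e-8)


class TestAnalyticDerivatives:
    def test_constant_functions_give_zero_jacobian(self, fluxes):
        inv = InvertaseParameters(v_max=0.0, k_m=1.0, k_i_glc=1.0, k_i_frc=1.0)
        sc = ParameterScenario("const", inv, FluxParameters(r_in=fluxes.r_in))
        assert np.allclose(analytic_jacobian(sc, MetabolicState(1, 2, 3)), 0.0)
        assert np.allclose(analytic_hessian(sc, MetabolicState(1, 2, 3), "suc"), 0.0)

    def test_jacobian_matches_oracle_on_random_states(self, scenario, rng):
        for state in random_states(rng, 30):
            report = derivative_report(scenario, state, include_efflux=True)
            err = np.max(np.abs(report.jacobian_analytic - report.jacobian_numeric))
            scale = max(np.max(np.abs(report.jacobian_analytic)), 1e-8)
            assert err / scale < 1e-6

    def test_hessian_matches_oracle_on_random_states(self, scenario, rng):
        for state in random_states(rng, 15):
            report = derivative_report(scenario, state, include_efflux=True)
            for name in ("suc", "glc", "frc"):
                a = report.hessians_analytic[name]
                n = report.hessians_numeric[name]
                scale = max(np.max(np.abs(a)), 1e-8)
                assert np.max(np.abs(a - n)) / scale < 1e-4

    def test_sucrose_row_sign_pattern(self, scenario, rng):
        """j11 < 0, j12 > 0, j13 > 0 wherever sucrose is present."""
        for state in random_states(rng, 100):
            jac = analytic_jacobian(scenario, state)
            assert jac[0, 0] < 0
            assert jac[0, 1] > 0
            assert jac[0, 2] > 0

    def test_hessian_symmetry_is_exact(self, scenario, rng):
        for state in random_states(rng, 20):
            for which in ("suc", "glc", "frc"):
                h = analytic_hessian(scenario, state, which, include_efflux=True)
                assert np.array_equal(h, h.T)

    def test_hexose_sensitivities_shrink_with_glucose(self, scenario):
        """Rising glucose (non-competitive inhibitor) damps both j12 and j13."""
        glc = np.linspace(0.1, 30.0, 40)
        entries = jacobian_entries(scenario, (np.full_like(glc, 5.0), glc, np.full_like(glc, 1.0)))
        assert np.all(np.diff(np.abs(entries["j12"])) < 0)
        assert np.all(np.diff(np.abs(entries["j13"])) < 0)

    def test_report_records_discrepancy(self, scenario):
        report = derivative_report(scenario, MetabolicState(2.0, 1.0, 0.5))
        assert report.max_rel_discrepancy < 1e-4
        assert report.max_rel_discrepancy > 0


class TestSymbolicCrossCheck:
    def test_closed_forms_match_sympy(self, scenario):
        sympy = pytest.importorskip("sympy")
        s, g, f = sympy.symbols("s g f", positive=True)
        p = scenario.invertase
        rate = p.v_max * s / ((p.k_m * (1 + f / p.k_i_frc) + s) * (1 + g / p.k_i_glc))
        point = {s: 3.2, g: 1.7, f: 0.9}
        state = (3.2, 1.7, 0.9)
        entries = jacobian_entries(scenario, state)
        for var, key in ((s, "j11"), (g, "j12"), (f, "j13")):
            expected = float(sympy.diff(-rate, var).subs(point))
            assert entries[key] == pytest.approx(expected, rel=1e-12)
        hess = hessian_entries(scenario, state, "suc")
        for (v1, v2), key in (
            ((s, s), "11"), ((s, g), "12"), ((s, f), "13"),
            ((g, g), "22"), ((g, f), "23"), ((f, f), "33"),
        ):
            expected = float(sympy.diff(-rate, v1, v2).subs(point))
            assert hess[key] == pytest.approx(expected, rel=1e-12)


class TestScaledElasticity:
    def test_linear_function_has_unit_elasticity(self):
        # no influx, no inhibition, far-from-saturation invertase: f(glc) ~ k*suc
        inv = InvertaseParameters(v_max=1.0, k_m=1e6, k_i_glc=1e12, k_i_frc=1e12)
        sc = ParameterScenario("linear", inv, FluxParameters(r_in=0.0))
        eps = scaled_elasticity(sc, MetabolicState(2.0, 1.0, 1.0), "glc", "suc")
        assert eps == pytest.approx(1.0, rel=1e-5)

    def test_independent_variable_has_zero_elasticity(self, scenario):
        # f(glc) without efflux does not depend on... every variable enters here,
        # so use the zero-v_max scenario where f(suc)=r_in is constant
        inv = InvertaseParameters(v_max=0.0, k_m=1.0, k_i_glc=1.0, k_i_frc=1.0)
        sc = ParameterScenario("const", inv, FluxParameters(r_in=1.0))
        assert scaled_elasticity(sc, MetabolicState(1, 1, 1), "suc", "glc") == 0.0

    def test_elasticity_matches_log_log_slope(self, scenario):
        state = MetabolicState(2.0, 1.0, 0.5)
        eps = scaled_elasticity(scenario, state, "glc", "glc", include_efflux=True)
        h = 1e-6
        def f(g):
            return metabolic_functions(
                scenario, MetabolicState(state.suc, g, state.frc), include_efflux=True
            )[1]
        slope = (
            (np.log(abs(f(state.glc * (1 + h)))) - np.log(abs(f(state.glc * (1 - h)))))
            / (np.log(1 + h) - np.log(1 - h))
        )
        assert eps == pytest.approx(slope, abs=1e-4)

    def test_vanishing_function_raises(self):
        inv = InvertaseParameters(v_max=0.0, k_m=1.0, k_i_glc=1.0, k_i_frc=1.0)
        sc = ParameterScenario("zero", inv, FluxParameters(r_in=0.0))
        with pytest.raises(UndefinedElasticityError):
            scaled_elasticity(sc, MetabolicState(1, 1, 1), "suc", "suc")
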