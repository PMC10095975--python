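"""Closed-form Jacobian and Hessian of the metabolic functions.

The scans and the regulatory interpretation built on them hinge on exact
first- and second-derivative surfaces, so these are hand-derived from the
rate laws rather than differentiated numerically at run time.  A central
finite-difference oracle is provided for verification (and used heavily
in the test suite); :func:`derivative_report` packages both routes with
their maximal discrepancy so that a disagreement is recorded, never
silently discarded.

With r = r_inv(S, G, F) the product-inhibited cleavage rate, the Jacobian
in (Suc, Glc, Frc) ordering is

    J = [[-r_S, -r_G, -r_F],          # f(Suc) = r_in - r
         [ r_S,  r_G - e'_G, r_F],    # f(Glc) = r - e_G(G)
         [ r_S,  r_G,  r_F - e'_F]]   # f(Frc) = r - e_F(F)

(efflux derivatives e' only in full-ODE mode).  The first row carries the
entries discussed throughout the grid analyses: j_11 <= 0, j_12 >= 0,
j_13 >= 0 for every admissible state under this rate law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from .errors import DomainError, UndefinedElasticityError
from .kinetics import (
    ArrayLike,
    invertase_rate_gradient,
    invertase_rate_hessian,
)
from .model import (
    SPECIES,
    MetabolicState,
    ParameterScenario,
    StateLike,
    _unpack,
    metabolic_functions,
)

__all__ = [
    "jacobian_entries",
    "hessian_entries",
    "analytic_jacobian",
    "analytic_hessian",
    "finite_difference_oracle",
    "scaled_elasticity",
    "DerivativeReport",
    "derivative_report",
]

_EFFLUX_OF = {"glc": "efflux_glc", "frc": "efflux_frc"}


def jacobian_entries(
    scenario: ParameterScenario, state: StateLike, include_efflux: bool = False
) -> Dict[str, ArrayLike]:
    """All nine Jacobian entries, vectorised over concentration arrays.

    Keys are ``'j11' .. 'j33'`` with row = function (Suc, Glc, Frc) and
    column = differentiation variable in the same order.
    """
    suc, glc, frc = _unpack(state)
    r_s, r_g, r_f = invertase_rate_gradient(scenario.invertase, suc, glc, frc)
    zeros = np.zeros_like(np.asarray(suc, dtype=float)) if np.ndim(suc) else 0.0
    e_g = scenario.fluxes.efflux_glc.derivative(glc) if include_efflux else zeros
    e_f = scenario.fluxes.efflux_frc.derivative(frc) if include_efflux else zeros
    return {
        "j11": -r_s, "j12": -r_g, "j13": -r_f,
        "j21": r_s, "j22": r_g - e_g, "j23": r_f,
        "j31": r_s, "j32": r_g, "j33": r_f - e_f,
    }


def hessian_entries(
    scenario: ParameterScenario,
    state: StateLike,
    which: str,
    include_efflux: bool = False,
) -> Dict[str, ArrayLike]:
    """Unique second partials of f(which), keyed ``'11','12','13','22','23','33'``."""
    if which not in SPECIES:
        raise DomainError(f"unknown metabolic function {which!r}; expected one of {SPECIES}")
    suc, glc, frc = _unpack(state)
    h = invertase_rate_hessian(scenario.invertase, suc, glc, frc)
    sign = -1.0 if which == "suc" else 1.0
    out = {
        "11": sign * h["ss"], "12": sign * h["sg"], "13": sign * h["sf"],
        "22": sign * h["gg"], "23": sign * h["gf"], "33": sign * h["ff"],
    }
    if include_efflux and which in _EFFLUX_OF:
        law = getattr(scenario.fluxes, _EFFLUX_OF[which])
        conc = glc if which == "glc" else frc
        key = "22" if which == "glc" else "33"
        out[key] = out[key] - law.second_derivative(conc)
    return out


def analytic_jacobian(
    scenario: ParameterScenario, state: StateLike, include_efflux: bool = False
) -> np.ndarray:
    """3x3 Jacobian matrix d f_i / d x_j at a single state."""
    e = jacobian_entries(scenario, state, include_efflux)
    return np.array(
        [
            [e["j11"], e["j12"], e["j13"]],
            [e["j21"], e["j22"], e["j23"]],
            [e["j31"], e["j32"], e["j33"]],
        ],
        dtype=float,
    )


def analytic_hessian(
    scenario: ParameterScenario,
    state: StateLike,
    which: str = "suc",
    include_efflux: bool = False,
) -> np.ndarray:
    """3x3 symmetric Hessian of f(which) at a single state.

    Symmetry is exact by construction: off-diagonal entries are the same
    expression, not two expressions that happen to agree.
    """
    h = hessian_entries(scenario, state, which, include_efflux)
    return np.array(
        [
            [h["11"], h["12"], h["13"]],
            [h["12"], h["22"], h["23"]],
            [h["13"], h["23"], h["33"]],
        ],
        dtype=float,
    )


def _fd_step(x: float, rel_step: float) -> float:
    return rel_step * max(abs(x), 1.0)


def finite_difference_oracle(
    f: Callable[[np.ndarray], float],
    state: MetabolicState,
    order: int = 1,
    rel_step: float | None = None,
) -> np.ndarray:
    """Central-difference gradient (order 1) or Hessian (order 2) of a scalar
    function of the concentration vector.

    Steps are relative (default 1e-6 for gradients, 1e-4 for Hessians,
    scaled by max(|x|, 1)).  Where a central stencil would cross the
    non-negativity boundary the whole stencil is shifted to one side; the
    scheme stays second-order accurate on the shifted nodes for the
    gradient and falls back to a forward scheme for the Hessian.
    Verification-only: production derivatives are the closed forms above.
    """
    if order not in (1, 2):
        raise DomainError("order must be 1 or 2")
    x0 = state.as_array()
    rel = rel_step if rel_step is not None else (1e-6 if order == 1 else 1e-4)
    h = np.array([_fd_step(xi, rel) for xi in x0])

    def fx(dx: np.ndarray) -> float:
        return float(f(x0 + dx))

    def e(i: int, scale: float) -> np.ndarray:
        dx = np.zeros(3)
        dx[i] = scale * h[i]
        return dx

    if order == 1:
        grad = np.empty(3)
        for i in range(3):
            if x0[i] - h[i] < 0:
                # one-sided second-order stencil at the boundary
                grad[i] = (-3 * fx(e(i, 0)) + 4 * fx(e(i, 1)) - fx(e(i, 2))) / (2 * h[i])
            else:
                grad[i] = (fx(e(i, 1)) - fx(e(i, -1))) / (2 * h[i])
        return grad

    hess = np.empty((3, 3))
    f0 = fx(np.zeros(3))
    for i in range(3):
        if x0[i] - h[i] < 0:
            hess[i, i] = (fx(e(i, 0)) - 2 * fx(e(i, 1)) + fx(e(i, 2))) / h[i] ** 2
        else:
            hess[i, i] = (fx(e(i, 1)) - 2 * f0 + fx(e(i, -1))) / h[i] ** 2
    for i in range(3):
        for j in range(i + 1, 3):
            si = 1.0 if x0[i] - h[i] < 0 else -1.0  # lowest admissible node
            sj = 1.0 if x0[j] - h[j] < 0 else -1.0
            if si < 0 and sj < 0:
                val = (
                    fx(e(i, 1) + e(j, 1))
                    - fx(e(i, 1) + e(j, -1))
                    - fx(e(i, -1) + e(j, 1))
                    + fx(e(i, -1) + e(j, -1))
                ) / (4 * h[i] * h[j])
            else:
                # forward/mixed stencil away from the boundary
                a = e(i, 1 if si > 0 else -1)
                b = e(j, 1 if sj > 0 else -1)
                val = (fx(a + b) - fx(a) - fx(b) + f0) / (
                    (1 if si > 0 else -1) * h[i] * (1 if sj > 0 else -1) * h[j]
                )
            hess[i, j] = hess[j, i] = val
    return hess


def scaled_elasticity(
    scenario: ParameterScenario,
    state: MetabolicState,
    function: str,
    variable: str,
    include_efflux: bool = False,
) -> float:
    """Dimensionless log-log sensitivity (x_j / f_i) * d f_i / d x_j.

    Raises :class:`UndefinedElasticityError` where f_i vanishes.
    """
    if function not in SPECIES or variable not in SPECIES:
        raise DomainError(f"function and variable must be in {SPECIES}")
    i, j = SPECIES.index(function), SPECIES.index(variable)
    f_vals = metabolic_functions(scenario, state, include_efflux)
    f_i = float(f_vals[i])
    if f_i == 0.0:
        raise UndefinedElasticityError(
            f"f({function}) vanishes at {state}; scaled elasticity undefined"
        )
    jac = analytic_jacobian(scenario, state, include_efflux)
    x_j = state.as_array()[j]
    return float(x_j / f_i * jac[i, j])


@dataclass(frozen=True)
class DerivativeReport:
    """Analytic vs finite-difference derivative blocks with their discrepancy."""

    jacobian_analytic: np.ndarray
    jacobian_numeric: np.ndarray
    hessians_analytic: Dict[str, np.ndarray]
    hessians_numeric: Dict[str, np.ndarray]
    max_rel_discrepancy: float


def _max_rel(a: np.ndarray, b: np.ndarray, floor: float = 1e-12) -> float:
    """Largest entry discrepancy relative to the block's scale.

    Normalising by the matrix scale (not entry-wise) keeps the metric
    meaningful where an entry is orders of magnitude below the dominant
    one and the finite-difference value is round-off limited.
    """
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), floor)
    return float(np.max(np.abs(a - b)) / scale)


def derivative_report(
    scenario: ParameterScenario,
    state: MetabolicState,
    include_efflux: bool = False,
) -> DerivativeReport:
    """Cross-check the closed-form derivatives against central differences."""
    jac_a = analytic_jacobian(scenario, state, include_efflux)
    jac_n = np.empty((3, 3))
    for i, name in enumerate(SPECIES):

        def fi(x, _i=i):
            vals = metabolic_functions(
                scenario, MetabolicState.from_array(np.maximum(x, 0.0)), include_efflux
            )
            return float(vals[_i])

        jac_n[i] = finite_difference_oracle(fi, state, order=1)
    hess_a, hess_n = {}, {}
    worst = _max_rel(jac_a, jac_n)
    for i, name in enumerate(SPECIES):

        def fi(x, _i=i):
            vals = metabolic_functions(
                scenario, MetabolicState.from_array(np.maximum(x, 0.0)), include_efflux
            )
            return float(vals[_i])

        hess_a[name] = analytic_hessian(scenario, state, name, include_efflux)
        hess_n[name] = finite_difference_oracle(fi, state, order=2)
        worst = max(worst, _max_rel(hess_a[name], hess_n[name], floor=1e-8))
    return DerivativeReport(
        jacobian_analytic=jac_a,
        jacobian_numeric=jac_n,
        hessians_analytic=hess_a,
        hessians_numeric=hess_n,
        max_rel_discrepancy=worst,
    )
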