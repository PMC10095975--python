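"""Metabolic functions and the ODE right-hand side of the sucrose system.

The three-species reaction scheme is

    --r_in--> Suc --r_inv--> Glc + Frc --r_out,Glc / r_out,Frc-->

and the metabolic function f(X) of a species X is the sum of rates
affecting it, i.e. the right-hand side of its ODE:

    f(Suc) = r_in - r_inv
    f(Glc) = r_inv - r_out,Glc
    f(Frc) = r_inv - r_out,Frc

Concentration-grid analyses of f(Suc) use the efflux-free mode
(``include_efflux=False``, the default for scans), where the hexose
functions reduce to the cleavage rate itself.  Time integration uses the
full form.

Variable ordering is fixed as (Suc, Glc, Frc) everywhere: Jacobian entry
(1,2) is the glucose sensitivity of f(Suc), entry (1,3) the fructose
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple, Union

import numpy as np

from .errors import DomainError
from .kinetics import (
    ArrayLike,
    FluxParameters,
    InvertaseParameters,
    invertase_rate,
)

SPECIES = ("suc", "glc", "frc")

__all__ = [
    "SPECIES",
    "MetabolicState",
    "ParameterScenario",
    "FunctionEvaluation",
    "metabolic_functions",
    "ode_rhs",
    "evaluate",
]


@dataclass(frozen=True)
class MetabolicState:
    """Concentrations of sucrose, glucose and fructose (mM) at one point."""

    suc: float
    glc: float
    frc: float

    def __post_init__(self):
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise DomainError(f"{name} concentration must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.suc, self.glc, self.frc], dtype=float)

    @classmethod
    def from_array(cls, x) -> "MetabolicState":
        x = np.asarray(x, dtype=float)
        return cls(suc=float(x[0]), glc=float(x[1]), frc=float(x[2]))


@dataclass(frozen=True)
class ParameterScenario:
    """Named set of kinetic constants for one temperature/compartment context."""

    name: str
    invertase: InvertaseParameters
    fluxes: FluxParameters
    temperature_label: str = ""
    compartment_label: str = ""

    def with_(self, **kwargs) -> "ParameterScenario":
        """Return a copy with selected fields replaced (keyword form of
        :func:`dataclasses.replace`)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FunctionEvaluation:
    """Metabolic-function values plus their Jacobian and Hessian blocks.

    ``jacobian[i, j]`` is d f_i / d x_j and ``hessians[name]`` the 3x3
    symmetric curvature matrix of f(name), all in (Suc, Glc, Frc) order.
    """

    state: MetabolicState
    f_suc: float
    f_glc: float
    f_frc: float
    jacobian: np.ndarray
    hessians: Dict[str, np.ndarray]

    @property
    def f(self) -> np.ndarray:
        return np.array([self.f_suc, self.f_glc, self.f_frc])


StateLike = Union[MetabolicState, Tuple[ArrayLike, ArrayLike, ArrayLike]]


def _unpack(state: StateLike) -> Tuple[ArrayLike, ArrayLike, ArrayLike]:
    if isinstance(state, MetabolicState):
        return state.suc, state.glc, state.frc
    suc, glc, frc = state
    return suc, glc, frc


def metabolic_functions(
    scenario: ParameterScenario,
    state: StateLike,
    include_efflux: bool = False,
) -> Tuple[ArrayLike, ArrayLike, ArrayLike]:
    """Evaluate (f_suc, f_glc, f_frc) at a state or at concentration arrays.

    With ``include_efflux=False`` (scan mode) the hexose functions equal
    the cleavage rate; with ``include_efflux=True`` (ODE mode) hexose
    consumption is subtracted.
    """
    suc, glc, frc = _unpack(state)
    r_inv = invertase_rate(scenario.invertase, suc, glc, frc)
    f_suc = scenario.fluxes.r_in - r_inv
    if include_efflux:
        f_glc = r_inv - scenario.fluxes.efflux_glc.rate(glc)
        f_frc = r_inv - scenario.fluxes.efflux_frc.rate(frc)
    else:
        f_glc = r_inv
        f_frc = r_inv
    return f_suc, f_glc, f_frc


def ode_rhs(scenario: ParameterScenario, state: StateLike) -> np.ndarray:
    """Time derivatives (dSuc/dt, dGlc/dt, dFrc/dt) including effluxes."""
    f_suc, f_glc, f_frc = metabolic_functions(scenario, state, include_efflux=True)
    return np.array([f_suc, f_glc, f_frc], dtype=float)


def evaluate(
    scenario: ParameterScenario,
    state: MetabolicState,
    include_efflux: bool = False,
) -> FunctionEvaluation:
    """Full local analysis: function values, Jacobian and all three Hessians."""
    from .derivatives import analytic_hessian, analytic_jacobian

    f_suc, f_glc, f_frc = metabolic_functions(scenario, state, include_efflux)
    jac = analytic_jacobian(scenario, state, include_efflux)
    hessians = {
        name: analytic_hessian(scenario, state, name, include_efflux) for name in SPECIES
    }
    return FunctionEvaluation(
        state=state,
        f_suc=float(f_suc),
        f_glc=float(f_glc),
        f_frc=float(f_frc),
        jacobian=jac,
        hessians=hessians,
    )
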