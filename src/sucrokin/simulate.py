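"""Time integration of the sucrose-cleavage ODE system and steady-state
location, at whole-cell and two-compartment resolution.

The whole-cell system integrates the three metabolic functions
(f(Suc), f(Glc), f(Frc), efflux terms included).  The coupled mode adds
a vacuolar copy of the system plus inter-compartment transport, modelled
first-order in the donor concentration with amount-conserving
volume-weighted exchange: a flux of k * c_donor * V_donor (umol/h)
leaving the donor raises the acceptor concentration by that amount over
V_acceptor.

A stiff-capable solver (LSODA, analytic Jacobian supplied) is the
default with tight tolerances (rtol 1e-8, atol 1e-10 mM): inhibition
constants can be small relative to cold-accumulated sugar levels, which
makes the system locally stiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import json
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import __version__
from .derivatives import analytic_jacobian
from .errors import DomainError, IntegrationError
from .model import SPECIES, MetabolicState, ParameterScenario, ode_rhs

__all__ = [
    "TimeCourse",
    "TransportParameters",
    "simulate",
    "simulate_two_compartments",
    "SteadyStateResult",
    "find_steady_state",
]


@dataclass(frozen=True)
class TimeCourse:
    """Integrated trajectory: time grid (h), one concentration column (mM)
    per species, and solver diagnostics."""

    time: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: Tuple[str, ...]
    scenario_name: str
    diagnostics: Dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        for i, name in enumerate(self.species):
            data[name] = self.states[:, i]
        return pd.DataFrame(data)

    def write(self, csv_path: str | Path) -> Path:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        sidecar = {
            "scenario": self.scenario_name,
            "species": list(self.species),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool))},
            "version": __version__,
        }
        meta = csv_path.with_suffix(".meta.json")
        meta.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
        return meta

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


def _clip_tiny_negatives(y: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Solver steps may undershoot zero by round-off; clip within -tol."""
    out = np.asarray(y, dtype=float).copy()
    mask = (out < 0) & (out > -tol)
    out[mask] = 0.0
    return out


def simulate(
    scenario: ParameterScenario,
    initial: MetabolicState,
    t_end: float,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval: Optional[np.ndarray] = None,
) -> TimeCourse:
    """Integrate the whole-cell system from ``initial`` to ``t_end`` hours.

    ``t_eval`` overrides the default uniform reporting grid (it must lie
    within [0, t_end]).
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")

    def rhs(t, y):
        # solver trial steps may undershoot zero; evaluate on the boundary
        y = np.maximum(y, 0.0)
        return ode_rhs(scenario, MetabolicState.from_array(y))

    def jac(t, y):
        y = np.maximum(y, 0.0)
        return analytic_jacobian(
            scenario, MetabolicState.from_array(y), include_efflux=True
        )

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        initial.as_array(),
        method=method,
        jac=jac,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    diagnostics = {
        "success": bool(sol.success),
        "message": sol.message,
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0) or 0),
        "method": method,
        "rtol": rtol,
        "atol": atol,
    }
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", diagnostics)
    states = _clip_tiny_negatives(sol.y.T)
    return TimeCourse(
        time=sol.t,
        states=states,
        species=SPECIES,
        scenario_name=scenario.name,
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class TransportParameters:
    """First-order inter-compartment transport constants (h^-1).

    ``k_suc_in`` moves sucrose cytosol -> vacuole; ``k_glc_out`` and
    ``k_frc_out`` move hexoses vacuole -> cytosol.
    """

    k_suc_in: float = 0.0
    k_glc_out: float = 0.0
    k_frc_out: float = 0.0

    def __post_init__(self):
        for name in ("k_suc_in", "k_glc_out", "k_frc_out"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


def simulate_two_compartments(
    cytosol: ParameterScenario,
    vacuole: ParameterScenario,
    initial_cytosol: MetabolicState,
    initial_vacuole: MetabolicState,
    t_end: float,
    transport: TransportParameters = TransportParameters(),
    volume_fractions: Tuple[float, float] = (0.05, 0.80),
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TimeCourse:
    """Integrate the coupled cytosol/vacuole system (6 state variables).

    Species order: suc_cyt, glc_cyt, frc_cyt, suc_vac, glc_vac, frc_vac.
    Transport conserves amounts: concentration changes are weighted by
    the donor/acceptor volume ratio.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    v_cyt, v_vac = volume_fractions
    if v_cyt <= 0 or v_vac <= 0:
        raise DomainError("volume fractions must be > 0")

    def rhs(t, y):
        y = np.maximum(y, 0.0)
        c = MetabolicState.from_array(y[:3])
        v = MetabolicState.from_array(y[3:])
        dc = ode_rhs(cytosol, c)
        dv = ode_rhs(vacuole, v)
        # sucrose: cytosol -> vacuole
        j_suc = transport.k_suc_in * c.suc  # mM/h in cytosol volume
        dc[0] -= j_suc
        dv[0] += j_suc * v_cyt / v_vac
        # hexoses: vacuole -> cytosol
        j_glc = transport.k_glc_out * v.glc
        dv[1] -= j_glc
        dc[1] += j_glc * v_vac / v_cyt
        j_frc = transport.k_frc_out * v.frc
        dv[2] -= j_frc
        dc[2] += j_frc * v_vac / v_cyt
        return np.concatenate([dc, dv])

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.concatenate([initial_cytosol.as_array(), initial_vacuole.as_array()]),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    diagnostics = {
        "success": bool(sol.success),
        "message": sol.message,
        "nfev": int(sol.nfev),
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "volume_fractions": volume_fractions,
    }
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", diagnostics)
    species = (
        "suc_cyt", "glc_cyt", "frc_cyt",
        "suc_vac", "glc_vac", "frc_vac",
    )
    return TimeCourse(
        time=sol.t,
        states=_clip_tiny_negatives(sol.y.T),
        species=species,
        scenario_name=f"{cytosol.name}+{vacuole.name}",
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class SteadyStateResult:
    state: MetabolicState
    residual: float
    converged: bool
    message: str = ""


def find_steady_state(
    scenario: ParameterScenario,
    initial_guess: MetabolicState,
    tol: float = 1e-10,
) -> SteadyStateResult:
    """Locate a non-negative root of the ODE right-hand side.

    Solves in square-root coordinates (x = u^2) so the root finder cannot
    leave the admissible orthant, then reports max |f| at the root.  A
    non-converged search is reported explicitly, never returned as a
    silent wrong root.
    """

    def rhs_sq(u):
        return ode_rhs(scenario, MetabolicState.from_array(u**2))

    u0 = np.sqrt(initial_guess.as_array())
    sol = root(rhs_sq, u0, method="hybr", tol=1e-13)
    state = MetabolicState.from_array(sol.x**2)
    residual = float(np.max(np.abs(ode_rhs(scenario, state))))
    # the parametrisation is singular at zero concentrations, so hybr may
    # report maxfev there; the residual is the ground truth
    converged = residual < tol
    message = sol.message if not converged else "converged"
    return SteadyStateResult(
        state=state, residual=residual, converged=converged, message=message
    )
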