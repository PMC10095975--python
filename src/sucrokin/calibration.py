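"""Kinetic parameter recovery from time-course data.

Weighted least squares on the log scale: parameters are optimised as
their logarithms (which enforces positivity and handles scale-spanning
constants), and residuals are differences of log-concentrations, which
matches the multiplicative error model of the synthetic data generator.
A multi-start strategy (log-normally perturbed initial guesses, best
optimum kept) guards against local minima.

Identifiability caveat: with a single relaxation experiment starting
from sucrose alone, the inhibition constants K_i are only weakly
constrained (hexoses stay in a narrow band); they should be fitted only
from designs that perturb initial hexose levels.  The default free set
is therefore (v_max, k_m, r_in).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError, IntegrationError
from .model import SPECIES, MetabolicState, ParameterScenario
from .simulate import simulate

__all__ = ["FitResult", "fit_parameters", "FREE_PARAMETERS"]

_LOG_FLOOR = 1e-9

#: Parameter names the fitter knows how to map onto a scenario.
FREE_PARAMETERS = (
    "v_max",
    "k_m",
    "k_i_glc",
    "k_i_frc",
    "r_in",
    "efflux_glc_v_max",
    "efflux_glc_k_m",
    "efflux_frc_v_max",
    "efflux_frc_k_m",
)


def _get_param(scenario: ParameterScenario, name: str) -> float:
    inv, flx = scenario.invertase, scenario.fluxes
    table = {
        "v_max": inv.v_max,
        "k_m": inv.k_m,
        "k_i_glc": inv.k_i_glc,
        "k_i_frc": inv.k_i_frc,
        "r_in": flx.r_in,
        "efflux_glc_v_max": flx.efflux_glc.v_max,
        "efflux_glc_k_m": flx.efflux_glc.k_m,
        "efflux_frc_v_max": flx.efflux_frc.v_max,
        "efflux_frc_k_m": flx.efflux_frc.k_m,
    }
    try:
        return table[name]
    except KeyError:
        raise InputError(f"unknown parameter {name!r}; known: {FREE_PARAMETERS}") from None


def _set_params(scenario: ParameterScenario, values: Mapping[str, float]) -> ParameterScenario:
    inv, flx = scenario.invertase, scenario.fluxes
    inv_kw = {k: values[k] for k in ("v_max", "k_m", "k_i_glc", "k_i_frc") if k in values}
    if inv_kw:
        inv = replace(inv, **inv_kw)
    glc_kw = {
        k.removeprefix("efflux_glc_"): values[k]
        for k in ("efflux_glc_v_max", "efflux_glc_k_m")
        if k in values
    }
    frc_kw = {
        k.removeprefix("efflux_frc_"): values[k]
        for k in ("efflux_frc_v_max", "efflux_frc_k_m")
        if k in values
    }
    efflux_glc = replace(flx.efflux_glc, **glc_kw) if glc_kw else flx.efflux_glc
    efflux_frc = replace(flx.efflux_frc, **frc_kw) if frc_kw else flx.efflux_frc
    flx = replace(
        flx,
        r_in=values.get("r_in", flx.r_in),
        efflux_glc=efflux_glc,
        efflux_frc=efflux_frc,
    )
    return replace(scenario, invertase=inv, fluxes=flx)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    parameters: Dict[str, float]
    rss: float
    converged: bool
    n_starts: int
    best_start: int
    seed: int
    relative_errors: Optional[Dict[str, float]] = None
    message: str = ""

    def to_dict(self) -> Dict:
        out = {
            "parameters": self.parameters,
            "rss": self.rss,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_start": self.best_start,
            "seed": self.seed,
            "message": self.message,
        }
        if self.relative_errors is not None:
            out["relative_errors"] = self.relative_errors
        return out


def fit_parameters(
    data: pd.DataFrame,
    scenario: ParameterScenario,
    initial: MetabolicState,
    free: Sequence[str] = ("v_max", "k_m", "r_in"),
    initial_guesses: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    n_starts: int = 10,
    perturbation_sd: float = 0.7,
    seed: int = 0,
    truth: Optional[Mapping[str, float]] = None,
    solver_rtol: float = 1e-7,
    solver_atol: float = 1e-9,
) -> FitResult:
    """Fit the named free parameters to a (time, suc, glc, frc) table.

    ``data`` must carry a ``time`` column and one column per species; row
    order is irrelevant (the table is sorted by time internally, so the
    objective is invariant to time-point permutation).  Bounds default to
    a factor of 10^3 around the initial guess.  When ``truth`` is given,
    per-parameter relative errors are attached to the result.
    """
    missing = [c for c in ("time", *SPECIES) if c not in data.columns]
    if missing:
        raise InputError(f"data table is missing columns {missing}")
    for name in free:
        _get_param(scenario, name)  # validates the names
    data = data.sort_values("time").reset_index(drop=True)
    t_grid = data["time"].to_numpy(dtype=float)
    obs = data[list(SPECIES)].to_numpy(dtype=float)
    log_obs = np.log(np.maximum(obs, _LOG_FLOOR))
    t_end = float(t_grid.max())

    guesses = {name: _get_param(scenario, name) for name in free}
    if initial_guesses:
        guesses.update({k: v for k, v in initial_guesses.items() if k in free})
    theta0 = np.log(np.array([guesses[name] for name in free]))

    if bounds is None:
        bounds = {}
    lo = np.array(
        [np.log(bounds[n][0]) if n in bounds else t - np.log(1e3) for n, t in zip(free, theta0)]
    )
    hi = np.array(
        [np.log(bounds[n][1]) if n in bounds else t + np.log(1e3) for n, t in zip(free, theta0)]
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        values = dict(zip(free, np.exp(theta)))
        trial = _set_params(scenario, values)
        try:
            course = simulate(
                trial, initial, t_end=t_end, t_eval=t_grid,
                rtol=solver_rtol, atol=solver_atol,
            )
        except IntegrationError:
            return np.full(log_obs.size, 1e3)
        sim = np.maximum(course.states, _LOG_FLOOR)
        return (np.log(sim) - log_obs).ravel()

    rng = np.random.default_rng(seed)
    best = None
    best_start = -1
    any_success = False
    for start in range(n_starts):
        theta_start = theta0 if start == 0 else np.clip(
            theta0 + rng.normal(0.0, perturbation_sd, size=theta0.size), lo, hi
        )
        try:
            sol = least_squares(
                residuals, theta_start, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # a diverging start must not kill the sweep
            continue
        if not np.isfinite(sol.cost):
            continue
        any_success = any_success or bool(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol
            best_start = start
    if best is None:
        return FitResult(
            parameters={}, rss=float("inf"), converged=False,
            n_starts=n_starts, best_start=-1, seed=seed,
            message="all starts failed",
        )
    estimates = dict(zip(free, np.exp(best.x)))
    rel_err = None
    if truth is not None:
        rel_err = {
            name: abs(estimates[name] - truth[name]) / abs(truth[name])
            for name in free
            if name in truth and truth[name] != 0
        }
    return FitResult(
        parameters={k: float(v) for k, v in estimates.items()},
        rss=float(2.0 * best.cost),
        converged=any_success,
        n_starts=n_starts,
        best_start=best_start,
        seed=seed,
        relative_errors=rel_err,
        message=best.message,
    )
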