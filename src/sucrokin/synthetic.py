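"""Synthetic parameter scenarios and noisy time courses.

The experimentally determined kinetic constants behind the published
warm/cold invertase analyses live in a prior study and are not bundled
here; this module generates parameter sets with the same *structure* --
two temperatures (ambient 22 degC and cold 4 degC), with the cold
scenario's maximal invertase rate and sucrose influx attenuated and its
concentration grids shifted upward to reflect cold-induced sugar
accumulation -- so that every downstream stage (scans, contrasts,
simulation, calibration) is testable end to end.

Default ranges are deliberately broad, synthetic placeholders:
v_max(22C) ~ U[1, 10] umol h^-1 gFW^-1, r_in(22C) ~ U[0.1, 1],
K_M ~ U[1, 10] mM (the low-millimolar range typical of both invertase
isoforms), K_i ~ U[0.5, 20] mM.  Cold attenuation of v_max and r_in is
drawn from U[0.15, 0.4]: over an 18 degC drop, a temperature coefficient
Q10 between ~2 and ~3 reduces enzymatic capacity 2.5- to 7-fold, and an
attenuation weaker than the saturation gain caused by cold sucrose
accumulation would not reproduce the reduced cold dynamics that define
the scenario pair (see docs/methods.md).  Grids default to sucrose
planes 1-3 (warm) and 4-8 (cold) umol gFW^-1 with the hexose range
0.05-3 (warm) scaled 5-fold to 0.25-15 (cold), cold-accumulated hexose
pools staying elevated across the cold range.

Everything is driven by an explicit seed and records it, so any
generated artefact can be regenerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .gridscan import GridSpec
from .kinetics import EffluxLaw, FluxParameters, InvertaseParameters
from .model import MetabolicState, ParameterScenario
from .simulate import simulate

__all__ = [
    "ScenarioTemplate",
    "ScenarioPair",
    "generate_scenario_pair",
    "generate_time_course_data",
]


@dataclass(frozen=True)
class ScenarioTemplate:
    """Sampling ranges for a warm/cold scenario pair.

    ``*_range`` entries are uniform sampling intervals for the warm
    (22 degC) parameters; the cold parameters are the warm ones times an
    attenuation factor drawn from ``attenuation_range`` (or fixed via
    ``attenuation_v_max`` / ``attenuation_r_in``).  Concentration grids
    for the cold scenario are shifted upward, emulating cold-induced
    sugar accumulation.
    """

    v_max_range: Tuple[float, float] = (1.0, 10.0)
    r_in_range: Tuple[float, float] = (0.1, 1.0)
    k_m_range: Tuple[float, float] = (1.0, 10.0)
    k_i_range: Tuple[float, float] = (0.5, 20.0)
    attenuation_range: Tuple[float, float] = (0.15, 0.4)
    attenuation_v_max: Optional[float] = None
    attenuation_r_in: Optional[float] = None
    efflux_v_max_factor_range: Tuple[float, float] = (2.0, 5.0)  # x r_in
    suc_planes_warm: Tuple[float, ...] = (1.0, 2.0, 3.0)
    suc_planes_cold: Tuple[float, ...] = (4.0, 6.0, 8.0)
    hexose_range_warm: Tuple[float, float] = (0.05, 3.0)
    hexose_range_cold: Tuple[float, float] = (0.25, 15.0)
    n_hexose: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("attenuation_v_max", "attenuation_r_in"):
            value = getattr(self, name)
            if value is not None and not (0.0 < value <= 1.0):
                raise DomainError(f"{name} must be in (0, 1]")
        lo, hi = self.attenuation_range
        if not (0.0 < lo <= hi <= 1.0):
            raise DomainError("attenuation_range must lie in (0, 1]")


@dataclass(frozen=True)
class ScenarioPair:
    """A matched warm/cold scenario pair with the grids they are scanned on."""

    warm: ParameterScenario
    cold: ParameterScenario
    grid_warm: GridSpec
    grid_cold: GridSpec
    seed: int
    template: ScenarioTemplate

    def as_record(self) -> Dict:
        return {
            "seed": self.seed,
            "template": asdict(self.template),
            "warm": _scenario_dict(self.warm),
            "cold": _scenario_dict(self.cold),
        }


def _scenario_dict(s: ParameterScenario) -> Dict:
    return {
        "name": s.name,
        "temperature_label": s.temperature_label,
        "compartment_label": s.compartment_label,
        "invertase": asdict(s.invertase),
        "fluxes": {
            "r_in": s.fluxes.r_in,
            "efflux_glc": asdict(s.fluxes.efflux_glc),
            "efflux_frc": asdict(s.fluxes.efflux_frc),
        },
    }


def _uniform(rng: np.random.Generator, interval: Tuple[float, float]) -> float:
    return float(rng.uniform(*interval))


def generate_scenario_pair(
    template: ScenarioTemplate = ScenarioTemplate(),
    seed: Optional[int] = None,
    name_prefix: str = "synthetic",
) -> ScenarioPair:
    """Draw one matched 22 degC / 4 degC scenario pair.

    The cold v_max and r_in are strictly below their warm counterparts
    by construction (attenuation factors in (0, 1)); K_M and the K_i's
    are shared between temperatures, as befits constants of the same
    enzyme; the efflux capacity scales with r_in so that generated
    scenarios admit a finite steady state.
    """
    if seed is None:
        seed = template.seed
    rng = np.random.default_rng(seed)
    v_max = _uniform(rng, template.v_max_range)
    r_in = _uniform(rng, template.r_in_range)
    k_m = _uniform(rng, template.k_m_range)
    k_i_glc = _uniform(rng, template.k_i_range)
    k_i_frc = _uniform(rng, template.k_i_range)
    att_v = (
        template.attenuation_v_max
        if template.attenuation_v_max is not None
        else _uniform(rng, template.attenuation_range)
    )
    att_r = (
        template.attenuation_r_in
        if template.attenuation_r_in is not None
        else _uniform(rng, template.attenuation_range)
    )
    efflux_factor = _uniform(rng, template.efflux_v_max_factor_range)
    efflux_k_m = _uniform(rng, template.k_m_range)

    def make(label: str, vm: float, ri: float, planes, hex_range) -> Tuple[ParameterScenario, GridSpec]:
        inv = InvertaseParameters(v_max=vm, k_m=k_m, k_i_glc=k_i_glc, k_i_frc=k_i_frc)
        efflux = EffluxLaw.michaelis_menten(v_max=efflux_factor * ri, k_m=efflux_k_m)
        fluxes = FluxParameters(r_in=ri, efflux_glc=efflux, efflux_frc=efflux)
        scenario = ParameterScenario(
            name=f"{name_prefix}_{label}_seed{seed}",
            invertase=inv,
            fluxes=fluxes,
            temperature_label=label,
            compartment_label="whole_cell",
        )
        grid = GridSpec(
            glc_range=hex_range,
            frc_range=hex_range,
            suc_planes=tuple(planes),
            n_glc=template.n_hexose,
            n_frc=template.n_hexose,
        )
        return scenario, grid

    warm, grid_warm = make("22C", v_max, r_in, template.suc_planes_warm, template.hexose_range_warm)
    cold, grid_cold = make(
        "4C", att_v * v_max, att_r * r_in, template.suc_planes_cold, template.hexose_range_cold
    )
    return ScenarioPair(
        warm=warm, cold=cold, grid_warm=grid_warm, grid_cold=grid_cold,
        seed=seed, template=template,
    )


def generate_time_course_data(
    scenario: ParameterScenario,
    initial: MetabolicState,
    t_grid: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate the scenario and add multiplicative log-normal noise.

    Each observation is the clean simulated concentration times
    ``exp(eps)`` with ``eps ~ Normal(0, noise_sd)`` i.i.d. -- metabolite
    measurements are positive with roughly concentration-proportional
    error.  Returns the noisy table (columns time, suc, glc, frc) and a
    sidecar dict recording the generating parameters and seed.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    course = simulate(scenario, initial, t_end=float(t_grid.max()), t_eval=t_grid)
    clean = course.states
    rng = np.random.default_rng(seed)
    noisy = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape)) if noise_sd > 0 else clean
    frame = pd.DataFrame(
        {"time": t_grid, "suc": noisy[:, 0], "glc": noisy[:, 1], "frc": noisy[:, 2]}
    )
    sidecar = {
        "scenario": _scenario_dict(scenario),
        "initial": {"suc": initial.suc, "glc": initial.glc, "frc": initial.frc},
        "noise_sd": noise_sd,
        "seed": seed,
        "n_points": int(t_grid.size),
    }
    return frame, sidecar
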