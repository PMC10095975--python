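"""Configuration schema, parsing and serialisation.

Scenario parameters enter the pipeline only through configuration files:
TOML for the human-edited bundled examples, JSON as a byte-stable
alternative (generated fixtures are written as JSON).  The schema is
validated with pydantic before any computation; unknown keys are
rejected so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .compartments import CompartmentSpec
from .errors import ConfigError
from .gridscan import GridSpec
from .kinetics import EffluxLaw, FluxParameters, InvertaseParameters
from .model import ParameterScenario

__all__ = [
    "EffluxConfig",
    "InvertaseConfig",
    "FluxesConfig",
    "GridConfig",
    "ScenarioConfig",
    "CompartmentConfig",
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_json_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffluxConfig(_Strict):
    kind: Literal["michaelis_menten", "first_order", "zero"] = "zero"
    v_max: float = 0.0
    k_m: float = 1.0
    k: float = 0.0

    def build(self) -> EffluxLaw:
        return EffluxLaw(kind=self.kind, v_max=self.v_max, k_m=self.k_m, k=self.k)


class InvertaseConfig(_Strict):
    v_max: float
    k_m: float
    k_i_glc: float
    k_i_frc: float

    def build(self) -> InvertaseParameters:
        return InvertaseParameters(**self.model_dump())


class FluxesConfig(_Strict):
    r_in: float
    efflux_glc: EffluxConfig = Field(default_factory=EffluxConfig)
    efflux_frc: EffluxConfig = Field(default_factory=EffluxConfig)

    def build(self) -> FluxParameters:
        return FluxParameters(
            r_in=self.r_in,
            efflux_glc=self.efflux_glc.build(),
            efflux_frc=self.efflux_frc.build(),
        )


class GridConfig(_Strict):
    glc_range: Tuple[float, float]
    frc_range: Tuple[float, float]
    suc_planes: List[float]
    n_glc: int = 50
    n_frc: int = 50
    units: Literal["mM", "umol_gFW"] = "mM"

    def build(self) -> GridSpec:
        return GridSpec(
            glc_range=tuple(self.glc_range),
            frc_range=tuple(self.frc_range),
            suc_planes=tuple(self.suc_planes),
            n_glc=self.n_glc,
            n_frc=self.n_frc,
            units=self.units,
        )


class ScenarioConfig(_Strict):
    name: str
    invertase: InvertaseConfig
    fluxes: FluxesConfig
    temperature_label: str = ""
    compartment_label: str = ""
    grid: Optional[GridConfig] = None

    def build(self) -> ParameterScenario:
        return ParameterScenario(
            name=self.name,
            invertase=self.invertase.build(),
            fluxes=self.fluxes.build(),
            temperature_label=self.temperature_label,
            compartment_label=self.compartment_label,
        )


class CompartmentConfig(_Strict):
    name: str
    volume_fraction: float
    #: keys are "sugar/temperature", e.g. "sucrose/22C"
    sugar_fractions: Dict[str, float] = Field(default_factory=dict)

    def build(self) -> CompartmentSpec:
        fractions = {}
        for key, value in self.sugar_fractions.items():
            sugar, _, temp = key.partition("/")
            if not temp:
                raise ConfigError(
                    f"sugar_fractions key {key!r} must have the form 'sugar/temperature'"
                )
            fractions[(sugar, temp)] = value
        return CompartmentSpec(self.name, self.volume_fraction, fractions)


class RunConfig(_Strict):
    scenarios: List[ScenarioConfig]
    compartments: List[CompartmentConfig] = Field(default_factory=list)
    seed: int = 0
    include_efflux: bool = False

    @model_validator(mode="after")
    def _unique_names(self):
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError(f"scenario names must be unique, got {names}")
        return self

    def scenario(self, name: str) -> ScenarioConfig:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise ConfigError(f"no scenario named {name!r}; have {[s.name for s in self.scenarios]}")


def _apply_override(raw: dict, expr: str) -> None:
    """Apply one ``dotted.path=value`` override to the raw config dict."""
    if "=" not in expr:
        raise ConfigError(f"override {expr!r} must have the form key.path=value")
    path, _, value = expr.partition("=")
    try:
        parsed = json.loads(value)
    except json.JSONDecodeError:
        parsed = value  # bare string
    node = raw
    parts = path.split(".")
    for part in parts[:-1]:
        key = int(part) if part.lstrip("-").isdigit() else part
        node = node[key]
    last = parts[-1]
    key = int(last) if last.lstrip("-").isdigit() else last
    node[key] = parsed


def load_run_config(path: str | Path, overrides: Optional[List[str]] = None) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r} (use .toml or .json)")
    for expr in overrides or []:
        try:
            _apply_override(raw, expr)
        except (KeyError, IndexError, TypeError) as err:
            raise ConfigError(f"override {expr!r} does not match the config structure: {err}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(f"invalid configuration {path}:\n{err}") from err


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the validated configuration."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_json_config(config: RunConfig, path: str | Path) -> Path:
    """Write a validated configuration back to disk as canonical JSON.

    Floats round-trip exactly (json uses shortest-repr, 17 significant
    digits where needed), so re-loading reproduces the configuration
    bit for bit.
    """
    path = Path(path)
    path.write_text(
        json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    )
    return path
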