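"""Subcellular compartments: effective concentrations and scenario building.

Whole-tissue sugar measurements (umol per g fresh weight) are converted
into compartment-local molar concentrations using (i) the fraction of
the total amount residing in the compartment, (ii) the compartment's
share of total cell volume, and (iii) the convention that 1 g fresh
weight of leaf material holds about 1 ml of water:

    c_eff = fraction * amount / (volume_fraction * fw_to_volume)    [mM]

In a leaf mesophyll cell the cytosol is taken to occupy 5 % and the
vacuole 80 % of cell volume, so an equal amount placed in either
compartment is 16-fold more dilute in the vacuole.

The default sugar-distribution fractions (sucrose vs. hexoses, at
ambient 22 degC and cold 4 degC) are bundled as configuration defaults;
the per-compartment sucrose grid ranges used by the subcellular scans
are kept as explicit, authoritative inputs rather than re-derived from
the fractions, because no single convention reproduces all of them (see
docs/methods.md).  Both routes - the formula and the preset ranges - are
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

from .errors import ConfigError, DomainError
from .kinetics import FluxParameters, InvertaseParameters
from .model import ParameterScenario

__all__ = [
    "CompartmentSpec",
    "TissueAmounts",
    "effective_concentration",
    "dilution_factor",
    "default_cytosol",
    "default_vacuole",
    "DEFAULT_SUBCELLULAR_SUC_RANGES",
    "build_subcellular_scenarios",
]

# sugar-distribution fractions of the total cellular amount,
# keyed (sugar_class, temperature_label)
_CYTOSOL_FRACTIONS = {
    ("sucrose", "22C"): 0.50,
    ("hexose", "22C"): 0.30,
    ("sucrose", "4C"): 0.40,
    ("hexose", "4C"): 0.30,
}
_VACUOLE_FRACTIONS = {
    ("sucrose", "22C"): 0.25,
    ("hexose", "22C"): 0.55,
    ("sucrose", "4C"): 0.33,
    ("hexose", "4C"): 0.50,
}

#: Sucrose-plane ranges (mM) used for the bundled subcellular scans,
#: keyed (compartment, temperature_label).
DEFAULT_SUBCELLULAR_SUC_RANGES: Dict[Tuple[str, str], Tuple[float, float]] = {
    ("cytosol", "22C"): (8.0, 24.0),
    ("vacuole", "22C"): (0.25, 0.75),
    ("cytosol", "4C"): (25.6, 51.2),
    ("vacuole", "4C"): (1.32, 2.64),
}


@dataclass(frozen=True)
class CompartmentSpec:
    """A compartment's volume share and sugar-distribution fractions."""

    name: str
    volume_fraction: float
    sugar_fractions: Mapping[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.volume_fraction <= 1.0):
            raise DomainError("volume_fraction must be in (0, 1]")
        for key, frac in self.sugar_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise DomainError(f"sugar fraction {key} must be in [0, 1], got {frac}")

    def fraction(self, sugar: str, temperature_label: str) -> float:
        try:
            return self.sugar_fractions[(sugar, temperature_label)]
        except KeyError:
            raise ConfigError(
                f"no distribution fraction for ({sugar!r}, {temperature_label!r}) "
                f"in compartment {self.name!r}"
            ) from None


@dataclass(frozen=True)
class TissueAmounts:
    """Whole-tissue sugar amounts (umol gFW^-1) with the fresh-weight to
    water-volume conversion factor (ml gFW^-1, default 1)."""

    amounts: Mapping[str, float]
    fw_to_volume: float = 1.0

    def __post_init__(self):
        if self.fw_to_volume <= 0:
            raise DomainError("fw_to_volume must be > 0")
        for sugar, amount in self.amounts.items():
            if amount < 0:
                raise DomainError(f"amount of {sugar!r} must be >= 0")


def default_cytosol() -> CompartmentSpec:
    """Cytosol: 5 % of cell volume, with the default sugar fractions."""
    return CompartmentSpec("cytosol", 0.05, dict(_CYTOSOL_FRACTIONS))


def default_vacuole() -> CompartmentSpec:
    """Vacuole: 80 % of cell volume, with the default sugar fractions."""
    return CompartmentSpec("vacuole", 0.80, dict(_VACUOLE_FRACTIONS))


def effective_concentration(
    amounts: TissueAmounts,
    comp: CompartmentSpec,
    sugar: str,
    temperature_label: str,
) -> float:
    """Compartment-local concentration (mM) of a sugar.

    ``fraction * amount / (volume_fraction * fw_to_volume)`` - linear in
    the amount and the fraction, inversely linear in the volume share.
    """
    if sugar not in amounts.amounts:
        raise ConfigError(f"no tissue amount given for {sugar!r}")
    frac = comp.fraction(sugar, temperature_label)
    return frac * amounts.amounts[sugar] / (comp.volume_fraction * amounts.fw_to_volume)


def dilution_factor(comp_a: CompartmentSpec, comp_b: CompartmentSpec) -> float:
    """Fold dilution an amount experiences in ``comp_b`` relative to ``comp_a``,
    i.e. the volume ratio V_b / V_a (16 for the default vacuole vs. cytosol)."""
    if comp_a.volume_fraction <= 0 or comp_b.volume_fraction <= 0:
        raise DomainError("volume fractions must be > 0")
    return comp_b.volume_fraction / comp_a.volume_fraction


def build_subcellular_scenarios(
    invertase: Mapping[str, InvertaseParameters],
    fluxes: Mapping[str, FluxParameters],
    temperature_labels: Tuple[str, ...] = ("22C", "4C"),
    compartment_names: Tuple[str, ...] = ("cytosol", "vacuole"),
    suc_ranges: Mapping[Tuple[str, str], Tuple[float, float]] | None = None,
) -> List[Tuple[ParameterScenario, Tuple[float, float]]]:
    """Build per-compartment, per-temperature scenarios with their default
    sucrose grid ranges.

    ``invertase`` and ``fluxes`` are keyed either by compartment name
    (isoform differs between compartments) or by ``"compartment/temperature"``
    for full resolution.  Returns ``[(scenario, (suc_lo, suc_hi)), ...]``
    in temperature-major order.  User-supplied ``suc_ranges`` override the
    bundled defaults verbatim.
    """
    ranges = dict(DEFAULT_SUBCELLULAR_SUC_RANGES)
    if suc_ranges:
        ranges.update(suc_ranges)
    out: List[Tuple[ParameterScenario, Tuple[float, float]]] = []
    for temp in temperature_labels:
        for comp in compartment_names:
            inv = invertase.get(f"{comp}/{temp}", invertase.get(comp))
            flx = fluxes.get(f"{comp}/{temp}", fluxes.get(comp))
            if inv is None or flx is None:
                raise ConfigError(
                    f"missing invertase/flux parameters for compartment {comp!r}"
                )
            key = (comp, temp)
            if key not in ranges:
                raise ConfigError(f"no sucrose range for {key}")
            scenario = ParameterScenario(
                name=f"{temp}_{comp}",
                invertase=inv,
                fluxes=flx,
                temperature_label=temp,
                compartment_label=comp,
            )
            out.append((scenario, ranges[key]))
    return out
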