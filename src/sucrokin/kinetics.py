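"""Rate laws for sucrose cleavage and the surrounding fluxes.

The core reaction is invertase-catalysed hydrolysis of sucrose into
glucose and fructose.  Plant invertases are product inhibited: glucose
acts as a non-competitive inhibitor (it scales the whole rate) and
fructose as a competitive inhibitor (it raises the apparent Michaelis
constant).  The rate law used throughout the package encodes exactly
those two mechanisms in their textbook form::

    r_inv = v_max * S / [ (K_M * (1 + F/K_iF) + S) * (1 + G/K_iG) ]

with S, G, F the sucrose, glucose and fructose concentrations.  Users
holding an independently derived formula for a particular isoform can
verify or swap this form; every downstream derivative is hand-derived
from it (see :mod:`sucrokin.derivatives`).

Sucrose supply (``r_in``) is modelled as a constant influx; hexose
consumption (e.g. phosphorylation by hexokinase) as an irreversible
Michaelis-Menten, first-order, or zero efflux.

Units: concentrations are mM throughout; rates are mM h^-1, numerically
identical to umol h^-1 gFW^-1 under the convention that 1 g fresh weight
corresponds to about 1 ml of cell water.

All rate functions accept scalars or numpy arrays elementwise, which is
what makes dense grid scans cheap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigError, DomainError, InputError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "MassActionSpec",
    "InvertaseParameters",
    "EffluxKind",
    "EffluxLaw",
    "FluxParameters",
    "mass_action_rate",
    "invertase_rate",
    "invertase_rate_gradient",
    "invertase_rate_hessian",
    "efflux_rate",
]


def _check_nonnegative(name: str, value: ArrayLike) -> None:
    if np.any(np.asarray(value) < 0):
        raise DomainError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class MassActionSpec:
    """Generic reversible mass-action rate law.

    The net rate is ``k_f * prod(S_i^m_i) - k_b * prod(P_j^m_j)`` where
    ``m`` are the integer molecularities of the substrates and products.

    Parameters
    ----------
    k_f, k_b
        Forward and backward rate constants (per hour, adjusted for the
        concentration power of the respective product term).
    substrates, products
        Sequences of ``(species_id, molecularity)`` pairs.
    """

    k_f: float
    k_b: float
    substrates: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self):
        if self.k_f < 0 or self.k_b < 0:
            raise DomainError("rate constants must be >= 0")
        object.__setattr__(self, "substrates", tuple((s, int(m)) for s, m in self.substrates))
        object.__setattr__(self, "products", tuple((s, int(m)) for s, m in self.products))
        for species, m in (*self.substrates, *self.products):
            if m < 1:
                raise DomainError(f"molecularity of {species!r} must be an integer >= 1, got {m}")


@dataclass(frozen=True)
class InvertaseParameters:
    """Kinetic constants of the product-inhibited invertase reaction.

    Parameters
    ----------
    v_max
        Maximal hydrolysis rate (mM h^-1, numerically umol h^-1 gFW^-1).
    k_m
        Michaelis constant for sucrose (mM); low-millimolar for both the
        neutral (cytosolic) and acidic (vacuolar) isoforms.
    k_i_glc
        Non-competitive inhibition constant for glucose (mM).
    k_i_frc
        Competitive inhibition constant for fructose (mM).
    """

    v_max: float
    k_m: float
    k_i_glc: float
    k_i_frc: float

    def __post_init__(self):
        for name in ("k_m", "k_i_glc", "k_i_frc"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.v_max < 0:
            raise DomainError("v_max must be >= 0")


class EffluxKind(str, enum.Enum):
    MICHAELIS_MENTEN = "michaelis_menten"
    FIRST_ORDER = "first_order"
    ZERO = "zero"


@dataclass(frozen=True)
class EffluxLaw:
    """Hexose-consuming efflux: saturable (default), linear, or absent.

    ``michaelis_menten`` uses ``v_max * c / (k_m + c)``; ``first_order``
    uses ``k * c``; ``zero`` returns 0 identically.
    """

    kind: EffluxKind = EffluxKind.ZERO
    v_max: float = 0.0
    k_m: float = 1.0
    k: float = 0.0

    def __post_init__(self):
        kind = EffluxKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.v_max < 0 or self.k < 0:
            raise DomainError("efflux rate parameters must be >= 0")
        if kind is EffluxKind.MICHAELIS_MENTEN and self.k_m <= 0:
            raise DomainError("efflux k_m must be > 0")

    @classmethod
    def michaelis_menten(cls, v_max: float, k_m: float) -> "EffluxLaw":
        return cls(kind=EffluxKind.MICHAELIS_MENTEN, v_max=v_max, k_m=k_m)

    @classmethod
    def first_order(cls, k: float) -> "EffluxLaw":
        return cls(kind=EffluxKind.FIRST_ORDER, k=k)

    @classmethod
    def zero(cls) -> "EffluxLaw":
        return cls(kind=EffluxKind.ZERO)

    def rate(self, conc: ArrayLike) -> ArrayLike:
        _check_nonnegative("efflux substrate concentration", conc)
        if self.kind is EffluxKind.ZERO:
            return np.zeros_like(np.asarray(conc, dtype=float)) if np.ndim(conc) else 0.0
        if self.kind is EffluxKind.FIRST_ORDER:
            return self.k * conc
        if self.kind is EffluxKind.MICHAELIS_MENTEN:
            return self.v_max * conc / (self.k_m + conc)
        raise ConfigError(f"unknown efflux kind {self.kind!r}")

    def derivative(self, conc: ArrayLike) -> ArrayLike:
        """d(rate)/d(conc)."""
        _check_nonnegative("efflux substrate concentration", conc)
        if self.kind is EffluxKind.ZERO:
            return np.zeros_like(np.asarray(conc, dtype=float)) if np.ndim(conc) else 0.0
        if self.kind is EffluxKind.FIRST_ORDER:
            return self.k * np.ones_like(np.asarray(conc, dtype=float)) if np.ndim(conc) else self.k
        return self.v_max * self.k_m / (self.k_m + conc) ** 2

    def second_derivative(self, conc: ArrayLike) -> ArrayLike:
        """d^2(rate)/d(conc)^2 (non-zero only for the saturable law)."""
        _check_nonnegative("efflux substrate concentration", conc)
        if self.kind is EffluxKind.MICHAELIS_MENTEN:
            return -2.0 * self.v_max * self.k_m / (self.k_m + conc) ** 3
        return np.zeros_like(np.asarray(conc, dtype=float)) if np.ndim(conc) else 0.0


@dataclass(frozen=True)
class FluxParameters:
    """Boundary fluxes of the three-species system.

    ``r_in`` is the constant sucrose influx (biosynthesis / carbon
    uptake, mM h^-1); the two efflux laws consume glucose and fructose.
    """

    r_in: float
    efflux_glc: EffluxLaw = field(default_factory=EffluxLaw.zero)
    efflux_frc: EffluxLaw = field(default_factory=EffluxLaw.zero)

    def __post_init__(self):
        if self.r_in < 0:
            raise DomainError("r_in must be >= 0")


def mass_action_rate(spec: MassActionSpec, state: Mapping[str, float]) -> float:
    """Net mass-action rate ``k_f * prod(S_i^m_i) - k_b * prod(P_j^m_j)``."""
    forward = spec.k_f
    for species, m in spec.substrates:
        if species not in state:
            raise InputError(f"species {species!r} missing from state")
        conc = state[species]
        _check_nonnegative(f"concentration of {species!r}", conc)
        forward *= conc**m
    backward = spec.k_b
    for species, m in spec.products:
        if species not in state:
            raise InputError(f"species {species!r} missing from state")
        conc = state[species]
        _check_nonnegative(f"concentration of {species!r}", conc)
        backward *= conc**m
    if not spec.products:
        backward = 0.0
    return forward - backward


def _denominators(p: InvertaseParameters, glc: ArrayLike, frc: ArrayLike):
    """Competitive term A = K_M*(1+F/K_iF) and non-competitive term B = 1+G/K_iG."""
    a = p.k_m * (1.0 + frc / p.k_i_frc)
    b = 1.0 + glc / p.k_i_glc
    return a, b


def invertase_rate(
    p: InvertaseParameters, suc: ArrayLike, glc: ArrayLike, frc: ArrayLike
) -> ArrayLike:
    """Product-inhibited invertase rate at the given concentrations (mM).

    Bounded by ``v_max``; strictly increasing in sucrose and strictly
    decreasing in each hexose for positive sucrose.
    """
    for name, value in (("suc", suc), ("glc", glc), ("frc", frc)):
        _check_nonnegative(name, value)
    a, b = _denominators(p, glc, frc)
    return p.v_max * suc / ((a + suc) * b)


def invertase_rate_gradient(
    p: InvertaseParameters, suc: ArrayLike, glc: ArrayLike, frc: ArrayLike
) -> Tuple[ArrayLike, ArrayLike, ArrayLike]:
    """Closed-form gradient ``(dr/dS, dr/dG, dr/dF)`` of :func:`invertase_rate`.

    With A = K_M (1 + F/K_iF), B = 1 + G/K_iG and D = A + S:

    * dr/dS =  v_max A / (D^2 B)            (> 0)
    * dr/dG = -v_max S / (D B^2 K_iG)       (<= 0)
    * dr/dF = -v_max S K_M / (D^2 B K_iF)   (<= 0)
    """
    for name, value in (("suc", suc), ("glc", glc), ("frc", frc)):
        _check_nonnegative(name, value)
    a, b = _denominators(p, glc, frc)
    d = a + suc
    dr_ds = p.v_max * a / (d**2 * b)
    dr_dg = -p.v_max * suc / (d * b**2 * p.k_i_glc)
    dr_df = -p.v_max * suc * (p.k_m / p.k_i_frc) / (d**2 * b)
    return dr_ds, dr_dg, dr_df


def invertase_rate_hessian(
    p: InvertaseParameters, suc: ArrayLike, glc: ArrayLike, frc: ArrayLike
) -> dict:
    """Closed-form second partials of :func:`invertase_rate`.

    Returns the six unique entries keyed ``'ss', 'sg', 'sf', 'gg', 'gf',
    'ff'`` in the (Suc, Glc, Frc) variable ordering.  Derived by direct
    differentiation of the gradient, with a' = K_M/K_iF and b' = 1/K_iG:

    * r_SS = -2 v_max A / (D^3 B)
    * r_SG = -v_max A b' / (D^2 B^2)
    * r_SF =  v_max a' (S - A) / (D^3 B)
    * r_GG =  2 v_max S b'^2 / (D B^3)
    * r_GF =  v_max S a' b' / (D^2 B^2)
    * r_FF =  2 v_max S a'^2 / (D^3 B)
    """
    for name, value in (("suc", suc), ("glc", glc), ("frc", frc)):
        _check_nonnegative(name, value)
    a, b = _denominators(p, glc, frc)
    d = a + suc
    ap = p.k_m / p.k_i_frc
    bp = 1.0 / p.k_i_glc
    v = p.v_max
    return {
        "ss": -2.0 * v * a / (d**3 * b),
        "sg": -v * a * bp / (d**2 * b**2),
        "sf": v * ap * (suc - a) / (d**3 * b),
        "gg": 2.0 * v * suc * bp**2 / (d * b**3),
        "gf": v * suc * ap * bp / (d**2 * b**2),
        "ff": 2.0 * v * suc * ap**2 / (d**3 * b),
    }


def efflux_rate(p: FluxParameters, hexose: str, conc: ArrayLike) -> ArrayLike:
    """Hexose efflux rate for ``hexose`` in ``{'glc', 'frc'}``."""
    if hexose == "glc":
        law = p.efflux_glc
    elif hexose == "frc":
        law = p.efflux_frc
    else:
        raise ConfigError(f"unknown hexose {hexose!r}; expected 'glc' or 'frc'")
    return law.rate(conc)
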