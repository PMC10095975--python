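"""Dense concentration-grid evaluation of metabolic functions and their
derivative surfaces, with dynamic-range summaries and scenario comparison.

A scan evaluates f(Suc), f(Glc), f(Frc), all nine Jacobian entries and
the six unique Hessian entries of each metabolic function at every point
of a glucose x fructose grid for each sucrose plane, mirroring how the
regulatory landscape of sucrose cleavage is analysed: each sucrose plane
is a surface over the two hexose (inhibitor) axes.

Output is a long-format table with a fixed column order, deterministic
row ordering (sucrose-plane major, then glucose, then fructose) and a
JSON sidecar carrying the scenario, grid and software version, so that
re-running a scan with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .derivatives import hessian_entries, jacobian_entries
from .errors import DomainError, InputError
from .model import ParameterScenario, metabolic_functions

__all__ = [
    "GridSpec",
    "GridScanResult",
    "scan",
    "dynamic_range_summary",
    "interval_jaccard",
    "compare_scenarios",
    "COLUMNS",
]

_J_COLS = [f"j{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_H_COLS = [
    f"h{tag}{ij}"
    for tag in ("S", "G", "F")
    for ij in ("11", "12", "13", "22", "23", "33")
]
#: Fixed column order of the long-format scan table.
COLUMNS = ["scenario", "suc", "glc", "frc", "f_suc", "f_glc", "f_frc"] + _J_COLS + _H_COLS

_HESS_TAG = {"suc": "S", "glc": "G", "frc": "F"}


@dataclass(frozen=True)
class GridSpec:
    """Rectangular hexose grid plus a list of sucrose planes.

    ``units`` is a bookkeeping flag: under the 1 gFW ~ 1 ml convention,
    amounts in umol gFW^-1 are numerically equal to mM, so it does not
    rescale values.
    """

    glc_range: Tuple[float, float]
    frc_range: Tuple[float, float]
    suc_planes: Tuple[float, ...]
    n_glc: int = 50
    n_frc: int = 50
    units: str = "mM"

    def __post_init__(self):
        object.__setattr__(self, "suc_planes", tuple(float(s) for s in self.suc_planes))
        if len(self.suc_planes) < 1:
            raise DomainError("at least one sucrose plane is required")
        if self.n_glc < 1 or self.n_frc < 1:
            raise DomainError("grid point counts must be >= 1")
        for name, (lo, hi), n in (
            ("glc", self.glc_range, self.n_glc),
            ("frc", self.frc_range, self.n_frc),
        ):
            if lo < 0 or hi < 0:
                raise DomainError(f"{name} range must be non-negative")
            if n > 1 and not hi > lo:
                raise DomainError(f"{name} range is degenerate for {n} points")
        if self.units not in ("mM", "umol_gFW"):
            raise DomainError("units must be 'mM' or 'umol_gFW'")

    def glc_values(self) -> np.ndarray:
        return np.linspace(self.glc_range[0], self.glc_range[1], self.n_glc)

    def frc_values(self) -> np.ndarray:
        return np.linspace(self.frc_range[0], self.frc_range[1], self.n_frc)

    @property
    def n_points(self) -> int:
        return len(self.suc_planes) * self.n_glc * self.n_frc

    @classmethod
    def from_suc_range(
        cls,
        suc_range: Tuple[float, float],
        glc_range: Tuple[float, float],
        frc_range: Tuple[float, float],
        n_planes: int = 3,
        n_glc: int = 50,
        n_frc: int = 50,
        units: str = "mM",
    ) -> "GridSpec":
        """Planes at evenly spaced points of ``suc_range`` (endpoints plus
        midpoints; default 3 planes)."""
        planes = tuple(np.linspace(suc_range[0], suc_range[1], n_planes))
        return cls(glc_range, frc_range, planes, n_glc, n_frc, units)


@dataclass(frozen=True)
class GridScanResult:
    """Long-format scan table plus provenance (scenario name, grid echo)."""

    frame: pd.DataFrame
    scenario_name: str
    grid: GridSpec
    include_efflux: bool = False

    def write(self, csv_path: str | Path) -> Path:
        """Write the table as CSV with a `<name>.meta.json` sidecar."""
        csv_path = Path(csv_path)
        self.frame.to_csv(csv_path, index=False, float_format="%.17g")
        sidecar = {
            "scenario": self.scenario_name,
            "grid": asdict(self.grid),
            "include_efflux": self.include_efflux,
            "units": self.grid.units,
            "n_records": int(len(self.frame)),
            "version": __version__,
        }
        meta_path = csv_path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
        return meta_path


def scan(
    scenario: ParameterScenario, grid: GridSpec, include_efflux: bool = False
) -> GridScanResult:
    """Evaluate functions, Jacobian and Hessians over the full grid.

    Row ordering is deterministic: sucrose-plane major, then glucose,
    then fructose (fructose varies fastest).
    """
    glc = grid.glc_values()
    frc = grid.frc_values()
    gg, ff = np.meshgrid(glc, frc, indexing="ij")  # glc outer, frc inner
    gg, ff = gg.ravel(), ff.ravel()
    blocks: List[pd.DataFrame] = []
    for suc_plane in grid.suc_planes:
        ss = np.full_like(gg, suc_plane)
        state = (ss, gg, ff)
        try:
            f_suc, f_glc, f_frc = metabolic_functions(scenario, state, include_efflux)
            jac = jacobian_entries(scenario, state, include_efflux)
        except DomainError as err:
            raise DomainError(
                f"scan aborted at sucrose plane {suc_plane}: {err}"
            ) from err
        cols: Dict[str, np.ndarray] = {
            "scenario": np.full(gg.shape, scenario.name, dtype=object),
            "suc": ss,
            "glc": gg,
            "frc": ff,
            "f_suc": np.broadcast_to(f_suc, gg.shape),
            "f_glc": np.broadcast_to(f_glc, gg.shape),
            "f_frc": np.broadcast_to(f_frc, gg.shape),
        }
        for name in _J_COLS:
            cols[name] = np.broadcast_to(jac[name], gg.shape)
        for which, tag in _HESS_TAG.items():
            h = hessian_entries(scenario, state, which, include_efflux)
            for ij, values in h.items():
                cols[f"h{tag}{ij}"] = np.broadcast_to(values, gg.shape)
        blocks.append(pd.DataFrame(cols, columns=COLUMNS))
    frame = pd.concat(blocks, ignore_index=True)
    return GridScanResult(
        frame=frame,
        scenario_name=scenario.name,
        grid=grid,
        include_efflux=include_efflux,
    )


def dynamic_range_summary(result: GridScanResult) -> pd.DataFrame:
    """Per-quantity min, max, range and order-of-magnitude span.

    The decade span is ``log10(max |x|) - log10(min nonzero |x|)``; for a
    column that is identically zero it is reported as NaN (undefined).
    """
    frame = result.frame
    if frame.empty:
        raise InputError("cannot summarise an empty scan")
    rows = []
    for col in COLUMNS[4:]:
        values = frame[col].to_numpy(dtype=float)
        absval = np.abs(values)
        nonzero = absval[absval > 0]
        span = (
            float(np.log10(nonzero.max()) - np.log10(nonzero.min()))
            if nonzero.size
            else float("nan")
        )
        rows.append(
            {
                "quantity": col,
                "min": float(values.min()),
                "max": float(values.max()),
                "range": float(values.max() - values.min()),
                "decade_span": span,
            }
        )
    return pd.DataFrame(rows).set_index("quantity")


def interval_jaccard(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Jaccard overlap of two closed intervals (0 = disjoint, 1 = identical)."""
    lo_a, hi_a = min(a), max(a)
    lo_b, hi_b = min(b), max(b)
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    union = max(hi_a, hi_b) - min(lo_a, lo_b)
    if union == 0.0:
        return 1.0
    return inter / union


def _value_interval(frame: pd.DataFrame, col: str) -> Tuple[float, float]:
    v = frame[col].to_numpy(dtype=float)
    return float(v.min()), float(v.max())


def compare_scenarios(a: GridScanResult, b: GridScanResult, quantity: str) -> Dict:
    """Compare the dynamic range of one scanned quantity between two scans.

    Also reports, for each scan, the Jaccard overlap of the value
    intervals of j12 and j13 - an operationalisation of how strongly the
    glucose and fructose sensitivities of f(Suc) overlap across the grid.
    """
    for result in (a, b):
        if quantity not in result.frame.columns:
            raise InputError(f"quantity {quantity!r} not present in scan of "
                             f"{result.scenario_name!r}")
    range_a = float(a.frame[quantity].max() - a.frame[quantity].min())
    range_b = float(b.frame[quantity].max() - b.frame[quantity].min())
    overlap_a = interval_jaccard(_value_interval(a.frame, "j12"), _value_interval(a.frame, "j13"))
    overlap_b = interval_jaccard(_value_interval(b.frame, "j12"), _value_interval(b.frame, "j13"))
    return {
        "quantity": quantity,
        "scenario_a": a.scenario_name,
        "scenario_b": b.scenario_name,
        "range_a": range_a,
        "range_b": range_b,
        "range_ratio": range_a / range_b if range_b != 0 else float("inf"),
        "j12_j13_overlap_a": overlap_a,
        "j12_j13_overlap_b": overlap_b,
    }
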