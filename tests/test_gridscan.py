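"""Grid scans: ordering, identities, summaries and scenario comparison."""

import numpy as np
import pandas as pd
import pytest

from sucrokin import (
    DomainError,
    FluxParameters,
    InputError,
    InvertaseParameters,
    MetabolicState,
    ParameterScenario,
    evaluate,
    GridSpec,
    scan,
    compare_scenarios,
    dynamic_range_summary,
)
from sucrokin.gridscan import COLUMNS, interval_jaccard


@pytest.fixture
def small_grid():
    return GridSpec(glc_range=(0.1, 3.0), frc_range=(0.1, 3.0),
                    suc_planes=(1.0, 2.0, 3.0), n_glc=6, n_frc=6)


def test_single_point_grid_matches_direct_evaluation(scan_scenario):
    grid = GridSpec((1.5, 1.5), (0.7, 0.7), (2.0,), n_glc=1, n_frc=1)
    frame = scan(scan_scenario, grid).frame
    assert len(frame) == 1
    ev = evaluate(scan_scenario, MetabolicState(2.0, 1.5, 0.7))
    row = frame.iloc[0]
    assert row["f_suc"] == pytest.approx(ev.f_suc)
    assert row["j11"] == pytest.approx(ev.jacobian[0, 0])
    assert row["hS13"] == pytest.approx(ev.hessians["suc"][0, 2])


def test_zero_vmax_gives_flat_f_suc_surface(small_grid):
    inv = InvertaseParameters(v_max=0.0, k_m=2.0, k_i_glc=5.0, k_i_frc=5.0)
    sc = ParameterScenario("flat", inv, FluxParameters(r_in=0.7))
    frame = scan(sc, small_grid).frame
    assert np.allclose(frame["f_suc"], 0.7)


def test_record_count_and_column_layout(scan_scenario, small_grid):
    result = scan(scan_scenario, small_grid)
    assert len(result.frame) == small_grid.n_points == 3 * 6 * 6
    assert list(result.frame.columns) == COLUMNS
    assert not result.frame.isna().any().any()


def test_row_ordering_is_plane_major_then_glc_then_frc(scan_scenario, small_grid):
    frame = scan(scan_scenario, small_grid).frame
    assert list(frame["suc"][:36]) == [1.0] * 36
    first_plane = frame[:36]
    # fructose varies fastest
    assert first_plane["frc"].iloc[0] < first_plane["frc"].iloc[1]
    assert first_plane["glc"].iloc[0] == first_plane["glc"].iloc[5]
    assert first_plane["glc"].iloc[6] > first_plane["glc"].iloc[5]


def test_scan_minimum_of_f_suc_at_low_product_high_sucrose_corner(scan_scenario, small_grid):
    """Cleavage peaks (f(Suc) most negative) at minimal hexoses, maximal sucrose."""
    frame = scan(scan_scenario, small_grid).frame
    idx = frame["f_suc"].idxmin()
    row = frame.loc[idx]
    assert row["suc"] == max(small_grid.suc_planes)
    assert row["glc"] == small_grid.glc_range[0]
    assert row["frc"] == small_grid.frc_range[0]


def test_rescan_is_byte_identical(scan_scenario, small_grid, tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    scan(scan_scenario, small_grid).write(p1)
    scan(scan_scenario, small_grid).write(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_every_record_satisfies_hexose_balance(scenario, small_grid):
    frame = scan(scenario, small_grid, include_efflux=True).frame
    lhs = 2 * frame["f_suc"] + frame["f_glc"] + frame["f_frc"]
    rhs = (
        2 * scenario.fluxes.r_in
        - scenario.fluxes.efflux_glc.rate(frame["glc"].to_numpy())
        - scenario.fluxes.efflux_frc.rate(frame["frc"].to_numpy())
    )
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


def test_grid_refinement_keeps_extrema_within_cell_bound(scan_scenario):
    """Halving step sizes moves min/max of the monotone f_suc surface by
    less than one coarse-grid cell's worth of variation."""
    coarse = GridSpec((0.1, 3.0), (0.1, 3.0), (1.0, 2.0, 3.0), n_glc=6, n_frc=6)
    fine = GridSpec((0.1, 3.0), (0.1, 3.0), (1.0, 2.0, 3.0), n_glc=11, n_frc=11)
    fc = scan(scan_scenario, coarse).frame["f_suc"]
    ff = scan(scan_scenario, fine).frame["f_suc"]
    cell_bound = (fc.max() - fc.min()) / 5  # 5 coarse intervals per axis
    assert abs(fc.min() - ff.min()) < cell_bound
    assert abs(fc.max() - ff.max()) < cell_bound


def test_degenerate_range_rejected():
    with pytest.raises(DomainError):
        GridSpec((1.0, 1.0), (0.0, 1.0), (1.0,), n_glc=5, n_frc=5)


class TestDynamicRangeSummary:
    def test_constant_column_has_zero_range(self, small_grid):
        inv = InvertaseParameters(v_max=0.0, k_m=2.0, k_i_glc=5.0, k_i_frc=5.0)
        sc = ParameterScenario("flat", inv, FluxParameters(r_in=0.7))
        summary = dynamic_range_summary(scan(sc, small_grid))
        assert summary.loc["f_suc", "range"] == 0.0
        # all-zero derivative columns have an undefined decade span
        assert np.isnan(summary.loc["j11", "decade_span"])

    def test_two_decade_span(self, scan_scenario, small_grid):
        result = scan(scan_scenario, small_grid)
        doctored = result.frame.copy()
        doctored["f_glc"] = np.linspace(0.1, 10.0, len(doctored))
        summary = dynamic_range_summary(
            type(result)(doctored, result.scenario_name, result.grid)
        )
        assert summary.loc["f_glc", "decade_span"] == pytest.approx(2.0)


class TestCompareScenarios:
    def test_self_comparison_is_identity(self, scan_scenario, small_grid):
        a = scan(scan_scenario, small_grid)
        record = compare_scenarios(a, a, "f_suc")
        assert record["range_ratio"] == pytest.approx(1.0)
        assert record["j12_j13_overlap_a"] == record["j12_j13_overlap_b"]

    def test_scaled_scan_gives_reciprocal_range_ratio(self, scan_scenario, small_grid):
        a = scan(scan_scenario, small_grid)
        scaled = a.frame.copy()
        for col in COLUMNS[4:]:
            scaled[col] = 0.1 * scaled[col]
        b = type(a)(scaled, "scaled", small_grid)
        record = compare_scenarios(a, b, "f_suc")
        assert record["range_ratio"] == pytest.approx(10.0)

    def test_unknown_quantity_rejected(self, scan_scenario, small_grid):
        a = scan(scan_scenario, small_grid)
        with pytest.raises(InputError):
            compare_scenarios(a, a, "bogus")


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0.0, 1.0), (0.0, 1.0), 1.0),
        ((0.0, 1.0), (2.0, 3.0), 0.0),
        ((0.0, 2.0), (1.0, 3.0), 1.0 / 3.0),
    ],
)
def test_interval_jaccard(a, b, expected):
    assert interval_jaccard(a, b) == pytest.approx(expected)
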