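"""Least-cost country optimisation, spin-up and agricultural competition."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_cells
from woodsim.optimizer import (
    FRACTION_COLUMNS,
    CostParams,
    apply_agricultural_demand,
    cell_yield,
    optimize_country,
    required_harvest,
    spinup_abandonment,
)
from woodsim.yields import R_MAX, R_MIN

COSTS = CostParams()


def timber_area(cells):
    return (cells["area_ha"] * cells["frac_timber"]).to_numpy(float)


def max_harvest(cells):
    A = timber_area(cells)
    return float((A * cell_yield(R_MAX, cells["ymax"].to_numpy(),
                                 cells["k"].to_numpy(), cells["p"].to_numpy())).sum())


def assert_land_conserved(before, after):
    s_before = before[FRACTION_COLUMNS].sum(axis=1).to_numpy()
    s_after = after[FRACTION_COLUMNS].sum(axis=1).to_numpy()
    assert np.abs(s_after - 1.0).max() < 1e-12
    assert np.abs(s_before - 1.0).max() < 1e-12


class TestRequiredHarvest:
    def test_netting_and_clipping(self):
        assert required_harvest(60, 40, 30) == pytest.approx(70)
        assert required_harvest(60, 40, 150) == 0.0
        assert required_harvest(60, 40, 0) == pytest.approx(100)

    def test_negative_demand_rejected(self):
        with pytest.raises(ValueError):
            required_harvest(-1, 0, 0)


class TestOptimizeCountry:
    def test_single_cell_matches_bisection_oracle(self):
        rng = np.random.default_rng(1)
        cells = random_cells(1, rng)
        A = timber_area(cells)[0]
        ymax, k, p = cells.ymax[0], cells.k[0], cells.p[0]
        target = 0.6 * A * cell_yield(R_MAX, ymax, k, p)
        dec = optimize_country(target, cells, COSTS)
        lo, hi = R_MIN, R_MAX
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if A * cell_yield(mid, ymax, k, p) < target:
                lo = mid
            else:
                hi = mid
        assert dec.cells["intensity"][0] == pytest.approx(hi, abs=1e-8)
        assert dec.realised_harvest == pytest.approx(target, rel=1e-9)

    def test_zero_requirement_minimum_intensity_no_expansion(self):
        rng = np.random.default_rng(2)
        cells = random_cells(3, rng)
        dec = optimize_country(0.0, cells, COSTS)
        assert (dec.cells.loc[dec.cells["frac_timber"] > 0, "intensity"]
                == R_MIN).all()
        assert dec.expanded_ha == 0.0
        assert dec.shortfall == 0.0

    def test_grid_search_oracle_small_instances(self):
        """Solver cost within 0.5% of exhaustive grid search on random
        instances of up to three cells."""
        rng = np.random.default_rng(12345)
        for _ in range(30):
            n = int(rng.integers(1, 4))
            cells = random_cells(n, rng)
            A = timber_area(cells)
            ymax = cells["ymax"].to_numpy()
            k = cells["k"].to_numpy()
            p = cells["p"].to_numpy()
            h_min = (A * cell_yield(R_MIN, ymax, k, p)).sum()
            h_max = (A * cell_yield(R_MAX, ymax, k, p)).sum()
            target = h_min + rng.uniform(0.05, 0.95) * (h_max - h_min)
            dec = optimize_country(target, cells, COSTS, refine=True,
                                   allow_expansion=False)
            npts = {1: 2000, 2: 250, 3: 75}[n]
            gr = np.linspace(R_MIN, R_MAX, npts)
            ys = [A[i] * cell_yield(gr, ymax[i], k[i], p[i]) for i in range(n)]
            grids = np.meshgrid(*[gr] * n, indexing="ij")
            H = sum(np.meshgrid(*ys, indexing="ij")[i] for i in range(n))
            C = sum(A[i] * grids[i] for i in range(n))
            oracle = np.where(H >= target, C, np.inf).min()
            assert dec.realised_harvest >= target * (1 - 1e-9)
            assert dec.cost / COSTS.management_cost <= oracle * 1.005

    def test_cost_monotone_in_requirement(self):
        rng = np.random.default_rng(9)
        cells = random_cells(5, rng)
        targets = np.linspace(0.0, 1.2 * max_harvest(cells), 12)
        costs = [optimize_country(t, cells, COSTS).cost for t in targets]
        assert (np.diff(costs) >= -1e-6 * max(costs)).all()

    def test_contraction_when_oversupplied(self):
        rng = np.random.default_rng(4)
        cells = random_cells(4, rng)
        A = timber_area(cells)
        h_min = (A * cell_yield(R_MIN, cells["ymax"].to_numpy(),
                                cells["k"].to_numpy(), cells["p"].to_numpy())).sum()
        dec = optimize_country(0.5 * h_min, cells, COSTS)
        assert dec.realised_harvest == pytest.approx(0.5 * h_min, rel=1e-9)
        assert timber_area(dec.cells).sum() < A.sum()
        assert_land_conserved(cells, dec.cells)

    def test_infeasible_requirement_reports_shortfall(self):
        rng = np.random.default_rng(5)
        cells = random_cells(2, rng)
        cells["protected"] = True  # no expansion possible
        need = 2.0 * max_harvest(cells)
        dec = optimize_country(need, cells, COSTS)
        assert dec.shortfall == pytest.approx(need - dec.realised_harvest)
        assert dec.shortfall > 0
        assert np.allclose(
            dec.cells.loc[dec.cells["frac_timber"] > 0, "intensity"], R_MAX)

    def test_empty_cell_set_full_shortfall(self):
        cells = random_cells(1, np.random.default_rng(0)).iloc[:0]
        dec = optimize_country(1000.0, cells, COSTS)
        assert dec.shortfall == 1000.0

    def test_expansion_spares_protected_unmanaged_forest(self):
        rng = np.random.default_rng(6)
        cells = random_cells(4, rng)
        cells["protected"] = [True, False, True, False]
        before = cells["frac_unmanaged"].copy()
        need = 1.5 * max_harvest(cells)
        dec = optimize_country(need, cells, COSTS)
        protected = dec.cells["protected"]
        assert (dec.cells.loc[protected, "frac_unmanaged"].to_numpy()
                >= before[protected.to_numpy()].to_numpy() - 1e-12).all()
        assert dec.expanded_ha > 0  # unprotected cells did expand
        assert_land_conserved(cells, dec.cells)


class TestSpinup:
    def test_viable_cells_unchanged(self):
        cells = random_cells(3, np.random.default_rng(7))
        out = spinup_abandonment(cells, 0.0)
        pd.testing.assert_frame_equal(out, cells)

    def test_zero_yield_cell_abandoned_land_conserved(self):
        cells = random_cells(3, np.random.default_rng(8))
        cells.loc[1, "ymax"] = 0.0
        out = spinup_abandonment(cells, 0.5)
        assert out.loc[1, "frac_timber"] == 0.0
        assert out.loc[1, "frac_unmanaged"] == pytest.approx(
            cells.loc[1, "frac_unmanaged"] + cells.loc[1, "frac_timber"])
        assert_land_conserved(cells, out)

    def test_infinite_threshold_abandons_everything(self):
        cells = random_cells(3, np.random.default_rng(9))
        out = spinup_abandonment(cells, np.inf)
        assert (out["frac_timber"] == 0.0).all()


class TestAgriculturalDemand:
    def test_flat_trajectory_no_change(self):
        cells = random_cells(4, np.random.default_rng(10))
        current = float((cells["area_ha"] * cells["frac_agri"]).sum())
        out = apply_agricultural_demand(cells, current)
        pd.testing.assert_frame_equal(out, cells.reset_index(drop=True))

    def test_expansion_bookkeeping(self):
        cells = random_cells(4, np.random.default_rng(11))
        current = float((cells["area_ha"] * cells["frac_agri"]).sum())
        out = apply_agricultural_demand(cells, current + 10_000.0)
        new = float((out["area_ha"] * out["frac_agri"]).sum())
        assert new == pytest.approx(current + 10_000.0)
        unman_before = float((cells["area_ha"] * cells["frac_unmanaged"]).sum())
        unman_after = float((out["area_ha"] * out["frac_unmanaged"]).sum())
        assert unman_before - unman_after == pytest.approx(10_000.0)
        assert_land_conserved(cells, out)

    def test_expansion_order_matches_sort_oracle(self):
        """Least productive unmanaged forest is converted first."""
        cells = random_cells(5, np.random.default_rng(12))
        y = cell_yield(R_MAX, cells["ymax"].to_numpy(), cells["k"].to_numpy(),
                       cells["p"].to_numpy())
        first = int(np.lexsort((cells["cell"].to_numpy(), y))[0])
        avail0 = cells.loc[first, "frac_unmanaged"] * cells.loc[first, "area_ha"]
        current = float((cells["area_ha"] * cells["frac_agri"]).sum())
        out = apply_agricultural_demand(cells, current + 0.5 * avail0)
        assert out.loc[first, "frac_unmanaged"] < cells.loc[first, "frac_unmanaged"]
        others = [i for i in range(5) if i != first]
        assert np.allclose(out.loc[others, "frac_unmanaged"],
                           cells.loc[others, "frac_unmanaged"])

    def test_contraction_returns_land_to_unmanaged(self):
        cells = random_cells(4, np.random.default_rng(13))
        current = float((cells["area_ha"] * cells["frac_agri"]).sum())
        out = apply_agricultural_demand(cells, 0.5 * current)
        assert float((out["area_ha"] * out["frac_agri"]).sum()) == pytest.approx(
            0.5 * current)
        assert_land_conserved(cells, out)

    def test_excess_demand_rejected(self):
        cells = random_cells(2, np.random.default_rng(14))
        total = float(cells["area_ha"].sum())
        with pytest.raises(ValueError, match="exceeds"):
            apply_agricultural_demand(cells, 2.0 * total)
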