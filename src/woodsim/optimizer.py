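"""Per-country least-cost timber area and management-intensity choice.

Each country must harvest its wood demand net of trade.  Harvest can be
raised by intensifying management on existing timber forest (annual
cost c*r per hectare) or by expanding timber forest into unmanaged
forest (one-off conversion cost per hectare).  The solver allocates
greedily by marginal harvest per marginal cost: per-cell intensity
increments are pooled to non-increasing marginal yield (pool-adjacent-
violators) and consumed globally in descending order, which solves the
Karush-Kuhn-Tucker conditions of the continuous problem to grid
resolution; an optional SLSQP refinement polishes small instances.
Expansion starts when intensification is exhausted, cheapest effective
cubic metre first; conversely, when even minimum-intensity management
would oversupply the requirement, timber area contracts (least
productive land abandoned to unmanaged forest first).  An infeasible
requirement returns maximal harvest with a positive shortfall for the
market to import from stock.

Cells are rows of a DataFrame with columns
{cell, area_ha, frac_timber, frac_unmanaged, frac_agri, frac_other,
 intensity, ymax, k, p, protected}; fractions sum to one per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .yields import R_MAX, R_MIN

CELL_COLUMNS = [
    "cell", "area_ha", "frac_timber", "frac_unmanaged", "frac_agri",
    "frac_other", "intensity", "ymax", "k", "p", "protected",
]
FRACTION_COLUMNS = ["frac_timber", "frac_unmanaged", "frac_agri", "frac_other"]


@dataclass(frozen=True)
class CostParams:
    """Cost structure of the land-use decision (scenario-scaled)."""

    management_cost: float = 300.0     # currency per ha per unit intensity-year
    conversion_cost: float = 1500.0    # currency per ha converted to timber
    trade_change_cost: float = 5.0     # currency per m3 of net-import change

    def __post_init__(self):
        if min(self.management_cost, self.conversion_cost, self.trade_change_cost) < 0:
            raise ValueError("costs must be nonnegative")


@dataclass
class CountryDecision:
    cells: pd.DataFrame
    realised_harvest: float
    shortfall: float
    cost: float
    expanded_ha: float = 0.0


def validate_cells(cells: pd.DataFrame) -> None:
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cells missing columns: {sorted(missing)}")
    frac = cells[FRACTION_COLUMNS].to_numpy()
    if (frac < -1e-12).any():
        raise ValueError("land-cover fractions must be nonnegative")
    if len(cells) and np.abs(frac.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("land-cover fractions must sum to 1")
    has_timber = cells["frac_timber"] > 0
    r = cells.loc[has_timber, "intensity"]
    if ((r < R_MIN - 1e-12) | (r > R_MAX + 1e-12)).any():
        raise ValueError("management intensity out of bounds on timber cells")


def cell_yield(r, ymax, k, p):
    """Vectorised annualised harvest per hectare with per-cell params."""
    r = np.asarray(r, float)
    return ymax * (1.0 - np.exp(k * np.power(r, p))) * r


def required_harvest(demand_roundwood, demand_woodfuel, net_imports) -> float:
    """Country harvest requirement: pooled wood demand net of imports."""
    if demand_roundwood < 0 or demand_woodfuel < 0:
        raise ValueError("demand must be nonnegative")
    return max(0.0, float(demand_roundwood) + float(demand_woodfuel) - float(net_imports))


def _pav_slopes(dy: np.ndarray, dr: np.ndarray):
    """Pool adjacent grid steps until marginal yield dy/dr is non-increasing."""
    blocks = [[dy[j], dr[j]] for j in range(dy.size)]
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-1][0] * out[-2][1] > out[-2][0] * out[-1][1]:
            y2, r2 = out.pop()
            out[-1][0] += y2
            out[-1][1] += r2
    return np.array([b[0] for b in out]), np.array([b[1] for b in out])


def _allocate_intensity(required, area, ymax, k, p, n_grid=384):
    """Greedy marginal allocation of r over cells with timber area.

    Intensity increments on a shared r grid are consumed globally in
    descending order of marginal yield per unit cost.  Marginal cost of
    dr in a cell is proportional to its area, so the ordering key is
    simply dy/dr per hectare; cells whose yield curve is not concave
    have their increments pooled to non-increasing slopes first, which
    keeps the greedy order feasible (concavification).
    """
    r_grid = np.geomspace(R_MIN, R_MAX, n_grid)
    r = np.full(area.size, R_MIN)
    total = float((area * cell_yield(R_MIN, ymax, k, p)).sum())
    if total >= required or not (area > 0).any():
        return r, total

    dr = np.diff(r_grid)
    y_ha = cell_yield(r_grid[None, :], ymax[:, None], k[:, None], p[:, None])
    dy_ha = np.diff(y_ha, axis=1)
    slopes = dy_ha / dr[None, :]
    # pool increments where slopes are not non-increasing (rare)
    rows = np.where(np.diff(slopes, axis=1).max(axis=1) > 1e-12)[0]
    dy_cell = dy_ha * area[:, None]
    dr_cell = np.broadcast_to(dr, dy_ha.shape).copy()
    for i in rows:
        dy_b, dr_b = _pav_slopes(dy_cell[i], dr_cell[i])
        dy_cell[i] = 0.0
        dr_cell[i] = 0.0
        dy_cell[i, : dy_b.size] = dy_b
        dr_cell[i, : dr_b.size] = dr_b
        slopes[i] = -np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            s = dy_b / (area[i] * dr_b)
        slopes[i, : s.size] = np.where(np.isfinite(s), s, -np.inf)

    flat_dy = dy_cell.ravel()
    flat_dr = dr_cell.ravel()
    order = np.argsort(-slopes.ravel(), kind="stable")
    cum = np.cumsum(np.maximum(flat_dy[order], 0.0))
    need = required - total
    m = int(np.searchsorted(cum, need))
    cell_of = order[: m + 1] // dy_cell.shape[1]
    take = np.ones(min(m + 1, order.size))
    if m < order.size and flat_dy[order[m]] > 0:
        prev = cum[m - 1] if m > 0 else 0.0
        take[-1] = (need - prev) / flat_dy[order[m]]
    elif m >= order.size:
        cell_of = order // dy_cell.shape[1]
        take = np.ones(order.size)
    dr_taken = np.bincount(cell_of, weights=flat_dr[order[: cell_of.size]] * take,
                           minlength=area.size)
    r = np.minimum(R_MIN + dr_taken, R_MAX)
    return r, float((area * cell_yield(r, ymax, k, p)).sum())


def _trim_overshoot(required, area, ymax, k, p, r):
    """Lower intensities so realised harvest meets the requirement exactly.

    The greedy grid allocation can overshoot by part of one pooled
    block; trimming the highest-intensity cells back (bisection on a
    single cell's r) removes the overshoot, strictly lowering cost.
    """
    total = float((area * cell_yield(r, ymax, k, p)).sum())
    for i in np.argsort(-r, kind="stable"):
        if total <= required * (1 + 1e-12):
            break
        if r[i] <= R_MIN or area[i] <= 0:
            continue
        y_i = area[i] * cell_yield(r[i], ymax[i], k[i], p[i])
        others = total - y_i
        target_i = required - others
        if target_i >= y_i:
            continue
        y_floor = area[i] * cell_yield(R_MIN, ymax[i], k[i], p[i])
        if target_i <= y_floor:
            r[i] = R_MIN
            total = others + y_floor
            continue
        lo, hi = R_MIN, r[i]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if area[i] * cell_yield(mid, ymax[i], k[i], p[i]) < target_i:
                lo = mid
            else:
                hi = mid
        r[i] = hi
        total = others + area[i] * cell_yield(hi, ymax[i], k[i], p[i])
    return r, total


def _refine_intensity(required, area, ymax, k, p, r0):
    """SLSQP polish of the greedy allocation (small instances)."""
    active = area > 0
    if not active.any():
        return r0
    idx = np.where(active)[0]

    def cost(rv):
        return float((area[idx] * rv).sum())

    def harvest(rv):
        return float((area[idx] * cell_yield(rv, ymax[idx], k[idx], p[idx])).sum())

    res = minimize(
        cost, r0[idx], method="SLSQP",
        bounds=[(R_MIN, R_MAX)] * idx.size,
        constraints=[{"type": "ineq", "fun": lambda rv: harvest(rv) - required}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success and harvest(res.x) >= required - 1e-6 * max(required, 1.0):
        out = r0.copy()
        out[idx] = np.clip(res.x, R_MIN, R_MAX)
        if (area * out).sum() <= (area * r0).sum():
            return out
    return r0


def optimize_country(
    required: float,
    cells: pd.DataFrame,
    costs: CostParams,
    *,
    allow_expansion: bool = True,
    refine: bool = False,
) -> CountryDecision:
    """Least-cost intensities/areas meeting a harvest requirement.

    Returns the updated cells plus realised harvest, shortfall and the
    decision cost (management + conversion).  Protected cells never
    lose unmanaged forest to timber expansion.
    """
    validate_cells(cells)
    out = cells.copy().reset_index(drop=True)
    area = (out["area_ha"] * out["frac_timber"]).to_numpy(float)
    ymax = out["ymax"].to_numpy(float)
    k = out["k"].to_numpy(float)
    p = out["p"].to_numpy(float)

    if required <= 0:
        r = np.where(out["frac_timber"] > 0, R_MIN, out["intensity"])
        out["intensity"] = r
        realised = float((area * cell_yield(np.full(len(out), R_MIN), ymax, k, p)).sum())
        return CountryDecision(out, realised, 0.0,
                               costs.management_cost * float((area * R_MIN).sum()))

    if len(out) == 0 or (area.sum() == 0 and not allow_expansion):
        return CountryDecision(out, 0.0, float(required), 0.0)

    total_area = out["area_ha"].to_numpy(float)
    y_min_ha = cell_yield(R_MIN, ymax, k, p)
    base = area * y_min_ha
    if base.sum() > required:
        # even minimum management oversupplies: contract timber area,
        # least productive land abandoned (to unmanaged forest) first
        excess = float(base.sum() - required)
        order = np.lexsort((out["cell"].to_numpy(), y_min_ha))
        released = np.zeros(len(out))
        for i in order:
            if excess <= 0:
                break
            if base[i] <= 0:
                continue
            drop = min(base[i], excess)
            released[i] = drop / y_min_ha[i]
            area[i] -= released[i]
            excess -= drop
        d_frac = np.divide(released, total_area, out=np.zeros_like(released),
                           where=total_area > 0)
        out["frac_timber"] = out["frac_timber"] - d_frac
        out["frac_unmanaged"] = out["frac_unmanaged"] + d_frac
        out["intensity"] = np.where(area > 0, R_MIN, out["intensity"])
        realised = float((area * y_min_ha).sum())
        return CountryDecision(
            out, realised, 0.0,
            costs.management_cost * float((area * R_MIN).sum()))

    r, realised = _allocate_intensity(required, area, ymax, k, p)
    if realised > required:
        r, realised = _trim_overshoot(required, area, ymax, k, p, r)
    if refine and realised >= required:
        r = _refine_intensity(required, area, ymax, k, p, r)
        realised = float((area * cell_yield(r, ymax, k, p)).sum())

    expanded = np.zeros(len(out))
    if realised < required * (1 - 1e-12) and allow_expansion:
        # expansion into unmanaged forest, cheapest effective m3 first
        r_grid = np.geomspace(R_MIN, R_MAX, 128)
        expandable = (
            out["area_ha"].to_numpy(float)
            * out["frac_unmanaged"].to_numpy(float)
            * (~out["protected"].to_numpy(bool))
        )
        cand = np.where(expandable > 0)[0]
        eff_cost = np.full(len(out), np.inf)
        best_r = np.full(len(out), R_MIN)
        for i in cand:
            y_g = cell_yield(r_grid, ymax[i], k[i], p[i])
            with np.errstate(divide="ignore"):
                cpm = (costs.management_cost * r_grid + costs.conversion_cost) / np.where(
                    y_g > 0, y_g, np.nan
                )
            if np.isfinite(cpm).any():
                j = int(np.nanargmin(cpm))
                eff_cost[i] = cpm[j]
                best_r[i] = r_grid[j]
        order = sorted(cand, key=lambda i: (eff_cost[i], out.at[i, "cell"]))
        for i in order:
            gap = required - realised
            if gap <= 0:
                break
            y_ha = cell_yield(best_r[i], ymax[i], k[i], p[i])
            if y_ha <= 0 or not np.isfinite(eff_cost[i]):
                continue
            add = min(expandable[i], gap / y_ha)
            expanded[i] += add
            # blend intensity over old and new timber area
            r[i] = (r[i] * area[i] + best_r[i] * add) / (area[i] + add) if (
                area[i] + add
            ) > 0 else best_r[i]
            area[i] += add
            realised = float((area * cell_yield(r, ymax, k, p)).sum())

    shortfall = max(0.0, float(required) - realised)
    total_area = out["area_ha"].to_numpy(float)
    d_frac = np.divide(expanded, total_area, out=np.zeros_like(expanded),
                       where=total_area > 0)
    out["frac_timber"] = out["frac_timber"] + d_frac
    out["frac_unmanaged"] = out["frac_unmanaged"] - d_frac
    out["intensity"] = np.where(area > 0, np.clip(r, R_MIN, R_MAX), out["intensity"])
    cost = (
        costs.management_cost * float((area * np.clip(r, R_MIN, R_MAX)).sum())
        + costs.conversion_cost * float(expanded.sum())
    )
    return CountryDecision(out, realised, shortfall, cost, float(expanded.sum()))


def spinup_abandonment(cells: pd.DataFrame, viability_threshold: float) -> pd.DataFrame:
    """Abandon timber forest where even maximal management is unviable.

    Cells whose annualised yield at r = R_MAX falls below the threshold
    (m3/ha/yr) have their timber fraction reassigned to unmanaged
    forest; total land is conserved per cell.
    """
    validate_cells(cells)
    out = cells.copy()
    y_max_r = cell_yield(R_MAX, out["ymax"].to_numpy(), out["k"].to_numpy(),
                         out["p"].to_numpy())
    drop = y_max_r < viability_threshold
    out.loc[drop, "frac_unmanaged"] += out.loc[drop, "frac_timber"]
    out.loc[drop, "frac_timber"] = 0.0
    return out


def apply_agricultural_demand(cells: pd.DataFrame, target_agri_ha: float) -> pd.DataFrame:
    """Move land to/from agriculture to hit an exogenous area target.

    Expansion takes unmanaged forest first, then timber forest, in
    ascending order of potential yield (least productive land is
    converted first); protected cells are untouched.  Contraction
    returns agricultural land to unmanaged forest in the same order.
    """
    validate_cells(cells)
    out = cells.copy().reset_index(drop=True)
    areas = out["area_ha"].to_numpy(float)
    current = float((areas * out["frac_agri"]).sum())
    delta = float(target_agri_ha) - current
    if abs(delta) < 1e-9:
        return out
    y_rank = cell_yield(R_MAX, out["ymax"].to_numpy(), out["k"].to_numpy(),
                        out["p"].to_numpy())
    order = np.lexsort((out["cell"].to_numpy(), y_rank))

    if delta > 0:
        for source in ("frac_unmanaged", "frac_timber"):
            for i in order:
                if delta <= 0:
                    break
                if out.at[i, "protected"]:
                    continue
                avail = out.at[i, source] * areas[i]
                take = min(avail, delta)
                if take <= 0:
                    continue
                out.at[i, source] -= take / areas[i]
                out.at[i, "frac_agri"] += take / areas[i]
                delta -= take
        if delta > 1e-6:
            raise ValueError("agricultural demand exceeds available country land")
    else:
        delta = -delta
        for i in order:
            if delta <= 0:
                break
            avail = out.at[i, "frac_agri"] * areas[i]
            give = min(avail, delta)
            if give <= 0:
                continue
            out.at[i, "frac_agri"] -= give / areas[i]
            out.at[i, "frac_unmanaged"] += give / areas[i]
            delta -= give
    return out
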