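"""Annual simulation loop, scenario configs and stochastic ensembles.

Each simulated year executes, in order: per-country demand projection
at current prices -> trade-constrained harvest requirement ->
least-cost country optimisation -> global market aggregation and price
update -> periodic sliding-window yield-curve re-estimation.  The
start-year state is the initialisation; simulation steps begin the
following year.  Scenario ensembles redraw sampled parameters per
member from configured distributions, with member substreams derived
from (master seed, member index) so ensemble size changes never
perturb earlier members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decomposition import HarvestFactors, decompose
from .demand import MAIDADSParams, predict_percapita
from .market import BASE_INDEX, update_price, constrain_net_imports
from .optimizer import (
    CostParams,
    apply_agricultural_demand,
    optimize_country,
    required_harvest,
    spinup_abandonment,
)
from .world import World, cohort_trend_from_series
from .yields import (
    fit_yield_curve,
    generate_yield_tables,
    window_rotation_yields,
)

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Drivers, costs and sampling rules for one scenario."""

    label: str = "baseline"
    start_year: int = 2020
    end_year: int = 2060
    population: pd.DataFrame | None = None     # country x year
    gdp_percap: pd.DataFrame | None = None     # country x year
    agri_area: pd.DataFrame | None = None      # country x year (ha)
    yield_trend: pd.Series | None = None       # year -> multiplier (start=1)
    costs: CostParams = field(default_factory=CostParams)
    price_adjustment: float = 0.05             # lambda of the price rule
    trade_limit_fraction: float = 0.2
    trade_floor: float = 1e4                   # m3, entrant band floor
    viability_threshold: float = 0.2           # m3/ha/yr spin-up abandonment
    refit_interval: int = 5                    # years between yield refits
    ensemble_size: int = 30
    master_seed: int = 0
    #: name -> distribution spec; multiplies the named scalar parameter.
    #: ("lognormal", sigma) | ("uniform", lo, hi) | ("normal", mu, sd)
    sampled: dict = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def config_from_world(world: World, label: str = "baseline", **overrides) -> ScenarioConfig:
    """Build a config from a synthetic world's default trajectories."""
    traj = world.trajectories
    cfg = ScenarioConfig(
        label=label,
        start_year=world.spec.start_year,
        end_year=world.spec.end_year,
        population=traj["population"],
        gdp_percap=traj["gdp_percap"],
        agri_area=traj.get("agri_area"),
        yield_trend=traj["yield_trend"],
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def load_scenario_file(path, world: World) -> ScenarioConfig:
    """Build a config from a plain-text YAML scenario file.

    Recognised keys: label, income_growth, population_growth,
    yield_trend_rate, agri_growth (trajectory generators applied to the
    world), ensemble_size, master_seed, price_adjustment,
    trade_limit_fraction, trade_floor, viability_threshold,
    refit_interval, costs {management_cost, conversion_cost,
    trade_change_cost}, sampled {name: [kind, args...]}.
    """
    import yaml

    from .world import make_trajectories

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    traj_kw = {k: raw.pop(k) for k in
               ("income_growth", "population_growth", "yield_trend_rate")
               if k in raw}
    world.trajectories = make_trajectories(world.spec, world.observations,
                                           **traj_kw)
    costs_kw = raw.pop("costs", {})
    sampled = {k: tuple(v) for k, v in raw.pop("sampled", {}).items()}
    cfg = config_from_world(world, label=raw.pop("label", "scenario"))
    for k, v in raw.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown scenario key {k!r}")
        setattr(cfg, k, v)
    if costs_kw:
        cfg.costs = CostParams(**costs_kw)
    cfg.sampled = sampled
    return cfg


@dataclass
class SimulationResult:
    label: str
    country_year: pd.DataFrame
    global_year: pd.DataFrame
    factors: dict            # year -> HarvestFactors snapshot
    cells_final: pd.DataFrame


def _refit_cells(tables, n_cells, year, warm=None):
    """Sliding-window yield params for every cell, warm-started."""
    params = []
    for i in range(n_cells):
        ages, ys, window = window_rotation_yields(tables, i, year)
        if ages.size < 4:
            raise ValueError(f"cell {tables.cell_ids[i]!r}: too few rotations")
        initial = warm[i] if warm is not None else None
        params.append(fit_yield_curve(ages, ys, window=window, initial=initial))
    return params


def _assign_params(cells, params):
    cells = cells.copy()
    cells["ymax"] = [q.ymax for q in params]
    cells["k"] = [q.k for q in params]
    cells["p"] = [q.p for q in params]
    return cells


def _snapshot(frames) -> HarvestFactors:
    cols = {
        name: np.concatenate([f[name].to_numpy(float) for f in frames])
        for name in ("area_ha", "frac_timber", "intensity", "ymax", "k", "p")
    }
    return HarvestFactors(
        area=cols["area_ha"] * cols["frac_timber"],
        intensity=cols["intensity"],
        ymax=cols["ymax"],
        k=cols["k"],
        p=cols["p"],
    )


def run_simulation(
    world: World,
    demand_params: MAIDADSParams,
    config: ScenarioConfig,
) -> SimulationResult:
    """Run the annual loop over the scenario horizon.

    The simulation is a pure function of (world, demand_params,
    config): repeated calls give identical output.
    """
    spec = world.spec
    years = config.years
    obs = world.observations.set_index("country")
    countries = list(obs.index)
    base_prices = obs[["price_roundwood", "price_woodfuel"]].to_numpy(float)

    trend = config.yield_trend
    if trend is None:
        trend = pd.Series(1.0, index=years)
    tables = generate_yield_tables(
        world.growth_params,
        cohort_trend=cohort_trend_from_series(trend, config.start_year),
        seed=spec.seed,
    )

    cells = world.cells.copy().reset_index(drop=True)
    yparams = _refit_cells(tables, len(cells), config.start_year)
    cells = _assign_params(cells, yparams)
    cells = spinup_abandonment(cells, config.viability_threshold)
    pos = {c: np.where(cells["country"].to_numpy() == c)[0] for c in countries}
    frames = {c: cells.iloc[pos[c]].reset_index(drop=True) for c in countries}

    def demand_at(year, index):
        inc = config.gdp_percap[year].reindex(countries).to_numpy(float)
        prices = base_prices * (index / BASE_INDEX)
        pred = predict_percapita(inc, prices, demand_params)
        pop = config.population[year].reindex(countries).to_numpy(float)
        return pred.quantity * pop[:, None]  # (n, 2) total m3

    # ---- initialisation year -------------------------------------------
    index = BASE_INDEX
    stock = 0.0
    totals0 = demand_at(years[0], index)
    demand_total = totals0.sum(axis=1)
    # base-year net-import shares from the panel, rescaled to the start year
    cons_base = (
        obs["cons_roundwood"] * obs["population"]
        + obs["cons_woodfuel"] * obs["population"]
    ).to_numpy(float)
    harv_base = (
        world.panel[(world.panel["flow"] == "production")]
        .groupby("country")["quantity"].sum().reindex(countries).to_numpy(float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t_share = np.where(cons_base > 0, 1.0 - harv_base / cons_base, 0.0)
    net_imports = demand_total * t_share
    country_rows, global_rows = [], []
    factors = {}

    # bring the start-year state onto the demand it initialises
    harvest = np.zeros(len(countries))
    for ci, c in enumerate(countries):
        req = required_harvest(totals0[ci, 0], totals0[ci, 1], net_imports[ci])
        dec = optimize_country(req, frames[c], config.costs)
        frames[c] = dec.cells
        harvest[ci] = dec.realised_harvest
    factors[int(years[0])] = _snapshot(frames.values())
    # consumption is met from stock where harvest+trade falls short, so
    # booked net imports are consumption minus harvest from day one
    _record(country_rows, global_rows, years[0], countries, totals0, harvest,
            demand_total - harvest, np.zeros(len(countries)), index, stock,
            frames)

    prev_demand = demand_total
    last_refit = years[0]

    # ---- annual loop ----------------------------------------------------
    for year in years[1:]:
        if year - last_refit >= config.refit_interval:
            yparams = _refit_cells(tables, len(cells), int(year), warm=yparams)
            for c in countries:
                sub = frames[c]
                sub["ymax"] = [yparams[i].ymax for i in pos[c]]
                sub["k"] = [yparams[i].k for i in pos[c]]
                sub["p"] = [yparams[i].p for i in pos[c]]
            last_refit = year

        totals = demand_at(int(year), index)
        demand_total = totals.sum(axis=1)

        if config.agri_area is not None:
            for ci, c in enumerate(countries):
                target = float(config.agri_area.loc[c, year])
                frames[c] = apply_agricultural_demand(frames[c], target)

        growth = np.divide(demand_total, prev_demand,
                           out=np.ones_like(demand_total), where=prev_demand > 0)
        desired = net_imports * growth
        allowed = np.array([
            constrain_net_imports(desired[i], net_imports[i],
                                  config.trade_limit_fraction, config.trade_floor)
            for i in range(len(countries))
        ])

        harvest = np.zeros(len(countries))
        shortfall = np.zeros(len(countries))
        for ci, c in enumerate(countries):
            req = required_harvest(totals[ci, 0], totals[ci, 1], allowed[ci])
            dec = optimize_country(req, frames[c], config.costs)
            frames[c] = dec.cells
            harvest[ci] = dec.realised_harvest
            shortfall[ci] = dec.shortfall

        supply = float(harvest.sum())
        demand_g = float(demand_total.sum())
        net_imports = demand_total - harvest  # consumption met from stock
        stock += supply - demand_g
        index = update_price(index, demand_g, supply, config.price_adjustment)
        factors[int(year)] = _snapshot(frames.values())
        _record(country_rows, global_rows, year, countries, totals, harvest,
                net_imports, shortfall, index, stock, frames)
        logger.info("%s %d: demand=%.3e supply=%.3e index=%.2f",
                    config.label, year, demand_g, supply, index)
        prev_demand = demand_total

    return SimulationResult(
        label=config.label,
        country_year=pd.DataFrame(country_rows),
        global_year=pd.DataFrame(global_rows),
        factors=factors,
        cells_final=pd.concat(frames.values(), ignore_index=True),
    )


def _record(country_rows, global_rows, year, countries, totals, harvest,
            net_imports, shortfall, index, stock, frames):
    for ci, c in enumerate(countries):
        country_rows.append(dict(
            year=int(year), country=c,
            demand_roundwood=totals[ci, 0], demand_woodfuel=totals[ci, 1],
            demand_total=totals[ci].sum(), harvest=harvest[ci],
            net_imports=net_imports[ci], shortfall=shortfall[ci]))
    w = np.concatenate([
        (f["area_ha"] * f["frac_timber"]).to_numpy(float) for f in frames.values()])
    r = np.concatenate([f["intensity"].to_numpy(float) for f in frames.values()])
    timber = pd.Series(w)
    global_rows.append(dict(
        year=int(year), price_index=index,
        demand_roundwood=float(totals[:, 0].sum()),
        demand_woodfuel=float(totals[:, 1].sum()),
        demand_total=float(totals.sum()), supply=float(harvest.sum()),
        stock=stock, timber_area_ha=float(timber.sum()),
        mean_intensity=float((w * r).sum() / w.sum()) if w.sum() > 0 else np.nan,
    ))


# ---------------------------------------------------------------------------
# ensembles


def _member_seed(master_seed: int, member: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(member))))


def _draw(rng, spec):
    kind = spec[0]
    if kind == "lognormal":
        return float(np.exp(rng.normal(0.0, spec[1])))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_member_config(config: ScenarioConfig, member: int) -> ScenarioConfig:
    """Per-member config with sampled parameter multipliers applied."""
    rng = _member_seed(config.master_seed, member)
    cfg = replace(config)
    costs = config.costs
    for name, dist in config.sampled.items():
        m = _draw(rng, dist)
        if name == "management_cost":
            costs = replace(costs, management_cost=costs.management_cost * m)
        elif name == "conversion_cost":
            costs = replace(costs, conversion_cost=costs.conversion_cost * m)
        elif name == "price_adjustment":
            cfg.price_adjustment = float(np.clip(config.price_adjustment * m, 1e-4, 1.0))
        elif name == "yield_trend_scale":
            if config.yield_trend is not None:
                cfg.yield_trend = config.yield_trend ** m
        else:
            raise ValueError(f"unknown sampled parameter {name!r}")
    cfg.costs = costs
    return cfg


GLOBAL_SERIES = ("demand_roundwood", "demand_woodfuel", "demand_total",
                 "supply", "price_index", "timber_area_ha", "mean_intensity",
                 "stock")


@dataclass
class EnsembleSummary:
    """Yearly median and 90% band (5th-95th percentile) per series."""

    label: str
    series: dict                 # name -> DataFrame(year, q05, median, q95)
    n_members: int
    members: list = field(default_factory=list)  # SimulationResult per member


def run_ensemble(world: World, demand_params: MAIDADSParams,
                 config: ScenarioConfig) -> EnsembleSummary:
    """Run the configured ensemble and summarise global trajectories."""
    members = []
    for m in range(config.ensemble_size):
        cfg_m = sample_member_config(config, m)
        try:
            members.append(run_simulation(world, demand_params, cfg_m))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("ensemble member %d failed: %s", m, exc)
    if not members:
        raise RuntimeError("every ensemble member failed")

    series = {}
    years = members[0].global_year["year"].to_numpy()
    for name in GLOBAL_SERIES:
        mat = np.column_stack([m.global_year[name].to_numpy() for m in members])
        series[name] = pd.DataFrame({
            "year": years,
            "q05": np.percentile(mat, 5, axis=1),
            "median": np.percentile(mat, 50, axis=1),
            "q95": np.percentile(mat, 95, axis=1),
        })
    return EnsembleSummary(label=config.label, series=series,
                           n_members=len(members), members=members)


def decompose_ensemble(summary: EnsembleSummary, baseline_year: int,
                       final_year: int) -> pd.DataFrame:
    """Attribution table across ensemble members (median and 90% band)."""
    rows = {}
    for m in summary.members:
        res = decompose(m.factors[baseline_year], m.factors[final_year])
        for k, v in res.contributions_pct.items():
            rows.setdefault(k, []).append(v)
    table = []
    for k, vals in rows.items():
        vals = np.asarray(vals)
        table.append(dict(factor=k,
                          median=float(np.percentile(vals, 50)),
                          q05=float(np.percentile(vals, 5)),
                          q95=float(np.percentile(vals, 95))))
    return pd.DataFrame(table)
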