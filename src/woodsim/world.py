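"""Synthetic world generation: country panels, grids, yield tables.

Produces all inputs the pipeline consumes, with the statistical
structure the real data sources carry: a country panel of wood-item
production/trade records whose bilateral trade is balanced (so the
mass balance closes globally by construction), Engel-shaped
income-consumption pairs (per-capita roundwood demand rising with
income, wood-fuel demand hump-shaped), gridded land-cover fractions
over three biome archetypes (boreal slow / temperate medium / tropical
fast growth), and stand-age yield tables.  Nothing here aims at
statistical realism of any specific country; the default world is
desk-scale (12 countries x 25 cells, horizon 2060).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import accounting
from .demand import MAIDADSParams, predict_percapita
from .yields import YieldTableSet, generate_yield_tables

#: Demand parameters used to generate consumption: per-capita roundwood
#: rises with income while the wood-fuel share collapses at high income
#: (its high-income marginal share is ~0), giving the hump-shaped
#: wood-fuel Engel curve seen in country data.
DEFAULT_TRUE_PARAMS = MAIDADSParams(
    gamma=(0.02, 0.05, 200.0),
    alpha=(0.0002, 0.0125, 0.9873),
    beta_star=(0.002, 1e-05, 0.99799),
    kappa=2.0,
    u0=8.5,
)

#: (name, v_max m3/ha, rate 1/yr, shape) per biome archetype.  Growth
#: saturates so that mean annual increment culminates by the shortest
#: admissible rotation (10 yr): the model's least-cost allocation
#: assumes annualised harvest rises with management intensity, and the
#: generator is kept consistent with that assumption.
DEFAULT_BIOMES = (
    ("boreal", 320.0, 0.07, 1.3),
    ("temperate", 450.0, 0.09, 1.35),
    ("tropical", 560.0, 0.13, 1.4),
)


@dataclass(frozen=True)
class WorldSpec:
    n_countries: int = 12
    cells_per_country: int = 25
    seed: int = 42
    base_year: int = 2017
    start_year: int = 2020
    end_year: int = 2060
    income_log_mean: float = 9.2     # median ~ 10k currency/person/yr
    income_log_sd: float = 1.1
    noise_sigma: float = 0.0         # log-scale noise on consumption
    price_roundwood: float = 90.0    # currency/m3, base-year world price
    price_woodfuel: float = 40.0
    price_log_sd: float = 0.12       # country scatter around world price
    population_log_mean: float = 16.2  # median ~ 11 M people
    population_log_sd: float = 1.0
    cell_area_ha: float = 250_000.0
    protected_fraction: float = 0.1
    trade_share_max: float = 0.25    # max |net imports| / consumption
    n_calibration_countries: int = 60  # base-year cross-section for fitting
    true_params: MAIDADSParams = DEFAULT_TRUE_PARAMS
    biomes: tuple = DEFAULT_BIOMES

    def __post_init__(self):
        if self.n_countries < 1 or self.cells_per_country < 1:
            raise ValueError("counts must be at least 1")


@dataclass
class World:
    spec: WorldSpec
    panel: pd.DataFrame              # long item records (accounting schema)
    observations: pd.DataFrame       # per-country demand observations
    calibration: pd.DataFrame        # larger base-year cross-section (fitting)
    cells: pd.DataFrame              # grid (optimizer schema + country/biome)
    growth_params: pd.DataFrame      # per-cell Chapman-Richards params
    tables: YieldTableSet            # flat-trend baseline yield tables
    trajectories: dict = field(default_factory=dict)


def _country_ids(n):
    return [f"C{i:02d}" for i in range(n)]


def make_country_panel(spec: WorldSpec, rng: np.random.Generator):
    """Base-year item records + the joined demand observations."""
    n = spec.n_countries
    countries = _country_ids(n)
    income = np.exp(rng.normal(spec.income_log_mean, spec.income_log_sd, n))
    population = np.exp(rng.normal(spec.population_log_mean, spec.population_log_sd, n))
    p_rw = spec.price_roundwood * np.exp(rng.normal(0, spec.price_log_sd, n))
    p_wf = spec.price_woodfuel * np.exp(rng.normal(0, spec.price_log_sd, n))

    pred = predict_percapita(income, np.column_stack([p_rw, p_wf]), spec.true_params)
    percap = pred.quantity * np.exp(rng.normal(0, spec.noise_sigma, (n, 2)))
    cons = percap * population[:, None]  # total m3 per commodity

    records = []
    obs_rows = []
    for ci, commodity in enumerate(accounting.COMMODITIES):
        raw_item = "Industrial roundwood" if ci == 0 else "Wood fuel"
        proc_item = "Wood pulp" if ci == 0 else "Wood charcoal"
        ratio = accounting.MASS_CONVERSION_M3_PER_T[proc_item]
        price = (p_rw, p_wf)[ci]
        # zero-sum net-import shares: harvest stays positive
        t = rng.uniform(-spec.trade_share_max, spec.trade_share_max, n)
        t -= (cons[:, ci] * t).sum() / cons[:, ci].sum()
        net = cons[:, ci] * t
        harvest = cons[:, ci] - net
        for j, c in enumerate(countries):
            records.append((c, spec.base_year, raw_item, "production",
                            harvest[j], "m3", np.nan))
            flow = "import" if net[j] >= 0 else "export"
            vol = abs(net[j])
            # split trade 70% raw item (m3) / 30% a processed item (tonnes)
            records.append((c, spec.base_year, raw_item, flow,
                            0.7 * vol, "m3", 0.7 * vol * price[j]))
            records.append((c, spec.base_year, proc_item, flow,
                            0.3 * vol / ratio, "t", 0.3 * vol * price[j]))
    panel = pd.DataFrame(records, columns=accounting.RECORD_COLUMNS)

    for j, c in enumerate(countries):
        obs_rows.append(
            dict(country=c, year=spec.base_year, gdp_percap=income[j],
                 population=population[j], price_roundwood=p_rw[j],
                 price_woodfuel=p_wf[j], cons_roundwood=percap[j, 0],
                 cons_woodfuel=percap[j, 1]))
    observations = pd.DataFrame(obs_rows)
    return panel, observations


def make_grid(spec: WorldSpec, rng: np.random.Generator):
    """Grid cells with land-cover fractions and growth parameters."""
    rows = []
    growth = []
    biomes = spec.biomes
    for gi, country in enumerate(_country_ids(spec.n_countries)):
        biome = biomes[gi % len(biomes)]
        for j in range(spec.cells_per_country):
            cell = f"{country}-{j:03d}"
            area = spec.cell_area_ha * rng.uniform(0.6, 1.4)
            f_timber = rng.uniform(0.05, 0.45)
            f_unman = rng.uniform(0.15, 0.45)
            f_agri = rng.uniform(0.05, 0.25)
            rest = f_timber + f_unman + f_agri
            f_other = max(1.0 - rest, 0.05)
            tot = f_timber + f_unman + f_agri + f_other
            rows.append(dict(
                cell=cell, country=country, biome=biome[0], area_ha=area,
                frac_timber=f_timber / tot, frac_unmanaged=f_unman / tot,
                frac_agri=f_agri / tot, frac_other=f_other / tot,
                intensity=0.02, ymax=np.nan, k=np.nan, p=np.nan,
                protected=bool(rng.random() < spec.protected_fraction),
            ))
            growth.append(dict(
                cell=cell, country=country,
                v_max=biome[1] * np.exp(rng.normal(0, 0.25)),
                rate=biome[2] * np.exp(rng.normal(0, 0.1)),
                shape=biome[3],
            ))
    return pd.DataFrame(rows), pd.DataFrame(growth)


def make_trajectories(
    spec: WorldSpec,
    observations: pd.DataFrame,
    *,
    income_growth: float = 0.02,
    population_growth: float = 0.005,
    yield_trend_rate: float = 0.0,
    agri_growth: float = 0.0,
    agri_base_ha: pd.Series | None = None,
) -> dict:
    """Exponential driver trajectories over the scenario horizon."""
    years = np.arange(spec.start_year, spec.end_year + 1)
    t = years - spec.start_year
    idx = observations.set_index("country")
    pop = pd.DataFrame(
        {y: idx["population"] * (1 + population_growth) ** dt
         for y, dt in zip(years, t)})
    inc = pd.DataFrame(
        {y: idx["gdp_percap"] * (1 + income_growth) ** dt
         for y, dt in zip(years, t)})
    trend = pd.Series((1 + yield_trend_rate) ** t, index=years)
    traj = {"population": pop, "gdp_percap": inc, "yield_trend": trend}
    if agri_base_ha is not None:
        traj["agri_area"] = pd.DataFrame(
            {y: agri_base_ha * (1 + agri_growth) ** dt for y, dt in zip(years, t)})
    return traj


def make_calibration_panel(spec: WorldSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Base-year demand cross-section over a larger synthetic country set.

    The demand system is fitted on a wide income cross-section (as a
    base-year world panel would provide), while the simulated grid
    covers a smaller country subset.
    """
    wide = replace(spec, n_countries=spec.n_calibration_countries)
    _, obs = make_country_panel(wide, rng)
    obs["country"] = ["F" + c[1:] for c in obs["country"]]
    return obs


def make_world(spec: WorldSpec | None = None) -> World:
    """Generate a full synthetic world (deterministic given spec.seed)."""
    spec = spec or WorldSpec()
    rng = np.random.default_rng(spec.seed)
    panel, observations = make_country_panel(spec, rng)
    calibration = make_calibration_panel(spec, rng)
    cells, growth = make_grid(spec, rng)
    tables = generate_yield_tables(growth, cohort_trend=None, seed=spec.seed)
    agri_base = (
        cells.assign(a=cells["area_ha"] * cells["frac_agri"])
        .groupby("country")["a"].sum()
    )
    trajectories = make_trajectories(spec, observations, agri_base_ha=agri_base)
    return World(spec, panel, observations, calibration, cells, growth, tables,
                 trajectories)


def cohort_trend_from_series(trend: pd.Series, start_year: int):
    """Per-cohort multiplier from a calendar-year trend series.

    Cohorts established before the scenario window keep multiplier 1;
    later cohorts take the trend at their establishment year (clamped
    to the series end)."""
    def f(cohort_year):
        if cohort_year < start_year:
            return 1.0
        y = min(int(cohort_year), int(trend.index.max()))
        return float(trend.loc[y])
    return f


def make_toy_printed_examples() -> dict:
    """Small named numeric fixtures for headline reported quantities.

    Synthetic stand-ins carrying reference magnitudes used in tests and
    reporting: the baseline global forest areas, the SSP2-style
    regional demand increase, the historical global harvest levels and
    the reference management intensity.
    """
    return {
        "rotation": {"intensity": 0.02},
        "baseline_areas": {"timber_Mha": 1460.0, "total_forest_Mha": 4102.0},
        "ssp2_regional_increase": {
            "global_Mm3": 2935.0, "asia_Mm3": 987.0, "africa_Mm3": 1636.0},
        "historical_harvest": {"y1961_Mm3": 2517.0, "y2022_Mm3": 3983.0},
    }
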