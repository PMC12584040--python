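"""Stand-age yield tables and the annualised harvest function.

Potential clear-cut yields come from stand-age yield tables: for each
grid cell, forest stands are (synthetically) established every 20 years
from 1850 to 2090 and the potential clear-cut volume is recorded for
every subsequent calendar year to 2100.  The synthetic generator uses a
Chapman-Richards age-volume curve per cell with a multiplicative
climate/CO2 trend per establishment cohort, standing in for a
process-based vegetation model.

Harvested biomass from a clear-cut is 100% of the trunk pool (65% of
wood biomass), 95% of twigs and branches (13%) and 10% of coarse roots
(22%), converted to volume at 0.3 tC per m3.

Management intensity r (1/yr) is the reciprocal of the rotation period.
The expected annualised harvest per hectare is

    y(r) = ymax * (1 - exp(k * r**p)) * r,     k < 0, p < 0,

whose per-harvest factor approaches ymax for long rotations (small r)
and 0 for short ones.  (ymax, k, p) are estimated from yield-table
slices by damped Gauss-Newton, re-estimated over a 160-year sliding
window as the simulation advances so that yields track the changing
climate signal baked into the cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

R_MIN = 0.00625  # 1/160 yr; window scope of the yield tables
R_MAX = 0.1      # shortest admissible rotation: 10 years
WINDOW_YEARS = 160

TRUNK_SHARE, BRANCH_SHARE, ROOT_SHARE = 0.65, 0.13, 0.22
TRUNK_FRAC, BRANCH_FRAC, ROOT_FRAC = 1.00, 0.95, 0.10
TC_PER_M3 = 0.3

COHORT_YEARS = np.arange(1850, 2091, 20)
TABLE_END_YEAR = 2100


@dataclass(frozen=True)
class WoodPools:
    """Clear-cut biomass pools (tC/ha)."""

    trunk: float
    branches: float
    coarse_roots: float

    @classmethod
    def from_wood_pool(cls, wood_pool_tc: float) -> "WoodPools":
        """Split a total wood pool by the fixed 65/13/22 shares."""
        return cls(
            trunk=TRUNK_SHARE * wood_pool_tc,
            branches=BRANCH_SHARE * wood_pool_tc,
            coarse_roots=ROOT_SHARE * wood_pool_tc,
        )


def harvestable_biomass(pools: WoodPools) -> float:
    """Harvested biomass: full trunk, 95% of branches, 10% of coarse roots."""
    if min(pools.trunk, pools.branches, pools.coarse_roots) < 0:
        raise ValueError("biomass pools must be nonnegative")
    return (
        TRUNK_FRAC * pools.trunk
        + BRANCH_FRAC * pools.branches
        + ROOT_FRAC * pools.coarse_roots
    )


def biomass_to_volume(biomass_tc):
    """tC/ha -> m3/ha at 0.3 tC per m3."""
    biomass_tc = np.asarray(biomass_tc, float)
    if (biomass_tc < 0).any():
        raise ValueError("biomass must be nonnegative")
    return biomass_tc / TC_PER_M3


def volume_to_biomass(volume_m3):
    return np.asarray(volume_m3, float) * TC_PER_M3


def chapman_richards(age, v_max, rate, shape):
    """Saturating age-volume curve v_max*(1-exp(-rate*age))**shape."""
    age = np.asarray(age, float)
    return v_max * np.power(1.0 - np.exp(-rate * np.maximum(age, 0.0)), shape)


@dataclass
class YieldTableSet:
    """Dense yield tables: potential clear-cut volume (m3/ha).

    ``values[cell, cohort, year_index]`` for calendar years
    ``years[0]..years[-1]``; NaN before a cohort's establishment.
    """

    cell_ids: np.ndarray          # (n_cells,)
    cohort_years: np.ndarray      # (n_cohorts,) establishment years
    years: np.ndarray             # (n_years,) calendar years covered
    values: np.ndarray            # (n_cells, n_cohorts, n_years)

    def yield_at(self, cell_index: int, cohort_year: int, year: int) -> float:
        ci = int(np.searchsorted(self.cohort_years, cohort_year))
        yi = int(year - self.years[0])
        return float(self.values[cell_index, ci, yi])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export {cell, cohort, year, yield_m3_ha}."""
        n_c, n_k, n_y = self.values.shape
        cell, coh, yr = np.meshgrid(
            self.cell_ids, self.cohort_years, self.years, indexing="ij"
        )
        df = pd.DataFrame(
            {
                "cell": cell.ravel(),
                "cohort": coh.ravel(),
                "year": yr.ravel(),
                "yield_m3_ha": self.values.ravel(),
            }
        )
        return df.dropna(subset=["yield_m3_ha"]).reset_index(drop=True)


def generate_yield_tables(
    growth_params: pd.DataFrame,
    cohort_trend=None,
    seed: int = 0,
    cohort_years: np.ndarray = COHORT_YEARS,
    end_year: int = TABLE_END_YEAR,
) -> YieldTableSet:
    """Synthetic yield tables from Chapman-Richards growth curves.

    growth_params : one row per cell with columns {cell, v_max, rate,
        shape} (m3/ha asymptote, 1/yr rate, dimensionless shape > 0).
    cohort_trend : optional multiplier per establishment cohort (array
        of len(cohort_years), or callable year->multiplier) emulating
        climate/CO2-driven productivity change between cohorts.
    seed : reserved for stochastic generator variants; the default
        generator is deterministic and seed only fixes reproducibility
        of any added noise.
    """
    if (growth_params["v_max"] < 0).any():
        raise ValueError("negative growth asymptote")
    cohort_years = np.asarray(cohort_years, int)
    if cohort_trend is None:
        trend = np.ones(cohort_years.size)
    elif callable(cohort_trend):
        trend = np.array([float(cohort_trend(y)) for y in cohort_years])
    else:
        trend = np.asarray(cohort_trend, float)
        if trend.shape != cohort_years.shape:
            raise ValueError("cohort_trend length must match cohort_years")

    start = int(cohort_years.min())
    years = np.arange(start, end_year + 1)
    n_cells = len(growth_params)
    values = np.full((n_cells, cohort_years.size, years.size), np.nan)
    v_max = growth_params["v_max"].to_numpy()[:, None]
    rate = growth_params["rate"].to_numpy()[:, None]
    shape = growth_params["shape"].to_numpy()[:, None]
    for k, cy in enumerate(cohort_years):
        # establishment follows one pasture year: first growth year is cy+1
        age = years - cy
        mask = age >= 1
        curve = chapman_richards(age[mask][None, :], v_max, rate, shape)
        values[:, k, mask] = trend[k] * curve
    return YieldTableSet(
        cell_ids=growth_params["cell"].to_numpy(),
        cohort_years=cohort_years,
        years=years,
        values=values,
    )


# ---------------------------------------------------------------------------
# the annualised harvest function and its Gauss-Newton fit


@dataclass(frozen=True)
class YieldCurveParams:
    """Fitted (ymax, k, p) of the annualised harvest function."""

    ymax: float
    k: float
    p: float
    window: tuple[int, int] | None = None
    rmse: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if self.ymax < 0:
            raise ValueError("ymax must be nonnegative")
        if self.k >= 0 or self.p >= 0:
            raise ValueError("sign convention requires k < 0 and p < 0")


def per_harvest_yield(r, params: YieldCurveParams):
    """Expected volume per clear-cut at intensity r: ymax*(1-exp(k r^p))."""
    r = np.asarray(r, float)
    return params.ymax * (1.0 - np.exp(params.k * np.power(r, params.p)))


def annualised_harvest(r, params: YieldCurveParams):
    """Annualised harvest y(r) = ymax*(1-exp(k r^p))*r, r in [R_MIN, R_MAX]."""
    r = np.asarray(r, float)
    if ((r < R_MIN - 1e-12) | (r > R_MAX + 1e-12)).any():
        raise ValueError(f"management intensity outside [{R_MIN}, {R_MAX}]")
    return per_harvest_yield(r, params) * r


def annualised_harvest_deriv(r, params: YieldCurveParams):
    """dy/dr, used by the least-cost optimiser."""
    r = np.asarray(r, float)
    e = np.exp(params.k * np.power(r, params.p))
    return params.ymax * (1.0 - e - e * params.k * params.p * np.power(r, params.p))


def _model_and_jacobian(theta, r):
    """Per-harvest model in transformed params theta=(ymax, a, b).

    k = -exp(a), p = -exp(b) keeps the sign constraints structural.
    """
    ymax, a, b = theta
    k, p = -np.exp(a), -np.exp(b)
    with np.errstate(over="ignore", invalid="ignore"):
        rp = np.minimum(np.power(r, p), 1e150)
        e = np.exp(np.maximum(k * rp, -745.0))
        f = ymax * (1.0 - e)
        d_ymax = 1.0 - e
        d_k = -ymax * e * rp          # d f / d k
        d_p = -ymax * e * k * rp * np.log(r)  # d f / d p
        # chain rule to (a, b)
        J = np.column_stack([d_ymax, d_k * k, d_p * p])
    if not np.isfinite(J).all():
        J = np.nan_to_num(J, nan=0.0, posinf=0.0, neginf=0.0)
    return f, J


def _gauss_newton(theta0, r, y, max_iter=200, step_tol=1e-10):
    """Damped (Levenberg) Gauss-Newton on per-harvest residuals."""
    theta = np.asarray(theta0, float).copy()
    f, J = _model_and_jacobian(theta, r)
    resid = f - y
    cost = float(resid @ resid)
    lam = 1e-6
    converged = False
    eye = np.eye(3)
    for _ in range(max_iter):
        A = J.T @ J
        g = J.T @ resid
        M = A + lam * eye
        det = (
            M[0, 0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
            - M[0, 1] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
            + M[0, 2] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0])
        )
        if not np.isfinite(det) or abs(det) < 1e-300:
            lam *= 10
            continue
        # Cramer's rule on the 3x3 normal equations (hot path)
        b = -g
        step = np.array([
            (b[0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
             - M[0, 1] * (b[1] * M[2, 2] - M[1, 2] * b[2])
             + M[0, 2] * (b[1] * M[2, 1] - M[1, 1] * b[2])) / det,
            (M[0, 0] * (b[1] * M[2, 2] - M[1, 2] * b[2])
             - b[0] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
             + M[0, 2] * (M[1, 0] * b[2] - b[1] * M[2, 0])) / det,
            (M[0, 0] * (M[1, 1] * b[2] - b[1] * M[2, 1])
             - M[0, 1] * (M[1, 0] * b[2] - b[1] * M[2, 0])
             + b[0] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0])) / det,
        ])
        new = theta + step
        new[0] = max(new[0], 0.0)
        new[1:] = np.clip(new[1:], -30.0, 30.0)
        f_new, J_new = _model_and_jacobian(new, r)
        resid_new = f_new - y
        cost_new = float(resid_new @ resid_new)
        if cost_new <= cost:
            theta, resid, J, cost = new, resid_new, J_new, cost_new
            lam = max(lam / 3, 1e-12)
            if np.linalg.norm(step) < step_tol:
                converged = True
                break
        else:
            lam *= 10
            if lam > 1e12:
                break
    return theta, cost, converged


_GRID_A = np.linspace(-8.0, 5.0, 14)
_GRID_B = np.linspace(-2.5, 2.0, 10)
_grid_cache: dict[bytes, np.ndarray] = {}


def _grid_weights(r: np.ndarray) -> np.ndarray:
    """Per-harvest factors 1-exp(k r^p) on the (k, p) start grid.

    Depends only on the intensity vector, so it is cached: repeated
    refits over the same rotation set reuse one matrix.
    """
    key = r.tobytes()
    W = _grid_cache.get(key)
    if W is None:
        a, b = np.meshgrid(_GRID_A, _GRID_B, indexing="ij")
        k = np.exp(a.ravel())[:, None]
        pw = np.exp(b.ravel())[:, None]
        W = 1.0 - np.exp(-k * np.power(r[None, :], -pw))
        if len(_grid_cache) > 64:
            _grid_cache.clear()
        _grid_cache[key] = W
    return W


def fit_yield_curve(
    rotation_ages,
    yields,
    window: tuple[int, int] | None = None,
    initial: "YieldCurveParams | None" = None,
) -> YieldCurveParams:
    """Fit (ymax, k, p) to per-harvest yields at given rotation ages.

    rotation_ages : rotation periods T (years); intensities r = 1/T.
    yields : per-harvest clear-cut yields (m3/ha) at those ages.
    Fits per-harvest yield (not the annualised product) by damped
    Gauss-Newton; ``initial`` warm-starts the iteration (e.g. the
    previous window's params); on non-convergence, falls back to the
    best of a coarse multi-start grid and flags the result.
    """
    T = np.asarray(rotation_ages, float)
    y = np.asarray(yields, float)
    if T.size < 4 or np.unique(T).size < 4:
        raise ValueError("need at least 4 distinct rotation ages")
    if (y < 0).any():
        raise ValueError("yields must be nonnegative")
    r = 1.0 / T

    if initial is not None:
        theta0 = np.array([initial.ymax, np.log(-initial.k), np.log(-initial.p)])
        theta, cost, converged = _gauss_newton(theta0, r, y)
        if converged:
            ymax, a, b = theta
            return YieldCurveParams(
                ymax=float(max(ymax, 0.0)), k=float(-np.exp(a)), p=float(-np.exp(b)),
                window=window, rmse=float(np.sqrt(cost / r.size)), converged=True,
            )

    scale = max(float(y.max()), 1e-12)
    # coarse grid start: ymax solved linearly given (k, p)
    W = _grid_weights(r)
    num = W @ y
    den = (W * W).sum(axis=1)
    ym = np.where(den > 0, np.maximum(num / np.maximum(den, 1e-300), 0.0), 0.0)
    sse = (y * y).sum() - 2 * ym * num + ym * ym * den
    j = int(np.argmin(sse))
    ab = np.array(np.meshgrid(_GRID_A, _GRID_B, indexing="ij"))
    best0 = np.array([ym[j], ab[0].ravel()[j], ab[1].ravel()[j]])
    if not np.isfinite(best0).all():
        best0 = np.array([scale, 1.0, 0.0])

    theta, cost, converged = _gauss_newton(best0, r, y)
    if not converged:
        # multi-start fallback around the grid best
        for da, db in [(-1, 0), (1, 0), (0, -1), (0, 1), (1, 1), (-1, -1)]:
            t2, c2, conv2 = _gauss_newton(best0 + [0.0, da, db], r, y)
            if c2 < cost:
                theta, cost, converged = t2, c2, conv2
    ymax, a, b = theta
    rmse = float(np.sqrt(cost / r.size))
    return YieldCurveParams(
        ymax=float(ymax), k=float(-np.exp(a)), p=float(-np.exp(b)),
        window=window, rmse=rmse, converged=bool(converged),
    )


class YieldCurveModel:
    """Scikit-learn style wrapper around the Gauss-Newton yield fit.

    fit(X, y) takes rotation ages X (n,) or (n,1) and per-harvest
    yields y; predict(X) returns fitted per-harvest yields.  Fitted
    attributes: ``params_`` (:class:`YieldCurveParams`), ``rmse_``,
    ``converged_``.
    """

    def __init__(self, window: tuple[int, int] | None = None):
        self.window = window

    def get_params(self, deep: bool = True):
        return {"window": self.window}

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        ages = np.asarray(X, float).ravel()
        self.params_ = fit_yield_curve(ages, y, window=self.window)
        self.rmse_ = self.params_.rmse
        self.converged_ = self.params_.converged
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        ages = np.asarray(X, float).ravel()
        return per_harvest_yield(1.0 / ages, self.params_)


DEFAULT_ROTATIONS = np.array([10, 13, 16, 20, 25, 32, 40, 50, 64, 80, 100, 128, 160])


def window_rotation_yields(
    tables: YieldTableSet,
    cell_index: int,
    year: int,
    rotations=DEFAULT_ROTATIONS,
):
    """Per-harvest yields vs rotation age from the sliding window.

    For rotation T, averages table yields at stand age T over all
    cohorts whose harvest year (establishment + T) falls inside
    [year - 160, year] and inside table coverage.  Returns (ages,
    yields, used_window).  If the requested window precedes coverage,
    the nearest available window is used and reported.
    """
    lo, hi = year - WINDOW_YEARS, year
    first, last = int(tables.years[0]), int(tables.years[-1])
    if hi > last:
        lo, hi = last - WINDOW_YEARS, last
    if lo < first:
        lo, hi = first, first + WINDOW_YEARS
    ages, means = [], []
    for T in np.asarray(rotations, int):
        vals = []
        for ci, cy in enumerate(tables.cohort_years):
            harvest_year = int(cy) + int(T)
            if lo <= harvest_year <= hi and first <= harvest_year <= last:
                v = tables.values[cell_index, ci, harvest_year - first]
                if np.isfinite(v):
                    vals.append(v)
        if vals:
            ages.append(int(T))
            means.append(float(np.mean(vals)))
    return np.array(ages), np.array(means), (lo, hi)


def sliding_window_refit(
    tables: YieldTableSet,
    year: int,
    rotations=DEFAULT_ROTATIONS,
) -> list[YieldCurveParams]:
    """Re-estimate (ymax, k, p) for every cell at a simulation year."""
    out = []
    for cell_index in range(tables.values.shape[0]):
        ages, ys, window = window_rotation_yields(tables, cell_index, year, rotations)
        if ages.size < 4:
            raise ValueError(
                f"cell {tables.cell_ids[cell_index]!r}: insufficient yield-table "
                f"coverage for window {window}"
            )
        out.append(fit_yield_curve(ages, ys, window=window))
    return out
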