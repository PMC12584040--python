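"""Price-elastic, income-dependent wood demand (MAIDADS).

Per-capita demand for industrial roundwood and wood fuel is modelled
with an implicitly directly additive demand system in which marginal
budget shares slide, as a function of the utility level, between a
low-income vector ``alpha`` and a high-income vector ``beta_star``.
A residual non-wood numeraire good (price 1) closes the budget so the
two-commodity wood subsystem is well posed.

For goods i = (roundwood, fuelwood, numeraire) with prices ``p``,
income ``x``, subsistence quantities ``gamma`` and utility ``u``:

    beta_i(u) = (alpha_i + beta_star_i * e^z) / (1 + e^z),  z = kappa*(u - u0)
    q_i       = gamma_i + beta_i(u)/p_i * (x - sum_j p_j gamma_j)

with ``u`` the root of the implicit-utility equation

    F(u) = sum_i beta_i(u) * log(beta_i(u) * s / p_i) - u = 0,
    s    = x - sum_j p_j gamma_j  (supernumerary income).

Because the marginal shares sum to one at every utility level, the
budget identity sum_i p_i q_i = x holds exactly for any ``u``; the root
of ``F`` selects the utility consistent with the implicitly additive
preferences (scale constant normalised to 1).  Marginal budget shares
approach ``beta_star`` as income grows, so price and income
elasticities vary with the income level.

The system is exposed both as plain functions and as a scikit-learn
style estimator (:class:`MAIDADSDemandSystem`) fitted by multi-start nonlinear least squares on log consumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

N_GOODS = 3  # roundwood, fuelwood, numeraire
WOOD_GOODS = 2

_U_LO, _U_HI = -80.0, 80.0  # bisection bracket for the implicit utility
_N_BISECT = 100


@dataclass(frozen=True)
class MAIDADSParams:
    """Parameters of the three-good demand system.

    gamma      : subsistence quantities (m3/person/yr; numeraire in its own unit)
    alpha      : marginal budget shares in the low-income limit (sum to 1)
    beta_star  : marginal budget shares in the high-income limit (sum to 1)
    kappa      : utility curvature governing the alpha -> beta_star transition
    u0         : utility level at the transition midpoint (the scale
                 normalisation of the implicitly additive preferences)
    """

    gamma: tuple[float, float, float]
    alpha: tuple[float, float, float]
    beta_star: tuple[float, float, float]
    kappa: float = 1.0
    u0: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.gamma, float)
        a = np.asarray(self.alpha, float)
        b = np.asarray(self.beta_star, float)
        if g.shape != (N_GOODS,) or a.shape != (N_GOODS,) or b.shape != (N_GOODS,):
            raise ValueError("gamma, alpha, beta_star must each have three entries")
        if (g < 0).any():
            raise ValueError("subsistence quantities must be nonnegative")
        for name, v in (("alpha", a), ("beta_star", b)):
            if (v < 0).any() or (v > 1).any() or abs(v.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be shares in [0,1] summing to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def as_arrays(self):
        return (
            np.asarray(self.gamma, float),
            np.asarray(self.alpha, float),
            np.asarray(self.beta_star, float),
        )


@dataclass
class DemandPrediction:
    """Per-capita demand prediction with diagnostics."""

    quantity: np.ndarray          # (n, 2) m3/person/yr for the wood goods
    utility: np.ndarray           # (n,) implicit utility level
    subsistence_limited: np.ndarray  # (n,) bool, income below subsistence cost
    income_elasticity: np.ndarray | None = None   # (n, 2)
    own_price_elasticity: np.ndarray | None = None  # (n, 2)


def marginal_shares(u, params: MAIDADSParams) -> np.ndarray:
    """beta_i(u): logistic interpolation between alpha and beta_star."""
    _, a, b = params.as_arrays()
    u = np.asarray(u, float)
    z = np.clip(params.kappa * (u - params.u0), -700.0, 700.0)
    w = 1.0 / (1.0 + np.exp(-z))  # logistic weight in (0,1)
    return a[None, :] * (1.0 - w[..., None]) + b[None, :] * w[..., None]


def _implicit_utility_residual(u, s, prices, params: MAIDADSParams):
    """F(u) for vectors of utilities/incomes; prices shape (n, 3)."""
    beta = marginal_shares(u, params)  # (n, 3)
    arg = beta * s[:, None] / prices
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(beta > 0, beta * np.log(np.where(arg > 0, arg, 1.0)), 0.0)
    return term.sum(axis=1) - np.asarray(u, float)


def solve_utility(s, prices, params: MAIDADSParams) -> np.ndarray:
    """Root of the implicit-utility equation, by vectorised bisection.

    F is +inf-like at u -> -inf and -inf-like at u -> +inf (the -u term
    dominates), so a sign change always exists inside a wide bracket.
    """
    s = np.asarray(s, float)
    prices = np.asarray(prices, float)
    lo = np.full(s.shape, _U_LO)
    hi = np.full(s.shape, _U_HI)
    flo = _implicit_utility_residual(lo, s, prices, params)
    fhi = _implicit_utility_residual(hi, s, prices, params)
    # widen where the fixed bracket misses (extreme incomes)
    for _ in range(10):
        bad_lo = flo < 0
        bad_hi = fhi > 0
        if not bad_lo.any() and not bad_hi.any():
            break
        lo = np.where(bad_lo, lo * 2, lo)
        hi = np.where(bad_hi, hi * 2, hi)
        flo = _implicit_utility_residual(lo, s, prices, params)
        fhi = _implicit_utility_residual(hi, s, prices, params)
    for _ in range(_N_BISECT):
        mid = 0.5 * (lo + hi)
        fm = _implicit_utility_residual(mid, s, prices, params)
        take_lo = fm > 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def predict_percapita(
    income,
    prices,
    params: MAIDADSParams,
    *,
    elasticities: bool = False,
) -> DemandPrediction:
    """Per-capita wood demands at given incomes and prices.

    income : (n,) currency/person/yr;  prices : (n, 2) wood prices
    (currency/m3); the numeraire price is 1.  Incomes at or below the
    subsistence expenditure get demands clipped at gamma with a flag.
    """
    x = np.atleast_1d(np.asarray(income, float))
    p_wood = np.atleast_2d(np.asarray(prices, float))
    if p_wood.shape != (x.size, WOOD_GOODS):
        raise ValueError("prices must have shape (n, 2)")
    if (x <= 0).any() or (p_wood <= 0).any():
        raise ValueError("income and prices must be positive")
    p = np.column_stack([p_wood, np.ones(x.size)])
    gamma, _, _ = params.as_arrays()
    s = x - p @ gamma
    limited = s <= 0

    u = np.zeros(x.size)
    q = np.tile(gamma, (x.size, 1))
    ok = ~limited
    if ok.any():
        u_ok = solve_utility(s[ok], p[ok], params)
        beta = marginal_shares(u_ok, params)
        q[ok] = gamma[None, :] + beta * (s[ok, None] / p[ok])
        u[ok] = u_ok
    u[limited] = -np.inf

    pred = DemandPrediction(
        quantity=q[:, :WOOD_GOODS],
        utility=u,
        subsistence_limited=limited,
    )
    if elasticities:
        h = 1e-4
        qx = predict_percapita(x * (1 + h), p_wood, params).quantity
        with np.errstate(divide="ignore", invalid="ignore"):
            pred.income_elasticity = (qx - pred.quantity) / (
                h * np.where(pred.quantity > 0, pred.quantity, np.nan)
            )
        ope = np.empty_like(pred.quantity)
        for i in range(WOOD_GOODS):
            pp = p_wood.copy()
            pp[:, i] *= 1 + h
            qp = predict_percapita(x, pp, params).quantity
            with np.errstate(divide="ignore", invalid="ignore"):
                ope[:, i] = (qp[:, i] - pred.quantity[:, i]) / (
                    h * np.where(pred.quantity[:, i] > 0, pred.quantity[:, i], np.nan)
                )
        pred.own_price_elasticity = ope
    return pred


def project_country_demand(percapita, population):
    """Total commodity demand: per-capita demand times population."""
    percapita = np.asarray(percapita, float)
    population = np.asarray(population, float)
    if (population < 0).any():
        raise ValueError("population must be nonnegative")
    return percapita * population[..., None] if percapita.ndim > 1 else percapita * population


# ---------------------------------------------------------------------------
# fitting


def _unpack(theta: np.ndarray, kappa: float) -> MAIDADSParams:
    """Unconstrained vector -> valid parameter set.

    theta = (log gamma_1..3, a_1, a_2, b_1, b_2, u0); shares via
    softmax with the numeraire logit pinned to 0.
    """
    gamma = np.exp(np.clip(theta[:3], -60.0, 60.0))
    a = np.append(np.clip(theta[3:5], -40.0, 40.0), 0.0)
    b = np.append(np.clip(theta[5:7], -40.0, 40.0), 0.0)
    alpha = np.exp(a - a.max())
    alpha /= alpha.sum()
    beta = np.exp(b - b.max())
    beta /= beta.sum()
    return MAIDADSParams(tuple(gamma), tuple(alpha), tuple(beta), kappa, float(theta[7]))


def _pack(params: MAIDADSParams) -> np.ndarray:
    g, a, b = params.as_arrays()
    eps = 1e-12
    return np.concatenate(
        [
            np.log(np.maximum(g, eps)),
            np.log(np.maximum(a[:2], eps)) - np.log(max(a[2], eps)),
            np.log(np.maximum(b[:2], eps)) - np.log(max(b[2], eps)),
            [params.u0],
        ]
    )


class MAIDADSDemandSystem:
    """Scikit-learn style estimator for the wood demand system.

    Parameters
    ----------
    n_starts : number of multi-start local optimisations (non-convex loss).
    kappa : fixed utility curvature of the share transition.
    floor : additive floor (m3/person/yr) applied to modelled and
        observed consumption inside the log loss, so zero-consumption
        observations remain informative.
    random_state : seed for the start perturbations.

    Fitted attributes: ``params_`` (:class:`MAIDADSParams`), ``loss_``
    (sum of squared log residuals of the best start), ``converged_``,
    ``n_starts_run_``, ``start_losses_``.
    """

    def __init__(self, n_starts: int = 10, kappa: float = 2.0,
                 floor: float = 1e-6, random_state: int = 0):
        self.n_starts = n_starts
        self.kappa = kappa
        self.floor = floor
        self.random_state = random_state

    # -- sklearn estimator interface ----------------------------------------
    def get_params(self, deep: bool = True):
        return {
            "n_starts": self.n_starts,
            "kappa": self.kappa,
            "floor": self.floor,
            "random_state": self.random_state,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core ---------------------------------------------------------------
    def _residuals(self, theta, x, p_wood, q_obs):
        params = _unpack(theta, self.kappa)
        q_hat = predict_percapita(x, p_wood, params).quantity
        return (
            np.log(q_hat + self.floor) - np.log(q_obs + self.floor)
        ).ravel()

    def _heuristic_start(self, x, p_wood, q_obs):
        q_pos = np.where(q_obs > 0, q_obs, np.nan)
        gamma_w = 0.5 * np.nanmin(q_pos, axis=0)
        gamma_w = np.where(np.isfinite(gamma_w), gamma_w, self.floor)
        gamma_n = 0.05 * float(np.min(x))
        order = np.argsort(x)
        lo = order[: max(3, x.size // 3)]
        hi = order[-max(3, x.size // 3):]
        share = p_wood * q_obs / x[:, None]

        def logits(idx):
            s = np.clip(share[idx].mean(axis=0), 1e-6, 0.5)
            rest = max(1.0 - s.sum(), 1e-6)
            return np.log(s / rest)

        u0_guess = np.log(float(np.median(x)))
        return np.concatenate(
            [np.log(np.r_[np.maximum(gamma_w, 1e-12), max(gamma_n, 1e-12)]),
             logits(lo), logits(hi), [u0_guess]]
        )

    def fit(self, X, y):
        """Fit to observations.

        X : (n, 3) columns [income, price_roundwood, price_fuelwood].
        y : (n, 2) per-capita consumption [roundwood, fuelwood].
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[1] != 3 or y.shape != (X.shape[0], 2):
            raise ValueError("X must be (n,3) [income, p_rw, p_wf]; y (n,2)")
        if X.shape[0] < 30:
            raise ValueError("need at least 30 observations")
        x, p_wood = X[:, 0], X[:, 1:3]
        if (x <= 0).any() or (p_wood <= 0).any():
            raise ValueError("income and prices must be positive")
        if (y < 0).any():
            raise ValueError("consumption must be nonnegative")
        if np.ptp(x) / np.median(x) < 1e-6:
            raise ValueError("degenerate panel: no income variation")

        rng = np.random.default_rng(self.random_state)
        theta0 = self._heuristic_start(x, p_wood, y)
        starts = [theta0]
        for _ in range(self.n_starts - 1):
            starts.append(theta0 + rng.normal(scale=[1.0] * 3 + [0.7] * 4 + [1.0]))

        best = None
        losses = []
        for s0 in starts:
            try:
                res = least_squares(
                    self._residuals, s0, args=(x, p_wood, y),
                    method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=4000,
                )
            except Exception:
                losses.append(np.inf)
                continue
            losses.append(2 * res.cost)
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        self.params_ = _unpack(best.x, self.kappa)
        self.loss_ = float(2 * best.cost)
        self.converged_ = bool(best.status > 0)
        self.n_starts_run_ = len(starts)
        self.start_losses_ = losses
        return self

    def predict(self, X, *, elasticities: bool = False):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, float)
        pred = predict_percapita(X[:, 0], X[:, 1:3], self.params_,
                                 elasticities=elasticities)
        return pred if elasticities else pred.quantity


def fit_demand_system(observations, **kw) -> MAIDADSDemandSystem:
    """Functional wrapper: observations is a DataFrame with columns
    gdp_percap, price_roundwood, price_woodfuel, cons_roundwood,
    cons_woodfuel (per-capita m3)."""
    X = observations[["gdp_percap", "price_roundwood", "price_woodfuel"]].to_numpy()
    y = observations[["cons_roundwood", "cons_woodfuel"]].to_numpy()
    return MAIDADSDemandSystem(**kw).fit(X, y)


def save_params(params: MAIDADSParams, meta: dict, path) -> None:
    """Write fitted parameters + metadata as a flat key-value text file."""
    lines = []
    names = ["roundwood", "woodfuel", "numeraire"]
    for i, n in enumerate(names):
        lines.append(f"gamma_{n} = {params.gamma[i]!r}")
        lines.append(f"alpha_{n} = {params.alpha[i]!r}")
        lines.append(f"beta_star_{n} = {params.beta_star[i]!r}")
    lines.append(f"kappa = {params.kappa!r}")
    lines.append(f"u0 = {params.u0!r}")
    for k, v in meta.items():
        lines.append(f"{k} = {v!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
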