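"""Shared fixtures: a default synthetic world and a fitted demand system."""

import numpy as np
import pandas as pd
import pytest

from woodsim.demand import MAIDADSDemandSystem, predict_percapita
from woodsim.world import DEFAULT_TRUE_PARAMS, WorldSpec, make_world


@pytest.fixture(scope="session")
def world():
    return make_world(WorldSpec())


@pytest.fixture(scope="session")
def demand_model(world):
    m = MAIDADSDemandSystem(n_starts=3, random_state=0)
    X = world.calibration[["gdp_percap", "price_roundwood", "price_woodfuel"]].to_numpy()
    y = world.calibration[["cons_roundwood", "cons_woodfuel"]].to_numpy()
    return m.fit(X, y)


@pytest.fixture(scope="session")
def noisy_panel():
    """Simulated observations from the implemented demand form, sigma=0.1."""
    rng = np.random.default_rng(2024)
    n = 200
    x = np.exp(rng.normal(9.2, 1.1, n))
    prices = np.column_stack([
        90 * np.exp(rng.normal(0, 0.12, n)),
        40 * np.exp(rng.normal(0, 0.12, n)),
    ])
    q = predict_percapita(x, prices, DEFAULT_TRUE_PARAMS).quantity
    q_noisy = q * np.exp(rng.normal(0, 0.1, (n, 2)))
    return np.column_stack([x, prices]), q, q_noisy


def random_cells(n, rng, protected_rate=0.0):
    """Random optimizer-schema cells with admissible yield parameters."""
    rows = []
    for i in range(n):
        ft, fu, fa = rng.uniform(0.1, 0.4), rng.uniform(0.2, 0.4), rng.uniform(0.05, 0.2)
        rows.append(dict(
            cell=f"X{i}", area_ha=rng.uniform(1e5, 3e5), frac_timber=ft,
            frac_unmanaged=fu, frac_agri=fa, frac_other=1 - ft - fu - fa,
            intensity=0.02, ymax=rng.uniform(200, 600),
            k=-(10.0 ** rng.uniform(-2, -0.5)), p=rng.uniform(-1.6, -0.9),
            protected=bool(rng.random() < protected_rate)))
    return pd.DataFrame(rows)
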