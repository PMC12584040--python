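"""Single global wood market: trade limits, balance, endogenous price.

All wood is traded in one pool (no distinction between products on the
supply side).  Net-import changes per country are constrained to a band
around the current level (a fraction of current trade, with an absolute
floor so zero-trade entrants can start trading) and carry a small
per-m3 change cost inside the country decision.  Each year the net
balance of global demand and supply moves a global stock, and the price
index (2020 = 100) is updated multiplicatively with the relative excess
demand:

    index' = index * (1 + lambda * (demand - supply) / max(demand, eps))

A cleared market is a fixed point; excess demand raises the index.
Both wood commodities carry the same index movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASE_YEAR = 2020
BASE_INDEX = 100.0


@dataclass
class MarketState:
    """Global wood-market state for one year."""

    year: int
    price_index: float = BASE_INDEX
    stock: float = 0.0                       # m3
    net_imports: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self):
        if self.price_index <= 0:
            raise ValueError("price index must be positive")


def constrain_net_imports(
    desired: float,
    current: float,
    limit_fraction: float,
    floor: float = 0.0,
) -> float:
    """Clip a desired net-import level to the allowed band.

    The band is current +- max(limit_fraction*|current|, floor); the
    floor admits entrants with no current trade.
    """
    if limit_fraction <= 0:
        raise ValueError("limit fraction must be positive")
    band = max(limit_fraction * abs(current), floor)
    return float(np.clip(desired, current - band, current + band))


def update_price(
    price_index: float,
    global_demand: float,
    global_supply: float,
    adjustment_rate: float,
    eps: float = 1e-9,
) -> float:
    """Multiplicative excess-demand price update (see module docstring)."""
    if global_demand < 0 or global_supply < 0:
        raise ValueError("demand and supply must be nonnegative")
    if not 0 < adjustment_rate <= 1:
        raise ValueError("adjustment rate must be in (0, 1]")
    excess = (global_demand - global_supply) / max(global_demand, eps)
    return float(price_index * (1.0 + adjustment_rate * excess))


def step_market(
    state: MarketState,
    consumption: pd.Series,
    harvest: pd.Series,
    adjustment_rate: float,
) -> MarketState:
    """Aggregate country balances, move the stock, update the price.

    Per-country net imports are consumption - harvest; their global sum
    is met from (or added to) the stock, so sum(net imports) + stock
    change = 0 holds by construction.
    """
    net_imports = (consumption - harvest).astype(float)
    demand = float(consumption.sum())
    supply = float(harvest.sum())
    new_index = update_price(state.price_index, demand, supply, adjustment_rate)
    return MarketState(
        year=state.year + 1,
        price_index=new_index,
        stock=state.stock + (supply - demand),
        net_imports=net_imports,
    )
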