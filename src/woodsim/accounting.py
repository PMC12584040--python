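"""Wood-product accounting: apparent consumption and price estimation.

Converts heterogeneous country-level wood-product statistics (production,
imports, exports of ten reported items) into commodity-level apparent
consumption of the two raw commodities — industrial roundwood and wood
fuel — together with trade-based price estimates.  Apparent consumption
per country and year is the mass balance

    consumption = harvest + sum(imports_i) - sum(exports_i)

where the sums run over all items mapped to the commodity, item
quantities reported in tonnes having first been converted to cubic
metres with fixed conversion ratios.  Processed items are counted at a
one-to-one volume equivalence with their raw commodity; their domestic
production is embodied in the raw harvest and does not enter the
balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

INDUSTRIAL_ROUNDWOOD = "industrial roundwood"
WOOD_FUEL = "wood fuel"
COMMODITIES = (INDUSTRIAL_ROUNDWOOD, WOOD_FUEL)

#: Reported item -> raw commodity it is counted against.
ITEM_COMMODITY: dict[str, str] = {
    "Industrial roundwood": INDUSTRIAL_ROUNDWOOD,
    "Sawnwood": INDUSTRIAL_ROUNDWOOD,
    "Wood-based panels": INDUSTRIAL_ROUNDWOOD,
    "Veneer sheets": INDUSTRIAL_ROUNDWOOD,
    "Wood chips, particles and residues": INDUSTRIAL_ROUNDWOOD,
    "Wood pulp": INDUSTRIAL_ROUNDWOOD,
    "Paper and paperboard": INDUSTRIAL_ROUNDWOOD,
    "Wood fuel": WOOD_FUEL,
    "Wood pellets and other agglomerates": WOOD_FUEL,
    "Wood charcoal": WOOD_FUEL,
}

#: m3 per tonne for the items reported by mass; all other items are in m3.
MASS_CONVERSION_M3_PER_T: dict[str, float] = {
    "Wood pulp": 1.48,
    "Paper and paperboard": 1.48,
    "Wood pellets and other agglomerates": 1.38,
    "Wood charcoal": 5.99,
}

#: Items whose production counts as raw harvest of the commodity itself.
RAW_ITEMS = ("Industrial roundwood", "Wood fuel")

FLOWS = ("production", "import", "export")

RECORD_COLUMNS = ["country", "year", "item", "flow", "quantity", "unit", "value"]


class UnknownItemError(ValueError):
    """Raised for an item name outside the reported-item vocabulary."""


def map_item(item: str) -> str:
    """Return the raw commodity an item is counted against."""
    try:
        return ITEM_COMMODITY[item]
    except KeyError:
        raise UnknownItemError(f"unknown wood item: {item!r}") from None


def convert_to_volume(quantity: float, item: str) -> float:
    """Convert a reported quantity to m3.

    Mass-reported items (wood pulp, paper and paperboard, wood pellets
    and other agglomerates, wood charcoal) are multiplied by their m3/t
    ratio; items already reported in m3 pass through unchanged.
    """
    if item not in ITEM_COMMODITY:
        raise UnknownItemError(f"unknown wood item: {item!r}")
    quantity = float(quantity)
    if quantity < 0:
        raise ValueError(f"negative quantity {quantity} for {item!r}")
    return quantity * MASS_CONVERSION_M3_PER_T.get(item, 1.0)


def apparent_consumption(
    harvest: float,
    imports: Iterable[float] = (),
    exports: Iterable[float] = (),
) -> float:
    """Mass-balance apparent consumption: harvest + imports − exports.

    A negative result signals inconsistent inputs and is returned as-is
    (callers flag it); the inputs themselves must be nonnegative.
    """
    imports = list(imports)
    exports = list(exports)
    for v in [harvest, *imports, *exports]:
        if v < 0:
            raise ValueError("flow volumes must be nonnegative")
    return float(harvest) + float(np.sum(imports)) - float(np.sum(exports))


@dataclass(frozen=True)
class PriceEstimate:
    """Trade-based commodity price for one country (currency per m3)."""

    country: str
    commodity: str
    price: float | None
    provenance: str  # "observed" | "median-imputed" | "absent"
    inconsistent: bool = False


def estimate_price(
    import_value: float,
    import_volume: float,
    export_value: float,
    export_volume: float,
    *,
    country: str = "",
    commodity: str = "",
) -> PriceEstimate:
    """Volume-weighted mean of unit import and export prices.

    price = (import value + export value) / (import volume + export volume).
    With no trade at all the estimate is absent (to be median-imputed
    later).  A nonzero value paired with zero volume is flagged
    inconsistent and the offending value is dropped from the average.
    """
    if import_volume < 0 or export_volume < 0:
        raise ValueError("trade volumes must be nonnegative")
    inconsistent = False
    if import_value > 0 and import_volume == 0:
        inconsistent = True
        import_value = 0.0
    if export_value > 0 and export_volume == 0:
        inconsistent = True
        export_value = 0.0
    total_volume = import_volume + export_volume
    if total_volume == 0:
        return PriceEstimate(country, commodity, None, "absent", inconsistent)
    price = (import_value + export_value) / total_volume
    if price <= 0:
        return PriceEstimate(country, commodity, None, "absent", inconsistent)
    return PriceEstimate(country, commodity, float(price), "observed", inconsistent)


CorrectionHook = Callable[[pd.DataFrame], pd.DataFrame]


def apply_corrections(
    records: pd.DataFrame, hook: CorrectionHook | None = None
) -> pd.DataFrame:
    """Apply a user-supplied correction transformation to raw records.

    The default hook is the identity.  The corrected records must keep
    the input schema and nonnegative quantities/values.
    """
    if hook is None:
        return records.copy()
    corrected = hook(records.copy())
    missing = set(RECORD_COLUMNS) - set(corrected.columns)
    if missing:
        raise ValueError(f"correction hook dropped columns: {sorted(missing)}")
    if (corrected["quantity"] < 0).any() or (corrected["value"].fillna(0) < 0).any():
        raise ValueError("correction hook produced negative quantities or values")
    return corrected


def validate_records(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    unknown = set(records["item"]) - set(ITEM_COMMODITY)
    if unknown:
        raise UnknownItemError(f"unknown wood item(s): {sorted(unknown)}")
    bad_flow = set(records["flow"]) - set(FLOWS)
    if bad_flow:
        raise ValueError(f"unknown flow kind(s): {sorted(bad_flow)}")
    if (records["quantity"] < 0).any():
        raise ValueError("quantities must be nonnegative")


def _to_m3(df: pd.DataFrame) -> pd.Series:
    ratio = df["item"].map(MASS_CONVERSION_M3_PER_T).fillna(1.0)
    is_tonnes = df["unit"].eq("t")
    # items reported in m3 keep ratio 1 regardless of the mass table
    return df["quantity"] * np.where(is_tonnes, ratio, 1.0)


def build_commodity_flows(
    records: pd.DataFrame, hook: CorrectionHook | None = None
) -> pd.DataFrame:
    """Aggregate item records into per-country commodity flow tables.

    Returns one row per (country, year, commodity) with columns
    harvest_m3, imports_m3, exports_m3, consumption_m3 (the mass
    balance, flagged when negative), price and price_provenance.
    Missing prices are imputed with the median over countries with
    observed prices for that commodity and year.
    """
    validate_records(records)
    df = apply_corrections(records, hook)
    df = df.assign(
        commodity=df["item"].map(ITEM_COMMODITY),
        volume_m3=_to_m3(df),
        is_raw=df["item"].isin(RAW_ITEMS),
    )

    keys = ["country", "year", "commodity"]
    harvest = (
        df[df["is_raw"] & df["flow"].eq("production")]
        .groupby(keys)["volume_m3"]
        .sum()
        .rename("harvest_m3")
    )
    imports = (
        df[df["flow"].eq("import")].groupby(keys)["volume_m3"].sum().rename("imports_m3")
    )
    exports = (
        df[df["flow"].eq("export")].groupby(keys)["volume_m3"].sum().rename("exports_m3")
    )
    trade_value = (
        df[df["flow"].isin(["import", "export"])]
        .groupby(keys)["value"]
        .sum(min_count=1)
        .rename("trade_value")
    )

    # full index so autarkic or one-sided records still appear
    idx = pd.MultiIndex.from_frame(
        df[["country", "year"]]
        .drop_duplicates()
        .merge(pd.DataFrame({"commodity": COMMODITIES}), how="cross")
    )
    out = (
        pd.concat([harvest, imports, exports, trade_value], axis=1)
        .reindex(idx)
        .fillna({"harvest_m3": 0.0, "imports_m3": 0.0, "exports_m3": 0.0})
        .reset_index()
    )
    out["consumption_m3"] = (
        out["harvest_m3"] + out["imports_m3"] - out["exports_m3"]
    )
    out["negative_consumption"] = out["consumption_m3"] < 0

    # trade-based price per (country, year, commodity)
    prices = []
    for _, row in out.iterrows():
        mask = (
            df["country"].eq(row["country"])
            & df["year"].eq(row["year"])
            & df["commodity"].eq(row["commodity"])
        )
        imp = df[mask & df["flow"].eq("import")]
        exp = df[mask & df["flow"].eq("export")]
        est = estimate_price(
            float(imp["value"].sum()),
            float(imp["volume_m3"].sum()),
            float(exp["value"].sum()),
            float(exp["volume_m3"].sum()),
            country=str(row["country"]),
            commodity=str(row["commodity"]),
        )
        prices.append(est)
    out["price"] = [e.price for e in prices]
    out["price_provenance"] = [e.provenance for e in prices]

    # median imputation over countries with observed prices (commodity-year)
    for (year, commodity), grp in out.groupby(["year", "commodity"]):
        observed = grp.loc[grp["price_provenance"].eq("observed"), "price"]
        if observed.empty:
            continue
        med = float(observed.median())
        fill = grp.index[grp["price"].isna()]
        out.loc[fill, "price"] = med
        out.loc[fill, "price_provenance"] = "median-imputed"

    return out[
        [
            "country",
            "year",
            "commodity",
            "harvest_m3",
            "imports_m3",
            "exports_m3",
            "consumption_m3",
            "negative_consumption",
            "price",
            "price_provenance",
        ]
    ]
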