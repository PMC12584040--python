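"""Multiplicative attribution of harvest change to its drivers.

The change in global wood harvest between a baseline and a final year
is decomposed into contributions from timber-forest area, management
intensity, potential yield (the fitted yield-curve parameters), and the
intensity x yield interaction.  Counterfactual harvests are computed
from the annualised harvest function for the corner combinations of the
two epochs:

    H(a, b, c) = sum_cells area[a] * ymax[c] * (1 - exp(k[c] r[b]^p[c])) * r[b]

with a, b, c in {baseline, final} selecting the epoch of area,
intensity and yield parameters.  Factor ratios are

    area      = H(1,0,0) / H(0,0,0)
    intensity = H(0,1,0) / H(0,0,0)
    yield     = H(0,0,1) / H(0,0,0)
    interaction = total / (area * intensity * yield)

Because harvest is linear in area, area has no interaction terms and
the residual interaction is exactly the intensity x yield term; the
product of the four ratios equals the total harvest ratio identically.
Contributions are reported as (ratio - 1) * 100 percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizer import cell_yield


@dataclass
class HarvestFactors:
    """Per-cell harvest drivers for one epoch."""

    area: np.ndarray       # timber area per cell (ha)
    intensity: np.ndarray  # management intensity r (1/yr)
    ymax: np.ndarray
    k: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        n = len(self.area)
        for name in ("intensity", "ymax", "k", "p"):
            if len(getattr(self, name)) != n:
                raise ValueError("factor arrays must share one cell set")

    @property
    def harvest(self) -> float:
        return float(
            (self.area * cell_yield(self.intensity, self.ymax, self.k, self.p)).sum()
        )


@dataclass(frozen=True)
class AttributionResult:
    """Multiplicative factor ratios and percentage contributions."""

    area_ratio: float
    intensity_ratio: float
    yield_ratio: float
    interaction_ratio: float
    total_ratio: float

    @property
    def contributions_pct(self) -> dict[str, float]:
        return {
            "area": (self.area_ratio - 1.0) * 100.0,
            "intensity": (self.intensity_ratio - 1.0) * 100.0,
            "potential_yield": (self.yield_ratio - 1.0) * 100.0,
            "intensity_x_yield": (self.interaction_ratio - 1.0) * 100.0,
            "total": (self.total_ratio - 1.0) * 100.0,
        }

    @property
    def closure_residual(self) -> float:
        prod = (
            self.area_ratio
            * self.intensity_ratio
            * self.yield_ratio
            * self.interaction_ratio
        )
        return abs(prod - self.total_ratio) / abs(self.total_ratio)


def counterfactual_harvest(
    baseline: HarvestFactors, final: HarvestFactors, a: int, b: int, c: int
) -> float:
    """Harvest with area from epoch a, intensity from b, yield params from c."""
    eps = (baseline, final)
    return float(
        (
            eps[a].area
            * cell_yield(eps[b].intensity, eps[c].ymax, eps[c].k, eps[c].p)
        ).sum()
    )


def decompose(baseline: HarvestFactors, final: HarvestFactors) -> AttributionResult:
    """Attribute the harvest change between two epochs to its factors."""
    if len(baseline.area) != len(final.area):
        raise ValueError("epochs must cover matching cell sets")
    h000 = counterfactual_harvest(baseline, final, 0, 0, 0)
    if h000 <= 0:
        raise ValueError("zero baseline harvest: factor ratios undefined")
    h111 = counterfactual_harvest(baseline, final, 1, 1, 1)
    area_ratio = counterfactual_harvest(baseline, final, 1, 0, 0) / h000
    intensity_ratio = counterfactual_harvest(baseline, final, 0, 1, 0) / h000
    yield_ratio = counterfactual_harvest(baseline, final, 0, 0, 1) / h000
    total_ratio = h111 / h000
    interaction = total_ratio / (area_ratio * intensity_ratio * yield_ratio)
    return AttributionResult(
        area_ratio=area_ratio,
        intensity_ratio=intensity_ratio,
        yield_ratio=yield_ratio,
        interaction_ratio=interaction,
        total_ratio=total_ratio,
    )
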