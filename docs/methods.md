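# Methods

This note documents the model equations, the numerical choices, the
synthetic-data generator and the known limitations of `woodsim`.

## Wood accounting

Ten reported wood items map to two raw commodities (industrial
roundwood, wood fuel).  Items reported in tonnes — wood pulp, paper and
paperboard (1.48 m³/t), wood pellets and other agglomerates (1.38 m³/t),
wood charcoal (5.99 m³/t) — are converted to cubic metres; all other
items are already volumes.  Processed items are counted at one-to-one
volume equivalence with their raw commodity and their *production* rows
do not enter the mass balance (the raw harvest already embodies them);
their trade does.  Apparent consumption per country, year and commodity
is

    consumption = harvest + Σᵢ importsᵢ − Σᵢ exportsᵢ

and may be negative for inconsistent inputs, in which case the row is
flagged rather than rejected.  Commodity prices are total trade value
over total trade volume — the volume-weighted mean of unit import and
export prices; countries without trade receive the median over
observed country prices for that commodity and year (midpoint
convention for even counts).  A value reported against zero volume is
flagged inconsistent and excluded from the average.  Data corrections
(under-reporting, inconsistencies) are a pluggable hook with identity
default; a non-default hook must preserve the record schema and
nonnegativity.

## Demand system

A three-good implicitly directly additive system: industrial
roundwood, wood fuel, and a non-wood numeraire (price 1) that closes
the budget so the two-good wood subsystem is well posed.  Parameters
per good: subsistence γᵢ ≥ 0, low-income marginal budget share αᵢ and
high-income share βᵢ\* (each share vector sums to 1), plus a curvature
κ > 0 and a transition location u₀ shared across goods.  Demands and
the implicit utility are

    βᵢ(u) = (αᵢ + βᵢ* e^{κ(u−u₀)}) / (1 + e^{κ(u−u₀)})
    qᵢ    = γᵢ + (βᵢ(u)/pᵢ)(x − Σⱼ pⱼγⱼ)
    0     = Σᵢ βᵢ(u) ln(βᵢ(u)(x − Σpγ)/pᵢ) − u .

Because Σᵢβᵢ(u) = 1 identically, adding-up (Σ pᵢqᵢ = x) holds exactly
for any u; the implicit equation (scale constant normalised to 1)
selects the utility consistent with the preferences.  u₀ plays the role
of the scale normalisation of the implicitly additive utility: without
it the α→β\* transition would be pinned near supernumerary income ≈ 1
currency unit.  The residual is decreasing at ±∞ (the −u term
dominates), so a sign change always exists in a wide bracket; the root
is found by 100 vectorised bisection steps (residual ≪ 1e-10).  Incomes
at or below subsistence expenditure get demands clipped at γ with a
flag.  Elasticities are forward-difference numerical (relative step
1e-4).

**Fitting.**  Sum of squared log residuals of the two wood goods, with
an additive floor of 1e-6 m³/person/yr on modelled and observed values
so zero-consumption observations stay in the loss.  Parameters are
transformed to an unconstrained vector (log γ, share logits with the
numeraire logit pinned at 0, u₀ free; κ is a fixed hyperparameter,
default 2) and minimised with Levenberg–Marquardt least squares from
multiple starts: one moment-based heuristic start (γ from minimum
observed consumption, shares from budget shares of the poorest and
richest income terciles, u₀ from log median income) plus seeded random
perturbations; the best of `n_starts` (default 10) is kept.  At least
30 observations with income variation are required.

## Yield tables and the harvest function

The synthetic generator stands in for a process-based vegetation
model.  Per grid cell, stand volume follows a Chapman-Richards curve
V(a) = v_max (1 − e^{−rate·a})^shape; stands are established every 20
years from 1850 to 2090 (after one non-forest year, so age 1 is the
first growth year) and tables run to 2100.  A multiplicative
climate/CO₂ trend applies per establishment cohort, which is how an
RCP-style productivity signal enters the simulator.  Harvested biomass
from a clear-cut is 100% of the trunk pool (65% of wood biomass), 95%
of twigs and branches (13%) and 10% of coarse roots (22%); volumes
convert at 0.3 tC per m³.

The annualised harvest at management intensity r (the reciprocal of
the rotation period, bounded to [0.00625, 0.1] yr⁻¹ by the 160-year
table scope and realistic shortest rotations) is

    y(r) = ymax (1 − e^{k rᵖ}) r ,  k < 0, p < 0 .

The per-harvest factor approaches ymax for long rotations and 0 for
short ones — the unique sign choice with that behaviour.  (ymax, k, p)
are fitted to per-harvest yields (volume at stand age T = 1/r, averaged
over the cohorts whose harvest year falls in the 160-year window ending
at the simulation year) rather than to annualised values; the residual
weighting differs between the two conventions and the per-harvest
choice weights long rotations equally.  The fit is damped Gauss–Newton
in transformed parameters (ymax, k = −eᵃ, p = −eᵇ, making the sign
constraints structural), at most 200 iterations, stopping when the step
norm falls below 1e-10, with a Levenberg damping parameter adapted by
accept/reject.  The start point comes from a cached coarse grid over
(a, b) with ymax solved linearly; non-convergence falls back to a
multi-start around the grid best and flags the result.  Warm starts
from the previous window accelerate the sliding-window refits inside
the simulation loop (refits run every 5 years by default; tables only
change at 20-year cohort spacing).

**Consistency between generator and optimiser.**  The least-cost
allocation assumes harvest rises with intensity.  y(r) is globally
nondecreasing iff p ≥ −1, and a fitted curve is monotone over the
admissible range exactly when the table's mean annual increment
culminates by the shortest rotation (10 years).  The default biome
archetypes (boreal 320 m³/ha, rate 0.07; temperate 450, 0.09; tropical
560, 0.13; shapes 1.3–1.4) are therefore fast-saturating: volume still
triples between ages 10 and 160, but MAI culminates early.  This is a
deliberate stylisation — real boreal MAI culminates far later — chosen
so that every fitted cell satisfies the monotonicity the optimiser
relies on.  Cross-family fits to these tables carry ~0.3% relative
RMSE.

## Least-cost land allocation

Cells carry land-cover fractions (timber forest, unmanaged forest,
agriculture, other; summing to 1), an intensity, fitted yield
parameters and a protection flag.  Annual management cost is c·r per
hectare; converting unmanaged forest to timber costs a one-off amount
per hectare (charged in the decision year); net-import changes carry a
small per-m³ cost.  Per country and year the solver:

1. contracts timber area (least-productive land first, released to
   unmanaged forest) when even minimum-intensity management would
   oversupply the requirement;
2. otherwise allocates intensity increments on a shared 384-point
   geometric r-grid greedily by marginal yield per unit cost —
   equivalent to equalising dy/dr across interior cells — after
   pooling any non-concave cell's increments to non-increasing slopes
   (pool-adjacent-violators), then trims the residual overshoot by
   bisection on single cells so the requirement is met exactly;
3. expands into unprotected unmanaged forest when intensification is
   exhausted, cheapest effective m³ first (minimising
   (c·r + conversion)/y(r) over r per cell), the final cell partially;
4. reports any remaining gap as a shortfall for the market to serve
   from stock.

An optional SLSQP refinement polishes small instances; on 100 random
instances of up to three cells the greedy solution's cost matches
exhaustive grid search to better than 0.5% (in practice it is never
worse than the grid optimum).  Ties between equal-cost cells break by
cell id, so runs are reproducible.  Spin-up abandonment moves timber
to unmanaged forest wherever even maximal management yields less than
a viability threshold (default 0.2 m³/ha/yr — a placeholder exposed as
config).  Agricultural area is an exogenous per-country trajectory:
expansion takes unmanaged forest first, then timber, least-productive
and unprotected cells first; contraction returns land to unmanaged
forest.

## Market and price

All wood trades in one pool.  Desired net imports evolve with a
country's demand growth and are clipped to current ± max(limit·|current|,
floor) — the floor admits entrants.  Each year the global stock absorbs
the supply–demand balance and the price index (2020 = 100) updates as

    index' = index · (1 + λ (D − S) / max(D, ε)) ,

a multiplicative excess-demand rule with one interpretable knob λ
(default 0.05, sampled across ensemble members).  A cleared market is a
fixed point; both commodity prices move with the same index.  Within
the simulation, consumption is always met (shortfalls are served from
stock), so the index rises exactly when countries cannot harvest their
requirement and falls when minimum-intensity management oversupplies.

## Scenarios, ensembles, attribution

A scenario bundles driver trajectories (population, income per capita,
agricultural area, potential-yield trend), cost parameters, the price
knob, trade limits and sampled-parameter distributions.  The annual
loop (start year is the initialisation; steps begin the following
year) executes demand projection → trade-constrained requirement →
country optimisation → market aggregation and price update → periodic
sliding-window yield refit.  The loop is a pure function of (world,
demand parameters, config).

Ensemble members draw multipliers for management cost, conversion
cost, λ and the yield-trend exponent from configured distributions,
using substreams seeded by hashing (master seed, member index), so
earlier members are unchanged when the ensemble grows.  Summaries
report the yearly median and the 5th–95th percentile band — the "90%
interval" of ensemble figures is implemented as that percentile band.
Failed members are logged and skipped.

Harvest change between two years is attributed with corner
counterfactuals of the annualised harvest sum: area ratio
H(1,0,0)/H(0,0,0), intensity ratio H(0,1,0)/H(0,0,0), potential-yield
ratio H(0,0,1)/H(0,0,0) (the yield factor swaps the *fitted curve
parameters*, not the underlying tables), and the interaction as the
total ratio divided by the three.  Harvest is linear in area, so the
residual interaction is exactly the intensity×yield term and the four
ratios multiply to the total identically.  Contributions are
(ratio − 1)·100%.

## Synthetic world

The default world has 12 simulated countries × 25 cells over three
biome archetypes, horizon 2020–2060 (a 2100 horizon is a spec field
away), plus a 60-country base-year cross-section for demand fitting —
the fit needs a wide income range, while the simulated grid stays
desk-scale.  Incomes are log-normal (median ≈ 10k, σ = 1.1 in logs);
prices scatter log-normally (σ = 0.12) around 90 (roundwood) and 40
(wood fuel) currency/m³; populations are log-normal.  Consumption
comes from the implemented demand system at generating parameters
chosen to reproduce the stylised Engel facts (roundwood rising in
income; wood fuel hump-shaped, peaking near 5–10k income) with optional
multiplicative log-normal noise.  Net-import shares are drawn in
±25% of consumption and recentred so trade sums to zero — the mass
balance closes globally by construction; trade splits 70% raw item /
30% a processed item (in tonnes) to exercise unit conversion.  Cell
land-cover fractions, areas (~250 kha ± scatter) and a 10% protected
share are drawn per cell; growth parameters scatter log-normally around
the biome archetype.  Everything is deterministic given the WorldSpec seed.

What the generator does *not* emulate: real country heterogeneity in
preferences (one parameter set generates all countries), reporting
error structure beyond log-normal noise, bilateral trade geography,
disturbance and species effects on yields, and within-year stock
dynamics.  Passing tests therefore demonstrate internal consistency
and recoverability under the model's own assumptions, not fidelity to
any specific country's statistics.

## Numerical choices and degenerate inputs

- Implicit-utility bracket [−80, 80], doubled up to 10 times if a sign
  change is missing; 100 bisection steps.
- Demand-fit tolerances 1e-14 (xtol/ftol/gtol), max 4000 evaluations.
- Yield fit: 140-point cached start grid, step-norm stop 1e-10,
  damping in [1e-12, 1e12].
- Optimiser r-grid 384 points (geometric); overshoot trim by 80
  bisection steps; requirement met to ~1e-12 relative, which is what
  makes a cleared stationary market an exact price fixed point.
- Constant yield tables fit to a flat curve (ymax ≈ the constant);
  zero-consumption observations enter via the 1e-6 floor; empty cell
  sets return a full shortfall; a correction hook violating
  nonnegativity is rejected.

## Problem sizes

Defaults used by the test suite and the acceptance script: 12×25-cell
worlds to 2060, a 60-country fitting cross-section, 30-member
ensembles, 50-replicate Monte-Carlo refit studies at n = 200
observations, and 100 random optimiser-oracle instances.  These sizes
were chosen to exercise every moving part at desk scale.

## Known limitations

- The agricultural side is an exogenous area trajectory, not a coupled
  food system; land competition is therefore one-directional.
- The under-reporting corrections applied to real-world statistics are
  not reproducible here; the hook defers them.
- Trade is a single global pool with band constraints; no bilateral
  structure, transport costs or tariffs.
- The price rule responds to quantity imbalance only; cost shocks move
  prices only through their effect on feasible supply.
- Conversion-cost magnitudes, the trade band/floor and the spin-up
  viability threshold are loosely set configuration defaults, not
  calibrated values.
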