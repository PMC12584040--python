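"""Yield tables, biomass conversion and the annualised harvest fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from woodsim.yields import (
    DEFAULT_ROTATIONS,
    R_MAX,
    R_MIN,
    WoodPools,
    YieldCurveModel,
    YieldCurveParams,
    annualised_harvest,
    biomass_to_volume,
    chapman_richards,
    fit_yield_curve,
    generate_yield_tables,
    harvestable_biomass,
    per_harvest_yield,
    sliding_window_refit,
    volume_to_biomass,
    window_rotation_yields,
)

T = DEFAULT_ROTATIONS.astype(float)


def _growth_df(n=3, v_max=450.0, rate=0.09, shape=1.35):
    return pd.DataFrame({
        "cell": [f"G{i}" for i in range(n)],
        "v_max": np.full(n, v_max), "rate": np.full(n, rate),
        "shape": np.full(n, shape)})


class TestBiomassAccounting:
    def test_pool_fractions(self):
        pools = WoodPools.from_wood_pool(100.0)  # 65 / 13 / 22 split
        assert harvestable_biomass(pools) == pytest.approx(
            65.0 + 0.95 * 13.0 + 0.10 * 22.0)  # = 79.55

    def test_zero_and_linearity(self):
        assert harvestable_biomass(WoodPools(0, 0, 0)) == 0.0
        a = harvestable_biomass(WoodPools(10, 4, 6))
        b = harvestable_biomass(WoodPools(20, 8, 12))
        assert b == pytest.approx(2 * a)

    def test_biomass_volume_conversion(self):
        assert biomass_to_volume(3.0) == pytest.approx(10.0)  # 3 / 0.3
        assert biomass_to_volume(0.0) == 0.0
        v = 123.4
        assert biomass_to_volume(volume_to_biomass(v)) == pytest.approx(v)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            biomass_to_volume(-1.0)


class TestTableGeneration:
    def test_deterministic_given_seed(self):
        t1 = generate_yield_tables(_growth_df(), seed=3)
        t2 = generate_yield_tables(_growth_df(), seed=3)
        assert np.array_equal(t1.values, t2.values, equal_nan=True)

    def test_zero_trend_cohorts_identical_at_equal_age(self):
        t = generate_yield_tables(_growth_df(1))
        ages = np.arange(1, 11)
        c0 = [t.yield_at(0, 1850, 1850 + a) for a in ages]
        c5 = [t.yield_at(0, 1950, 1950 + a) for a in ages]
        assert np.allclose(c0, c5)

    def test_cohort_trend_is_multiplicative(self):
        base = generate_yield_tables(_growth_df(1))
        trend = np.ones(base.cohort_years.size)
        trend[3] = 1.2
        bumped = generate_yield_tables(_growth_df(1), cohort_trend=trend)
        ratio = bumped.values[0, 3] / base.values[0, 3]
        assert np.allclose(ratio[np.isfinite(ratio)], 1.2)
        same = bumped.values[0, 4] / base.values[0, 4]
        assert np.allclose(same[np.isfinite(same)], 1.0)

    def test_yield_nondecreasing_in_stand_age(self):
        t = generate_yield_tables(_growth_df(1))
        row = t.values[0, 0]
        row = row[np.isfinite(row)]
        assert (np.diff(row) >= -1e-9).all()

    def test_negative_asymptote_rejected(self):
        bad = _growth_df(1)
        bad["v_max"] = -5.0
        with pytest.raises(ValueError):
            generate_yield_tables(bad)

    def test_tidy_export_schema(self):
        df = generate_yield_tables(_growth_df(1)).to_frame()
        assert list(df.columns) == ["cell", "cohort", "year", "yield_m3_ha"]
        assert (df["yield_m3_ha"] >= 0).all()


class TestYieldCurveFit:
    def test_self_consistency_recovery(self):
        true = YieldCurveParams(ymax=400.0, k=-0.02, p=-1.5)
        fit = fit_yield_curve(T, per_harvest_yield(1.0 / T, true))
        assert fit.ymax == pytest.approx(true.ymax, rel=1e-6)
        assert fit.k == pytest.approx(true.k, rel=1e-6)
        assert fit.p == pytest.approx(true.p, rel=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("v_max,rate,shape", [
        (320.0, 0.07, 1.3), (450.0, 0.09, 1.35), (560.0, 0.13, 1.4)])
    def test_chapman_richards_cross_family(self, v_max, rate, shape):
        """Out-of-family tables are fitted within 5% relative RMSE,
        matching an independent multi-start scipy least-squares oracle."""
        y = chapman_richards(T, v_max, rate, shape)
        fit = fit_yield_curve(T, y)
        pred = per_harvest_yield(1.0 / T, fit)
        rel_rmse = np.sqrt(np.mean((pred - y) ** 2)) / y.mean()
        assert rel_rmse < 0.05

        def resid(theta):
            ym, a, b = theta
            with np.errstate(over="ignore"):
                w = 1 - np.exp(np.maximum(
                    -np.exp(a) * (1.0 / T) ** (-np.exp(b)), -745.0))
            return ym * w - y

        best = None
        for a0 in np.linspace(-6, 3, 8):
            for b0 in np.linspace(-2, 1, 5):
                r = least_squares(resid, [y.max(), a0, b0])
                if best is None or r.cost < best.cost:
                    best = r
        oracle_rmse = np.sqrt(2 * best.cost / T.size) / y.mean()
        assert rel_rmse <= oracle_rmse * 1.05 + 1e-9

    def test_constant_table_degenerate_limit(self):
        fit = fit_yield_curve(T, np.full(T.size, 250.0))
        pred = per_harvest_yield(1.0 / T, fit)
        assert fit.ymax == pytest.approx(250.0, rel=1e-3)
        assert np.ptp(pred) < 0.01 * 250.0

    def test_fit_idempotence(self):
        y = chapman_richards(T, 450.0, 0.09, 1.35)
        f1 = fit_yield_curve(T, y)
        f2 = fit_yield_curve(T, per_harvest_yield(1.0 / T, f1))
        assert f2.ymax == pytest.approx(f1.ymax, abs=1e-8 * f1.ymax)
        assert f2.k == pytest.approx(f1.k, rel=1e-6)
        assert f2.p == pytest.approx(f1.p, rel=1e-6)

    def test_too_few_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_yield_curve([10, 20, 30], [1, 2, 3])

    def test_estimator_wrapper(self):
        y = chapman_richards(T, 450.0, 0.09, 1.35)
        m = YieldCurveModel().fit(T, y)
        assert m.converged_
        assert np.allclose(m.predict(T), per_harvest_yield(1.0 / T, m.params_))
        assert m.get_params() == {"window": None}


class TestAnnualisedHarvest:
    def test_rotation_intensity_reciprocity(self):
        """r = 0.02 harvests the stand on a 50-year rotation: the
        annualised value is the 50-year per-cut yield times r."""
        params = YieldCurveParams(ymax=400.0, k=-0.02, p=-1.2)
        r = 0.02
        assert 1.0 / r == pytest.approx(50.0)
        assert annualised_harvest(r, params) == pytest.approx(
            per_harvest_yield(r, params) * r)

    def test_formula_against_direct_evaluation(self):
        params = YieldCurveParams(ymax=371.0, k=-0.013, p=-1.31)
        r = np.linspace(R_MIN, R_MAX, 37)
        direct = 371.0 * (1.0 - np.exp(-0.013 * r ** -1.31)) * r
        assert np.allclose(annualised_harvest(r, params), direct, rtol=1e-14)

    def test_out_of_bounds_intensity_rejected(self):
        params = YieldCurveParams(ymax=400.0, k=-0.02, p=-1.2)
        for bad in (0.0, 0.005, 0.2):
            with pytest.raises(ValueError):
                annualised_harvest(bad, params)

    def test_small_intensity_small_harvest(self):
        params = YieldCurveParams(ymax=400.0, k=-0.02, p=-1.2)
        assert annualised_harvest(R_MIN, params) < annualised_harvest(R_MAX, params)
        assert annualised_harvest(R_MIN, params) <= 400.0 * R_MIN

    def test_sign_convention_enforced(self):
        with pytest.raises(ValueError):
            YieldCurveParams(ymax=100.0, k=0.1, p=-1.0)
        with pytest.raises(ValueError):
            YieldCurveParams(ymax=100.0, k=-0.1, p=1.0)


class TestSlidingWindow:
    def test_stationary_tables_stationary_params(self):
        tables = generate_yield_tables(_growth_df(2))
        p1 = sliding_window_refit(tables, 2030)
        p2 = sliding_window_refit(tables, 2045)
        for a, b in zip(p1, p2):
            assert a.ymax == pytest.approx(b.ymax, rel=1e-9)
            assert a.k == pytest.approx(b.k, rel=1e-6)
            assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_uniform_cohort_trend_moves_ymax(self):
        """+x% per cohort shifts fitted ymax by +x% between windows one
        cohort interval (20 yr) apart."""
        x = 0.08
        growth = _growth_df(1)
        n_coh = generate_yield_tables(growth).cohort_years.size
        trend = (1 + x) ** np.arange(n_coh)
        tables = generate_yield_tables(growth, cohort_trend=trend)
        # rotations short enough that both windows draw on cohorts fully
        # inside table coverage, so the cohort sets shift by exactly one
        rotations = np.array([10, 13, 16, 20, 25])
        p1 = sliding_window_refit(tables, 2040, rotations=rotations)[0]
        p2 = sliding_window_refit(tables, 2060, rotations=rotations)[0]
        assert p2.ymax / p1.ymax == pytest.approx(1 + x, rel=1e-6)

    def test_deterministic_no_hidden_state(self):
        tables = generate_yield_tables(_growth_df(1))
        a = sliding_window_refit(tables, 2035)[0]
        b = sliding_window_refit(tables, 2035)[0]
        assert (a.ymax, a.k, a.p) == (b.ymax, b.k, b.p)

    def test_early_year_uses_nearest_window(self):
        tables = generate_yield_tables(_growth_df(1))
        ages, ys, window = window_rotation_yields(tables, 0, 1900)
        assert window[0] >= int(tables.years[0])
        assert ages.size >= 4

    def test_monotonicity_of_fitted_curves(self):
        """Fitted cells: y nondecreasing and y/r nonincreasing in r on a
        100-point grid (default generator archetypes with scatter)."""
        rng = np.random.default_rng(11)
        growth = pd.DataFrame({
            "cell": [f"G{i}" for i in range(30)],
            "v_max": 320 * np.exp(rng.normal(0, 0.25, 30)),
            "rate": np.repeat([0.07, 0.09, 0.13], 10) * np.exp(rng.normal(0, 0.1, 30)),
            "shape": np.repeat([1.3, 1.35, 1.4], 10)})
        tables = generate_yield_tables(growth)
        grid = np.linspace(R_MIN, R_MAX, 100)
        for f in sliding_window_refit(tables, 2030):
            y = annualised_harvest(grid, f)
            ph = per_harvest_yield(grid, f)
            assert (np.diff(y) >= -1e-9 * y.max()).all()
            assert (np.diff(ph) <= 1e-9 * ph.max()).all()
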