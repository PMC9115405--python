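"""The four expected-mortality estimators against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from emsens.baseline import (
    METHODS,
    BaselineMortalityModel,
    ReferencePeriod,
)
from emsens.excess import PanelArrays, _index_rates
from emsens.panel import ConfigurationError
from emsens.rates import RateSeries


def rate_series(matrix, years, time_unit="week"):
    """RateSeries from a (years x periods) array, uniform exposure."""
    matrix = np.asarray(matrix, dtype=float)
    nper = matrix.shape[1]
    rows = [
        (y, p + 1, matrix[i, p], 1_000_000 / nper)
        for i, y in enumerate(years)
        for p in range(nper)
    ]
    return RateSeries(
        "AA",
        "CDR",
        time_unit,
        pd.DataFrame(rows, columns=["year", "period", "rate", "exposure"]),
    )


def weekly_series(per_week_rates_by_year, years):
    """Replicate one value per (year) across 52 weeks."""
    return rate_series(
        np.repeat(np.asarray(per_week_rates_by_year, float)[:, None], 52, axis=1),
        years,
    )


class TestSpecificAverage:
    def test_mean_of_reference_years(self):
        rs = weekly_series([10e-5, 12e-5, 14e-5, 16e-5, 18e-5], range(2015, 2020))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2015, 2019)).fit()
        pred = res.predict(2020)
        assert np.allclose(pred, 14e-5, rtol=1e-12)

    def test_prediction_independent_of_target_year(self):
        rng = np.random.default_rng(0)
        rs = rate_series(rng.uniform(5e-5, 2e-4, size=(5, 52)), range(2015, 2020))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2015, 2019)).fit()
        assert np.allclose(res.predict(2020), res.predict(2024), rtol=0)

    def test_oracle_equivalence_per_period_mean(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(5e-5, 2e-4, size=(5, 52))
        rs = rate_series(A, range(2015, 2020))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2015, 2019)).fit()
        oracle = A.mean(axis=0)  # brute-force per-period arithmetic mean
        assert np.max(np.abs(res.predict(2020).to_numpy() - oracle)) < 1e-12


class TestSpecificAverageTrend:
    def test_linear_series_extrapolates_exactly(self):
        rs = weekly_series([10e-5, 12e-5, 14e-5, 16e-5, 18e-5], range(2015, 2020))
        res = BaselineMortalityModel(
            rs, "specific_average_trend", ReferencePeriod(2015, 2019)
        ).fit()
        # slope 2e-5/yr extrapolated one year past 2019
        assert np.allclose(res.predict(2020), 20e-5, rtol=1e-10)
        assert res.params["trend"] == pytest.approx(2e-5, rel=1e-10)

    def test_common_slope_pools_periods(self):
        # two periods with different per-period slopes: the common slope is
        # their average, intercepts remain per-period
        years = np.arange(2015, 2020)
        A = np.stack([1e-4 + 1e-6 * (years - 2017), 2e-4 + 3e-6 * (years - 2017)]).T
        A12 = np.column_stack([A[:, 0]] * 6 + [A[:, 1]] * 6)
        rs = rate_series(A12, years, time_unit="month")
        res = BaselineMortalityModel(
            rs, "specific_average_trend", ReferencePeriod(2015, 2019)
        ).fit()
        assert res.params["trend"] == pytest.approx(2e-6, rel=1e-9)


class TestSpecificTrend:
    def test_exact_per_period_extrapolation_and_zero_residuals(self):
        years = np.arange(2015, 2020)
        slopes = np.linspace(-2e-6, 2e-6, 52)
        levels = np.linspace(8e-5, 3e-4, 52)
        A = levels[None, :] + slopes[None, :] * (years[:, None] - 2017)
        rs = rate_series(A, years)
        res = BaselineMortalityModel(rs, "specific_trend", ReferencePeriod(2015, 2019)).fit()
        expected = levels + slopes * (2020 - 2017)
        assert np.allclose(res.predict(2020).to_numpy(), expected, rtol=1e-10)
        assert np.max(np.abs(res.resid)) < 1e-16

    def test_oracle_equivalence_closed_form_ols(self):
        rng = np.random.default_rng(2)
        years = np.arange(2010, 2020)
        A = rng.uniform(5e-5, 2e-4, size=(10, 52))
        rs = rate_series(A, years)
        res = BaselineMortalityModel(rs, "specific_trend", ReferencePeriod(2010, 2019)).fit()
        c = years - years.mean()
        slope = ((c[:, None]) * (A - A.mean(axis=0))).sum(axis=0) / (c**2).sum()
        oracle = A.mean(axis=0) + slope * (2020 - years.mean())
        assert np.max(np.abs(res.predict(2020).to_numpy() - oracle)) < 1e-10


class TestHarmonicTrend:
    def test_constant_series_gives_constant_fit(self):
        rs = rate_series(np.full((5, 52), 1.3e-4), range(2015, 2020))
        res = BaselineMortalityModel(rs, "harmonic_trend", ReferencePeriod(2015, 2019)).fit()
        assert res.params["const"] == pytest.approx(1.3e-4, abs=1e-12)
        for name in ("trend", "sin1", "cos1", "sin2", "cos2"):
            assert abs(res.params[name]) < 1e-9

    def test_matches_statsmodels_ols(self):
        """Independent cross-check of the pooled Serfling fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        years = np.arange(2015, 2020)
        A = rng.uniform(5e-5, 2e-4, size=(5, 52))
        rs = rate_series(A, years)
        res = BaselineMortalityModel(rs, "harmonic_trend", ReferencePeriod(2015, 2019)).fit()
        hh = np.repeat(years - years.mean(), 52)
        ii = np.tile(np.arange(1, 53), 5)
        w = 2 * np.pi * ii / 52
        X = sm.add_constant(
            np.column_stack([hh, np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)])
        )
        fit = sm.OLS(A.ravel(), X).fit()
        assert np.allclose(res.params.to_numpy(), fit.params, rtol=1e-8)
        assert np.allclose(res.bse.to_numpy(), fit.bse, rtol=1e-6)


class TestPredictRules:
    def test_week_53_copies_week_52_exactly(self):
        rng = np.random.default_rng(4)
        rs = rate_series(rng.uniform(5e-5, 2e-4, size=(5, 52)), range(2015, 2020))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2015, 2019)).fit()
        pred = res.predict(2020, periods=list(range(1, 54)))  # 2020 has 53 weeks
        assert pred[53] == pred[52]

    def test_week_53_rejected_for_52_week_target_year(self):
        rng = np.random.default_rng(5)
        rs = rate_series(rng.uniform(5e-5, 2e-4, size=(5, 52)), range(2016, 2021))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2016, 2020)).fit()
        with pytest.raises(ConfigurationError, match="52 weeks"):
            res.predict(2021, periods=[52, 53])

    def test_negative_predictions_floored_with_warning(self):
        rs = weekly_series([10e-5, 8e-5, 6e-5, 4e-5, 2e-5], range(2015, 2020))
        res = BaselineMortalityModel(
            rs, "specific_average_trend", ReferencePeriod(2015, 2019)
        ).fit()
        with pytest.warns(UserWarning, match="floored"):
            pred = res.predict(2021)  # extrapolates to 0 at 2020, negative beyond
        assert (pred >= 0).all()

    def test_target_inside_reference_rejected(self):
        rs = weekly_series([1e-4] * 5, range(2015, 2020))
        res = BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2015, 2019)).fit()
        with pytest.raises(ValueError):
            res.predict(2019)

    def test_trend_methods_need_two_years(self):
        rs = weekly_series([1e-4], [2019])
        with pytest.raises(ConfigurationError):
            BaselineMortalityModel(rs, "specific_trend", ReferencePeriod(2019, 2019))
        BaselineMortalityModel(rs, "specific_average", ReferencePeriod(2019, 2019))


class TestEstimatorAgreementUnderNull:
    def test_methods_converge_without_trend(self, null_replicates):
        """With no true trend or seasonality, all four estimators target the
        same surface: the mean annualized prediction difference across 200
        replicates is within 3 standard errors of zero (r = 10)."""
        ref = ReferencePeriod(2010, 2019)
        diffs = {m: [] for m in METHODS if m != "specific_average"}
        for weekly, _, _ in null_replicates:
            arr = PanelArrays.from_panel(weekly, "SIM-A")
            R = _index_rates(arr, arr.D, "CDR", None)
            hs = [arr.year_index(y) for y in ref.years]
            A = R[hs][:, :52]
            rs = rate_series(A, ref.years)
            base = (
                BaselineMortalityModel(rs, "specific_average", ref)
                .fit()
                .predict(2020)
                .mean()
            )
            for m in diffs:
                p = BaselineMortalityModel(rs, m, ref).fit().predict(2020).mean()
                diffs[m].append(p - base)
        for m, d in diffs.items():
            d = np.asarray(d) * 1e5
            se = d.std(ddof=1) / np.sqrt(len(d))
            assert abs(d.mean()) < 3 * se, (m, d.mean(), se)
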