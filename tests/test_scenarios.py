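"""Scenario grid contents, grid execution, contrasts and rankings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emsens.baseline import ReferencePeriod
from emsens.panel import ConfigurationError
from emsens.scenarios import (
    CONTRASTS,
    GridResults,
    difference_table,
    get_scenario,
    rank_and_correlate,
    run_grid,
    scenario_grid,
)
from emsens.standard import StandardPopulation


class TestScenarioGrid:
    def test_sixteen_scenarios_with_expected_structure(self):
        grid = scenario_grid()
        assert [s.id for s in grid] == list(range(1, 17))
        assert sum(s.index_kind == "SDR" for s in grid) == 8
        assert sum(s.time_unit == "month" for s in grid) == 2
        assert [s.id for s in grid if s.weeks_1_52] == [13, 15]

    @pytest.mark.parametrize(
        "sid,index_kind,method,ref,unit",
        [
            (1, "SDR", "specific_average", (2015, 2019), "week"),
            (3, "SDR", "harmonic_trend", (2015, 2019), "week"),
            (5, "CDR", "specific_average", (2015, 2019), "week"),
            (8, "CDR", "specific_trend", (2015, 2019), "week"),
            (9, "SDR", "specific_average_trend", (2010, 2019), "week"),
            (10, "SDR", "specific_average_trend", (2017, 2019), "week"),
            (11, "CDR", "specific_average_trend", (2010, 2019), "week"),
            (12, "CDR", "specific_average_trend", (2017, 2019), "week"),
            (13, "SDR", "harmonic_trend", (2015, 2019), "week"),
            (14, "SDR", "harmonic_trend", (2015, 2019), "month"),
            (16, "CDR", "harmonic_trend", (2015, 2019), "month"),
        ],
    )
    def test_rows(self, sid, index_kind, method, ref, unit):
        s = get_scenario(sid)
        assert s.index_kind == index_kind
        assert s.method == method
        assert s.reference_period == ReferencePeriod(*ref)
        assert s.time_unit == unit


class TestRunGrid:
    def test_two_countries_times_16_scenarios(self, two_country_sim, esp):
        _, weekly, monthly, _ = two_country_sim
        panels = {c: {"week": weekly, "month": monthly} for c in weekly.countries}
        results = run_grid(panels, standard=esp, n_iterations=0)
        assert len(results.table) == 32
        assert results.table["excess_rate"].notna().all()
        assert (results.table["error"] == "").all()

    def test_coverage_gaps_reported_not_fatal(self, small_sim, esp):
        _, weekly, monthly, _ = small_sim  # 2015-2020: cannot serve 2010-2019
        panels = {"SIM-A": {"week": weekly, "month": monthly}}
        results = run_grid(panels, standard=esp, n_iterations=0)
        bad = results.table[results.table["scenario"].isin([9, 11])]
        assert bad["excess_rate"].isna().all()
        assert bad["error"].str.contains("2010").all()
        good = results.table[~results.table["scenario"].isin([9, 11])]
        assert good["excess_rate"].notna().all()

    def test_reference_period_is_the_only_difference_on_noiseless_constant_trend(
        self, esp
    ):
        """On a noiseless panel whose per-year decline is exactly linear in
        the fitted scale, the 2010-19 and 2015-19 specific-average-trend
        baselines extrapolate to the same surface, so scenarios 2 and 9
        agree."""
        # linear (not geometric) trend surface built directly in rate space
        from emsens.excess import PanelArrays, _pipeline_excess

        rows = []
        for year in range(2010, 2021):
            for week in range(1, 53 + (1 if year in (2015, 2020) else 0)):
                rate = 0.012 - 0.0002 * (year - 2010)
                expo = 1e6 / (53 if year in (2015, 2020) else 52)
                rows.append(("AA", year, week, "all", rate * expo, expo))
        from emsens.panel import MortalityPanel

        panel = MortalityPanel(
            pd.DataFrame(
                rows,
                columns=["country", "year", "period", "age_group", "deaths", "exposure"],
            ),
            "week",
        )
        arr = PanelArrays.from_panel(panel, "AA")
        e2 = _pipeline_excess(arr, arr.D, get_scenario(6), None, 2020)
        e9 = _pipeline_excess(arr, arr.D, get_scenario(11), None, 2020)
        assert e2 == pytest.approx(e9, abs=1e-9)


class TestDifferences:
    def test_identical_arms_give_zero_with_degenerate_ci(self, two_country_sim, esp):
        _, weekly, monthly, _ = two_country_sim
        panels = {c: {"week": weekly, "month": monthly} for c in weekly.countries}
        results = run_grid(panels, standard=esp, n_iterations=100, seed=0)
        diff = difference_table(results, [(3, 3)])
        assert np.allclose(diff["difference"], 0.0)
        assert np.allclose(diff["ci_low"], 0.0)
        assert np.allclose(diff["ci_high"], 0.0)

    def test_contrast_presets_cover_the_figure_comparisons(self):
        assert CONTRASTS["index"] == [(1, 5), (2, 6), (3, 7), (4, 8)]
        assert CONTRASTS["reference_period"] == [(2, 9), (2, 10), (6, 11), (6, 12)]
        assert CONTRASTS["time_unit"] == [(13, 14), (15, 16)]

    def test_sdr_cdr_contrast_vanishes_when_composition_matches_standard(self):
        """Noiseless panel whose age structure equals the standard
        population: excess SDR minus excess CDR is zero."""
        from emsens.excess import PanelArrays, _pipeline_excess
        from emsens.panel import MortalityPanel

        weights = {"0-64": 0.8, "65+": 0.2}
        std = StandardPopulation(pd.Series(weights))
        rows = []
        for year in range(2015, 2021):
            nper = 53 if year in (2015, 2020) else 52
            for week in range(1, nper + 1):
                for age, w in weights.items():
                    rate = (0.006 if age == "0-64" else 0.05) * (
                        1 - 0.01 * (year - 2015)
                    ) * (1.2 if (year == 2020 and 10 <= week <= 20) else 1.0)
                    expo = 1e6 * w / nper
                    rows.append(("AA", year, week, age, rate * expo, expo))
        panel = MortalityPanel(
            pd.DataFrame(
                rows,
                columns=["country", "year", "period", "age_group", "deaths", "exposure"],
            ),
            "week",
        )
        arr = PanelArrays.from_panel(panel, "AA")
        sdr = _pipeline_excess(arr, arr.D, get_scenario(2), std, 2020)
        cdr = _pipeline_excess(arr, arr.D, get_scenario(6), None, 2020)
        assert sdr == pytest.approx(cdr, abs=1e-9)

    def test_missing_arm_rejected(self, two_country_sim, esp):
        _, weekly, monthly, _ = two_country_sim
        panels = {c: {"week": weekly, "month": monthly} for c in weekly.countries}
        results = run_grid(panels, specs=[get_scenario(1)], standard=esp, n_iterations=0)
        with pytest.raises(ConfigurationError, match="missing arm"):
            difference_table(results, [(1, 5)])


class TestRankings:
    @staticmethod
    def grid_table(excess_by_country_scenario):
        rows = [
            {"country": c, "scenario": s, "excess_rate": v}
            for (c, s), v in excess_by_country_scenario.items()
        ]
        return GridResults(pd.DataFrame(rows))

    def test_identical_rankings_give_rho_one(self):
        vals = {}
        for i, c in enumerate("abcde"):
            vals[(c, 1)] = 100.0 - i
            vals[(c, 2)] = 500.0 - 10 * i  # same order, different scale
        rc = rank_and_correlate(self.grid_table(vals))
        assert rc.spearman.loc[1, 2] == pytest.approx(1.0)

    def test_reversed_rankings_give_rho_minus_one(self):
        vals = {}
        for i, c in enumerate("abcde"):
            vals[(c, 1)] = 100.0 - i
            vals[(c, 2)] = float(i)
        rc = rank_and_correlate(self.grid_table(vals))
        assert rc.spearman.loc[1, 2] == pytest.approx(-1.0)

    def test_five_country_hand_example_matches_sum_d2_formula(self):
        x = [310.0, 150.0, 270.0, 90.0, 200.0]
        y = [260.0, 120.0, 310.0, 70.0, 150.0]
        vals = {}
        for c, xi, yi in zip("abcde", x, y):
            vals[(c, 1)] = xi
            vals[(c, 2)] = yi
        rc = rank_and_correlate(self.grid_table(vals))
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        d2 = ((rx - ry) ** 2).sum()
        n = 5
        oracle = 1 - 6 * d2 / (n * (n**2 - 1))  # tie-free closed form
        assert abs(rc.spearman.loc[1, 2] - oracle) < 1e-12

    def test_rank_one_is_highest_excess(self):
        vals = {(c, 1): v for c, v in zip("abc", (10.0, 30.0, 20.0))}
        vals.update({(c, 2): v for c, v in zip("abc", (1.0, 3.0, 2.0))})
        rc = rank_and_correlate(self.grid_table(vals))
        assert rc.rankings.loc["b", 1] == 1.0
        assert rc.rankings.loc["a", 1] == 3.0

    def test_ranking_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        base = rng.normal(100, 30, size=6)
        vals = {}
        for i, c in enumerate("abcdef"):
            vals[(c, 1)] = base[i]
            vals[(c, 2)] = float(np.exp(base[i] / 50))  # strictly monotone
        rc = rank_and_correlate(self.grid_table(vals))
        assert rc.spearman.loc[1, 2] == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal_in_range(self):
        vals = {}
        rng = np.random.default_rng(12)
        for c in ("u", "v", "w", "x"):
            for s in range(1, 13):
                vals[(c, s)] = float(rng.normal(100, 40))
        rc = rank_and_correlate(self.grid_table(vals))
        m = rc.spearman.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()
        assert list(rc.spearman.columns) == list(range(1, 13))

    def test_default_excludes_monthly_comparison_scenarios(self):
        vals = {}
        for c in "abc":
            for s in range(1, 17):
                vals[(c, s)] = float(ord(c) * s)
        rc = rank_and_correlate(self.grid_table(vals))
        assert set(rc.spearman.columns) == set(range(1, 13))

    def test_fewer_than_three_countries_rejected(self):
        vals = {("a", 1): 1.0, ("a", 2): 2.0, ("b", 1): 3.0, ("b", 2): 4.0}
        with pytest.raises(ConfigurationError):
            rank_and_correlate(self.grid_table(vals))

    def test_matches_scipy_on_tied_data(self):
        x = [10.0, 20.0, 20.0, 5.0, 7.0]
        y = [1.0, 3.0, 2.0, 2.0, 5.0]
        vals = {}
        for c, xi, yi in zip("abcde", x, y):
            vals[(c, 1)] = xi
            vals[(c, 2)] = yi
        rc = rank_and_correlate(self.grid_table(vals))
        rho, _ = stats.spearmanr(x, y)
        assert rc.spearman.loc[1, 2] == pytest.approx(rho)
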