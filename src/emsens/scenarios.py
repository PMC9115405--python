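"""The 16-scenario sensitivity grid and cross-scenario comparisons.

Scenarios combine a mortality index (SDR or CDR), one of four baseline
methods, a reference period (2010-19, 2015-19 or 2017-19) and a data time
unit (weeks or months):

* scenarios 1-8 vary index x method at 2015-19, weekly;
* scenarios 9-12 vary the reference period for Specific-Average with
  Trend (compare with scenarios 2 and 6);
* scenarios 13-16 compare weekly (restricted to weeks 1-52) against
  monthly data under Harmonic with Trend.

``run_grid`` shares one set of resampled panels per (country, time unit)
across all scenarios and Monte-Carlo iterations, so pairwise differences
can be computed within each iteration (common random numbers isolate the
contrast).  Country rankings (rank 1 = highest excess) are compared with
Spearman rank correlations; the monthly-comparison scenarios 13-16 are
excluded from the default ranking analysis because their observation
window drops week 53.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import ReferencePeriod
from .excess import PanelArrays, _pipeline_excess, resample_deaths
from .panel import ConfigurationError, MortalityPanel
from .preprocess import adjust_month_lengths
from .standard import StandardPopulation

__all__ = [
    "ScenarioSpec",
    "scenario_grid",
    "run_grid",
    "GridResults",
    "difference_table",
    "rank_and_correlate",
    "RankingComparison",
    "plot_spearman_heatmap",
]

REF_2010_19 = ReferencePeriod(2010, 2019)
REF_2015_19 = ReferencePeriod(2015, 2019)
REF_2017_19 = ReferencePeriod(2017, 2019)


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the sensitivity grid."""

    id: int
    index_kind: str  # "SDR" | "CDR"
    method: str
    reference_period: ReferencePeriod
    time_unit: str  # "week" | "month"
    weeks_1_52: bool = False

    def label(self) -> str:
        unit = {
            ("week", False): "Weeks",
            ("week", True): "Weeks (1-52)",
            ("month", False): "Months",
            ("month", True): "Months",
        }[(self.time_unit, self.weeks_1_52)]
        return (
            f"S{self.id}: {self.index_kind}, {self.method}, "
            f"{self.reference_period}, {unit}"
        )


def scenario_grid() -> list[ScenarioSpec]:
    """The 16 scenarios of the sensitivity analysis, in canonical order."""
    methods = (
        "specific_average",
        "specific_average_trend",
        "harmonic_trend",
        "specific_trend",
    )
    grid: list[ScenarioSpec] = []
    # 1-8: index x method, 2015-19, weekly
    sid = 1
    for index_kind in ("SDR", "CDR"):
        for method in methods:
            grid.append(
                ScenarioSpec(sid, index_kind, method, REF_2015_19, "week")
            )
            sid += 1
    # 9-12: reference period, Specific-Average with Trend, weekly
    for index_kind in ("SDR", "CDR"):
        for ref in (REF_2010_19, REF_2017_19):
            grid.append(
                ScenarioSpec(sid, index_kind, "specific_average_trend", ref, "week")
            )
            sid += 1
    # 13-16: time unit, Harmonic with Trend, 2015-19
    for index_kind in ("SDR", "CDR"):
        grid.append(
            ScenarioSpec(
                sid, index_kind, "harmonic_trend", REF_2015_19, "week",
                weeks_1_52=True,
            )
        )
        sid += 1
        grid.append(
            ScenarioSpec(sid, index_kind, "harmonic_trend", REF_2015_19, "month")
        )
        sid += 1
    return grid


def get_scenario(sid: int) -> ScenarioSpec:
    for s in scenario_grid():
        if s.id == sid:
            return s
    raise KeyError(f"no scenario {sid}")


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------


@dataclass
class GridResults:
    """Excess estimates for every (country, scenario), with paired draws."""

    table: pd.DataFrame
    draws: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    n_iterations: int = 0
    seed: int | None = None
    target_year: int = 2020


def run_grid(
    panels: dict[str, dict[str, MortalityPanel]],
    specs: list[ScenarioSpec] | None = None,
    standard: StandardPopulation | None = None,
    n_iterations: int = 1000,
    seed: int | None = None,
    target_year: int = 2020,
) -> GridResults:
    """Run scenarios across countries.

    ``panels`` maps country -> {"week": panel, "month": panel}.  For each
    (country, time unit) the Monte-Carlo deaths are redrawn once and
    shared by every scenario using that panel, pairing iterations across
    scenarios.  Countries whose panels do not cover a scenario's years
    are reported with NaN estimates and an error message; the run
    continues.
    """
    if specs is None:
        specs = scenario_grid()
    root = np.random.SeedSequence(seed)
    rows = []
    draws_store: dict[tuple[str, int], np.ndarray] = {}
    for ci, country in enumerate(sorted(panels)):
        unit_arrays: dict[str, PanelArrays] = {}
        unit_draws: dict[str, np.ndarray] = {}
        for ui, unit in enumerate(("week", "month")):
            if unit not in panels[country]:
                continue
            panel = panels[country][unit]
            if unit == "month" and not panel.meta.get("month_lengths_adjusted"):
                panel = adjust_month_lengths(panel)
            arrays = PanelArrays.from_panel(panel, country)
            unit_arrays[unit] = arrays
            if n_iterations > 0:
                child = np.random.SeedSequence(
                    entropy=root.entropy if seed is not None else root.entropy,
                    spawn_key=(ci, ui),
                )
                rng = np.random.default_rng(child)
                unit_draws[unit] = resample_deaths(
                    arrays, n_iterations, rng, "all", target_year
                )
        for spec in specs:
            row = {
                "country": country,
                "scenario": spec.id,
                "index_kind": spec.index_kind,
                "method": spec.method,
                "reference_period": str(spec.reference_period),
                "time_unit": spec.time_unit,
                "weeks_1_52": spec.weeks_1_52,
                "n_iterations": n_iterations,
                "seed": seed,
            }
            try:
                arrays = unit_arrays[spec.time_unit]
                n_fit = 52 if spec.time_unit == "week" else 12
                arrays.check_coverage(spec.reference_period, target_year, n_fit)
                point = float(
                    _pipeline_excess(
                        arrays, arrays.D, spec, standard, target_year
                    )
                )
                row["excess_rate"] = point
                if n_iterations > 0:
                    d = np.asarray(
                        _pipeline_excess(
                            arrays,
                            unit_draws[spec.time_unit],
                            spec,
                            standard,
                            target_year,
                        )
                    )
                    draws_store[(country, spec.id)] = d
                    lo, hi = np.percentile(d, [2.5, 97.5])
                    row["ci_low"], row["ci_high"] = float(lo), float(hi)
                else:
                    row["ci_low"] = row["ci_high"] = np.nan
                row["error"] = ""
            except (ConfigurationError, KeyError) as exc:
                row["excess_rate"] = np.nan
                row["ci_low"] = row["ci_high"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    return GridResults(table, draws_store, n_iterations, seed, target_year)


# ---------------------------------------------------------------------------
# contrasts and rankings
# ---------------------------------------------------------------------------

#: Figure-style contrasts: (minuend scenario, subtrahend scenario).
CONTRASTS = {
    # excess SDR minus excess CDR, per method (2015-19, weekly)
    "index": [(1, 5), (2, 6), (3, 7), (4, 8)],
    # 2015-19 minus 2010-19 / 2017-19, Specific-Average with Trend
    "reference_period": [(2, 9), (2, 10), (6, 11), (6, 12)],
    # weekly (1-52) minus monthly, Harmonic with Trend
    "time_unit": [(13, 14), (15, 16)],
}


def difference_table(
    results: GridResults,
    contrast: str | list[tuple[int, int]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Signed per-country differences between scenario pairs.

    Differences are formed within each Monte-Carlo iteration from the
    shared resampled panels, so the interval reflects the contrast rather
    than two independent uncertainties.  ``contrast`` is a preset name
    (``index``, ``reference_period``, ``time_unit``) or explicit pairs.
    """
    pairs = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    q = [50 * (1 - level), 50 * (1 + level)]
    tab = results.table.set_index(["country", "scenario"])
    rows = []
    for country in sorted(results.table["country"].unique()):
        for a, b in pairs:
            try:
                pa = tab.loc[(country, a), "excess_rate"]
                pb = tab.loc[(country, b), "excess_rate"]
            except KeyError as exc:
                raise ConfigurationError(
                    f"missing arm for contrast ({a}, {b}) in {country}"
                ) from exc
            row = {
                "country": country,
                "scenario_a": a,
                "scenario_b": b,
                "difference": float(pa - pb),
            }
            da = results.draws.get((country, a))
            db = results.draws.get((country, b))
            if da is not None and db is not None:
                dd = da - db
                lo, hi = np.percentile(dd, q)
                row["ci_low"], row["ci_high"] = float(lo), float(hi)
            else:
                row["ci_low"] = row["ci_high"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RankingComparison:
    """Country rankings per scenario and their Spearman correlations."""

    rankings: pd.DataFrame  # countries x scenarios, rank 1 = highest excess
    spearman: pd.DataFrame  # scenarios x scenarios


def rank_and_correlate(
    results: GridResults | pd.DataFrame,
    scenario_ids: list[int] | None = None,
) -> RankingComparison:
    """Rank countries by excess rate and correlate rankings across scenarios.

    By default scenarios 13-16 are excluded (their observation window
    omits week 53 and is not comparable with the others).  Ties receive
    average ranks; Spearman's rho uses the tie-corrected formula.
    """
    table = results.table if isinstance(results, GridResults) else results
    if scenario_ids is None:
        scenario_ids = [s for s in sorted(table["scenario"].unique()) if s <= 12]
    wide = table.pivot(index="country", columns="scenario", values="excess_rate")
    wide = wide[[s for s in scenario_ids if s in wide.columns]]
    wide = wide.dropna(axis=1, how="all").dropna(axis=0)
    if len(wide) < 3:
        raise ConfigurationError("ranking comparison needs at least 3 countries")
    rankings = wide.rank(ascending=False, method="average").astype(float)
    rho, _ = stats.spearmanr(wide.to_numpy())
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-column case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    spearman = pd.DataFrame(rho, index=wide.columns, columns=wide.columns)
    return RankingComparison(rankings, spearman)


def plot_spearman_heatmap(comparison: RankingComparison, path: str | None = None):
    """Heatmap of the scenario-by-scenario Spearman matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = comparison.spearman
    fig, ax = plt.subplots(figsize=(0.6 * len(m) + 2, 0.6 * len(m) + 1.5))
    im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(m)), [f"S{c}" for c in m.columns])
    ax.set_yticks(range(len(m)), [f"S{c}" for c in m.index])
    for i in range(len(m)):
        for j in range(len(m)):
            ax.text(
                j, i, f"{m.iloc[i, j]:.2f}", ha="center", va="center", fontsize=7
            )
    ax.set_title("Spearman correlation of excess-mortality rankings")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
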