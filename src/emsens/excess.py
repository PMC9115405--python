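"""Annual excess mortality with Monte-Carlo binomial confidence intervals.

Excess mortality for a target year is the observed all-cause mortality
minus the baseline the fitted model predicts for the same periods,
expressed as an annual rate per 100,000 person-years:

    excess = sum_i (obs_rate_i - expected_rate_i) * exposure_i
             / annual_exposure * 100,000.

Uncertainty comes from a parametric Monte-Carlo scheme: in each iteration
the deaths of every (year, period, age) cell are redrawn as
Binomial(persons, observed rate) — person counts being the offset — and
the full pipeline (rates, baseline fit, prediction, annual excess) is
re-run on the redrawn panel.  By default both the reference-period and the
target-year deaths are resampled, so baseline-estimation uncertainty
propagates into the interval; ``resample="target"`` restricts redrawing to
the target year.  Intervals are percentile intervals of the resampled
excess (skew-safe); the point estimate itself never depends on the seed or
the number of iterations.

The whole Monte-Carlo batch is evaluated in one vectorized pass through
the same array routines the point estimate uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .baseline import ReferencePeriod, fit_coefficients, predict_matrix
from .panel import ConfigurationError, MortalityPanel
from .preprocess import adjust_month_lengths, observation_periods
from .rates import REPORT_SCALE
from .standard import StandardPopulation
from .timeunits import iso_weeks_in_year, periods_in_year

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import ScenarioSpec

__all__ = [
    "annual_excess",
    "monte_carlo_ci",
    "ExcessMortalityModel",
    "ExcessMortalityResults",
]


def annual_excess(
    observed_rates: pd.Series,
    expected_rates: pd.Series,
    exposures: pd.Series,
    annual_exposure: float,
) -> float:
    """Annual excess rate per 100,000 from aligned per-period series.

    All three series must be indexed by the same period set (week-53
    handling already applied on both sides).
    """
    if not (
        observed_rates.index.equals(expected_rates.index)
        and observed_rates.index.equals(exposures.index)
    ):
        raise ConfigurationError("observed, expected and exposures periods differ")
    gap = (observed_rates - expected_rates) * exposures
    return float(gap.sum() / annual_exposure * REPORT_SCALE)


# ---------------------------------------------------------------------------
# array pipeline
# ---------------------------------------------------------------------------


@dataclass
class PanelArrays:
    """Dense (age, year, period) arrays for one country of a panel.

    Cells absent from the panel (week 53 of 52-week years) are NaN.
    """

    country: str
    time_unit: str
    ages: list[str]
    years: list[int]
    D: np.ndarray  # deaths, (A, H, P)
    E: np.ndarray  # person-year exposures, (A, H, P)

    @classmethod
    def from_panel(cls, panel: MortalityPanel, country: str) -> "PanelArrays":
        sub = panel.data[panel.data["country"] == country]
        if sub.empty:
            raise KeyError(f"country {country!r} not in panel")
        ages = list(dict.fromkeys(sub["age_group"]))
        years = sorted(sub["year"].unique())
        P = 53 if panel.time_unit == "week" else 12
        A, H = len(ages), len(years)
        D = np.full((A, H, P), np.nan)
        E = np.full((A, H, P), np.nan)
        ai = sub["age_group"].map({a: i for i, a in enumerate(ages)}).to_numpy()
        yi = sub["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        pi = sub["period"].to_numpy() - 1
        D[ai, yi, pi] = sub["deaths"].to_numpy()
        E[ai, yi, pi] = sub["exposure"].to_numpy()
        return cls(country, panel.time_unit, ages, [int(y) for y in years], D, E)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise ConfigurationError(
                f"{self.country}: panel lacks year {year}"
            ) from None

    def annual_exposure(self, year: int) -> float:
        h = self.year_index(year)
        per_age = np.nanmean(self.E[:, h, :], axis=1)
        return float(per_age.sum() * periods_in_year(year, self.time_unit))

    def persons(self) -> np.ndarray:
        """Binomial trial counts: period exposure converted to persons.

        Everyone alive contributes to every period of the year, so the
        person count at risk in a period is the period exposure times the
        number of periods, rounded to the nearest person.
        """
        out = np.empty_like(self.E)
        for h, y in enumerate(self.years):
            out[:, h, :] = self.E[:, h, :] * periods_in_year(y, self.time_unit)
        return np.round(out)

    def check_coverage(
        self, ref: ReferencePeriod, target_year: int, fit_p: int
    ) -> None:
        """Fail early when a scenario's reference/target cells are missing."""
        gaps = []
        for y in [*ref.years, target_year]:
            if y not in self.years:
                gaps.append(f"year {y} absent")
                continue
            h = self.years.index(y)
            if np.isnan(self.D[:, h, :fit_p]).any():
                gaps.append(f"year {y} has missing periods 1..{fit_p}")
        if gaps:
            raise ConfigurationError(
                f"{self.country}: insufficient coverage: " + "; ".join(gaps)
            )


def resample_deaths(
    arrays: PanelArrays,
    n_iterations: int,
    rng: np.random.Generator,
    resample: str = "all",
    target_year: int | None = None,
) -> np.ndarray:
    """Parametric binomial redraw of the panel's deaths.

    Returns an array of shape (A, H, P, B).  With ``resample="target"``
    only the target year's cells are redrawn; other years are repeated.
    """
    if resample not in ("all", "target"):
        raise ValueError("resample must be 'all' or 'target'")
    D, persons = arrays.D, arrays.persons()
    valid = ~np.isnan(D)
    n = np.where(valid, persons, 1).astype(np.int64)
    p = np.where(valid, D / np.where(n > 0, n, 1), 0.0)
    if (p > 1).any():
        raise ConfigurationError("observed rate exceeds 1 per person-period")
    if resample == "target":
        if target_year is None:
            raise ValueError("resample='target' needs target_year")
        keep = np.array(arrays.years) != target_year
    draws = rng.binomial(
        n[None, ...], p[None, ...], size=(n_iterations,) + D.shape
    ).astype(float)
    out = np.moveaxis(draws, 0, -1)
    if resample == "target":
        out[:, keep, :, :] = D[:, keep, :, None]
    out[~valid, :] = np.nan
    return out


def _index_rates(
    arrays: PanelArrays,
    D: np.ndarray,
    index_kind: str,
    standard: StandardPopulation | None,
) -> np.ndarray:
    """Per-period all-ages rate matrix (H, P[, B]) for one mortality index.

    SDR splits each period's aggregate deaths by the year's annual age
    distribution of deaths before standardizing.
    """
    E = arrays.E
    batched = D.ndim == 4
    T = np.nansum(D, axis=0)  # (H, P[, B])
    if index_kind == "CDR":
        E_all = np.nansum(E, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = T / (E_all[..., None] if batched else E_all)
        return R
    if index_kind != "SDR":
        raise ValueError("index_kind must be 'CDR' or 'SDR'")
    if standard is None:
        raise ConfigurationError("SDR requires a standard population")
    w = standard.aligned_to(arrays.ages).to_numpy()
    annual_a = np.nansum(D, axis=2)  # (A, H[, B])
    shares = annual_a / annual_a.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        if batched:
            # k[h, p, b] = sum_a w_a * s[a, h, b] / E[a, h, p]
            k = np.einsum("a,ahb,ahp->hpb", w, shares, 1.0 / E)
        else:
            k = np.einsum("a,ah,ahp->hp", w, shares, 1.0 / E)
    return T * k


def _pipeline_excess(
    arrays: PanelArrays,
    D: np.ndarray,
    scenario: "ScenarioSpec",
    standard: StandardPopulation | None,
    target_year: int,
) -> np.ndarray | float:
    """Rates -> baseline fit -> prediction -> annual excess, batch-aware."""
    time_unit = arrays.time_unit
    n = 52 if time_unit == "week" else 12
    fit_periods = np.arange(1, n + 1)
    ref = scenario.reference_period
    R = _index_rates(arrays, D, scenario.index_kind, standard)

    hs = [arrays.year_index(y) for y in ref.years]
    ht = arrays.year_index(target_year)
    A_fit = R[hs][:, :n]
    coefs = fit_coefficients(
        A_fit, np.asarray(ref.years, float), scenario.method, fit_periods, n
    )
    pred = predict_matrix(
        coefs, scenario.method, target_year, fit_periods, n
    )  # (n[, B])

    obs_periods = observation_periods(
        target_year, time_unit, scenario.weeks_1_52
    )
    idx = np.asarray(obs_periods) - 1
    obs = R[ht][idx]
    expo = np.nansum(arrays.E, axis=0)[ht][idx]
    # week 53 copies the week-52 expected value
    pred_idx = np.minimum(idx, n - 1)
    pred_obs = pred[pred_idx]
    gap = (obs - pred_obs) * (expo[:, None] if obs.ndim == 2 else expo)
    annual_expo = arrays.annual_exposure(target_year)
    return gap.sum(axis=0) / annual_expo * REPORT_SCALE


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class ExcessMortalityModel:
    """Excess mortality for one country under one scenario.

    Parameters
    ----------
    panel
        Weekly or monthly panel covering the scenario's reference period
        and the target year.  Monthly panels are month-length adjusted on
        construction unless already flagged (``adjust_months=False`` opts
        out).
    scenario
        A :class:`~emsens.scenarios.ScenarioSpec`; its time unit must
        match the panel.
    standard
        Standard population; required for the SDR index.
    """

    def __init__(
        self,
        panel: MortalityPanel,
        scenario: "ScenarioSpec",
        standard: StandardPopulation | None = None,
        country: str | None = None,
        target_year: int = 2020,
        adjust_months: bool = True,
    ) -> None:
        if scenario.time_unit != panel.time_unit:
            raise ConfigurationError(
                f"scenario expects {scenario.time_unit}ly data, panel is "
                f"{panel.time_unit}ly"
            )
        if country is None:
            cs = panel.countries
            if len(cs) != 1:
                raise ConfigurationError("panel has several countries; pass country=")
            country = cs[0]
        if panel.time_unit == "month" and adjust_months and not panel.meta.get(
            "month_lengths_adjusted"
        ):
            panel = adjust_month_lengths(panel)
        self.panel = panel
        self.scenario = scenario
        self.standard = standard
        self.country = country
        self.target_year = int(target_year)
        self.arrays = PanelArrays.from_panel(panel, country)
        n_fit = 52 if panel.time_unit == "week" else 12
        self.arrays.check_coverage(
            scenario.reference_period, self.target_year, n_fit
        )
        if panel.time_unit == "week" and not scenario.weeks_1_52:
            # the full observation window needs week 53 when the target
            # ISO year is a leap-week year
            if iso_weeks_in_year(self.target_year) == 53:
                ht = self.arrays.year_index(self.target_year)
                if np.isnan(self.arrays.D[:, ht, 52]).any():
                    raise ConfigurationError(
                        f"{country}: week 53 of {self.target_year} missing from panel"
                    )

    def point_estimate(self) -> float:
        return float(
            _pipeline_excess(
                self.arrays,
                self.arrays.D,
                self.scenario,
                self.standard,
                self.target_year,
            )
        )

    def fit(
        self,
        n_iterations: int = 1000,
        seed: int | np.random.SeedSequence | None = None,
        level: float = 0.95,
        resample: str = "all",
    ) -> "ExcessMortalityResults":
        point = self.point_estimate()
        rng = np.random.default_rng(seed)
        D_star = resample_deaths(
            self.arrays, n_iterations, rng, resample, self.target_year
        )
        draws = np.asarray(
            _pipeline_excess(
                self.arrays, D_star, self.scenario, self.standard, self.target_year
            )
        )
        return ExcessMortalityResults(
            model=self,
            excess_rate=point,
            draws=draws,
            n_iterations=n_iterations,
            seed=seed,
            level=level,
        )


@dataclass
class ExcessMortalityResults:
    """Annual excess rate per 100,000 with its Monte-Carlo interval."""

    model: ExcessMortalityModel
    excess_rate: float
    draws: np.ndarray
    n_iterations: int
    seed: object
    level: float = 0.95

    def conf_int(self, level: float | None = None) -> tuple[float, float]:
        """Percentile bounds of the resampled excess at the given level."""
        lv = self.level if level is None else level
        if not 0 < lv < 1:
            raise ValueError("level must be in (0, 1)")
        lo, hi = np.percentile(self.draws, [50 * (1 - lv), 50 * (1 + lv)])
        return float(lo), float(hi)

    @property
    def ci_low(self) -> float:
        return self.conf_int()[0]

    @property
    def ci_high(self) -> float:
        return self.conf_int()[1]

    @property
    def mc_sd(self) -> float:
        """Monte-Carlo standard deviation of the excess estimate."""
        return float(self.draws.std(ddof=1))

    def summary(self) -> str:
        s = self.model.scenario
        lo, hi = self.conf_int()
        return "\n".join(
            [
                "Excess mortality",
                f"  country:          {self.model.country}",
                f"  scenario:         {s.id} ({s.index_kind}, {s.method}, "
                f"{s.reference_period}, {s.time_unit}"
                + (", weeks 1-52)" if s.weeks_1_52 else ")"),
                f"  target year:      {self.model.target_year}",
                f"  excess rate:      {self.excess_rate:.1f} per 100,000",
                f"  {self.level:.0%} CI:           [{lo:.1f}, {hi:.1f}] "
                f"({self.n_iterations} Monte-Carlo iterations)",
            ]
        )


def monte_carlo_ci(
    panel: MortalityPanel,
    scenario: "ScenarioSpec",
    n_iterations: int = 1000,
    seed: int | None = None,
    standard: StandardPopulation | None = None,
    country: str | None = None,
    target_year: int = 2020,
    level: float = 0.95,
    resample: str = "all",
) -> tuple[float, float]:
    """Percentile Monte-Carlo confidence interval for one scenario."""
    model = ExcessMortalityModel(
        panel, scenario, standard=standard, country=country, target_year=target_year
    )
    res = model.fit(
        n_iterations=n_iterations, seed=seed, level=level, resample=resample
    )
    return res.conf_int()
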