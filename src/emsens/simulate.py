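"""Synthetic short-term mortality panels with known ground truth.

The generator simulates deaths at *daily* resolution and aggregates the
same draw into ISO weeks and civil-calendar months, so weekly/monthly
comparisons rest on identical underlying deaths rather than on two
approximations.  For each country, age group and day:

    deaths ~ Binomial(population_age, daily rate),

with an annualized rate surface

    rate(age, day) = base_rate * (1 + trend)^(year - first_year)
                     * seasonality(day-of-year) [* shock] [* epidemic]

divided by 365.25 to give the daily probability.  Seasonality is a
two-harmonic factor 1 + a1*cos(2*pi*doy/365.25) + a2*cos(4*pi*doy/365.25),
truncated below at 0.05.  An optional multiplicative shock (a pandemic
analogue) raises rates of all ages in a window of ISO weeks of one year;
an optional epidemic year (an influenza-season analogue) raises rates in
the first quarter of that year.

Randomness uses one global seed with an independent substream per country
derived as ``SeedSequence([seed, crc32(country)])``, so any country's
series can be reproduced in isolation.

:class:`GroundTruth` records the noiseless generating surface, the drawn
daily deaths, the implied noiseless annual CDR/SDR, and the true excess
rate the shock adds under each mortality index.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .panel import MortalityPanel
from .rates import REPORT_SCALE
from .standard import BROAD_AGE_GROUPS, StandardPopulation, load_standard_population
from .timeunits import iso_weeks_in_year, iso_year_bounds

__all__ = ["Shock", "SimConfig", "GroundTruth", "simulate_panel", "default_config"]

DAYS_PER_YEAR = 365.25
SEASONALITY_FLOOR = 0.05


@dataclass(frozen=True)
class Shock:
    """Multiplicative rate shock over a window of ISO weeks of one year."""

    year: int
    week_start: int
    week_end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("shock multiplier must be >= 1")
        if not 1 <= self.week_start <= self.week_end <= 53:
            raise ValueError("shock week window must satisfy 1 <= start <= end <= 53")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic experiment."""

    countries: tuple[str, ...]
    years: tuple[int, int]
    age_groups: tuple[str, ...]
    base_rates: dict[str, float]
    annual_trend: dict[str, float]
    seasonal_amplitude: dict[str, tuple[float, float]]
    population: dict[str, int]
    shock: Shock | None = None
    epidemic_year: tuple[int, float] | None = None
    country_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 - y0 + 1 < 3:
            raise ValueError("simulation span must cover at least 3 years")
        for a in self.age_groups:
            if not 0 < self.base_rates[a] < 1:
                raise ValueError(f"base rate of {a} must be in (0, 1)")
            if self.population[a] <= 0:
                raise ValueError(f"population of {a} must be positive")
            a1, a2 = self.seasonal_amplitude[a]
            if a1 < 0 or a2 < 0:
                raise ValueError("seasonal amplitudes must be nonnegative")
        if self.epidemic_year is not None and self.epidemic_year[1] < 1:
            raise ValueError("epidemic multiplier must be >= 1")

    def country_effect(self, country: str) -> tuple[float, float]:
        """(rate scale, additive trend offset) for one country."""
        return self.country_effects.get(country, (1.0, 0.0))


def default_config(**overrides: Any) -> SimConfig:
    """The canonical synthetic study: two countries, 2010-2020, broad ages.

    Levels approximate a mid-size European population of one million with
    an all-ages crude death rate near 1,100 per 100,000, mortality
    declining about 1 percent a year (faster at young ages), winter-peaked
    seasonality strongest at old ages, a 2015 first-quarter epidemic
    season, and a 30 percent pandemic shock in ISO weeks 10-20 of 2020.
    The second country runs 15 percent higher mortality with a slightly
    slower decline.
    """
    base = dict(
        countries=("SIM-A", "SIM-B"),
        years=(2010, 2020),
        age_groups=tuple(BROAD_AGE_GROUPS),
        base_rates={
            "0-14": 0.0003,
            "15-64": 0.002,
            "65-74": 0.015,
            "75-84": 0.05,
            "85+": 0.15,
        },
        annual_trend={
            "0-14": -0.020,
            "15-64": -0.015,
            "65-74": -0.012,
            "75-84": -0.008,
            "85+": -0.005,
        },
        seasonal_amplitude={
            "0-14": (0.05, 0.01),
            "15-64": (0.08, 0.02),
            "65-74": (0.10, 0.02),
            "75-84": (0.12, 0.03),
            "85+": (0.15, 0.04),
        },
        population={
            "0-14": 160_000,
            "15-64": 640_000,
            "65-74": 100_000,
            "75-84": 70_000,
            "85+": 30_000,
        },
        shock=Shock(2020, 10, 20, 1.3),
        epidemic_year=(2015, 1.10),
        country_effects={"SIM-A": (1.0, 0.0), "SIM-B": (1.15, 0.004)},
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class GroundTruth:
    """The generating surface and the quantities it implies.

    Per country: the calendar dates simulated, the noiseless expected
    daily deaths with and without the shock, the drawn daily deaths, the
    noiseless annual CDR/SDR per calendar year, and the true excess rate
    per 100,000 the shock adds under each index (zero when no shock).
    """

    config: SimConfig
    dates: pd.DatetimeIndex
    per_country: dict[str, dict[str, Any]]

    def annual_cdr(self, country: str) -> pd.Series:
        return self.per_country[country]["annual_cdr"]

    def gold_standard_rates(self, country: str | None = None) -> pd.Series:
        """Annual all-ages death rates playing the role of the gold standard.

        Computed from the drawn daily deaths per civil-calendar year with
        person-year exposure ``population * days_in_year / 365.25`` — the
        year-length-normalized annual rates an annual reference source
        (such as the HMD core) would report for the same underlying
        deaths.  Calibrating the weekly and monthly panels to these rates
        puts 364-, 365-, 366- and 371-day panel years on a common
        person-year footing; without it, annual totals carry the ISO/civil
        year-length imprint.  With ``country=None`` a series over all
        countries indexed by (country, year) is returned, ready for
        :func:`~emsens.preprocess.calibrate_to_annual`.
        """
        if country is not None:
            return self.per_country[country]["gold_standard_cdr"]
        parts = {}
        for c, d in self.per_country.items():
            for y, v in d["gold_standard_cdr"].items():
                parts[(c, int(y))] = float(v)
        return pd.Series(parts)

    def annual_sdr(self, country: str) -> pd.Series | None:
        return self.per_country[country]["annual_sdr"]

    def true_excess(self, country: str, index_kind: str = "CDR") -> float:
        return self.per_country[country]["true_excess"][index_kind]

    def daily_deaths(self, country: str) -> np.ndarray:
        """Drawn daily deaths, shape (ages, days)."""
        return self.per_country[country]["drawn_daily"]

    def to_json_dict(self) -> dict[str, Any]:
        """JSON-serializable summary (surfaces are regenerable, not stored)."""
        cfg = self.config
        out: dict[str, Any] = {
            "config": {
                "countries": list(cfg.countries),
                "years": list(cfg.years),
                "age_groups": list(cfg.age_groups),
                "base_rates": cfg.base_rates,
                "annual_trend": cfg.annual_trend,
                "seasonal_amplitude": {
                    k: list(v) for k, v in cfg.seasonal_amplitude.items()
                },
                "population": cfg.population,
                "shock": (
                    None
                    if cfg.shock is None
                    else [
                        cfg.shock.year,
                        cfg.shock.week_start,
                        cfg.shock.week_end,
                        cfg.shock.multiplier,
                    ]
                ),
                "epidemic_year": (
                    None if cfg.epidemic_year is None else list(cfg.epidemic_year)
                ),
                "country_effects": {
                    k: list(v) for k, v in cfg.country_effects.items()
                },
                "seed": cfg.seed,
            },
            "countries": {},
        }
        for c, d in self.per_country.items():
            out["countries"][c] = {
                "annual_cdr": {int(k): float(v) for k, v in d["annual_cdr"].items()},
                "gold_standard_cdr": {
                    int(k): float(v) for k, v in d["gold_standard_cdr"].items()
                },
                "annual_sdr": (
                    None
                    if d["annual_sdr"] is None
                    else {int(k): float(v) for k, v in d["annual_sdr"].items()}
                ),
                "true_excess": {
                    k: (None if v is None else float(v))
                    for k, v in d["true_excess"].items()
                },
            }
        return out


def _country_rng(seed: int, country: str) -> np.random.Generator:
    """Independent, order-free substream for one country."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(country.encode())])
    )


def _rate_surface(
    config: SimConfig, country: str, dates: pd.DatetimeIndex, with_shock: bool
) -> np.ndarray:
    """Noiseless annualized rate per (age, day)."""
    scale, trend_off = config.country_effect(country)
    y0 = config.years[0]
    cal_year = dates.year.to_numpy()
    doy = dates.dayofyear.to_numpy()
    iso = dates.isocalendar()
    iso_year = iso["year"].to_numpy().astype(int)
    iso_week = iso["week"].to_numpy().astype(int)

    rates = np.empty((len(config.age_groups), len(dates)))
    for i, age in enumerate(config.age_groups):
        trend = config.annual_trend[age] + trend_off
        level = config.base_rates[age] * scale * (1.0 + trend) ** (cal_year - y0)
        a1, a2 = config.seasonal_amplitude[age]
        season = (
            1.0
            + a1 * np.cos(2 * np.pi * doy / DAYS_PER_YEAR)
            + a2 * np.cos(4 * np.pi * doy / DAYS_PER_YEAR)
        )
        rates[i] = level * np.clip(season, SEASONALITY_FLOOR, None)
    if config.epidemic_year is not None:
        ey, em = config.epidemic_year
        mask = (cal_year == ey) & (doy <= 91)  # first quarter
        rates[:, mask] *= em
    if with_shock and config.shock is not None:
        s = config.shock
        mask = (
            (iso_year == s.year)
            & (iso_week >= s.week_start)
            & (iso_week <= s.week_end)
        )
        rates[:, mask] *= s.multiplier
    return rates


def _aggregate(
    deaths: np.ndarray,
    keys_year: np.ndarray,
    keys_period: np.ndarray,
    years: list[int],
    config: SimConfig,
    country: str,
    time_unit: str,
) -> pd.DataFrame:
    """Sum daily deaths into (year, period) rows with uniform exposures."""
    rows = []
    frame = pd.DataFrame({"year": keys_year, "period": keys_period})
    for i, age in enumerate(config.age_groups):
        frame["deaths"] = deaths[i]
        g = frame.groupby(["year", "period"])["deaths"].sum()
        g = g[g.index.get_level_values("year").isin(years)]
        pop = config.population[age]
        for (y, p), d in g.items():
            nper = iso_weeks_in_year(int(y)) if time_unit == "week" else 12
            rows.append((country, int(y), int(p), age, float(d), pop / nper))
    return pd.DataFrame(
        rows, columns=["country", "year", "period", "age_group", "deaths", "exposure"]
    )


def simulate_panel(
    config: SimConfig,
    noiseless: bool = False,
    standard: StandardPopulation | None = None,
) -> tuple[MortalityPanel, MortalityPanel, GroundTruth]:
    """Simulate weekly and monthly panels from one daily draw.

    Returns the weekly panel (ISO week-years), the monthly panel (civil
    calendar years) and the :class:`GroundTruth`.  With ``noiseless=True``
    the expected (real-valued) deaths are used instead of binomial draws.
    The same seed always yields bit-identical panels.
    """
    y0, y1 = config.years
    start = min(pd.Timestamp(y0, 1, 1), pd.Timestamp(iso_year_bounds(y0)[0]))
    end = max(pd.Timestamp(y1, 12, 31), pd.Timestamp(iso_year_bounds(y1)[1]))
    dates = pd.date_range(start, end, freq="D")
    iso = dates.isocalendar()
    iso_year = iso["year"].to_numpy().astype(int)
    iso_week = iso["week"].to_numpy().astype(int)
    cal_year = dates.year.to_numpy()
    month = dates.month.to_numpy()
    years = list(range(y0, y1 + 1))
    pop = np.array([config.population[a] for a in config.age_groups])

    if standard is None and set(config.age_groups) == set(BROAD_AGE_GROUPS):
        standard = load_standard_population()

    weekly_parts, monthly_parts = [], []
    per_country: dict[str, dict[str, Any]] = {}
    for country in config.countries:
        rates = _rate_surface(config, country, dates, with_shock=True)
        p_daily = rates / DAYS_PER_YEAR
        if (p_daily >= 1).any():
            raise ValueError(
                f"{country}: daily death probability reaches 1; reduce rates"
            )
        expected = pop[:, None] * p_daily
        if noiseless:
            deaths = expected
        else:
            rng = _country_rng(config.seed, country)
            deaths = rng.binomial(pop[:, None], p_daily).astype(float)

        weekly_parts.append(
            _aggregate(deaths, iso_year, iso_week, years, config, country, "week")
        )
        monthly_parts.append(
            _aggregate(deaths, cal_year, month, years, config, country, "month")
        )

        if config.shock is None:
            baseline = expected  # no shock: the truth excess is exactly zero
        else:
            baseline = pop[:, None] * _rate_surface(
                config, country, dates, with_shock=False
            ) / DAYS_PER_YEAR
        per_country[country] = _ground_truth_entry(
            config, country, dates, cal_year, expected, baseline, deaths, standard
        )

    weekly = MortalityPanel(
        pd.concat(weekly_parts, ignore_index=True), "week", {"calendar": "iso"}
    )
    monthly = MortalityPanel(
        pd.concat(monthly_parts, ignore_index=True), "month", {"calendar": "civil"}
    )
    truth = GroundTruth(config, dates, per_country)
    return weekly, monthly, truth


def _ground_truth_entry(
    config: SimConfig,
    country: str,
    dates: pd.DatetimeIndex,
    cal_year: np.ndarray,
    expected: np.ndarray,
    baseline: np.ndarray,
    drawn: np.ndarray,
    standard: StandardPopulation | None,
) -> dict[str, Any]:
    pop = np.array([config.population[a] for a in config.age_groups])
    years = list(range(config.years[0], config.years[1] + 1))

    annual_cdr = {}
    gold = {}
    annual_sdr: dict[int, float] | None = {} if standard is not None else None
    w = (
        standard.aligned_to(list(config.age_groups)).to_numpy()
        if standard is not None
        else None
    )
    for y in years:
        mask = cal_year == y
        deaths_a = expected[:, mask].sum(axis=1)
        annual_cdr[y] = float(deaths_a.sum() / pop.sum())
        days = int(mask.sum())
        person_years = pop.sum() * days / DAYS_PER_YEAR
        gold[y] = float(drawn[:, mask].sum() / person_years)
        if annual_sdr is not None:
            annual_sdr[y] = float(np.dot(w, deaths_a / pop))

    extra = expected - baseline  # shock-attributable expected deaths per day
    extra_a = extra.sum(axis=1)
    true_cdr = float(extra_a.sum() / pop.sum() * REPORT_SCALE)
    true_sdr = (
        float(np.dot(w, extra_a / pop) * REPORT_SCALE) if w is not None else None
    )
    return {
        "expected_daily": expected,
        "baseline_daily": baseline,
        "drawn_daily": drawn,
        "annual_cdr": pd.Series(annual_cdr),
        "gold_standard_cdr": pd.Series(gold),
        "annual_sdr": None if annual_sdr is None else pd.Series(annual_sdr),
        "true_excess": {"CDR": true_cdr, "SDR": true_sdr},
    }
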