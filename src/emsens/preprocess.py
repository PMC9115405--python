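"""Harmonization of weekly and monthly death series.

Four steps make weekly and monthly panels comparable with each other and
with annual gold-standard rates:

* uniform period exposures — annual person-years divided by the number of
  ISO weeks (52 or 53) or by 12, under zero migration;
* month-length adjustment — months are rescaled to a common 365.25/12-day
  length, then the year total is restored exactly;
* calibration — period deaths of each year are scaled so the panel's annual
  all-ages rate matches an external (gold standard) annual rate;
* week 1-52 restriction — week-53 records are dropped so leap-week ISO
  years can be compared with civil-calendar months.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import ConfigurationError, MortalityPanel
from .timeunits import (
    DAYS_PER_MONTH_STANDARD,
    days_in_month,
    iso_weeks_in_year,
    periods_in_year,
)

__all__ = [
    "period_exposures",
    "adjust_month_lengths",
    "calibrate_to_annual",
    "restrict_weeks_1_52",
]


def period_exposures(annual_exposure: float, year: int, time_unit: str) -> np.ndarray:
    """Spread annual person-years uniformly over the year's periods.

    Weekly exposures are ``annual / W`` with W the number of ISO weeks in
    the year (52 or 53); monthly exposures are ``annual / 12``.
    """
    if annual_exposure <= 0:
        raise ValueError("annual exposure must be positive")
    n = periods_in_year(year, time_unit)
    return np.full(n, annual_exposure / n)


def adjust_month_lengths(panel: MortalityPanel) -> MortalityPanel:
    """Rescale monthly deaths to a common 365.25/12-day month.

    Each month's deaths are multiplied by 30.44/actual-days (30.44 being
    365.25/12); all months of a (country, year) are then rescaled by one
    common factor so the annual total is exactly what it was before.  The
    resulting panel is marked ``month_lengths_adjusted`` and a second call
    is a no-op: re-applying the day-length ratio to already-harmonized
    counts would distort them.
    """
    if panel.time_unit != "month":
        raise ValueError("month-length adjustment applies to monthly panels only")
    if panel.meta.get("month_lengths_adjusted"):
        warnings.warn("panel already month-length adjusted; returning unchanged")
        return panel

    df = panel.data.copy()
    ratio = np.array(
        [
            DAYS_PER_MONTH_STANDARD / days_in_month(y, m)
            for y, m in zip(df["year"], df["period"])
        ]
    )
    before = df.groupby(["country", "year"])["deaths"].transform("sum")
    df["deaths"] = df["deaths"] * ratio
    after = df.groupby(["country", "year"])["deaths"].transform("sum")
    # restore each year's total exactly (years with zero deaths stay zero)
    factor = np.where(after > 0, before / after.replace(0, np.nan), 1.0)
    df["deaths"] = df["deaths"] * np.nan_to_num(factor, nan=1.0)
    return panel.replace(df, month_lengths_adjusted=True)


def calibrate_to_annual(
    panel: MortalityPanel, annual_reference_rates: pd.Series | dict
) -> tuple[MortalityPanel, pd.DataFrame]:
    """Scale period deaths so annual rates match gold-standard annual rates.

    ``annual_reference_rates`` maps (country, year) to an all-ages annual
    death rate in deaths per person-year.  All period deaths of a
    (country, year) are multiplied by reference/panel annual rate, making
    the panel's annual rate equal the reference to machine precision.
    Years without a reference are left unchanged and flagged in the
    returned report (columns: factor, calibrated).
    """
    ref = pd.Series(annual_reference_rates, dtype=float)
    if (ref <= 0).any():
        raise ConfigurationError("reference annual rates must be positive")
    if not any(k in ref.index for k in panel.annual_rate().index):
        raise ConfigurationError(
            "no (country, year) key of the panel matches the reference rates; "
            "references must be keyed by (country, year)"
        )

    panel_rate = panel.annual_rate()
    df = panel.data.copy()
    rows = []
    factors = pd.Series(1.0, index=panel_rate.index)
    for key, rate in panel_rate.items():
        if key in ref.index:
            factors[key] = ref[key] / rate
            rows.append((*key, factors[key], True))
        else:
            rows.append((*key, 1.0, False))
    fmap = df.set_index(["country", "year"]).index.map(factors)
    df["deaths"] = df["deaths"] * np.asarray(fmap, dtype=float)
    report = pd.DataFrame(rows, columns=["country", "year", "factor", "calibrated"])
    return panel.replace(df, calibration=report), report


def restrict_weeks_1_52(panel: MortalityPanel) -> MortalityPanel:
    """Drop week-53 records from a weekly panel.

    Used both for fitting baselines (which always use weeks 1-52) and for
    the observation window of the monthly-comparison scenarios, so that
    leap-week ISO years line up with 52-week years and with months.
    """
    if panel.time_unit != "week":
        raise ValueError("weeks 1-52 restriction applies to weekly panels only")
    df = panel.data[panel.data["period"] <= 52]
    if len(df) == len(panel.data):
        return panel
    return panel.replace(df.copy(), weeks_restricted_to_52=True)


def weeks_53_present(panel: MortalityPanel) -> list[tuple[str, int]]:
    """(country, year) pairs that still carry a week-53 record."""
    df = panel.data
    sub = df[df["period"] == 53]
    return sorted({(c, int(y)) for c, y in zip(sub["country"], sub["year"])})


def fit_periods(year_range: list[int], time_unit: str) -> list[int]:
    """Periods used for baseline fitting: weeks 1-52 or months 1-12."""
    if time_unit == "week":
        return list(range(1, 53))
    return list(range(1, 13))


def observation_periods(year: int, time_unit: str, weeks_1_52: bool) -> list[int]:
    """Periods of the target-year observation window for one scenario."""
    if time_unit == "month":
        return list(range(1, 13))
    if weeks_1_52:
        return list(range(1, 53))
    return list(range(1, iso_weeks_in_year(year) + 1))
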