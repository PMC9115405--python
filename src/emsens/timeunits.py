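"""ISO 8601 week-year and civil-calendar helpers.

Weekly death series follow the ISO 8601 convention: a week belongs to the
year that contains its Thursday, so ISO years have either 52 or 53 weeks
("long" or leap-week years, e.g. 2015 and 2020).  Monthly series follow the
civil calendar.  The three average month lengths used by the month-length
adjustment are kept here as exact fractions.
"""

from __future__ import annotations

import calendar
import datetime as dt

__all__ = [
    "DAYS_PER_MONTH_LEAP",
    "DAYS_PER_MONTH_COMMON",
    "DAYS_PER_MONTH_STANDARD",
    "iso_weeks_in_year",
    "is_long_iso_year",
    "iso_year_bounds",
    "days_in_month",
    "periods_in_year",
]

#: Average days per month in a leap year (366/12 = 30.50).
DAYS_PER_MONTH_LEAP = 366 / 12
#: Average days per month in a common year (365/12 ~= 30.42).
DAYS_PER_MONTH_COMMON = 365 / 12
#: Year-independent average month length (365.25/12 ~= 30.44) used to put
#: months of different lengths on a common footing.
DAYS_PER_MONTH_STANDARD = 365.25 / 12


def iso_weeks_in_year(year: int) -> int:
    """Number of ISO 8601 weeks (52 or 53) in ISO year ``year``.

    December 28 always falls in the last ISO week of its year.
    """
    return dt.date(year, 12, 28).isocalendar().week


def is_long_iso_year(year: int) -> bool:
    """True when ISO year ``year`` has 53 weeks."""
    return iso_weeks_in_year(year) == 53


def iso_year_bounds(year: int) -> tuple[dt.date, dt.date]:
    """First and last calendar date covered by ISO year ``year``."""
    first = dt.date.fromisocalendar(year, 1, 1)
    last = dt.date.fromisocalendar(year, iso_weeks_in_year(year), 7)
    return first, last


def days_in_month(year: int, month: int) -> int:
    """Actual number of days in a civil-calendar month (leap-aware)."""
    return calendar.monthrange(year, month)[1]


def periods_in_year(year: int, time_unit: str) -> int:
    """Periods per year: 52/53 ISO weeks or 12 months."""
    if time_unit == "week":
        return iso_weeks_in_year(year)
    if time_unit == "month":
        return 12
    raise ValueError(f"unknown time unit {time_unit!r} (expected 'week' or 'month')")
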