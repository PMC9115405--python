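"""Crude and age-standardized death rates.

Rates are stored in deaths per person-year; the conventional per-100,000
scaling is applied only when results are reported.  The age detail needed
for standardization is recovered from aggregate period deaths by a
proportional split: each period's total is allocated to age groups
according to that year's annual age distribution of deaths.  This is a
deliberate simplification of the full weekly age-splitting methodology
(which combines weekly totals with detailed annual data); it preserves
annual age totals exactly and is unbiased whenever the within-year age
mix of deaths is stable across periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ConfigurationError, MortalityPanel
from .standard import StandardPopulation

__all__ = [
    "RateSeries",
    "split_ages",
    "crude_rate",
    "standardized_rate",
    "build_rate_series",
]

REPORT_SCALE = 100_000.0


@dataclass
class RateSeries:
    """Per-period all-ages death rates for one country and mortality index.

    ``frame`` has columns ``year, period, rate, exposure`` where ``rate``
    is an annualized death rate (deaths per person-year) and ``exposure``
    the all-ages person-years of the period.
    """

    country: str
    index_kind: str  # "CDR" or "SDR"
    time_unit: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.index_kind not in ("CDR", "SDR"):
            raise ValueError("index_kind must be 'CDR' or 'SDR'")
        if (self.frame["rate"] < 0).any():
            raise ValueError("negative rates")
        self.frame = self.frame.sort_values(["year", "period"]).reset_index(drop=True)

    def matrix(self, years: list[int], periods: list[int]) -> np.ndarray:
        """Rates as an array of shape (len(years), len(periods)).

        Raises when any requested (year, period) cell is absent.
        """
        piv = self.frame.pivot(index="year", columns="period", values="rate")
        try:
            out = piv.loc[years, periods].to_numpy(dtype=float)
        except KeyError as exc:
            raise ConfigurationError(f"rate series missing cells: {exc}") from exc
        if np.isnan(out).any():
            raise ConfigurationError("rate series has missing (year, period) cells")
        return out

    def exposures(self, year: int, periods: list[int]) -> np.ndarray:
        piv = self.frame.pivot(index="year", columns="period", values="exposure")
        return piv.loc[year, periods].to_numpy(dtype=float)


def split_ages(
    total_period_deaths: np.ndarray | float,
    annual_age_distribution: np.ndarray | pd.Series,
) -> np.ndarray:
    """Allocate aggregate period deaths to age groups by annual shares.

    ``annual_age_distribution`` must sum to 1 (within 1e-9).  Returns an
    array with a leading age axis; the age sum reproduces the input totals
    exactly.
    """
    shares = np.asarray(annual_age_distribution, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"annual age shares sum to {shares.sum():.12f}, expected 1"
        )
    totals = np.asarray(total_period_deaths, dtype=float)
    return shares.reshape(shares.shape + (1,) * totals.ndim) * totals[np.newaxis, ...]


def crude_rate(deaths: float, exposure: float) -> float:
    """All-ages deaths over person-years (annualized by the exposure units)."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    return deaths / exposure


def standardized_rate(
    age_rates: pd.Series | np.ndarray, standard: StandardPopulation
) -> float:
    """Weighted sum of age-specific rates with standard-population weights."""
    if isinstance(age_rates, pd.Series):
        w = standard.aligned_to(list(age_rates.index)).to_numpy()
        r = age_rates.to_numpy(dtype=float)
    else:
        r = np.asarray(age_rates, dtype=float)
        if len(r) != len(standard.weights):
            raise ConfigurationError("age groups of rates and weights do not match")
        w = standard.weights.to_numpy()
    return float(np.dot(w, r))


def build_rate_series(
    panel: MortalityPanel,
    index_kind: str,
    standard: StandardPopulation | None = None,
    country: str | None = None,
) -> RateSeries:
    """Per-period CDR or SDR series for one country of a panel.

    CDR: total deaths over total exposure per period.  SDR: aggregate
    period deaths are split by the year's annual age distribution of
    deaths, turned into age-specific rates with the age-specific
    exposures, and combined with the standard-population weights.
    """
    if country is None:
        cs = panel.countries
        if len(cs) != 1:
            raise ConfigurationError("panel has several countries; pass country=")
        country = cs[0]
    sub = panel.data[panel.data["country"] == country]
    if sub.empty:
        raise KeyError(f"country {country!r} not in panel")

    if index_kind == "CDR":
        g = sub.groupby(["year", "period"])[["deaths", "exposure"]].sum()
        frame = g.reset_index()
        frame["rate"] = frame["deaths"] / frame["exposure"]
        frame = frame[["year", "period", "rate", "exposure"]]
        return RateSeries(country, "CDR", panel.time_unit, frame)

    if index_kind != "SDR":
        raise ValueError("index_kind must be 'CDR' or 'SDR'")
    if standard is None:
        raise ConfigurationError("SDR requires a standard population")

    ages = panel.age_groups
    w = standard.aligned_to(ages).to_numpy()

    rows = []
    for year, ysub in sub.groupby("year"):
        piv_d = ysub.pivot(index="age_group", columns="period", values="deaths")
        piv_e = ysub.pivot(index="age_group", columns="period", values="exposure")
        piv_d = piv_d.reindex(ages)
        piv_e = piv_e.reindex(ages)
        totals = piv_d.sum(axis=0).to_numpy()
        annual_by_age = piv_d.sum(axis=1).to_numpy()
        shares = annual_by_age / annual_by_age.sum()
        split = split_ages(totals, shares)  # (age, period)
        age_rates = split / piv_e.to_numpy()
        sdr = w @ age_rates
        expo = piv_e.sum(axis=0).to_numpy()
        for p, r, e in zip(piv_d.columns, sdr, expo):
            rows.append((int(year), int(p), float(r), float(e)))
    frame = pd.DataFrame(rows, columns=["year", "period", "rate", "exposure"])
    return RateSeries(country, "SDR", panel.time_unit, frame)
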