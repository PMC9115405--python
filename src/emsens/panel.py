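"""The mortality panel container.

A :class:`MortalityPanel` holds death counts and person-year exposures
indexed by (country, year, period, age group) for a single time unit —
ISO weeks or civil months — in the broad-age-group dialect of short-term
mortality series (weekly counts by country, week and age band, with
exposures obtained by spreading annual population uniformly across the
periods of the year under zero migration).

Deaths may be real-valued: the month-length adjustment and the calibration
to annual gold-standard rates both rescale counts multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .timeunits import periods_in_year

__all__ = [
    "PanelFormatError",
    "PanelIntegrityError",
    "ConfigurationError",
    "PANEL_COLUMNS",
    "MortalityPanel",
]


class PanelFormatError(ValueError):
    """A panel file or frame does not have the expected layout."""


class PanelIntegrityError(ValueError):
    """A panel violates an internal consistency rule (duplicates, bad periods)."""


class ConfigurationError(ValueError):
    """Inputs (standard population, references, scenarios) do not fit the panel."""


PANEL_COLUMNS = ["country", "year", "period", "age_group", "deaths", "exposure"]


@dataclass
class MortalityPanel:
    """Death counts and exposures for one time unit.

    Parameters
    ----------
    data
        Long-format frame with columns ``country, year, period, age_group,
        deaths, exposure``.  ``period`` is an ISO week (1..52/53) or a civil
        month (1..12); ``exposure`` is person-years per period and age group.
    time_unit
        ``"week"`` or ``"month"``.
    meta
        Free-form provenance (e.g. ``month_lengths_adjusted``, calibration
        report); carried along by the preprocessing steps.
    """

    data: pd.DataFrame
    time_unit: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_unit not in ("week", "month"):
            raise PanelFormatError(
                f"time_unit must be 'week' or 'month', got {self.time_unit!r}"
            )
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelFormatError(f"panel is missing columns {missing}")
        df = self.data.loc[:, PANEL_COLUMNS].copy()
        df["country"] = df["country"].astype(str)
        df["year"] = df["year"].astype(int)
        df["period"] = df["period"].astype(int)
        df["age_group"] = df["age_group"].astype(str)
        df["deaths"] = df["deaths"].astype(float)
        df["exposure"] = df["exposure"].astype(float)
        self.data = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if (df["deaths"] < 0).any():
            raise PanelIntegrityError("negative death counts")
        if (df["exposure"] <= 0).any():
            raise PanelIntegrityError("nonpositive exposures")
        dup = df.duplicated(subset=["country", "year", "period", "age_group"])
        if dup.any():
            keys = df.loc[dup, ["country", "year", "period", "age_group"]].iloc[0]
            raise PanelIntegrityError(
                f"duplicate (country, year, period, age_group) key: {tuple(keys)}"
            )
        for year, sub in df.groupby("year"):
            nper = periods_in_year(int(year), self.time_unit)
            bad = sub[(sub["period"] < 1) | (sub["period"] > nper)]
            if not bad.empty:
                p = int(bad["period"].iloc[0])
                raise PanelIntegrityError(
                    f"period {p} out of range 1..{nper} for year {year} "
                    f"({self.time_unit}ly panel)"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())

    @property
    def age_groups(self) -> list[str]:
        """Age groups in first-appearance order."""
        return list(dict.fromkeys(self.data["age_group"]))

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def annual_exposure(self) -> pd.Series:
        """Person-years per (country, year), summed over age groups.

        Period exposures are uniform within the year by construction
        (annual exposure divided by the number of periods), so the annual
        figure is the per-period exposure times the number of periods in
        the year's calendar, summed over ages.  This is robust to panels
        from which week 53 has been dropped.
        """
        df = self.data
        per = (
            df.groupby(["country", "year", "age_group"])["exposure"]
            .mean()
            .reset_index()
        )
        per["annual"] = [
            e * periods_in_year(y, self.time_unit)
            for y, e in zip(per["year"], per["exposure"])
        ]
        return per.groupby(["country", "year"])["annual"].sum()

    def annual_deaths(self) -> pd.Series:
        """Total deaths per (country, year) over the periods present."""
        return self.data.groupby(["country", "year"])["deaths"].sum()

    def annual_rate(self) -> pd.Series:
        """All-ages annual death rate (deaths per person-year) per (country, year)."""
        return self.annual_deaths() / self.annual_exposure()

    def select(self, country: str) -> "MortalityPanel":
        """Sub-panel for one country (meta carried over)."""
        sub = self.data[self.data["country"] == country]
        if sub.empty:
            raise KeyError(f"country {country!r} not in panel")
        return MortalityPanel(sub.copy(), self.time_unit, dict(self.meta))

    def replace(self, data: pd.DataFrame, **meta: Any) -> "MortalityPanel":
        """New panel with the same time unit and updated meta."""
        merged = dict(self.meta)
        merged.update(meta)
        return MortalityPanel(data, self.time_unit, merged)

    def total_deaths(self) -> float:
        return float(self.data["deaths"].sum())

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, MortalityPanel):
            return NotImplemented
        if self.time_unit != other.time_unit:
            return False
        a = self.data.sort_values(PANEL_COLUMNS[:4]).reset_index(drop=True)
        b = other.data.sort_values(PANEL_COLUMNS[:4]).reset_index(drop=True)
        return a.equals(b)

    def allclose(self, other: "MortalityPanel", rtol: float = 1e-12) -> bool:
        """Numeric near-equality on the shared key set."""
        key = PANEL_COLUMNS[:4]
        a = self.data.set_index(key).sort_index()
        b = other.data.set_index(key).sort_index()
        if not a.index.equals(b.index):
            return False
        return bool(
            np.allclose(a["deaths"], b["deaths"], rtol=rtol)
            and np.allclose(a["exposure"], b["exposure"], rtol=rtol)
        )
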