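"""Standard populations for age-standardized death rates.

Ships the 2013 European Standard Population (ESP2013) in its published
5-year bands and collapses it by summation to the broad age groups of the
short-term mortality series (0-14, 15-64, 65-74, 75-84, 85+).  Weights are
stored as fractions of the standard population and sum to one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .panel import ConfigurationError

__all__ = [
    "BROAD_AGE_GROUPS",
    "StandardPopulation",
    "esp2013_fine",
    "load_standard_population",
]

BROAD_AGE_GROUPS = ["0-14", "15-64", "65-74", "75-84", "85+"]

# Upper bound (inclusive) of each broad band; 85+ is open-ended.
_BROAD_BOUNDS = [(0, 14), (15, 64), (65, 74), (75, 84), (85, None)]


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights of a standard population (fractions summing to 1)."""

    weights: pd.Series  # index: age_group label, values: fraction

    def __post_init__(self) -> None:
        w = self.weights.astype(float)
        if (w <= 0).any():
            raise ConfigurationError("standard-population weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"standard-population weights sum to {w.sum():.12f}, expected 1"
            )
        object.__setattr__(self, "weights", w)

    @property
    def age_groups(self) -> list[str]:
        return list(self.weights.index)

    def aligned_to(self, age_groups: list[str]) -> pd.Series:
        """Weights reindexed to a panel's age grouping; must cover it exactly."""
        missing = [a for a in age_groups if a not in self.weights.index]
        if missing:
            raise ConfigurationError(
                f"standard population lacks weights for age groups {missing}"
            )
        return self.weights.reindex(age_groups)

    @classmethod
    def uniform(cls, age_groups: list[str]) -> "StandardPopulation":
        k = len(age_groups)
        return cls(pd.Series(1.0 / k, index=list(age_groups)))

    @classmethod
    def from_counts(cls, counts: pd.Series) -> "StandardPopulation":
        return cls(counts.astype(float) / float(counts.sum()))


def _lower_bound(label: str) -> int:
    m = re.match(r"^\s*(\d+)", str(label))
    if m is None:
        raise ConfigurationError(f"cannot parse age-group label {label!r}")
    return int(m.group(1))


def broad_group_for(label: str) -> str:
    """Map a fine age band (by its lower bound) to the broad STMF group."""
    low = _lower_bound(label)
    for (lo, hi), name in zip(_BROAD_BOUNDS, BROAD_AGE_GROUPS):
        if hi is None or low <= hi:
            if low >= lo:
                return name
    raise ConfigurationError(f"age band {label!r} does not fit the broad grouping")


def esp2013_fine() -> pd.Series:
    """The published ESP2013 table (counts per 100,000) in 5-year bands."""
    with resources.files("emsens.data").joinpath("esp2013.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("age_group")["standard_population"].astype(float)


def collapse_to_broad(fine: pd.Series) -> pd.Series:
    """Sum fine bands into the broad groups, preserving the broad order."""
    grouped = fine.groupby([broad_group_for(a) for a in fine.index]).sum()
    return grouped.reindex(BROAD_AGE_GROUPS)


def load_standard_population(path: str | None = None) -> StandardPopulation:
    """Load a standard population and collapse it to the broad age groups.

    With ``path=None`` the packaged ESP2013 table is used.  A user-supplied
    CSV must have columns ``age_group`` and ``standard_population``; fine
    bands are collapsed by summation, labels already matching the broad
    groups are passed through.
    """
    if path is None:
        fine = esp2013_fine()
    else:
        df = pd.read_csv(path)
        for col in ("age_group", "standard_population"):
            if col not in df.columns:
                raise ConfigurationError(
                    f"standard-population file lacks column {col!r}"
                )
        fine = df.set_index("age_group")["standard_population"].astype(float)
    if set(fine.index) == set(BROAD_AGE_GROUPS):
        counts = fine.reindex(BROAD_AGE_GROUPS)
    else:
        counts = collapse_to_broad(fine)
    if counts.isna().any():
        raise ConfigurationError("standard population does not cover the broad groups")
    return StandardPopulation.from_counts(counts)
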