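"""Reading and writing panels, ground truth and simulation configs.

Panels travel as plain CSV in the short-term-mortality dialect with
columns ``country, year, period, age_group, deaths, exposure``; the time
unit is a property of the file as a whole.  Ground truth is summarized to
a JSON sidecar; simulation configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .panel import PANEL_COLUMNS, MortalityPanel, PanelFormatError
from .simulate import GroundTruth, Shock, SimConfig
from .standard import load_standard_population  # noqa: F401  (re-export)

__all__ = [
    "read_panel",
    "write_panel",
    "load_standard_population",
    "write_ground_truth",
    "read_ground_truth",
    "read_sim_config",
    "write_sim_config",
]


def read_panel(path: str | Path, time_unit: str) -> MortalityPanel:
    """Read and validate a panel CSV.

    Raises :class:`~emsens.panel.PanelFormatError` on missing columns and
    :class:`~emsens.panel.PanelIntegrityError` on duplicate keys, negative
    deaths, nonpositive exposures or out-of-calendar periods (week 53 in a
    52-week ISO year).
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing columns {missing}")
    return MortalityPanel(df, time_unit, {"source": str(path)})


def write_panel(panel: MortalityPanel, path: str | Path) -> None:
    """Write a panel CSV in canonical column and sort order."""
    df = panel.data.sort_values(PANEL_COLUMNS[:4])
    df.to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


def read_ground_truth(path: str | Path) -> dict:
    """Ground-truth summary as a plain dict (config echo, annual rates, excess)."""
    with open(path) as fh:
        return json.load(fh)


def read_sim_config(path: str | Path) -> SimConfig:
    """Build a :class:`~emsens.simulate.SimConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    shock = raw.get("shock")
    if shock is not None:
        shock = Shock(
            int(shock["year"]),
            int(shock["week_start"]),
            int(shock["week_end"]),
            float(shock["multiplier"]),
        )
    epidemic = raw.get("epidemic_year")
    if epidemic is not None:
        epidemic = (int(epidemic["year"]), float(epidemic["multiplier"]))
    seas = {k: tuple(v) for k, v in raw["seasonal_amplitude"].items()}
    effects = {
        k: tuple(v) for k, v in (raw.get("country_effects") or {}).items()
    }
    return SimConfig(
        countries=tuple(raw["countries"]),
        years=tuple(raw["years"]),
        age_groups=tuple(raw["age_groups"]),
        base_rates={k: float(v) for k, v in raw["base_rates"].items()},
        annual_trend={k: float(v) for k, v in raw["annual_trend"].items()},
        seasonal_amplitude=seas,
        population={k: int(v) for k, v in raw["population"].items()},
        shock=shock,
        epidemic_year=epidemic,
        country_effects=effects,
        seed=int(raw.get("seed", 0)),
    )


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    raw = {
        "countries": list(config.countries),
        "years": list(config.years),
        "age_groups": list(config.age_groups),
        "base_rates": config.base_rates,
        "annual_trend": config.annual_trend,
        "seasonal_amplitude": {k: list(v) for k, v in config.seasonal_amplitude.items()},
        "population": config.population,
        "shock": (
            None
            if config.shock is None
            else {
                "year": config.shock.year,
                "week_start": config.shock.week_start,
                "week_end": config.shock.week_end,
                "multiplier": config.shock.multiplier,
            }
        ),
        "epidemic_year": (
            None
            if config.epidemic_year is None
            else {
                "year": config.epidemic_year[0],
                "multiplier": config.epidemic_year[1],
            }
        ),
        "country_effects": {k: list(v) for k, v in config.country_effects.items()},
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
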