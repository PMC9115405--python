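"""Shared fixtures: small synthetic panels and replicate batches.

Everything is generated at test time from the package's own synthetic
generator with fixed seeds; heavy replicate batches are session-scoped so
the statistical suites share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from emsens.preprocess import calibrate_to_annual
from emsens.simulate import default_config, simulate_panel
from emsens.standard import load_standard_population

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def esp():
    return load_standard_population()


@pytest.fixture(scope="session")
def small_sim():
    """One-country 2015-2020 draw with the default shock, plus truth."""
    cfg = default_config(countries=("SIM-A",), years=(2015, 2020), seed=42)
    weekly, monthly, truth = simulate_panel(cfg)
    return cfg, weekly, monthly, truth


@pytest.fixture(scope="session")
def two_country_sim():
    """The canonical two-country 2010-2020 study draw, calibrated."""
    cfg = default_config(seed=7)
    weekly, monthly, truth = simulate_panel(cfg)
    gold = truth.gold_standard_rates()
    weekly, _ = calibrate_to_annual(weekly, gold)
    monthly, _ = calibrate_to_annual(monthly, gold)
    return cfg, weekly, monthly, truth


def make_null_config(seed: int):
    """Shock-free, trend-free, season-free study conditions (2010-2020)."""
    ages = ("0-14", "15-64", "65-74", "75-84", "85+")
    return default_config(
        annual_trend={a: 0.0 for a in ages},
        seasonal_amplitude={a: (0.0, 0.0) for a in ages},
        shock=None,
        epidemic_year=None,
        countries=("SIM-A",),
        country_effects={},
        seed=seed,
    )


@pytest.fixture(scope="session")
def null_replicates():
    """200 calibrated replicate panels under the null (no shock/trend/season).

    Returns a list of (weekly, monthly, truth) triples; used by the
    null-behaviour and estimator-agreement suites.
    """
    reps = []
    root = np.random.SeedSequence(2024)
    for child in root.spawn(200):
        seed = int(child.generate_state(1)[0] % (2**31))
        weekly, monthly, truth = simulate_panel(make_null_config(seed))
        gold = truth.gold_standard_rates()
        weekly, _ = calibrate_to_annual(weekly, gold)
        monthly, _ = calibrate_to_annual(monthly, gold)
        reps.append((weekly, monthly, truth))
    return reps


@pytest.fixture()
def tiny_panel_df():
    """Hand-written two-country weekly panel frame (2 years x 3 weeks x 2 ages)."""
    rows = []
    for country in ("AA", "BB"):
        for year in (2018, 2019):
            for week in (1, 2, 3):
                for age, deaths, expo in (("0-64", 4.0, 50_000.0), ("65+", 20.0, 10_000.0)):
                    rows.append((country, year, week, age, deaths, expo))
    return pd.DataFrame(
        rows, columns=["country", "year", "period", "age_group", "deaths", "exposure"]
    )
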