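# emsens

Sensitivity analysis of excess-mortality estimates from weekly and monthly
all-cause death series.

Excess mortality — observed all-cause mortality minus the level expected
had a crisis not occurred — is the standard yardstick for the overall
mortality burden of a pandemic, but the number depends on choices that are
often made silently: the mortality index, the baseline model, the
reference period, and the time unit of the death data.  `emsens`
implements the full machinery needed to make those choices explicit and to
quantify how much they matter, and ships a synthetic data generator with
known ground truth so every step can be validated end to end.

## What it computes

For a country with death counts D(h, i) and uniform period exposures in
year h and week/month i (annualized rates a(h, i)), four baseline models
estimate the expected rate y(t, i) for a target year t from a reference
period of r years:

| method | model |
| --- | --- |
| Specific-Average | y(t,i) = (1/r) Σ_h a(h,i) |
| Specific-Average with Trend | y(t,i) = μ_i + β·h (common slope, per-period intercepts) |
| Harmonic with Trend | y(t,i) = μ + β·h + δ sin(2πi/n) + η cos(2πi/n) + θ sin(4πi/n) + υ cos(4πi/n) |
| Specific-Trend | y(t,i) = μ_i + β_i·h (independent slope per period) |

all fitted by unweighted least squares with the year covariate centered.
The annual excess rate per 100,000 person-years is

    excess = Σ_i (a(t,i) − y(t,i)) · e(t,i) / E(t) · 100,000,

with e the period exposures and E the annual exposure.  Mortality is
summarized either as the crude death rate (CDR) or as the age-standardized
death rate (SDR) with the 2013 European Standard Population collapsed to
the broad groups 0–14 / 15–64 / 65–74 / 75–84 / 85+; age detail is
recovered from aggregate period deaths by a proportional annual-share
split.  95 % confidence intervals come from Monte-Carlo simulation:
deaths in every (year, period, age) cell are redrawn as
Binomial(persons, observed rate) and the whole pipeline is re-run, 1,000
iterations by default.

A 16-scenario grid crosses {SDR, CDR} × {four methods} × {2010–19,
2015–19, 2017–19} × {weeks, months}; helper routines compute pairwise
scenario differences (with common random numbers), country rankings, and
Spearman rank correlations between rankings.

Weekly series follow ISO 8601 week-years (52 or 53 weeks; baselines are
fitted on weeks 1–52 and the week-53 baseline copies week 52), monthly
series are harmonized to a common 365.25/12-day month, and panels can be
calibrated to annual gold-standard rates — the step that puts 364-, 365-,
366- and 371-day panel years on a common person-year footing.

## Worked example

```python
from emsens import (default_config, simulate_panel, calibrate_to_annual,
                    load_standard_population, ExcessMortalityModel)
from emsens.scenarios import get_scenario

cfg = default_config(seed=1)                  # two countries, 2010-2020,
weekly, monthly, truth = simulate_panel(cfg)  # 30% shock in weeks 10-20 of 2020
weekly, _ = calibrate_to_annual(weekly, truth.gold_standard_rates())

esp = load_standard_population()              # ESP2013, broad age groups
scenario = get_scenario(2)                    # SDR, Specific-Average with Trend,
model = ExcessMortalityModel(weekly, scenario,  # 2015-2019, weekly
                             standard=esp, country="SIM-A")
print(model.fit(n_iterations=1000, seed=1).summary())
```

```
Excess mortality
  country:          SIM-A
  scenario:         2 (SDR, specific_average_trend, 2015-2019, week)
  target year:      2020
  excess rate:      89.0 per 100,000
  95% CI:           [61.7, 117.1] (1000 Monte-Carlo iterations)
```

The generator's true shock-attributable excess is 55.4 per 100,000.  The
estimate overshoots deliberately: the default study conditions place an
epidemic season (2015, +10 % in the first quarter) inside the 2015–2019
reference period, which steepens the fitted decline and lowers the
baseline — exactly the reference-period sensitivity the scenario grid is
built to expose.  Running all 16 scenarios makes the method sensitivity
visible within one draw: the trend-aware scenarios 2–4 give 88–89, the
trend-free Specific-Average (scenario 1) gives 34.7, and the CDR analogues
(scenarios 5–8) run ~4–8 per 100,000 higher, with the SDR−CDR contrast
resolved within iterations:

```
country  scenario  excess_rate  ci_low  ci_high
  SIM-A         1         34.7    14.6     54.0
  SIM-A         2         89.0    60.6    116.0
  ...
  SIM-A         8         95.3    62.0    124.3
```

The same pipeline is scriptable from the shell:

```
emsens simulate --out-dir study/
emsens grid --weekly study/panel_weekly.csv --monthly study/panel_monthly.csv \
            --iterations 1000 --seed 1 --out-dir study/results
emsens rank --results study/results/excess_by_scenario.csv --out-dir study/results
```

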