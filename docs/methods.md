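# Methods

## The estimation problem

Annual excess mortality for a target year t is the difference between the
observed all-cause mortality of that year and a counterfactual baseline —
the mortality expected had the crisis not occurred — expressed here as an
annual death rate per 100,000 person-years.  The baseline must be
estimated from pre-crisis data, and the estimate depends on four analysis
choices that this package treats as first-class parameters: the mortality
index, the baseline model, the reference period, and the time unit of the
death series.

## Data model

A `MortalityPanel` holds deaths and person-year exposures by (country,
year, period, age group) for one time unit.  Periods are ISO 8601 weeks
(1..52, or 1..53 in leap-week years such as 2015 and 2020) or civil months
(1..12).  Exposures spread annual person-years uniformly across the
periods of the year (annual/52, annual/53 or annual/12) under zero
migration, so the period exposures of a year always sum to the annual
exposure.  Deaths are real-valued: two harmonization steps rescale them.

* **Month-length adjustment.**  Monthly deaths are multiplied by
  (365.25/12)/actual-days — the three relevant constants are exactly
  366/12 = 30.50, 365/12 ≈ 30.42 and 365.25/12 ≈ 30.44 — and then all
  twelve months of a year are rescaled by a single factor so the annual
  total is unchanged.  The operation marks the panel and is a no-op on a
  second call: re-applying the day-length ratio to already-harmonized
  counts would distort them, so idempotence is enforced by flag rather
  than by recomputation.
* **Gold-standard calibration.**  All period deaths of a (country, year)
  are scaled so the panel's annual all-ages rate matches an external
  annual reference rate; unmatched years are left unchanged and flagged.
  This step matters more than it looks: an ISO week-year spans 364 or 371
  days while the panel's annual exposure is fixed, so uncalibrated weekly
  panels carry a year-length imprint of up to ~2 % of annual deaths
  (~1/53 for a 53-week target year), and civil leap days leave a ~0.3 %
  imprint on monthly panels.  Calibration to year-length-normalized
  annual rates removes both.  For synthetic studies the generator
  supplies the reference (see below); with real data the role is played
  by definitive annual rates from a vital-statistics source.

## Mortality indices

The crude death rate (CDR) is total deaths over total exposure per
period.  The age-standardized death rate (SDR) weights age-specific rates
with the 2013 European Standard Population, whose published 5-year bands
are shipped with the package and collapsed by summation to the broad
groups 0–14, 15–64, 65–74, 75–84, 85+ (weights 0.16, 0.645, 0.105, 0.065,
0.025).  Because only aggregate period deaths are assumed observable, age
detail is recovered by a deliberately simplified proportional split: each
period's total is allocated to age groups by that year's annual age
distribution of deaths.  The split preserves annual age totals exactly
and is exact whenever the within-year age mix of deaths is stable across
periods (for example, when seasonality and shocks act proportionally on
all ages); it is *not* the full weekly age-splitting methodology that
combines weekly totals with detailed annual data, and it will be biased
when age groups have genuinely different within-year death patterns.

## Baseline models

Four least-squares estimators of the expected rate y(t, i), fitted to the
observed rates a(h, i) over a reference period h = t−r..t−1 (three studied
periods: 2010–19, 2015–19, 2017–19):

1. **Specific-Average** — the per-period mean over reference years; no
   year term, so the prediction is independent of the target year.
2. **Specific-Average with Trend** — per-period intercepts plus one
   common linear year slope.  The pooled-slope reading distinguishes this
   model from Specific-Trend; with per-period slopes the two would
   coincide.
3. **Harmonic with Trend** — a Serfling-type cyclical regression pooled
   over all (h, i): intercept, linear year term, and sine/cosine pairs at
   the annual and semi-annual frequencies 2πi/n and 4πi/n.  The printed
   form of this model family sometimes omits the intercept; one is
   included here, since a no-intercept fit on strictly positive rates
   would be systematically biased and would break the residual-mean-zero
   property.  The second harmonic is read in the standard Serfling form
   sin(4πi/n).
4. **Specific-Trend** — an independent intercept + slope per period.

The year covariate is centered at the reference mean before fitting
(predictions are invariant; conditioning is not).  Weekly fits always use
weeks 1–52; when a 53-week target year is predicted, the week-53 baseline
copies week 52 — the reading adopted for the leap-week rule — which is
also the behaviour that keeps the annual expected-death budget consistent
with exposures of 1/53 of a person-year per week.  Negative predictions
are floored at zero and reported with a warning so extrapolation
pathologies stay visible.  Trend methods require at least two reference
years; residual variance uses the method's exact parameter count, and
coefficient standard errors are ordinary OLS errors (cross-checked
against an independent OLS implementation in the tests).

## Excess and Monte-Carlo intervals

Annual excess is Σ_i (a(t,i) − y(t,i))·e(t,i) / E(t) × 100,000 over the
observation window: all 52/53 weeks, weeks 1–52 for the
monthly-comparison scenarios, or all 12 months.  Confidence intervals are
percentile intervals from a parametric Monte-Carlo scheme: deaths in
every (year, period, age) cell are redrawn as Binomial(persons, observed
rate), with persons the period exposure converted to people at risk, and
the entire pipeline — rates, split, fit, prediction, excess — is re-run
per iteration (1,000 by default).  Both reference and target years are
resampled by default so baseline-estimation uncertainty propagates into
the interval; `resample="target"` restricts redrawing to the target year
and demonstrably narrows the interval.  The point estimate never depends
on the seed or the iteration count.  The whole iteration batch runs as
one vectorized pass through the same array code as the point estimate, so
there is no separate "fast path" to diverge from the definition.

## The scenario grid and comparisons

Sixteen scenarios: 1–8 cross {SDR, CDR} with the four methods at 2015–19
weekly; 9–12 vary the reference period (2010–19, 2017–19) for
Specific-Average with Trend in both indices; 13–16 compare weekly
(restricted to weeks 1–52) against monthly data under Harmonic with
Trend.  `run_grid` shares a single set of resampled panels per (country,
time unit) across scenarios and iterations, so scenario differences are
formed within iterations (common random numbers isolate the contrast, and
identical arms give an exactly degenerate interval).  Rankings (rank 1 =
highest excess) are compared with Spearman's correlation using
average-rank ties; scenarios 13–16 are excluded from the default ranking
analysis because their observation window omits week 53.  Rankings use
point estimates only, not interval overlap.

## The synthetic generator

Deaths are simulated at daily resolution and the same draw is aggregated
into ISO weeks and civil months, so weekly/monthly comparisons rest on
identical underlying deaths.  Per country, age group and day, deaths are
Binomial(population, rate/365.25) with

rate(age, day) = base(age) · (1 + trend(age) + country offset)^(year − y0)
· seasonality(doy) · [shock] · [epidemic],

seasonality being 1 + a₁cos(2π·doy/365.25) + a₂cos(4π·doy/365.25)
truncated below at 0.05.  The canonical study conditions approximate a
one-million-person European population: broad-age base rates 0.0003 /
0.002 / 0.015 / 0.05 / 0.15 deaths per person-year (all-ages CDR ≈ 1,100
per 100,000), annual declines of 2.0 / 1.5 / 1.2 / 0.8 / 0.5 % (faster at
young ages), winter-peaked seasonal amplitudes rising with age from
(0.05, 0.01) to (0.15, 0.04), an epidemic season (+10 % in the first
quarter of 2015, mimicking a severe influenza year inside the 2015–19
reference), and a pandemic shock of +30 % in ISO weeks 10–20 of 2020.  A
second country runs 15 % higher mortality with a slightly slower decline.
Randomness derives from one global seed with an independent substream per
country (`SeedSequence([seed, crc32(country)])`), so any country
reproduces in isolation and independently of the country list.

`GroundTruth` records the noiseless surface, the drawn daily deaths, the
implied noiseless annual CDR/SDR, the true shock-attributable excess per
index (exactly zero without a shock), and `gold_standard_rates`: the
draw's own calendar-year deaths divided by year-length-normalized
person-years (population × days/365.25).  These play the role of the
definitive annual source for calibration; they are computed from the
*drawn* deaths, not the noiseless surface, so calibration preserves the
sampling variation that the Monte-Carlo interval must capture —
calibrating to noiseless truth would collapse the variance of
trend-method excess to zero.

What the generator does *not* emulate: migration, demographic change
within the simulated span, age-dependent within-year death patterns
beyond amplitude scaling, reporting delays or preliminary-data revisions,
and sub-national heterogeneity.  Passing tests therefore demonstrate the
pipeline's internal consistency and statistical calibration under the
stated stochastic model, not robustness to those real-data features.

## Validation experiments and problem sizes

* **Coverage** (`emsens.validation.coverage_study`, also the acceptance
  script): 200 replicates of a one-country 2015–2020 study with the 2020
  shock and no epidemic year (the generator must be correctly specified
  for the fitted scenario), each run through the default scenario (SDR,
  Specific-Average with Trend, 2015–19, weekly) with 1,000 iterations;
  the empirical coverage of the 95 % interval is compared with the
  nominal level within three binomial standard errors (±4.6 points).
  About a minute on one CPU.
* **Null behaviour**: 200 replicates with no shock, no trend and no
  seasonality; the mean excess of each of the 16 scenarios across
  replicates lies within three standard errors of zero.
* **Estimator agreement**: on the same null replicates at r = 10, the
  mean annualized prediction difference between Specific-Average and each
  trend-aware method is within three standard errors of zero.
* **Exact identities** (machine precision on noiseless or hand-built
  input): Specific-Average = per-period mean; Specific-Trend = per-period
  closed-form OLS; Spearman = the Σd² formula on tie-free data; SDR = CDR
  when the panel's age composition equals the standard population;
  weekly = monthly excess for the average-based methods once both panels
  are calibrated to common annual rates and no year in the window has 53
  ISO weeks (the tests use a 2017–19 reference with a 52-week target
  year — a 53-week target breaks the algebra through the week-53 copy);
  and on noiseless declining rates the Specific-Average excess is
  strictly the lowest of the four methods.

## Numerical choices and known limitations

* Rates are stored as deaths per person-year; the ×100,000 scaling is
  applied only at reporting, avoiding unit mistakes inside fits.
* Binomial trials are exposures rounded to whole persons; probabilities
  are observed rates; a rate above 1 per person-period is rejected.
* Percentile (not normal-approximation) intervals; bounds are monotone in
  the nominal level by construction, and the percentile construction may
  exclude the point estimate under skew — only lower ≤ upper is
  guaranteed.
* The proportional age split understates SDR uncertainty slightly when
  age mixes genuinely vary within the year.
* The generator's multiplicative annual trend is geometric while the
  trend models are linear in the year; over the reference lengths used
  the curvature contributes well under one death per 100,000 and is
  ignored.
* Scenario estimates on uncalibrated panels remain available but carry
  the ISO/civil year-length imprint described above; cross-time-unit
  comparisons should always calibrate first.
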