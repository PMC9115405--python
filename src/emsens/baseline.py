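"""Baseline (expected) mortality models.

Four estimators of the expected death rate y(t, i) for target year t and
week/month i, fitted by unweighted least squares to the observed rates
a(h, i) of a pre-pandemic reference period h = t-r, ..., t-1:

``specific_average``
    y(t, i) = mean over reference years of a(h, i) — a per-period mean
    with no year term.
``specific_average_trend``
    per-period intercepts plus one common linear year slope beta shared by
    all periods.
``harmonic_trend``
    a Serfling-type cyclical regression pooled over all (h, i): intercept,
    linear year term, and first and second within-year harmonics
    sin(2*pi*i/n), cos(2*pi*i/n), sin(4*pi*i/n), cos(4*pi*i/n).
``specific_trend``
    an independent intercept + linear year slope per period i.

The year covariate is centered at the reference-period mean year before
fitting (predictions are invariant to the centering; conditioning is not).
Weekly fits always use weeks 1-52; a week-53 prediction, when the target
year has 53 ISO weeks, copies the week-52 value.  Negative predictions are
floored at zero with a warning, so extrapolation pathologies stay visible.

The plain-array routines (:func:`fit_coefficients`, :func:`predict_matrix`)
carry an optional trailing batch axis and are reused unchanged by the
Monte-Carlo resampling in :mod:`emsens.excess`, so the point estimate and
every resampled replicate go through identical code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ConfigurationError
from .rates import RateSeries
from .timeunits import iso_weeks_in_year

__all__ = [
    "METHODS",
    "ReferencePeriod",
    "BaselineMortalityModel",
    "BaselineResults",
]

METHODS = (
    "specific_average",
    "specific_average_trend",
    "harmonic_trend",
    "specific_trend",
)

_MIN_YEARS = {
    "specific_average": 1,
    "specific_average_trend": 2,
    "harmonic_trend": 2,
    "specific_trend": 2,
}


@dataclass(frozen=True)
class ReferencePeriod:
    """Inclusive span of pre-target years used to fit the baseline."""

    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError("reference period is empty")

    @property
    def r(self) -> int:
        """Length of the reference period in years."""
        return self.last_year - self.first_year + 1

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    def __str__(self) -> str:
        return f"{self.first_year}-{self.last_year}"

    @classmethod
    def parse(cls, text: str) -> "ReferencePeriod":
        a, b = str(text).replace("–", "-").split("-")
        return cls(int(a), int(b))


# ---------------------------------------------------------------------------
# array core (optionally batched along a trailing axis)
# ---------------------------------------------------------------------------


def _harmonic_design(years_c: np.ndarray, periods: np.ndarray, n: int) -> np.ndarray:
    """Design matrix rows ordered as the flattened (year, period) grid."""
    H, P = len(years_c), len(periods)
    hh = np.repeat(years_c, P)
    ii = np.tile(periods.astype(float), H)
    w = 2.0 * np.pi * ii / n
    return np.column_stack(
        [np.ones(H * P), hh, np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)]
    )


def fit_coefficients(
    A: np.ndarray, years: np.ndarray, method: str, periods: np.ndarray, n: int
) -> dict[str, np.ndarray]:
    """Least-squares coefficients for one method.

    ``A`` has shape (H, P) or (H, P, B); returned arrays carry the same
    optional batch axis.  Keys: ``mu`` per-period intercepts (at the
    centered-year origin), ``beta`` common slope, ``beta_i`` per-period
    slopes, ``harmonic`` the six pooled coefficients.
    """
    years = np.asarray(years, dtype=float)
    ybar = years.mean()
    c = years - ybar  # centered year covariate
    coefs: dict[str, np.ndarray] = {"ybar": np.array(ybar)}

    if method == "specific_average":
        coefs["mu"] = A.mean(axis=0)
    elif method == "specific_average_trend":
        mu = A.mean(axis=0)
        sxx = float((c**2).sum())
        # common slope of OLS with per-period intercepts
        num = np.tensordot(c, A, axes=(0, 0)).sum(axis=0)
        coefs["mu"] = mu
        coefs["beta"] = num / (A.shape[1] * sxx)
    elif method == "specific_trend":
        sxx = float((c**2).sum())
        coefs["mu"] = A.mean(axis=0)
        coefs["beta_i"] = np.tensordot(c, A, axes=(0, 0)) / sxx
    elif method == "harmonic_trend":
        X = _harmonic_design(c, periods, n)
        Y = A.reshape(A.shape[0] * A.shape[1], -1)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        coefs["harmonic"] = beta if A.ndim == 3 else beta[:, 0]
        coefs["_design"] = X
    else:
        raise ValueError(f"unknown method {method!r}")
    return coefs


def predict_matrix(
    coefs: dict[str, np.ndarray],
    method: str,
    target_year: int,
    periods: np.ndarray,
    n: int,
    floor: bool = True,
) -> np.ndarray:
    """Expected rates for the fitted periods at ``target_year``.

    Shape (P,) or (P, B), matching the batch axis of the fit.
    """
    dt = float(target_year) - float(coefs["ybar"])
    if method == "specific_average":
        pred = np.array(coefs["mu"], copy=True)
    elif method == "specific_average_trend":
        pred = coefs["mu"] + coefs["beta"] * dt
    elif method == "specific_trend":
        pred = coefs["mu"] + coefs["beta_i"] * dt
    elif method == "harmonic_trend":
        w = 2.0 * np.pi * periods.astype(float) / n
        Xt = np.column_stack(
            [
                np.ones(len(periods)),
                np.full(len(periods), dt),
                np.sin(w),
                np.cos(w),
                np.sin(2 * w),
                np.cos(2 * w),
            ]
        )
        beta = coefs["harmonic"]
        pred = Xt @ (beta if beta.ndim == 2 else beta[:, None])
        if beta.ndim == 1:
            pred = pred[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")
    if floor and np.any(pred < 0):
        warnings.warn(
            "negative expected rates floored at 0; the trend extrapolation "
            "leaves the admissible range"
        )
        pred = np.maximum(pred, 0.0)
    return pred


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class BaselineMortalityModel:
    """Expected-mortality model for one rate series and reference period.

    Parameters
    ----------
    rates
        Observed per-period rates (one country, one index, one time unit).
    method
        One of :data:`METHODS`.
    reference
        The reference period; trend methods need at least two years.
    """

    def __init__(
        self,
        rates: RateSeries,
        method: str,
        reference: ReferencePeriod,
    ) -> None:
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        if reference.r < _MIN_YEARS[method]:
            raise ConfigurationError(
                f"{method} needs at least {_MIN_YEARS[method]} reference years, "
                f"got {reference.r}"
            )
        self.rates = rates
        self.method = method
        self.reference = reference
        self.n_periods = 52 if rates.time_unit == "week" else 12
        self.periods = np.arange(1, self.n_periods + 1)
        # weekly fits use weeks 1-52 regardless of leap weeks
        self.endog = rates.matrix(reference.years, list(self.periods))

    def fit(self) -> "BaselineResults":
        years = np.asarray(self.reference.years, dtype=float)
        coefs = fit_coefficients(
            self.endog, years, self.method, self.periods, self.n_periods
        )
        # in-sample fitted surface: evaluate at each reference year
        fitted_surface = np.vstack(
            [
                predict_matrix(
                    coefs, self.method, y, self.periods, self.n_periods, floor=False
                )
                for y in years
            ]
        )
        resid = self.endog - fitted_surface
        return BaselineResults(self, coefs, resid)


@dataclass
class BaselineResults:
    """Fitted baseline: coefficients, uncertainties and predictions."""

    model: BaselineMortalityModel
    coefs: dict[str, np.ndarray]
    resid: np.ndarray  # (r, n) residual surface
    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.params, self.bse = self._params_and_bse()

    # -- inference ----------------------------------------------------------

    @property
    def df_resid(self) -> int:
        r, n = self.resid.shape
        k = {
            "specific_average": n,
            "specific_average_trend": n + 1,
            "harmonic_trend": 6,
            "specific_trend": 2 * n,
        }[self.model.method]
        return r * n - k

    @property
    def scale(self) -> float:
        """Residual variance estimate (rate units squared)."""
        dof = max(self.df_resid, 1)
        return float((self.resid**2).sum() / dof)

    def _params_and_bse(self) -> tuple[pd.Series, pd.Series]:
        m = self.model
        years = np.asarray(m.reference.years, dtype=float)
        c = years - years.mean()
        sxx = float((c**2).sum())
        r = len(years)
        method = m.method
        if method == "harmonic_trend":
            names = ["const", "trend", "sin1", "cos1", "sin2", "cos2"]
            params = pd.Series(self.coefs["harmonic"], index=names)
            X = self.coefs["_design"]
            cov = self.scale * np.linalg.inv(X.T @ X)
            bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
            return params, bse
        labels = [f"mu_{p:02d}" for p in m.periods]
        mu = pd.Series(self.coefs["mu"], index=labels)
        sd = np.sqrt(self.scale)
        if method == "specific_average":
            return mu, pd.Series(sd / np.sqrt(r), index=labels)
        if method == "specific_average_trend":
            params = pd.concat([mu, pd.Series({"trend": float(self.coefs["beta"])})])
            bse = pd.concat(
                [
                    pd.Series(sd / np.sqrt(r), index=labels),
                    pd.Series({"trend": sd / np.sqrt(m.n_periods * sxx)}),
                ]
            )
            return params, bse
        # specific_trend
        beta = pd.Series(
            self.coefs["beta_i"], index=[f"beta_{p:02d}" for p in m.periods]
        )
        params = pd.concat([mu, beta])
        bse = pd.concat(
            [
                pd.Series(sd / np.sqrt(r), index=labels),
                pd.Series(sd / np.sqrt(sxx), index=beta.index),
            ]
        )
        return params, bse

    # -- prediction ---------------------------------------------------------

    def predict(
        self, target_year: int, periods: list[int] | None = None
    ) -> pd.Series:
        """Expected rates y(target_year, i) for the requested periods.

        Weekly models predict weeks 1-52 from the fit; a requested week 53
        copies week 52 and is only legal when the target ISO year actually
        has 53 weeks.
        """
        m = self.model
        if target_year <= m.reference.last_year:
            raise ValueError("target year must follow the reference period")
        if periods is None:
            periods = list(m.periods)
        base = predict_matrix(
            self.coefs, m.method, target_year, m.periods, m.n_periods
        )
        series = pd.Series(base, index=m.periods)
        out = {}
        for p in periods:
            if p == 53 and m.rates.time_unit == "week":
                if iso_weeks_in_year(target_year) != 53:
                    raise ConfigurationError(
                        f"week 53 requested but ISO year {target_year} has 52 weeks"
                    )
                out[p] = series[52]
            else:
                out[p] = series[p]
        return pd.Series(out, name="expected_rate")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Baseline mortality model",
            f"  method:           {m.method}",
            f"  index / unit:     {m.rates.index_kind} / {m.rates.time_unit}",
            f"  country:          {m.rates.country}",
            f"  reference period: {m.reference} (r={m.reference.r})",
            f"  periods per year: {m.n_periods}",
            f"  residual scale:   {np.sqrt(self.scale):.6g} (rate units)",
        ]
        show = self.params if len(self.params) <= 8 else self.params.tail(4)
        lines.append("  coefficients" + (" (tail):" if len(self.params) > 8 else ":"))
        for k, v in show.items():
            lines.append(f"    {k:<10} {v:>12.6g}  (se {self.bse[k]:.3g})")
        return "\n".join(lines)
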