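"""Daily surgical-volume forecasting with seasonal ARIMA.

Order identification follows the classical correlogram workflow: the sample
ACF/PACF of the daily count series show a period-7 cycle; after one seasonal
difference at lag 7 a single significant ACF spike at lag 7 indicates a
seasonal MA(1) term, and the remaining week-to-week spikes line up with
hospital holidays, which therefore enter as a 0/1 exogenous regressor.  The
working model is SARIMAX (0,0,0)(0,1,1)7 + holidays, estimated by state-space
maximum likelihood, and evaluated with rolling one-week-ahead forecasts from
an expanding window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import acf as _acf, pacf as _pacf

from .calendars import Calendar, generate_calendar
from .config import SarimaxSpec
from .series import DailySeries

__all__ = [
    "build_daily_counts",
    "CorrelogramReport",
    "correlogram",
    "seasonal_difference",
    "FitFailureError",
    "SarimaxModel",
    "fit_sarimax",
    "forecast",
    "RollingForecastResult",
    "rolling_forecast",
]


def build_daily_counts(encounters: pd.DataFrame, calendar: Calendar) -> DailySeries:
    """Number of cases per day; days without cases count 0."""
    day = encounters["day_index"].to_numpy(dtype=int)
    if len(day) and (day.min() < 0 or day.max() >= calendar.n_days):
        raise ValueError("encounter day_index outside calendar")
    counts = np.bincount(day, minlength=calendar.n_days).astype(float)
    return DailySeries(calendar=calendar, values=counts, name="daily_counts")


@dataclass(frozen=True)
class CorrelogramReport:
    """Sample ACF/PACF with the white-noise 95% band ±1.96/√n."""

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    band: float
    acf_significant: np.ndarray  # excludes lag 0
    pacf_significant: np.ndarray
    degenerate: bool = False


def correlogram(series: DailySeries, max_lag: int) -> CorrelogramReport:
    values = series.values
    n = len(values)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    band = 1.96 / np.sqrt(n)
    lags = np.arange(max_lag + 1)
    if np.ptp(values) == 0:
        nan = np.full(max_lag + 1, np.nan)
        return CorrelogramReport(
            lags=lags, acf=nan, pacf=nan, band=band,
            acf_significant=np.zeros(max_lag, dtype=bool),
            pacf_significant=np.zeros(max_lag, dtype=bool),
            degenerate=True,
        )
    acf_vals = _acf(values, nlags=max_lag, fft=True)
    pacf_vals = _pacf(values, nlags=max_lag, method="ywm")
    return CorrelogramReport(
        lags=lags,
        acf=acf_vals,
        pacf=pacf_vals,
        band=band,
        acf_significant=np.abs(acf_vals[1:]) > band,
        pacf_significant=np.abs(pacf_vals[1:]) > band,
    )


def seasonal_difference(series: DailySeries, period: int = 7, order: int = 1) -> DailySeries:
    """Lag-``period`` difference, applied ``order`` times; leading days dropped."""
    values = series.values
    if len(values) <= period * order:
        raise ValueError("series too short for the requested seasonal difference")
    for _ in range(order):
        values = values[period:] - values[:-period]
    offset = period * order
    cal = series.calendar
    holidays = frozenset(h - offset for h in cal.holidays if h >= offset)
    new_cal = generate_calendar(cal.n_days - offset, cal.weekday_of(offset), holidays)
    return DailySeries(calendar=new_cal, values=values, name=f"{series.name}_sdiff{period}x{order}")


class FitFailureError(RuntimeError):
    """Maximum-likelihood estimation failed to converge or produced an invalid fit."""


def _quiet_fit(model):
    """MLE fit with statsmodels' warning chatter suppressed.

    Convergence is checked explicitly afterwards (:func:`_check_converged`),
    so the warnings would only duplicate what becomes a hard error or an
    accepted near-converged fit.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(disp=False)


@dataclass
class SarimaxModel:
    """A fitted seasonal ARIMA (with optional exogenous regressors)."""

    spec: SarimaxSpec
    results: object  # statsmodels SARIMAXResults
    n_obs: int

    @property
    def params(self) -> pd.Series:
        return self.results.params

    def exog_coefficients(self) -> dict[str, float]:
        return {name: float(self.results.params[i]) for i, name in enumerate(self.spec.exog_names)}

    def residual_correlogram(self, max_lag: int = 28) -> CorrelogramReport:
        resid = np.asarray(self.results.resid)
        # the first seasonal cycle of residuals is dominated by differencing start-up
        start = self.spec.m * self.spec.D + self.spec.d
        resid = resid[start:]
        cal = generate_calendar(len(resid), 0, frozenset())
        return correlogram(DailySeries(cal, resid, "resid"), max_lag)


def _check_converged(results, allow_nonconverged: bool) -> None:
    retvals = getattr(results, "mle_retvals", None) or {}
    converged = bool(retvals.get("converged", True))
    if not np.isfinite(results.llf):
        raise FitFailureError(f"non-finite log-likelihood (llf={results.llf})")
    if not converged and not allow_nonconverged:
        raise FitFailureError(f"MLE did not converge: {retvals}")


def _stack_exog(exog: Sequence[DailySeries] | None) -> np.ndarray | None:
    if not exog:
        return None
    return np.column_stack([e.values for e in exog])


def fit_sarimax(
    series: DailySeries,
    spec: SarimaxSpec,
    exog: Sequence[DailySeries] | None = None,
    allow_nonconverged: bool = False,
) -> SarimaxModel:
    """Maximum-likelihood SARIMAX fit of a daily series.

    Raises :class:`FitFailureError` on non-convergence or an invalid
    likelihood rather than silently returning a bad fit.
    """
    exog_mat = _stack_exog(exog)
    if exog_mat is not None and len(exog_mat) != len(series):
        raise ValueError("exogenous series not aligned with the endogenous series")
    model = SARIMAX(
        series.values,
        exog=exog_mat,
        order=spec.order,
        seasonal_order=spec.seasonal_order,
        trend=spec.trend,
    )
    try:
        results = _quiet_fit(model)
    except Exception as err:  # statsmodels raises LinAlgError and friends
        raise FitFailureError(f"SARIMAX fit failed: {err}") from err
    _check_converged(results, allow_nonconverged)
    return SarimaxModel(spec=spec, results=results, n_obs=len(series))


def forecast(model: SarimaxModel, horizon: int, future_exog: np.ndarray | None = None) -> np.ndarray:
    """Point (mean) forecasts for the ``horizon`` days after the fit window."""
    if model.spec.exog_names or (future_exog is not None and future_exog.size):
        if future_exog is None or len(future_exog) != horizon:
            raise ValueError("future_exog must cover every forecast day")
    pred = model.results.get_forecast(steps=horizon, exog=future_exog).predicted_mean
    out = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(out)):
        raise FitFailureError("non-finite forecast values")
    return out


@dataclass
class RollingForecastResult:
    """Concatenated out-of-sample forecasts from expanding-window origins."""

    records: pd.DataFrame  # origin, target_day, forecast, actual, error
    rmse: float
    failed_origins: list[int] = field(default_factory=list)

    @property
    def n_forecasts(self) -> int:
        return len(self.records)


def rolling_forecast(
    series: DailySeries,
    spec: SarimaxSpec,
    exog: Sequence[DailySeries] | None = None,
    origin_start: int = 224,
    step: int = 7,
    horizon: int = 7,
    refit: bool = True,
) -> RollingForecastResult:
    """Rolling multi-day-ahead forecasts from expanding origins.

    At each origin ``t`` the model is (re)fitted on days ``0..t`` and days
    ``t+1..t+horizon`` are forecast using known future exogenous values
    (holidays are calendar-known in advance).  With ``refit=False`` the
    parameters estimated at the first origin are kept and later origins only
    update the state filter, which is much faster and usually nearly
    identical.
    """
    n = len(series)
    if not 0 < origin_start < n - 1:
        raise ValueError("origin_start must leave room for at least one forecast day")
    exog_mat = _stack_exog(exog)

    rows = []
    failed: list[int] = []
    results = None
    prev_end = None  # last day index included in `results`
    for origin in range(origin_start, n - 1, step):
        endog = series.values[: origin + 1]
        ex = exog_mat[: origin + 1] if exog_mat is not None else None
        try:
            if refit or results is None:
                model = SARIMAX(endog, exog=ex, order=spec.order, seasonal_order=spec.seasonal_order, trend=spec.trend)
                results = _quiet_fit(model)
                # near-converged fits are accepted; a non-finite likelihood or
                # forecast still fails the origin
                _check_converged(results, allow_nonconverged=True)
            else:
                new = series.values[prev_end + 1 : origin + 1]
                new_ex = exog_mat[prev_end + 1 : origin + 1] if exog_mat is not None else None
                results = results.append(new, exog=new_ex, refit=False)
            prev_end = origin
            h = min(horizon, n - 1 - origin)
            fex = exog_mat[origin + 1 : origin + 1 + h] if exog_mat is not None else None
            pred = np.asarray(results.get_forecast(steps=h, exog=fex).predicted_mean, dtype=float)
            if not np.all(np.isfinite(pred)):
                raise FitFailureError("non-finite forecast")
        except (FitFailureError, Exception) as err:
            if not isinstance(err, (FitFailureError, np.linalg.LinAlgError, ValueError)):
                raise
            failed.append(origin)
            results = None
            prev_end = None
            continue
        target_days = np.arange(origin + 1, origin + 1 + h)
        actual = series.values[target_days]
        for td, f, a in zip(target_days, pred, actual):
            rows.append({"origin": origin, "target_day": int(td), "forecast": float(f), "actual": float(a), "error": float(f - a)})

    records = pd.DataFrame(rows, columns=["origin", "target_day", "forecast", "actual", "error"])
    rmse = float(np.sqrt(np.mean(records["error"] ** 2))) if len(records) else float("nan")
    return RollingForecastResult(records=records, rmse=rmse, failed_origins=failed)
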