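"""Inpatient surgical bed-census construction and forecasting.

Census convention: a case with surgery day ``d`` and LOS ``l`` nights occupies
one bed on nights ``d, d+1, ..., d+l-1``; ``l = 0`` (same-day discharge)
occupies none; stays running past the calendar are truncated at the last day.
This makes total occupied bed-nights exactly equal the sum of truncated LOS —
a conservation identity asserted throughout.

Forecasting protocols (per forecast target day ``T``):

* ``long_term`` — one static multi-step forecast of the whole evaluation
  window from the end of the fitting window (">2 weeks" of lead time).
* ``two_week``  — rolling daily origins; day ``T`` forecast using data
  through ``T - 14``.
* ``same_day``  — rolling daily origins; day ``T`` forecast using data
  through ``T - 1`` plus day-``T`` schedule information (the case list and
  its predicted LOS are known before the operating-room day starts).

Exogenous values dated after an origin's information cutoff are never taken
from the observed future: they are either calendar-known (holidays),
schedule-known (same-day only), or fed forward from the volume/LOS
forecasters.  A cutoff audit records the provenance of every exogenous value
consumed by a forecast and can be verified after any run; a feature with no
forecaster whose future value would be needed raises :class:`LeakageError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tsa.api import VAR

from .calendars import Calendar
from .config import SarimaxSpec, SplitSpec
from .los import HistoricMeanLOS
from .series import DailySeries
from .volume import FitFailureError, build_daily_counts, _check_converged, _quiet_fit

__all__ = [
    "build_census",
    "census_variants",
    "ExogFeature",
    "LeakageError",
    "CutoffAudit",
    "VolumeForecaster",
    "CensusFeedForward",
    "ForecastEvaluation",
    "run_model",
    "run_model_grid",
    "relative_error_report",
    "observed_census_canary",
]

Protocol = Literal["long_term", "two_week", "same_day"]


# ---------------------------------------------------------------------------
# census arrays


def build_census(
    encounters: pd.DataFrame,
    calendar: Calendar,
    los: np.ndarray | None = None,
    aggregation: Literal["round", "expected"] = "round",
) -> DailySeries:
    """Nightly bed census implied by per-case LOS.

    ``los`` overrides the observed ``los_days`` column (e.g. with forest
    predictions).  With ``aggregation="round"`` fractional LOS is rounded
    half-up per case before aggregation (occupancy is a head count); with
    ``"expected"`` a case with fractional LOS ``f + r`` contributes a full bed
    on its first ``f`` nights and ``r`` of a bed on the next, so the array is
    the expected head count and per-case quantization artifacts are avoided.
    Conservation holds exactly under both: the array sums to the total
    (truncated) occupied bed-nights implied by the per-case LOS.
    """
    if los is None:
        los = encounters["los_days"].to_numpy(dtype=float)
    los = np.asarray(los, dtype=float)
    if len(los) != len(encounters):
        raise ValueError("LOS source must cover every case")
    if not np.all(np.isfinite(los)):
        raise ValueError("LOS source contains missing values; impute before building a census")
    if np.any(los < 0):
        raise ValueError("negative LOS")
    day = encounters["day_index"].to_numpy(dtype=np.int64)
    n = calendar.n_days
    if aggregation == "round":
        nights = np.floor(los + 0.5).astype(np.int64)
        end = np.minimum(day + nights, n)  # truncate at the calendar edge
        delta = np.zeros(n + 1, dtype=np.int64)
        occupied = nights > 0
        np.add.at(delta, day[occupied], 1)
        np.add.at(delta, end[occupied], -1)
        values = np.cumsum(delta[:-1]).astype(float)
    elif aggregation == "expected":
        full = np.floor(los).astype(np.int64)
        frac = los - full
        end = np.minimum(day + full, n)
        delta = np.zeros(n + 1, dtype=float)
        occupied = full > 0
        np.add.at(delta, day[occupied], 1.0)
        np.add.at(delta, end[occupied], -1.0)
        partial = (frac > 0) & (day + full < n)
        np.add.at(delta, (day + full)[partial], frac[partial])
        np.add.at(delta, (day + full)[partial] + 1, -frac[partial])
        values = np.cumsum(delta[:-1])
    else:
        raise ValueError(f"unknown aggregation: {aggregation}")
    return DailySeries(calendar=calendar, values=values, name="census")


def census_variants(
    encounters: pd.DataFrame,
    calendar: Calendar,
    predicted_los: np.ndarray,
    type_mean_los: HistoricMeanLOS,
    aggregation: Literal["round", "expected"] = "expected",
) -> dict[str, DailySeries]:
    """The five census arrays used across the model grid.

    observed  — realized LOS per case (the forecast target).
    predicted — forest-predicted LOS per case.
    adjusted  — predicted LOS overridden to 0 for planned same-day discharges.
    perfect   — oracle: actual LOS (identical to observed by construction).
    surgery_mean — per-type mean LOS from the fitting window.

    The observed (and perfect) arrays are integer head counts; the
    model-derived arrays default to expected-count aggregation because their
    per-case LOS sources are conditional means, which per-case rounding would
    quantize into type-level threshold artifacts.
    """
    observed = build_census(encounters, calendar)
    adjusted_los = np.where(encounters["planned_same_day_discharge"].to_numpy(bool), 0.0, predicted_los)
    return {
        "observed": observed,
        "predicted": build_census(encounters, calendar, predicted_los, aggregation),
        "adjusted": build_census(encounters, calendar, adjusted_los, aggregation),
        "perfect": build_census(encounters, calendar),
        "surgery_mean": build_census(
            encounters, calendar, type_mean_los.lookup(encounters["surgery_type"]), aggregation
        ),
    }


# ---------------------------------------------------------------------------
# exogenous features, cutoff audit


class LeakageError(RuntimeError):
    """A forecast would consume a value dated after its information cutoff."""


@dataclass
class ExogFeature:
    """A named exogenous series with provenance semantics.

    kind:
      ``calendar`` — known arbitrarily far ahead (holidays).
      ``schedule`` — value for day d derivable from the surgical schedule on
      the morning of day d (e.g. predicted census); usable as an actual value
      only for past days or for the target day of a same-day forecast.
      ``observed`` — value for day d recorded at day ``d - known_lag``.

    ``forecaster(cutoff, days) -> values`` supplies feed-forward estimates for
    days whose actual value is unavailable at the cutoff; without one, needing
    such a value raises :class:`LeakageError`.
    """

    name: str
    values: np.ndarray
    kind: Literal["calendar", "schedule", "observed"]
    known_lag: int = 0
    forecaster: Callable[[int, np.ndarray], np.ndarray] | None = None


@dataclass
class CutoffAudit:
    """Provenance record of every exogenous value consumed by forecasts."""

    entries: list[dict] = field(default_factory=list)

    def record(self, target_day: int, cutoff: int, protocol: str, feature: ExogFeature, day: int, status: str) -> None:
        self.entries.append(
            {
                "target_day": int(target_day),
                "cutoff": int(cutoff),
                "protocol": protocol,
                "feature": feature.name,
                "kind": feature.kind,
                "known_lag": feature.known_lag,
                "day": int(day),
                "status": status,
            }
        )

    def verify(self) -> dict[str, int]:
        """Re-derive the legality of every consumed value; raise on violation."""
        counts = {"calendar_known": 0, "schedule_known": 0, "observed_past": 0, "forecast_fed": 0}
        for e in self.entries:
            status, day, cutoff = e["status"], e["day"], e["cutoff"]
            if status == "calendar_known":
                ok = e["kind"] == "calendar"
            elif status == "schedule_known":
                ok = e["kind"] == "schedule" and e["protocol"] == "same_day" and day == e["target_day"]
            elif status == "observed_past":
                ok = day - e["known_lag"] <= cutoff
            elif status == "forecast_fed":
                ok = True
            else:
                ok = False
            if not ok:
                raise LeakageError(f"audit violation: {e}")
            counts[status] += 1
        return counts


def _exog_for_days(
    features: Sequence[ExogFeature],
    cutoff: int,
    days: np.ndarray,
    protocol: str,
    target_day: int,
    audit: CutoffAudit,
) -> np.ndarray | None:
    """Exogenous matrix for forecast days, feeding forward where required."""
    if not features:
        return None
    cols = []
    for feat in features:
        col = np.empty(len(days), dtype=float)
        needs_forecast = []
        for i, d in enumerate(days):
            d = int(d)
            if feat.kind == "calendar":
                col[i] = feat.values[d]
                audit.record(target_day, cutoff, protocol, feat, d, "calendar_known")
            elif feat.kind == "schedule" and (d <= cutoff or (protocol == "same_day" and d == target_day)):
                col[i] = feat.values[d]
                status = "observed_past" if d <= cutoff else "schedule_known"
                audit.record(target_day, cutoff, protocol, feat, d, status)
            elif feat.kind == "observed" and d - feat.known_lag <= cutoff:
                col[i] = feat.values[d]
                audit.record(target_day, cutoff, protocol, feat, d, "observed_past")
            else:
                needs_forecast.append(i)
        if needs_forecast:
            if feat.forecaster is None:
                bad_day = int(days[needs_forecast[0]])
                raise LeakageError(
                    f"feature '{feat.name}' needed for day {bad_day} but only available after cutoff {cutoff}"
                )
            fdays = days[needs_forecast]
            fed = feat.forecaster(cutoff, np.asarray(fdays, dtype=int))
            for i, d in zip(needs_forecast, fdays):
                audit.record(target_day, cutoff, protocol, feat, int(d), "forecast_fed")
            col[needs_forecast] = fed
        cols.append(col)
    return np.column_stack(cols)


def _exog_history(features: Sequence[ExogFeature], end: int) -> np.ndarray | None:
    """Actual exogenous values for fitting days ``0 .. end`` (all in the past)."""
    if not features:
        return None
    return np.column_stack([f.values[: end + 1] for f in features])


def observed_census_canary(census: DailySeries) -> ExogFeature:
    """A deliberately illegal regressor: the observed census itself.

    Planted in tests to prove the cutoff audit blocks direct target leakage.
    """
    return ExogFeature(name="observed_census", values=census.values, kind="observed", forecaster=None)


# ---------------------------------------------------------------------------
# feed-forward forecasters for exogenous series


class VolumeForecaster:
    """Expanding-window surgical-count forecaster used to feed future exog.

    Fits once at the first requested cutoff and filter-updates (``append``)
    as the cutoff advances; forecasts are cached per cutoff.
    """

    def __init__(
        self,
        counts: DailySeries,
        holidays: np.ndarray,
        spec: SarimaxSpec | None = None,
    ) -> None:
        self.counts = counts.values
        self.holidays = np.asarray(holidays, dtype=float).reshape(-1, 1)
        self.spec = spec or SarimaxSpec(P=0, D=1, Q=1, m=7, exog_names=("holidays",))
        self._results = None
        self._fitted_end: int | None = None
        self._cache: dict[int, np.ndarray] = {}  # cutoff -> forecasts for cutoff+1..

    def _ensure_fitted(self, cutoff: int) -> None:
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        if self._results is None or (self._fitted_end is not None and cutoff < self._fitted_end):
            model = SARIMAX(
                self.counts[: cutoff + 1],
                exog=self.holidays[: cutoff + 1],
                order=self.spec.order,
                seasonal_order=self.spec.seasonal_order,
            )
            self._results = _quiet_fit(model)
            _check_converged(self._results, allow_nonconverged=True)
            self._fitted_end = cutoff
        elif cutoff > self._fitted_end:
            new = self.counts[self._fitted_end + 1 : cutoff + 1]
            new_ex = self.holidays[self._fitted_end + 1 : cutoff + 1]
            self._results = self._results.append(new, exog=new_ex, refit=False)
            self._fitted_end = cutoff

    def forecast(self, cutoff: int, days: np.ndarray) -> np.ndarray:
        days = np.asarray(days, dtype=int)
        if days.min() <= cutoff:
            raise ValueError("volume forecaster only supplies post-cutoff days")
        steps = int(days.max()) - cutoff
        if cutoff not in self._cache or len(self._cache[cutoff]) < steps:
            self._ensure_fitted(cutoff)
            fex = self.holidays[cutoff + 1 : cutoff + 1 + steps]
            pred = np.asarray(self._results.get_forecast(steps=steps, exog=fex).predicted_mean)
            self._cache[cutoff] = np.clip(pred, 0.0, None)
        return self._cache[cutoff][days - cutoff - 1]


class CensusFeedForward:
    """Feed-forward estimate of a schedule-derived census for future days.

    The value for day ``T`` seen from cutoff ``C < T`` combines (a) the exact
    contribution of cases already scheduled (surgery day <= C) under the
    feature's per-case LOS source, and (b) the expected contribution of
    not-yet-known cases on days ``C+1..T``: forecast daily counts times the
    probability, under the fitting-window LOS distribution, that a case is
    still in a bed ``T - s`` nights after surgery on day ``s``.
    """

    def __init__(
        self,
        encounters: pd.DataFrame,
        calendar: Calendar,
        case_los: np.ndarray,
        volume_forecaster: VolumeForecaster,
        survival_window_los: np.ndarray,
    ) -> None:
        self.day = encounters["day_index"].to_numpy(dtype=int)
        self.nights = np.floor(np.asarray(case_los, dtype=float) + 0.5).astype(int)
        self.n_days = calendar.n_days
        self.volume = volume_forecaster
        ref = np.floor(np.asarray(survival_window_los, dtype=float) + 0.5).astype(int)
        max_l = int(ref.max()) if len(ref) else 0
        # survival[k] = P(a case occupies a bed on its k-th night), k >= 1
        self.survival = np.array([np.mean(ref >= k) for k in range(1, max_l + 2)]) if max_l else np.zeros(1)

    def _known_contribution(self, cutoff: int, days: np.ndarray) -> np.ndarray:
        mask = self.day <= cutoff
        d, l = self.day[mask], self.nights[mask]
        out = np.empty(len(days), dtype=float)
        for i, t in enumerate(days):
            out[i] = np.count_nonzero((d <= t) & (d + l > t))
        return out

    def __call__(self, cutoff: int, days: np.ndarray) -> np.ndarray:
        days = np.asarray(days, dtype=int)
        known = self._known_contribution(cutoff, days)
        tmax = int(days.max())
        future_days = np.arange(cutoff + 1, tmax + 1)
        if len(future_days) == 0:
            return known
        counts = self.volume.forecast(cutoff, future_days)
        expected = np.zeros(len(days))
        for i, t in enumerate(days):
            lag = t - future_days  # nights since surgery-day s: t - s + 1 -> index t - s
            valid = (lag >= 0) & (lag < len(self.survival))
            expected[i] = float(np.sum(counts[valid] * self.survival[lag[valid]]))
        return known + expected


# ---------------------------------------------------------------------------
# model runners


@dataclass
class ForecastEvaluation:
    """One grid row: per-day forecasts and RMSE/SD for a model x horizon."""

    model: str
    spec_label: str
    exog_names: tuple[str, ...]
    protocol: str
    records: pd.DataFrame  # target_day, forecast, actual, error
    rmse: float
    sd: float  # standard deviation of absolute errors across forecast days
    audit: CutoffAudit
    failed_origins: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "spec": self.spec_label,
            "exog": list(self.exog_names),
            "protocol": self.protocol,
            "rmse": self.rmse,
            "sd": self.sd,
            "n_forecast_days": len(self.records),
            "n_failed_origins": len(self.failed_origins),
            "audit": self.audit.verify(),
        }


def _evaluation(model, spec_label, features, protocol, rows, audit, failed) -> ForecastEvaluation:
    records = pd.DataFrame(rows, columns=["target_day", "forecast", "actual", "error"])
    if len(records):
        errors = records["error"].to_numpy()
        rmse = float(np.sqrt(np.mean(errors**2)))
        sd = float(np.std(np.abs(errors), ddof=1)) if len(errors) > 1 else 0.0
    else:
        rmse, sd = float("nan"), float("nan")
    return ForecastEvaluation(
        model=model,
        spec_label=spec_label,
        exog_names=tuple(f.name for f in features),
        protocol=protocol,
        records=records,
        rmse=rmse,
        sd=sd,
        audit=audit,
        failed_origins=failed,
    )


def _sarimax_protocol(
    census: DailySeries,
    spec: SarimaxSpec,
    features: Sequence[ExogFeature],
    protocol: Protocol,
    split: SplitSpec,
    refit: bool,
    lead: int,
) -> ForecastEvaluation:
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    y = census.values
    n = len(y)
    test_start = split.val_end_day
    audit = CutoffAudit()
    rows: list[dict] = []
    failed: list[int] = []

    def fit(cutoff: int):
        ex = _exog_history(features, cutoff)
        model = SARIMAX(y[: cutoff + 1], exog=ex, order=spec.order, seasonal_order=spec.seasonal_order, trend=spec.trend)
        res = _quiet_fit(model)
        _check_converged(res, allow_nonconverged=True)
        return res

    if protocol == "long_term":
        cutoff = test_start - 1
        days = np.arange(test_start, n)
        fex = _exog_for_days(features, cutoff, days, protocol, target_day=int(days[-1]), audit=audit)
        try:
            res = fit(cutoff)
            pred = np.asarray(res.get_forecast(steps=len(days), exog=fex).predicted_mean)
        except (FitFailureError, np.linalg.LinAlgError) as err:
            raise FitFailureError(f"long-term fit failed: {err}") from err
        for d, f in zip(days, pred):
            rows.append({"target_day": int(d), "forecast": float(f), "actual": float(y[d]), "error": float(f - y[d])})
        return _evaluation("sarimax" if features else "sarima", spec.label(), features, protocol, rows, audit, failed)

    offset = lead if protocol == "two_week" else 1
    res = None
    fitted_end = None
    for target in range(test_start, n):
        cutoff = target - offset
        try:
            if res is None or refit:
                res = fit(cutoff)
                fitted_end = cutoff
            elif cutoff > fitted_end:
                new_ex = _exog_history(features, cutoff)
                new_ex = new_ex[fitted_end + 1 :] if new_ex is not None else None
                res = res.append(y[fitted_end + 1 : cutoff + 1], exog=new_ex, refit=False)
                fitted_end = cutoff
            days = np.arange(cutoff + 1, target + 1)
            fex = _exog_for_days(features, cutoff, days, protocol, target_day=target, audit=audit)
            pred = np.asarray(res.get_forecast(steps=len(days), exog=fex).predicted_mean)
            f = float(pred[-1])
            if not np.isfinite(f):
                raise FitFailureError("non-finite forecast")
        except (FitFailureError, np.linalg.LinAlgError) as err:
            failed.append(target)
            res, fitted_end = None, None
            continue
        rows.append({"target_day": target, "forecast": f, "actual": float(y[target]), "error": f - float(y[target])})
    return _evaluation("sarimax" if features else "sarima", spec.label(), features, protocol, rows, audit, failed)


def _ols_protocol(
    census: DailySeries,
    features: Sequence[ExogFeature],
    protocol: Protocol,
    split: SplitSpec,
    lead: int,
) -> ForecastEvaluation:
    if not features:
        raise ValueError("OLS requires at least one exogenous regressor")
    y = census.values
    n = len(y)
    test_start = split.val_end_day
    audit = CutoffAudit()
    rows: list[dict] = []

    def fit(cutoff: int):
        X = sm.add_constant(_exog_history(features, cutoff))
        return sm.OLS(y[: cutoff + 1], X).fit()

    def predict(res, cutoff: int, target: int) -> float:
        fex = _exog_for_days(features, cutoff, np.array([target]), protocol, target_day=target, audit=audit)
        return float(res.params[0] + fex[0] @ res.params[1:])

    if protocol == "long_term":
        cutoff = test_start - 1
        res = fit(cutoff)
        for target in range(test_start, n):
            f = predict(res, cutoff, target)
            rows.append({"target_day": target, "forecast": f, "actual": float(y[target]), "error": f - float(y[target])})
    else:
        offset = lead if protocol == "two_week" else 1
        for target in range(test_start, n):
            cutoff = target - offset
            res = fit(cutoff)
            f = predict(res, cutoff, target)
            rows.append({"target_day": target, "forecast": f, "actual": float(y[target]), "error": f - float(y[target])})
    return _evaluation("ols", "OLS", features, protocol, rows, audit, [])


def _var_protocol(
    census: DailySeries,
    counts: DailySeries,
    features: Sequence[ExogFeature],
    split: SplitSpec,
    maxlags: int = 10,
) -> ForecastEvaluation:
    """VAR of (census, surgery counts) with exogenous holidays; long-term only."""
    y = np.column_stack([census.values, counts.values])
    n = len(census.values)
    test_start = split.val_end_day
    cutoff = test_start - 1
    audit = CutoffAudit()
    days = np.arange(test_start, n)
    exog = _exog_history(features, cutoff)
    fex = _exog_for_days(features, cutoff, days, "long_term", target_day=int(days[-1]), audit=audit)
    model = VAR(y[: cutoff + 1], exog=exog)
    res = model.fit(maxlags=maxlags, ic="aic")
    lag = max(res.k_ar, 1)
    pred = res.forecast(y[cutoff + 1 - lag : cutoff + 1], steps=len(days), exog_future=fex)
    rows = [
        {"target_day": int(d), "forecast": float(p), "actual": float(census.values[d]), "error": float(p - census.values[d])}
        for d, p in zip(days, pred[:, 0])
    ]
    return _evaluation("var", f"VAR({res.k_ar})", features, "long_term", rows, audit, [])


def run_model(
    census: DailySeries,
    model: Literal["sarimax", "ols", "var"],
    features: Sequence[ExogFeature],
    protocol: Protocol,
    split: SplitSpec,
    spec: SarimaxSpec | None = None,
    counts: DailySeries | None = None,
    refit: bool = False,
    lead: int = 14,
) -> ForecastEvaluation:
    """Score one (model, exogenous set, horizon protocol) combination.

    The evaluation covers the test window only; the audit on the returned
    evaluation is verified before returning.
    """
    if model == "sarimax":
        if spec is None:
            raise ValueError("sarimax requires a SarimaxSpec")
        ev = _sarimax_protocol(census, spec, features, protocol, split, refit, lead)
    elif model == "ols":
        ev = _ols_protocol(census, features, protocol, split, lead)
    elif model == "var":
        if counts is None:
            raise ValueError("VAR requires the surgery-count series")
        if protocol != "long_term":
            raise ValueError("VAR is implemented for the long-term protocol only")
        ev = _var_protocol(census, counts, features, split)
    else:
        raise ValueError(f"unknown model: {model}")
    ev.audit.verify()
    return ev


# ---------------------------------------------------------------------------
# the full model x horizon grid


def run_model_grid(
    encounters: pd.DataFrame,
    calendar: Calendar,
    split: SplitSpec,
    predicted_los: np.ndarray,
    type_mean_los: HistoricMeanLOS,
    los_fit_window_observed: np.ndarray,
    refit: bool = False,
    include_bounds: bool = True,
) -> list[ForecastEvaluation]:
    """Run the standard model x horizon grid over the test window.

    ``predicted_los`` holds the forest prediction for every case;
    ``los_fit_window_observed`` is the LOS-model fitting window's observed LOS
    (used for the feed-forward survival profile of not-yet-scheduled cases).
    """
    counts = build_daily_counts(encounters, calendar)
    variants = census_variants(encounters, calendar, predicted_los, type_mean_los)
    observed = variants["observed"]
    holidays = calendar.holiday_indicator.astype(float)

    vol = VolumeForecaster(counts, holidays)
    lag7 = np.concatenate([counts.values[:7], counts.values[:-7]])

    def schedule_feature(name: str, variant: str, case_los: np.ndarray) -> ExogFeature:
        forecaster = CensusFeedForward(encounters, calendar, case_los, vol, los_fit_window_observed)
        return ExogFeature(name=name, values=variants[variant].values, kind="schedule", forecaster=forecaster)

    adjusted_los = np.where(encounters["planned_same_day_discharge"].to_numpy(bool), 0.0, predicted_los)
    feats = {
        "holidays": ExogFeature("holidays", holidays, "calendar"),
        "surgery_count_lag7": ExogFeature(
            "surgery_count_lag7", lag7, "observed", known_lag=7,
            forecaster=lambda cutoff, days: vol.forecast(cutoff, days - 7),
        ),
        "predicted_census": schedule_feature("predicted_census", "predicted", predicted_los),
        "adjusted_census": schedule_feature("adjusted_census", "adjusted", adjusted_los),
        "perfect_census": schedule_feature("perfect_census", "perfect", encounters["los_days"].to_numpy(float)),
        "surgery_mean_census": schedule_feature(
            "surgery_mean_census", "surgery_mean", type_mean_los.lookup(encounters["surgery_type"])
        ),
    }

    sma = SarimaxSpec(P=0, D=1, Q=1, m=7)  # (0,0,0)(0,1,1)7
    sar = SarimaxSpec(P=1, D=1, Q=0, m=7)  # (0,0,0)(1,1,0)7
    grid: list[tuple[str, SarimaxSpec | None, Protocol, list[str]]] = [
        ("sarimax", sma, "long_term", []),
        ("sarimax", sma, "long_term", ["holidays"]),
        ("var", None, "long_term", ["holidays"]),
        ("ols", None, "two_week", ["predicted_census"]),
        ("sarimax", sar, "two_week", ["predicted_census"]),
        ("sarimax", sar, "two_week", ["holidays", "surgery_count_lag7"]),
        ("sarimax", sma, "same_day", ["holidays"]),
        ("sarimax", sar, "same_day", ["predicted_census"]),
        ("sarimax", sar, "same_day", ["adjusted_census"]),
    ]
    if include_bounds:
        grid += [
            ("sarimax", sar, "same_day", ["perfect_census"]),
            ("sarimax", sar, "same_day", ["surgery_mean_census"]),
        ]

    evaluations: list[ForecastEvaluation] = []
    for model, spec, protocol, names in grid:
        features = [feats[name] for name in names]
        spec_ex = spec.model_copy(update={"exog_names": tuple(names)}) if spec is not None else None
        ev = run_model(
            observed, model, features, protocol, split, spec=spec_ex, counts=counts, refit=refit
        )
        evaluations.append(ev)
    return evaluations


def relative_error_report(evaluation: ForecastEvaluation, capacity_reference: float, observed: DailySeries | None = None) -> dict:
    """RMSE as a percentage of a bed-capacity reference (e.g. peak census)."""
    if capacity_reference <= 0:
        raise ValueError("capacity_reference must be positive")
    out = {
        "rmse": evaluation.rmse,
        "capacity_reference": float(capacity_reference),
        "relative_error_pct": 100.0 * evaluation.rmse / capacity_reference,
    }
    if observed is not None:
        out["max_observed_census"] = float(observed.values.max())
    return out
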