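"""Validated configuration objects shared across pipeline stages.

All tunable knobs live here: the synthetic-generator parameters (which define
the statistical structure of the simulated hospital), the chronological
train/validation/test split, the random-forest hyperparameters for the
length-of-stay model, and the seasonal ARIMA order notation
``(p, d, q)(P, D, Q)m`` used by the volume and census forecasters.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ComorbidityCountLaw",
    "GeneratorConfig",
    "SplitSpec",
    "ForestSpec",
    "SarimaxSpec",
]


class ComorbidityCountLaw(BaseModel):
    """Truncated-normal law for the number of comorbidity codes per case.

    Defaults reflect a long-tailed burden distribution: mean 10.9 codes,
    SD 11.2, between 1 and 160 codes per patient.
    """

    mean: float = 10.9
    sd: float = 11.2
    min: int = 1
    max: int = 160

    @model_validator(mode="after")
    def _check(self) -> "ComorbidityCountLaw":
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be nonnegative")
        if self.min > self.max:
            raise ValueError("min must be <= max")
        if self.min < 1:
            raise ValueError("every case carries at least one code")
        return self


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic surgical-encounter generator.

    The defaults emulate a large academic surgical service over one year:
    weekly (period-7) volume seasonality with holiday troughs, ~72% outpatient
    cases, median length of stay of 1 night with a long right tail, and a
    power-law comorbidity code vocabulary averaging ~11 codes per case.
    """

    n_days: int = 365
    day0_weekday: int = Field(4, ge=0, le=6)
    weekday_volume_mean: float = 320.0
    weekend_volume_mean: float = 170.0
    holiday_volume_mean: float = 120.0
    # Negative-binomial size parameter for daily counts; None -> Poisson,
    # 0 -> deterministic counts (the zero-dispersion limit).
    volume_dispersion: Optional[float] = 80.0
    holidays: frozenset[int] = frozenset()

    n_surgery_types: int = 150
    # Zipf exponent of the categorical over surgery types (larger = more
    # concentrated on a few common procedures).
    surgery_type_popularity: float = 0.8
    n_departments: int = 12
    # Optional explicit per-type LOS law: type label -> (mean positive-part
    # LOS in days, gamma shape, probability of same-day discharge).  When
    # None, laws are derived deterministically from the seed and recorded in
    # the ground-truth record.
    per_type_los: Optional[dict[str, tuple[float, float, float]]] = None
    los_gamma_shape: float = 1.3
    # Lognormal law for per-type mean positive LOS (median, log-sd, ceiling).
    # The ceiling caps how extreme the rarest procedure types can be; smaller
    # (scaled-down) hospitals see proportionally shorter extreme stays.
    type_mean_los_median: float = 1.8
    type_mean_los_sigma: float = 0.5
    type_mean_los_max: float = 25.0
    # Same-day-discharge probability by planned admission class (ignored when
    # per_type_los supplies explicit type-level probabilities).
    outpatient_sdd_prob: float = Field(0.30, ge=0.0, le=1.0)
    inpatient_sdd_prob: float = Field(0.02, ge=0.0, le=1.0)
    # Within-type LOS contrast: planned inpatients of a type stay this many
    # times longer (positive part) than planned outpatients, normalized so the
    # type's mean positive LOS is unchanged.
    admission_los_contrast: float = Field(4.0, gt=0.0)
    # Day-to-day swing (logit-scale SD) of the admission-class mix: OR block
    # schedules make some days inpatient-heavy and others ambulatory-heavy.
    daily_class_mix_sd: float = Field(0.8, ge=0.0)
    outpatient_fraction: float = Field(0.724, ge=0.0, le=1.0)

    n_codes: int = 2000
    code_popularity_exponent: float = 1.3
    comorbidity_count_law: ComorbidityCountLaw = Field(default_factory=ComorbidityCountLaw)
    # Multiplicative effect of the standardized latent comorbidity burden on
    # the log-mean positive LOS; 0 removes all code->LOS signal.
    comorbidity_los_coef: float = 0.7
    # Number of leading (most frequent) codes that carry LOS signal.
    n_signal_codes: int = 100

    # Fraction of expected case volume used as the recurring-patient pool size
    # (patients are drawn with replacement, so repeat patients occur).
    patient_pool_factor: float = Field(0.66, gt=0.0, le=1.0)
    # Rate at which the planned-same-day-discharge flag disagrees with the
    # realized LOS (schedule errors / unplanned admissions).
    sdd_flag_error_rate: float = Field(0.05, ge=0.0, le=1.0)

    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: {"asa_ps": 0.02, "los_days": 0.0011, "scheduled_duration_min": 0.0}
    )
    seed: int = 0
    # When set, the latent hospital structure (type laws, departments,
    # popularity) is drawn from this seed while case-level sampling follows
    # `seed` — so replicate runs share one ground truth.
    structure_seed: Optional[int] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for name in ("weekday_volume_mean", "weekend_volume_mean", "holiday_volume_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.volume_dispersion is not None and self.volume_dispersion < 0:
            raise ValueError("volume_dispersion must be >= 0 (or None for Poisson)")
        bad = [h for h in self.holidays if not 0 <= h < self.n_days]
        if bad:
            raise ValueError(f"holidays outside [0, n_days): {sorted(bad)}")
        for field_name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {field_name} not in [0, 1]")
        if self.per_type_los is not None:
            for t, (mean, shape, p0) in self.per_type_los.items():
                if mean < 0 or shape <= 0 or not 0.0 <= p0 <= 1.0:
                    raise ValueError(f"invalid LOS law for type {t}")
        return self


class SplitSpec(BaseModel):
    """Chronological train/validation/test partition by day index.

    Default 225/70/70 days: training before day 225, validation days
    225-294, test days 295-364.  Membership is decided solely by the day of
    surgery; rows are never shuffled.
    """

    train_end_day: int = 225
    val_end_day: int = 295
    n_days: int = 365

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SplitSpec":
        if not 0 < self.train_end_day < self.val_end_day <= self.n_days:
            raise ValueError("require 0 < train_end_day < val_end_day <= n_days")
        return self

    @property
    def n_train_days(self) -> int:
        return self.train_end_day

    @property
    def n_val_days(self) -> int:
        return self.val_end_day - self.train_end_day

    @property
    def n_test_days(self) -> int:
        return self.n_days - self.val_end_day


class ForestSpec(BaseModel):
    """Random-forest hyperparameters for the LOS regressor.

    Defaults follow the tuned configuration: each tree sees at most 92% of
    the training rows and grows to at most 580 leaves.
    """

    n_trees: int = Field(500, ge=1)
    max_leaf_nodes: int = Field(580, ge=2)
    max_samples_fraction: float = Field(0.92, gt=0.0, le=1.0)
    max_depth: Optional[int] = None
    min_samples_split: int = Field(2, ge=2)
    seed: int = 0

    model_config = {"frozen": True}


class SarimaxSpec(BaseModel):
    """Seasonal ARIMA order ``(p, d, q)(P, D, Q)m`` plus named exogenous set."""

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 1
    Q: int = 1
    m: int = Field(7, ge=1)
    exog_names: tuple[str, ...] = ()
    trend: Optional[str] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SarimaxSpec":
        if min(self.p, self.d, self.q, self.P, self.D, self.Q) < 0:
            raise ValueError("all orders must be >= 0")
        return self

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.m)

    def label(self) -> str:
        base = "SARIMAX" if self.exog_names else "SARIMA"
        return f"{base} ({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q}){self.m}"
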