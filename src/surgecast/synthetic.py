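"""Synthetic surgical-encounter generator.

Emulates one year of perioperative EHR data from a large academic hospital:
daily case volumes with a weekly work-week cycle and holiday troughs, a
long-tailed mix of surgery types with type-specific length-of-stay (LOS)
laws, ~72% outpatient cases, and sparse comorbidity code sets drawn from a
power-law vocabulary.  Every latent parameter is retained in a ground-truth
record so downstream models can be checked for parameter recovery.

Generative model
----------------
* Daily case counts: negative binomial around a regime mean (weekday /
  weekend / holiday); Poisson in the zero-dispersion limit.
* Surgery type: Zipf-weighted categorical over ``n_surgery_types`` types.
* LOS: zero-inflated — a point mass at 0 (same-day discharge) with
  type-specific probability; otherwise ``1 + Poisson(Gamma)`` nights (a
  gamma-Poisson mixture whose mean is exactly the type's configured positive
  mean), so the positive part has median 1-2 nights and a long right tail.
* Comorbidity codes: each case draws a truncated-normal number of distinct
  codes without replacement, with power-law inclusion weights (Plackett-Luce
  sampling via the Gumbel top-k trick).
* Comorbidity -> LOS link: the leading ``n_signal_codes`` codes carry
  weights whose standardized per-case sum (the latent burden) shifts the
  log-mean of the positive LOS, so comorbidity-derived features are
  genuinely predictive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from scipy import optimize, stats

from .calendars import Calendar, generate_calendar
from .config import GeneratorConfig

__all__ = [
    "generate_encounters",
    "inject_missingness",
    "encounters_to_csv",
    "encounters_from_csv",
    "ground_truth_to_json",
]

URGENCY_LEVELS = ("elective", "same_day_add_on", "urgent", "emergent")
URGENCY_PROBS = (0.85, 0.05, 0.07, 0.03)

IMPUTABLE_FIELDS = ("asa_ps", "scheduled_duration_min", "los_days", "surgery_type")

ENCOUNTER_COLUMNS = [
    "case_id",
    "patient_id",
    "day_index",
    "surgery_type",
    "service_line",
    "planned_admission_class",
    "urgency",
    "age_years",
    "sex",
    "asa_ps",
    "scheduled_duration_min",
    "comorbidity_codes",
    "los_days",
    "planned_same_day_discharge",
]


def _type_labels(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def _code_labels(n: int) -> list[str]:
    return [f"C{i:05d}" for i in range(n)]


def _derive_type_laws(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent per-surgery-type parameters (popularity, LOS law, case mix)."""
    n = config.n_surgery_types
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-config.surgery_type_popularity)
    weights /= weights.sum()

    f = config.outpatient_fraction
    # Beta with mean f, recentred so the popularity-weighted mean is exactly f
    # (otherwise the handful of dominant types would let the realized
    # outpatient fraction drift by several points from seed to seed).
    if 0.0 < f < 1.0:
        outpatient_prop = np.clip(rng.beta(6.0 * f, 6.0 * (1.0 - f), size=n), 0.005, 0.995)
        for _ in range(4):
            outpatient_prop = np.clip(outpatient_prop + (f - weights @ outpatient_prop), 0.005, 0.995)
    else:
        outpatient_prop = np.full(n, f)

    if config.per_type_los is not None:
        labels = _type_labels(n)
        missing = [t for t in labels if t not in config.per_type_los]
        if missing:
            raise ValueError(f"per_type_los missing laws for types: {missing[:5]} ...")
        mean_pos = np.array([max(1.0, config.per_type_los[t][0]) for t in labels])
        shape = np.array([config.per_type_los[t][1] for t in labels])
        p_same_day = np.array([config.per_type_los[t][2] for t in labels])
        explicit_laws = True
    else:
        mean_pos = np.clip(
            rng.lognormal(mean=np.log(config.type_mean_los_median), sigma=config.type_mean_los_sigma, size=n),
            1.0,
            config.type_mean_los_max,
        )
        shape = np.full(n, config.los_gamma_shape)
        # class-dependent same-day discharge, aggregated to the type level
        p_same_day = outpatient_prop * config.outpatient_sdd_prob + (1 - outpatient_prop) * config.inpatient_sdd_prob
        explicit_laws = False

    departments = rng.integers(0, config.n_departments, size=n)
    median_duration = np.clip(rng.lognormal(mean=np.log(60.0), sigma=0.8, size=n), 15.0, 480.0)

    return {
        "weights": weights,
        "outpatient_prop": outpatient_prop,
        "mean_pos_los": mean_pos,
        "gamma_shape": shape,
        "p_same_day": p_same_day,
        "explicit_laws": explicit_laws,
        "department": departments,
        "median_duration": median_duration,
    }


def _daily_counts(config: GeneratorConfig, calendar: Calendar, rng: np.random.Generator) -> np.ndarray:
    means = np.where(calendar.is_weekend, config.weekend_volume_mean, config.weekday_volume_mean)
    means = np.where(calendar.holiday_indicator.astype(bool), config.holiday_volume_mean, means)
    if config.volume_dispersion is None:
        counts = rng.poisson(means)
    elif config.volume_dispersion == 0:  # zero-dispersion limit: deterministic
        counts = np.rint(means)
    else:
        r = config.volume_dispersion
        p = r / (r + np.maximum(means, 1e-12))
        counts = np.where(means > 0, rng.negative_binomial(r, p), 0)
    return counts.astype(np.int64)


def _truncated_count_location(law) -> float:
    """Location mu of the underlying normal so that clip(N(mu, sd), lo, hi)
    has mean equal to the configured mean (clipping inflates the raw mean)."""
    lo, hi, sd, target = float(law.min), float(law.max), float(law.sd), float(law.mean)
    if sd == 0 or lo == hi:
        return target

    def clipped_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        inside = stats.norm.cdf(b) - stats.norm.cdf(a)
        mid = mu * inside + sd * (stats.norm.pdf(a) - stats.norm.pdf(b))
        return lo * stats.norm.cdf(a) + hi * stats.norm.sf(b) + mid

    lo_b, hi_b = target - 4 * sd, target + 4 * sd
    if clipped_mean(lo_b) > target or clipped_mean(hi_b) < target:
        return target
    return float(optimize.brentq(lambda mu: clipped_mean(mu) - target, lo_b, hi_b))


def _sample_codes(
    m: np.ndarray, n_codes: int, exponent: float, rng: np.random.Generator, chunk: int = 4096
) -> list[np.ndarray]:
    """Draw ``m[i]`` distinct code indices per case, weight ∝ rank^-exponent.

    Gumbel top-k: the indices of the ``m`` largest ``log w_j + G_ij`` are a
    without-replacement sample proportional to the weights.
    """
    logw = (-exponent * np.log(np.arange(1, n_codes + 1, dtype=float))).astype(np.float32)
    out: list[np.ndarray] = []
    n_cases = len(m)
    for start in range(0, n_cases, chunk):
        mm = m[start : start + chunk]
        u = rng.random(size=(len(mm), n_codes), dtype=np.float32)
        np.maximum(u, np.float32(1e-12), out=u)
        keys = logw - np.log(-np.log(u))
        kmax = int(mm.max())
        top = np.argpartition(-keys, kmax - 1, axis=1)[:, :kmax]
        # order the retained candidates so row-wise prefixes are exact top-m
        order = np.argsort(-np.take_along_axis(keys, top, axis=1), axis=1)
        top = np.take_along_axis(top, order, axis=1)
        for i, mi in enumerate(mm):
            out.append(np.sort(top[i, :mi]))
    return out


def generate_encounters(config: GeneratorConfig) -> tuple[pd.DataFrame, Calendar, dict[str, Any]]:
    """Generate a complete (no missingness) encounter table.

    Returns the encounter table (one row per case), the calendar, and a
    ground-truth record of every latent parameter.  Deterministic given
    ``config`` (including its seed): identical configs yield byte-identical
    tables.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_volume, rng_case, rng_codes = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    if config.structure_seed is not None:
        rng_structure = np.random.default_rng(np.random.SeedSequence(config.structure_seed))

    calendar = generate_calendar(config.n_days, config.day0_weekday, config.holidays)
    laws = _derive_type_laws(config, rng_structure)
    type_labels = np.array(_type_labels(config.n_surgery_types))
    code_labels = np.array(_code_labels(config.n_codes))

    counts = _daily_counts(config, calendar, rng_volume)
    n_cases = int(counts.sum())
    day_index = np.repeat(np.arange(config.n_days), counts)

    if n_cases == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in ENCOUNTER_COLUMNS})
        return empty, calendar, {"config": json.loads(config.model_dump_json()), "daily_counts": counts.tolist()}

    type_idx = rng_case.choice(config.n_surgery_types, size=n_cases, p=laws["weights"])

    pool = max(1, int(round(config.patient_pool_factor * n_cases)))
    patient_idx = rng_case.integers(0, pool, size=n_cases)

    # admission-class mix: type propensity with a day-level logit swing
    # (block scheduling concentrates inpatient-heavy services on some days)
    day_shift = rng_case.normal(0.0, config.daily_class_mix_sd, size=config.n_days)
    o_case = np.clip(laws["outpatient_prop"][type_idx], 1e-6, 1 - 1e-6)
    logit = np.log(o_case / (1 - o_case)) + day_shift[day_index]
    outpatient = rng_case.random(n_cases) < 1.0 / (1.0 + np.exp(-logit))
    urgency = rng_case.choice(URGENCY_LEVELS, size=n_cases, p=URGENCY_PROBS)
    age = np.clip(rng_case.normal(57.0, 17.0, size=n_cases), 18.0, 95.0).round(1)
    sex = np.where(rng_case.random(n_cases) < 0.464, "M", "F")
    asa = rng_case.choice(np.arange(1, 6), size=n_cases, p=[0.05, 0.33, 0.47, 0.13, 0.02])
    duration = (laws["median_duration"][type_idx] * rng_case.lognormal(0.0, 0.3, size=n_cases)).round(0)

    law = config.comorbidity_count_law
    mu = _truncated_count_location(law)
    m = np.rint(rng_case.normal(mu, law.sd, size=n_cases)).astype(int)
    m = np.clip(m, law.min, min(law.max, config.n_codes))
    code_sets = _sample_codes(m, config.n_codes, config.code_popularity_exponent, rng_codes)

    # latent burden: weighted count of signal codes, standardized in-population
    effect_w = np.zeros(config.n_codes)
    k_sig = min(config.n_signal_codes, config.n_codes)
    effect_w[:k_sig] = 1.0 / np.sqrt(np.arange(1, k_sig + 1))
    burden = np.array([effect_w[idx].sum() for idx in code_sets])
    bsd = burden.std()
    burden_z = (burden - burden.mean()) / bsd if bsd > 0 else np.zeros(n_cases)

    coef = config.comorbidity_los_coef
    # exp(coef*z - coef^2/2) has unit mean, so the type mean is preserved
    mult = np.exp(coef * burden_z - 0.5 * coef**2)
    if laws["explicit_laws"]:
        p0_case = laws["p_same_day"][type_idx]
        class_mult = np.ones(n_cases)
    else:
        # planned inpatients of a type rarely leave same-day and stay
        # `admission_los_contrast` times longer than planned outpatients,
        # normalized so the type's mean positive LOS is unchanged
        p0_case = np.where(outpatient, config.outpatient_sdd_prob, config.inpatient_sdd_prob)
        c = config.admission_los_contrast
        o_case = laws["outpatient_prop"][type_idx]
        class_mult = np.where(outpatient, 1.0, c) / (o_case + (1.0 - o_case) * c)
    same_day = rng_case.random(n_cases) < p0_case
    shape = laws["gamma_shape"][type_idx]
    mean_extra = np.maximum(laws["mean_pos_los"][type_idx] - 1.0, 0.0) * mult * class_mult
    # gamma-Poisson mixture: integer nights beyond the first with mean exactly
    # mean_extra and a gamma-shaped long right tail
    extra = rng_case.poisson(rng_case.gamma(shape, mean_extra / shape, size=n_cases))
    los = np.where(same_day, 0, 1 + extra).astype(np.int64)

    flag_err = rng_case.random(n_cases) < config.sdd_flag_error_rate
    planned_sdd = (los == 0) ^ flag_err

    frame = pd.DataFrame(
        {
            "case_id": [f"E{i:07d}" for i in range(n_cases)],
            "patient_id": [f"P{i:06d}" for i in patient_idx],
            "day_index": day_index,
            "surgery_type": type_labels[type_idx],
            "service_line": [
                f"D{laws['department'][t]:02d}|{'OP' if o else 'IP'}" for t, o in zip(type_idx, outpatient)
            ],
            "planned_admission_class": np.where(outpatient, "outpatient", "inpatient"),
            "urgency": urgency,
            "age_years": age,
            "sex": sex,
            "asa_ps": asa.astype(float),
            "scheduled_duration_min": duration,
            "comorbidity_codes": [tuple(code_labels[idx]) for idx in code_sets],
            "los_days": los.astype(float),
            "planned_same_day_discharge": planned_sdd,
        }
    )

    mu, o_t = laws["mean_pos_los"], laws["outpatient_prop"]
    if laws["explicit_laws"]:
        type_mean_overall = (1.0 - laws["p_same_day"]) * mu
    else:
        c = config.admission_los_contrast
        norm = o_t + (1.0 - o_t) * c
        mean_out = 1.0 + (mu - 1.0) / norm
        mean_in = 1.0 + (mu - 1.0) * c / norm
        type_mean_overall = o_t * (1.0 - config.outpatient_sdd_prob) * mean_out + (1.0 - o_t) * (
            1.0 - config.inpatient_sdd_prob
        ) * mean_in

    ground_truth: dict[str, Any] = {
        "config": json.loads(config.model_dump_json()),
        "type_labels": type_labels.tolist(),
        "type_weights": laws["weights"].tolist(),
        "type_mean_pos_los": laws["mean_pos_los"].tolist(),
        "type_p_same_day": laws["p_same_day"].tolist(),
        "type_mean_overall_los": type_mean_overall.tolist(),
        "type_outpatient_propensity": laws["outpatient_prop"].tolist(),
        "code_effect_weights": effect_w.tolist(),
        "comorbidity_los_coef": coef,
        "daily_counts": counts.tolist(),
        "n_cases": n_cases,
        "patient_pool_size": pool,
    }
    return frame, calendar, ground_truth


def inject_missingness(
    encounters: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Blank fields independently at the given per-field rates.

    Only fields with defined imputation rules downstream may be targeted.
    Returns a copy; reproducible given the seed.
    """
    unknown = set(rates) - set(IMPUTABLE_FIELDS)
    if unknown:
        raise ValueError(f"no imputation rule for fields: {sorted(unknown)}")
    for field, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {field} not in [0, 1]")
    out = encounters.copy()
    rng = np.random.default_rng(seed)
    for field in IMPUTABLE_FIELDS:  # fixed order -> reproducible draws
        rate = rates.get(field, 0.0)
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if field == "surgery_type":
            out.loc[mask, field] = None
        else:
            out.loc[mask, field] = np.nan
    return out


def encounters_to_csv(encounters: pd.DataFrame, path: str | Path) -> None:
    """Write one row per case; comorbidity codes semicolon-joined, missing cells empty."""
    out = encounters.copy()
    out["comorbidity_codes"] = [";".join(c) if c is not None else "" for c in out["comorbidity_codes"]]
    out.to_csv(path, index=False)


def encounters_from_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"case_id": str, "patient_id": str, "surgery_type": object})
    frame["comorbidity_codes"] = [
        tuple(c.split(";")) if isinstance(c, str) and c else () for c in frame["comorbidity_codes"]
    ]
    frame["planned_same_day_discharge"] = frame["planned_same_day_discharge"].astype(bool)
    return frame


def ground_truth_to_json(ground_truth: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=1))
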