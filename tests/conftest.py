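"""Shared fixtures: scaled study configurations and expensive model batteries.

The scaled configuration keeps the default per-case laws (LOS, comorbidity,
class mix) but runs a smaller hospital (~60 weekday cases instead of ~320 and
a 300-code vocabulary) so forests and rolling forecasts fit the test budget.
Session-scoped batteries are shared across tests that read different aspects
of the same computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from surgecast import GeneratorConfig, SplitSpec, ForestSpec, SarimaxSpec, default_holidays
from surgecast.census import ExogFeature, census_variants, run_model
from surgecast.los import (
    LOSFeatureSchema,
    assemble_features,
    compute_historic_mean_los,
    fit_forest,
    predict_los,
)
from surgecast.preprocessing import build_onehot_matrix, fit_decomposition, select_top_n_codes
from surgecast.synthetic import generate_encounters

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25, database=None)
settings.load_profile("suite")


def small_config(seed=0, **overrides):
    """A tiny hospital (140 days, ~25 weekday cases) for fast unit tests."""
    from surgecast import ComorbidityCountLaw

    base = dict(
        n_days=140,
        weekday_volume_mean=25.0,
        weekend_volume_mean=12.0,
        holiday_volume_mean=8.0,
        holidays=frozenset({10, 75}),
        n_codes=80,
        n_surgery_types=15,
        n_signal_codes=25,
        comorbidity_count_law=ComorbidityCountLaw(mean=6.0, sd=4.0, min=1, max=30),
        seed=seed,
    )
    base.update(overrides)
    base["holidays"] = frozenset(h for h in base["holidays"] if h < base["n_days"])
    return GeneratorConfig(**base)


def scaled_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default per-case laws at roughly one-fifth hospital volume."""
    base = dict(
        holidays=default_holidays(),
        weekday_volume_mean=60.0,
        weekend_volume_mean=30.0,
        holiday_volume_mean=20.0,
        n_codes=300,
        n_surgery_types=40,
        n_signal_codes=50,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def split() -> SplitSpec:
    return SplitSpec()


@pytest.fixture(scope="session")
def scaled_dataset():
    """One scaled synthetic year: encounters, calendar, ground truth."""
    return generate_encounters(scaled_generator_config(seed=11))


def fit_los_pipeline(encounters: pd.DataFrame, split: SplitSpec, seed: int, n_trees: int = 200):
    """Train+val LOS pipeline: decomposition, historic means, forest, per-case predictions."""
    fit_window = encounters[encounters["day_index"] < split.val_end_day].reset_index(drop=True)
    vocab = select_top_n_codes(fit_window, 250)
    decomposition = fit_decomposition(build_onehot_matrix(fit_window, vocab), "truncated_svd", 12)
    historic = compute_historic_mean_los(fit_window)
    schema = LOSFeatureSchema.fit(fit_window, 12)
    X_fit, y_fit = assemble_features(fit_window, decomposition, historic, schema)
    forest = fit_forest(X_fit, y_fit, ForestSpec(n_trees=n_trees, seed=seed))
    X_all, _ = assemble_features(encounters, decomposition, historic, schema)
    predicted = predict_los(forest, X_all)
    return {
        "fit_window": fit_window,
        "decomposition": decomposition,
        "historic": historic,
        "schema": schema,
        "forest": forest,
        "predicted_los": predicted,
    }


def same_day_rmse(encounters, calendar, split, predicted_los, historic, variant_names):
    """Same-day SARIMAX(0,0,0)(1,1,0)7 RMSE per census-variant exogenous set."""
    variants = census_variants(encounters, calendar, predicted_los, historic)
    sar = SarimaxSpec(P=1, D=1, Q=0, m=7)
    out = {}
    for name in variant_names:
        feature = ExogFeature(name, variants[name].values, "schedule")
        spec = sar.model_copy(update={"exog_names": (name,)})
        ev = run_model(variants["observed"], "sarimax", [feature], "same_day", split, spec=spec)
        out[name] = ev.rmse
    return out


def _battery(split: SplitSpec, variant_names, n_seeds=10, **gen_overrides):
    results = []
    for seed in range(n_seeds):
        enc, cal, _ = generate_encounters(scaled_generator_config(seed=seed, **gen_overrides))
        art = fit_los_pipeline(enc, split, seed=seed)
        results.append(
            same_day_rmse(enc, cal, split, art["predicted_los"], art["historic"], variant_names)
        )
    return results


@pytest.fixture(scope="session")
def sameday_information_battery(split):
    """Per-seed same-day RMSEs for perfect / predicted / surgery-mean LOS sources."""
    return _battery(split, ["perfect", "predicted", "surgery_mean"])


@pytest.fixture(scope="session")
def sameday_adjusted_battery(split):
    """Per-seed same-day RMSEs for predicted vs adjusted LOS at a same-day-discharge
    fraction >= 0.5 (ambulatory-heavy case mix)."""
    return _battery(
        split,
        ["predicted", "adjusted"],
        outpatient_sdd_prob=0.70,
        inpatient_sdd_prob=0.05,
    )
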