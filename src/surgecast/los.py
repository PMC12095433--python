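"""Per-case length-of-stay (LOS) prediction with a random-forest regressor.

The feature set mirrors what a perioperative data warehouse can supply before
the day of surgery: age, sex, ASA PS, scheduled case duration, service line,
planned admission class, the raw comorbidity count, k decomposition scores of
the comorbidity incidence matrix, and an engineered historic mean LOS for the
surgery type.  Alongside the forest, a per-type mean-LOS baseline is provided
for model comparison, and permutation importance ranks the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .config import ForestSpec
from .preprocessing import DecompositionModel, build_onehot_matrix

__all__ = [
    "HistoricMeanLOS",
    "compute_historic_mean_los",
    "LOSFeatureSchema",
    "assemble_features",
    "fit_forest",
    "predict_los",
    "LOSEvaluation",
    "evaluate_los",
    "permutation_importance",
]


@dataclass(frozen=True)
class HistoricMeanLOS:
    """Mean observed LOS per surgery type over a fitting window.

    Types unseen in the window fall back to the window's global mean.
    """

    per_type: dict[str, float]
    global_mean: float

    def lookup(self, surgery_types: pd.Series) -> np.ndarray:
        return surgery_types.map(self.per_type).fillna(self.global_mean).to_numpy(dtype=float)


def compute_historic_mean_los(fitting_window: pd.DataFrame) -> HistoricMeanLOS:
    if len(fitting_window) == 0:
        raise ValueError("fitting window must be non-empty")
    per_type = fitting_window.groupby("surgery_type")["los_days"].mean()
    return HistoricMeanLOS(
        per_type={t: float(v) for t, v in per_type.items()},
        global_mean=float(fitting_window["los_days"].mean()),
    )


NUMERIC_FEATURES = ["age_years", "scheduled_duration_min", "n_comorbidities", "historic_mean_los", "asa_ps"]
CATEGORICAL_FEATURES = ["sex", "service_line", "planned_admission_class"]


@dataclass(frozen=True)
class LOSFeatureSchema:
    """Fixed feature layout determined by the training window.

    One-hot category levels are frozen at fit time; unseen categories at
    predict time map to an all-zero block.  ASA PS enters as an ordinal
    column, with the imputer's "unknown" token carried by a dedicated
    indicator column (ordinal set to 0 for those rows).
    """

    k: int
    category_levels: dict[str, tuple[str, ...]]

    @classmethod
    def fit(cls, train: pd.DataFrame, k: int) -> "LOSFeatureSchema":
        levels = {
            col: tuple(sorted(train[col].dropna().astype(str).unique())) for col in CATEGORICAL_FEATURES
        }
        return cls(k=k, category_levels=levels)

    @property
    def feature_names(self) -> list[str]:
        names = list(NUMERIC_FEATURES)
        names += [f"svd_{i:02d}" for i in range(self.k)]
        names += ["asa_unknown"]
        for col in CATEGORICAL_FEATURES:
            names += [f"{col}={lvl}" for lvl in self.category_levels[col]]
        return names


def assemble_features(
    table: pd.DataFrame,
    decomposition: DecompositionModel,
    historic_mean: HistoricMeanLOS,
    schema: LOSFeatureSchema,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One feature row per case (imputation must already be applied).

    Returns the feature matrix with the schema's fixed column layout and the
    observed LOS target vector.
    """
    if schema.k != decomposition.k:
        raise ValueError(f"schema expects k={schema.k} but decomposition has k={decomposition.k}")
    n = len(table)
    asa_raw = table["asa_ps"]
    asa_unknown = asa_raw.apply(lambda v: isinstance(v, str)).to_numpy()
    asa_ordinal = pd.to_numeric(asa_raw.where(~asa_unknown, np.nan), errors="coerce").fillna(0.0).to_numpy()

    cols: dict[str, np.ndarray] = {
        "age_years": table["age_years"].to_numpy(dtype=float),
        "scheduled_duration_min": table["scheduled_duration_min"].to_numpy(dtype=float),
        "n_comorbidities": np.array([len(c) for c in table["comorbidity_codes"]], dtype=float),
        "historic_mean_los": historic_mean.lookup(table["surgery_type"]),
        "asa_ps": asa_ordinal,
    }
    scores = decomposition.transform(build_onehot_matrix(table, decomposition.vocabulary))
    for i in range(schema.k):
        cols[f"svd_{i:02d}"] = scores[:, i]
    cols["asa_unknown"] = asa_unknown.astype(float)
    for col in CATEGORICAL_FEATURES:
        values = table[col].astype(str)
        for lvl in schema.category_levels[col]:
            cols[f"{col}={lvl}"] = (values == lvl).to_numpy(dtype=float)

    X = pd.DataFrame(cols, columns=schema.feature_names, index=range(n))
    y = table["los_days"].to_numpy(dtype=float)
    return X, y


def fit_forest(features: pd.DataFrame, targets: np.ndarray, spec: ForestSpec) -> RandomForestRegressor:
    """Fit the LOS random forest.  Deterministic given the spec's seed.

    ``max_samples_fraction < 1`` bootstraps that fraction of training rows per
    tree; a fraction of exactly 1 gives every tree the full training set
    (no resampling), which makes a one-tree forest coincide with a single
    decision tree.
    """
    if len(features) == 0:
        raise ValueError("empty training set")
    if np.any(targets < 0):
        raise ValueError("LOS targets must be nonnegative")
    bootstrap = spec.max_samples_fraction < 1.0
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_leaf_nodes=spec.max_leaf_nodes,
        max_samples=spec.max_samples_fraction if bootstrap else None,
        bootstrap=bootstrap,
        max_depth=spec.max_depth,
        min_samples_split=spec.min_samples_split,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(features, targets)
    return model


def predict_los(model: RandomForestRegressor, features: pd.DataFrame) -> np.ndarray:
    """Predicted LOS in days per case, clipped at 0."""
    return np.clip(model.predict(features), 0.0, None)


@dataclass(frozen=True)
class LOSEvaluation:
    rmse: float
    mae: float
    strata: dict[str, dict[str, float]] = field(default_factory=dict)


def evaluate_los(model: RandomForestRegressor, features: pd.DataFrame, targets: np.ndarray) -> LOSEvaluation:
    """RMSE, MAE, and errors stratified by short (<10 d) vs long stays."""
    if len(features) == 0:
        raise ValueError("empty evaluation set")
    pred = predict_los(model, features)
    rmse = float(np.sqrt(mean_squared_error(targets, pred)))
    mae = float(mean_absolute_error(targets, pred))
    strata = {}
    for label, mask in (("los<10", targets < 10), ("los>=10", targets >= 10)):
        if mask.any():
            strata[label] = {
                "rmse": float(np.sqrt(mean_squared_error(targets[mask], pred[mask]))),
                "mae": float(mean_absolute_error(targets[mask], pred[mask])),
                "n": int(mask.sum()),
            }
    return LOSEvaluation(rmse=rmse, mae=mae, strata=strata)


def permutation_importance(
    model: RandomForestRegressor,
    features: pd.DataFrame,
    targets: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean increase in MSE when each feature column is shuffled, descending."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    result = _sk_permutation_importance(
        model,
        features,
        targets,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    out = pd.DataFrame(
        {
            "feature": features.columns,
            "importance": result.importances_mean,
            "importance_sd": result.importances_std,
        }
    ).sort_values("importance", ascending=False, kind="mergesort", ignore_index=True)
    return out
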