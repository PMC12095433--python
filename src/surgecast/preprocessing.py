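"""Encounter preprocessing: exclusions, imputation, chronological splitting,
comorbidity-code selection/encoding, and dimensionality reduction.

Every fitted statistic (imputation means/modes, code vocabulary, decomposition
loadings) is a pure function of the fitting window — typically the training
days, or train+validation for the final refit before scoring the test window —
so nothing from the future leaks into model inputs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Any, Iterable, Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.linalg import LinearOperator, svds
from sklearn.decomposition import TruncatedSVD

from .config import SplitSpec

__all__ = [
    "exclude_invalid",
    "chronological_split",
    "ImputationModel",
    "fit_imputer",
    "apply_imputer",
    "select_top_n_codes",
    "ComorbidityMatrix",
    "build_onehot_matrix",
    "DecompositionModel",
    "fit_decomposition",
    "tune_n_and_k",
]

DecompositionMethod = Literal["truncated_svd", "pca", "feature_agglomeration"]


# ---------------------------------------------------------------------------
# exclusions and splitting


def exclude_invalid(encounters: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows with a missing surgery type; report removals by reason."""
    missing = encounters["surgery_type"].isna()
    report = {"missing_surgery_type": int(missing.sum()), "n_input": len(encounters), "n_kept": int((~missing).sum())}
    kept = encounters.loc[~missing].reset_index(drop=True)
    return kept, report


def chronological_split(
    encounters: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition rows into train/validation/test purely by day of surgery."""
    day = encounters["day_index"]
    if len(day) and int(day.max()) >= spec.n_days:
        raise ValueError("encounter day_index outside the split calendar")
    train = encounters.loc[day < spec.train_end_day]
    val = encounters.loc[(day >= spec.train_end_day) & (day < spec.val_end_day)]
    test = encounters.loc[day >= spec.val_end_day]
    return tuple(t.reset_index(drop=True) for t in (train, val, test))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# imputation


@dataclass(frozen=True)
class ImputationModel:
    """Per-surgery-type imputation statistics fitted on one window.

    Missing scheduled durations and LOS values are replaced by the mean for
    that surgery type; missing ASA PS by the per-type mode (ties broken to the
    smallest score).  A type absent from the fitting window, or with every
    value missing, falls back to the global mean (numeric) or the literal
    token ``"unknown"`` (ASA PS).
    """

    duration_mean: dict[str, float]
    los_mean: dict[str, float]
    asa_mode: dict[str, float]
    global_duration_mean: float
    global_los_mean: float
    unknown_token: str = "unknown"


def _per_type_mean(table: pd.DataFrame, col: str) -> dict[str, float]:
    means = table.groupby("surgery_type", sort=True)[col].mean()
    return {t: float(v) for t, v in means.items() if np.isfinite(v)}


def _per_type_mode_min(table: pd.DataFrame, col: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for t, grp in table.groupby("surgery_type", sort=True)[col]:
        vals = grp.dropna()
        if len(vals) == 0:
            continue
        counts = Counter(vals)
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))  # tie -> smallest value
        out[t] = float(best[0])
    return out


def fit_imputer(train: pd.DataFrame) -> ImputationModel:
    if len(train) == 0:
        raise ValueError("cannot fit imputer on an empty window")
    return ImputationModel(
        duration_mean=_per_type_mean(train, "scheduled_duration_min"),
        los_mean=_per_type_mean(train, "los_days"),
        asa_mode=_per_type_mode_min(train, "asa_ps"),
        global_duration_mean=float(train["scheduled_duration_min"].mean()),
        global_los_mean=float(train["los_days"].mean()),
    )


def apply_imputer(model: ImputationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing fields from the fitted statistics.  Idempotent."""
    out = table.copy()
    types = out["surgery_type"]

    for col, per_type, global_fallback in (
        ("scheduled_duration_min", model.duration_mean, model.global_duration_mean),
        ("los_days", model.los_mean, model.global_los_mean),
    ):
        missing = out[col].isna()
        if missing.any():
            fill = types[missing].map(per_type).astype(float)
            fill = fill.fillna(global_fallback)
            out.loc[missing, col] = fill

    asa = out["asa_ps"]
    missing = asa.isna() if asa.dtype != object else asa.apply(lambda v: not isinstance(v, str) and pd.isna(v))
    if missing.any():
        fill = types[missing].map(model.asa_mode)
        fill = fill.astype(object).where(fill.notna(), model.unknown_token)
        out["asa_ps"] = out["asa_ps"].astype(object)
        out.loc[missing, "asa_ps"] = fill
    return out


# ---------------------------------------------------------------------------
# comorbidity vocabulary and one-hot encoding


def select_top_n_codes(train: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` most frequent codes in the fitting window, frequency-descending.

    Frequency ties break lexicographically.  If fewer than ``n`` distinct
    codes occur, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: Counter[str] = Counter()
    for codes in train["comorbidity_codes"]:
        counts.update(codes)
    if n > len(counts):
        warnings.warn(
            f"requested top {n} codes but only {len(counts)} distinct codes occur; returning all",
            stacklevel=2,
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [code for code, _ in ranked[:n]]


@dataclass
class ComorbidityMatrix:
    """Sparse binary case x code incidence matrix with an ordered vocabulary."""

    case_ids: list[str]
    vocabulary: list[str]
    matrix: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def sparsity(self) -> float:
        """Fraction of zero entries."""
        n_total = self.matrix.shape[0] * self.matrix.shape[1]
        return 1.0 - self.matrix.nnz / n_total if n_total else 1.0


def build_onehot_matrix(table: pd.DataFrame, vocabulary: Iterable[str]) -> ComorbidityMatrix:
    """Binary incidence over the vocabulary; out-of-vocabulary codes are ignored."""
    vocab = list(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    col_of = {c: j for j, c in enumerate(vocab)}
    indptr = [0]
    indices: list[int] = []
    for codes in table["comorbidity_codes"]:
        row = sorted({col_of[c] for c in codes if c in col_of})
        indices.extend(row)
        indptr.append(len(indices))
    matrix = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.int8), np.asarray(indices, dtype=np.int32), np.asarray(indptr)),
        shape=(len(table), len(vocab)),
    )
    return ComorbidityMatrix(case_ids=list(table["case_id"]), vocabulary=vocab, matrix=matrix)


# ---------------------------------------------------------------------------
# dimensionality reduction


@dataclass
class DecompositionModel:
    """Fitted projection of an n-column binary row onto k component scores."""

    method: DecompositionMethod
    k: int
    vocabulary: list[str]
    components: np.ndarray | None = None  # (k, n) loadings for svd/pca
    mean: np.ndarray | None = None  # column means for pca
    cluster_of: np.ndarray | None = None  # (n,) cluster labels for agglomeration
    cluster_sizes: np.ndarray | None = None
    singular_values: np.ndarray | None = None

    def transform(self, matrix: ComorbidityMatrix) -> np.ndarray:
        if matrix.vocabulary != self.vocabulary:
            raise ValueError("matrix vocabulary does not match the fitted model")
        X = matrix.matrix.astype(np.float64)
        if self.method == "truncated_svd":
            return np.asarray(X @ self.components.T)
        if self.method == "pca":
            scores = np.asarray(X @ self.components.T)
            return scores - self.mean @ self.components.T
        # feature_agglomeration: mean of member columns per cluster
        M = sp.csr_matrix(
            (1.0 / self.cluster_sizes[self.cluster_of], (np.arange(len(self.cluster_of)), self.cluster_of)),
            shape=(len(self.cluster_of), self.k),
        )
        return np.asarray((X @ M).todense())


def _fit_sparse_pca(X: sp.csr_matrix, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a sparse binary matrix without densifying it.

    The column-centered operator ``X - 1 mu^T`` is applied implicitly through a
    LinearOperator, and its top-k singular triplets are extracted with ARPACK.
    """
    n_rows, n_cols = X.shape
    mu = np.asarray(X.mean(axis=0)).ravel()
    ones = np.ones(n_rows)

    def matvec(v: np.ndarray) -> np.ndarray:
        return X @ v - ones * (mu @ v)

    def rmatvec(v: np.ndarray) -> np.ndarray:
        return X.T @ v - mu * v.sum()

    def matmat(V: np.ndarray) -> np.ndarray:
        return X @ V - np.outer(ones, mu @ V)

    def rmatmat(V: np.ndarray) -> np.ndarray:
        return X.T @ V - np.outer(mu, V.sum(axis=0))

    op = LinearOperator(
        (n_rows, n_cols), matvec=matvec, rmatvec=rmatvec, matmat=matmat, rmatmat=rmatmat, dtype=np.float64
    )
    v0 = np.full(min(n_rows, n_cols), 1.0 / np.sqrt(min(n_rows, n_cols)))
    u, s, vt = svds(op, k=k, v0=v0)
    order = np.argsort(-s)
    return vt[order], mu, s[order]


def _fit_agglomeration(X: sp.csr_matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of columns by cosine distance, k clusters."""
    G = np.asarray((X.T @ X).todense(), dtype=np.float64)  # (n_cols, n_cols) Gram
    norms = np.sqrt(np.diag(G))
    norms[norms == 0] = 1.0
    cos = G / np.outer(norms, norms)
    dist = np.clip(1.0 - cos, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    sizes = np.bincount(labels, minlength=k).astype(float)
    sizes[sizes == 0] = 1.0
    return labels, sizes


def fit_decomposition(matrix: ComorbidityMatrix, method: DecompositionMethod, k: int) -> DecompositionModel:
    """Fit a k-component reduction of the one-hot comorbidity matrix.

    ``truncated_svd`` factorizes the raw (uncentered) sparse matrix;
    ``pca`` centers columns implicitly so the matrix is never densified;
    ``feature_agglomeration`` merges similar columns by cosine similarity.
    """
    n_rows, n_cols = matrix.shape
    if k > min(n_rows, n_cols):
        raise ValueError(f"k={k} exceeds matrix dimensions {matrix.shape}")
    X = matrix.matrix.astype(np.float64)
    model = DecompositionModel(method=method, k=k, vocabulary=matrix.vocabulary)
    if method == "truncated_svd":
        svd = TruncatedSVD(n_components=k, algorithm="randomized", random_state=0, n_iter=7)
        svd.fit(X)
        model.components = svd.components_
        model.singular_values = svd.singular_values_
    elif method == "pca":
        components, mu, s = _fit_sparse_pca(X, k)
        model.components = components
        model.mean = mu
        model.singular_values = s
    elif method == "feature_agglomeration":
        labels, sizes = _fit_agglomeration(X, k)
        model.cluster_of = labels
        model.cluster_sizes = sizes
    else:
        raise ValueError(f"unknown method: {method}")
    return model


# ---------------------------------------------------------------------------
# hyperparameter tuning (vocabulary size n and component count k)


def tune_n_and_k(
    train: pd.DataFrame,
    val: pd.DataFrame,
    n_grid: Iterable[int],
    k_grid: Iterable[int],
    methods: Iterable[DecompositionMethod] = ("truncated_svd",),
    mode: Literal["sequential", "joint"] = "sequential",
    forest_spec: Any = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Select vocabulary size n and component count k by validation MSE.

    For each candidate, a decomposition is fitted on the training window, a
    (small) LOS random forest is trained on its scores plus the standard
    feature set, and the validation mean squared error is recorded; the
    argmin wins.  ``sequential`` tunes k at the largest n, then n at the best
    k; ``joint`` sweeps the full product grid.
    """
    from .config import ForestSpec
    from .los import assemble_features, compute_historic_mean_los, evaluate_los, fit_forest, LOSFeatureSchema

    n_grid = sorted(set(int(n) for n in n_grid))
    k_grid = sorted(set(int(k) for k in k_grid))
    if not n_grid or not k_grid:
        raise ValueError("grids must be non-empty")
    if forest_spec is None:
        forest_spec = ForestSpec(n_trees=100, seed=seed)

    historic = compute_historic_mean_los(train)

    def evaluate(method: DecompositionMethod, n: int, k: int) -> float:
        vocab = select_top_n_codes(train, n)
        train_m = build_onehot_matrix(train, vocab)
        if k > min(train_m.shape):
            return float("inf")
        dec = fit_decomposition(train_m, method, k)
        schema = LOSFeatureSchema.fit(train, k)
        Xtr, ytr = assemble_features(train, dec, historic, schema)
        Xva, yva = assemble_features(val, dec, historic, schema)
        model = fit_forest(Xtr, ytr, forest_spec)
        ev = evaluate_los(model, Xva, yva)
        return ev.rmse**2

    evaluations: list[dict[str, Any]] = []

    def record(method: DecompositionMethod, n: int, k: int) -> float:
        mse = evaluate(method, n, k)
        evaluations.append({"method": method, "n": n, "k": k, "val_mse": mse})
        return mse

    for method in methods:
        if mode == "joint":
            for n in n_grid:
                for k in k_grid:
                    record(method, n, k)
        else:
            n_max = n_grid[-1]
            k_scores = {k: record(method, n_max, k) for k in k_grid}
            best_k = min(k_scores, key=lambda k: (k_scores[k], k))
            for n in n_grid[:-1]:
                record(method, n, best_k)

    best = min(evaluations, key=lambda e: (e["val_mse"], e["n"], e["k"]))
    return {"selected": best, "grid": evaluations, "mode": mode}
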