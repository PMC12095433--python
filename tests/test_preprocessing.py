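import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from surgecast import GeneratorConfig, SplitSpec
from surgecast.preprocessing import (
    apply_imputer,
    build_onehot_matrix,
    chronological_split,
    exclude_invalid,
    fit_decomposition,
    fit_imputer,
    select_top_n_codes,
    tune_n_and_k,
)
from surgecast.synthetic import generate_encounters

from conftest import small_config


def toy_table(**cols):
    defaults = {
        "case_id": [f"E{i}" for i in range(len(next(iter(cols.values()))))],
        "comorbidity_codes": [() for _ in next(iter(cols.values()))],
    }
    defaults.update(cols)
    return pd.DataFrame(defaults)


class TestExcludeInvalid:
    def test_no_missing_types_is_identity(self):
        t = toy_table(surgery_type=["A", "B"], day_index=[0, 1])
        out, report = exclude_invalid(t)
        assert out.equals(t)
        assert report["missing_surgery_type"] == 0

    def test_single_missing_type_removed(self):
        t = toy_table(surgery_type=["A", None, "B"], day_index=[0, 1, 2])
        out, report = exclude_invalid(t)
        assert len(out) == 2 and report["missing_surgery_type"] == 1

    def test_all_missing_gives_empty_table(self):
        t = toy_table(surgery_type=[None, None], day_index=[0, 1])
        out, report = exclude_invalid(t)
        assert len(out) == 0 and report["n_kept"] == 0


class TestChronologicalSplit:
    def test_default_split_day_ranges(self):
        t = toy_table(surgery_type=["A"] * 365, day_index=list(range(365)))
        tr, va, te = chronological_split(t, SplitSpec())
        assert (len(tr), len(va), len(te)) == (225, 70, 70)
        assert tr["day_index"].max() == 224 and va["day_index"].min() == 225
        assert te["day_index"].min() == 295

    def test_minimal_three_day_split(self):
        t = toy_table(surgery_type=list("ABC"), day_index=[0, 1, 2])
        tr, va, te = chronological_split(t, SplitSpec(train_end_day=1, val_end_day=2, n_days=3))
        assert len(tr) == len(va) == len(te) == 1

    @given(days=st.lists(st.integers(0, 364), min_size=1, max_size=60))
    def test_split_is_a_partition(self, days):
        t = toy_table(surgery_type=["A"] * len(days), day_index=days)
        tr, va, te = chronological_split(t, SplitSpec())
        assert len(tr) + len(va) + len(te) == len(t)
        recombined = pd.concat([tr, va, te]).sort_values(["day_index", "case_id"]).reset_index(drop=True)
        assert sorted(recombined["case_id"]) == sorted(t["case_id"])

    def test_out_of_calendar_rejected(self):
        t = toy_table(surgery_type=["A"], day_index=[400])
        with pytest.raises(ValueError):
            chronological_split(t, SplitSpec())


def imputer_toy():
    return pd.DataFrame(
        {
            "case_id": [f"E{i}" for i in range(5)],
            "surgery_type": ["A", "A", "A", "B", "C"],
            "scheduled_duration_min": [30.0, 60.0, np.nan, 10.0, np.nan],
            "los_days": [2.0, np.nan, 4.0, 1.0, np.nan],
            "asa_ps": [2.0, 2.0, 3.0, np.nan, np.nan],
            "comorbidity_codes": [()] * 5,
        }
    )


class TestImputation:
    def test_type_mean_duration(self):
        model = fit_imputer(imputer_toy())
        out = apply_imputer(model, imputer_toy())
        assert out.loc[2, "scheduled_duration_min"] == 45.0  # mean of 30, 60

    def test_type_mean_los(self):
        model = fit_imputer(imputer_toy())
        out = apply_imputer(model, imputer_toy())
        assert out.loc[1, "los_days"] == 3.0  # mean of 2, 4

    def test_type_mode_asa_with_tie_to_smallest(self):
        t = imputer_toy()
        t.loc[3, "asa_ps"] = 3.0  # type A now {2,2,3}, B has 3, C missing
        t2 = pd.concat(
            [t, pd.DataFrame({"case_id": ["E9"], "surgery_type": ["A"], "scheduled_duration_min": [5.0],
                              "los_days": [1.0], "asa_ps": [3.0], "comorbidity_codes": [()]})],
            ignore_index=True,
        )  # A: {2,2,3,3} -> tie -> 2
        model = fit_imputer(t2)
        assert model.asa_mode["A"] == 2.0

    def test_all_missing_type_gets_unknown_token(self):
        model = fit_imputer(imputer_toy())
        out = apply_imputer(model, imputer_toy())
        assert out.loc[4, "asa_ps"] == "unknown"  # type C has no observed ASA

    def test_unseen_type_falls_back_to_global(self):
        model = fit_imputer(imputer_toy())
        new = pd.DataFrame(
            {
                "case_id": ["X"],
                "surgery_type": ["Z"],
                "scheduled_duration_min": [np.nan],
                "los_days": [np.nan],
                "asa_ps": [np.nan],
                "comorbidity_codes": [()],
            }
        )
        out = apply_imputer(model, new)
        assert out.loc[0, "scheduled_duration_min"] == pytest.approx(np.nanmean([30, 60, 10]))
        assert out.loc[0, "asa_ps"] == "unknown"

    def test_idempotent(self):
        model = fit_imputer(imputer_toy())
        once = apply_imputer(model, imputer_toy())
        twice = apply_imputer(model, once)
        assert twice.equals(once)


class TestVocabulary:
    def test_top_n_by_frequency(self):
        t = toy_table(
            surgery_type=["A"] * 9,
            day_index=range(9),
            comorbidity_codes=[("x",)] * 5 + [("y",)] * 3 + [("z",)],
        )
        assert select_top_n_codes(t, 2) == ["x", "y"]

    def test_frequency_tie_breaks_lexicographically(self):
        t = toy_table(
            surgery_type=["A"] * 6,
            day_index=range(6),
            comorbidity_codes=[("x",)] * 3 + [("y",)] * 3,
        )
        assert select_top_n_codes(t, 1) == ["x"]

    def test_n_larger_than_vocabulary_returns_all(self):
        t = toy_table(surgery_type=["A"], day_index=[0], comorbidity_codes=[("a", "b")])
        assert sorted(select_top_n_codes(t, 1750)) == ["a", "b"]


class TestOneHot:
    def test_rows_follow_vocabulary(self):
        t = toy_table(surgery_type=["A"], day_index=[0], comorbidity_codes=[("a", "b")])
        m = build_onehot_matrix(t, ["a", "c"])
        assert m.matrix.toarray().tolist() == [[1, 0]]

    def test_out_of_vocabulary_gives_zero_row(self):
        t = toy_table(surgery_type=["A"], day_index=[0], comorbidity_codes=[("q",)])
        m = build_onehot_matrix(t, ["a", "c"])
        assert m.matrix.nnz == 0

    def test_synthetic_default_matrix_is_sparse(self):
        enc, _, _ = generate_encounters(small_config(seed=4))
        vocab = select_top_n_codes(enc, 80)
        m = build_onehot_matrix(enc, vocab)
        assert m.sparsity >= 0.90  # ~6 of 80 codes per case

    def test_incidence_definition(self):
        t = toy_table(surgery_type=["A", "B"], day_index=[0, 1], comorbidity_codes=[("a", "c"), ("b",)])
        m = build_onehot_matrix(t, ["a", "b", "c"])
        dense = m.matrix.toarray()
        for i, codes in enumerate(t["comorbidity_codes"]):
            for j, code in enumerate(m.vocabulary):
                assert dense[i, j] == (1 if code in codes else 0)


class TestDecomposition:
    @staticmethod
    def random_matrix(n_rows=50, n_cols=20, seed=0):
        rng = np.random.default_rng(seed)
        t = toy_table(
            surgery_type=["A"] * n_rows,
            day_index=range(n_rows),
            comorbidity_codes=[
                tuple(f"c{j}" for j in np.nonzero(rng.random(n_cols) < 0.3)[0]) for _ in range(n_rows)
            ],
        )
        return build_onehot_matrix(t, [f"c{j}" for j in range(n_cols)])

    def test_rank_one_matrix_reconstructed_exactly(self):
        t = toy_table(surgery_type=["A"] * 4, day_index=range(4), comorbidity_codes=[("a", "b")] * 4)
        m = build_onehot_matrix(t, ["a", "b"])
        model = fit_decomposition(m, "truncated_svd", 1)
        scores = model.transform(m)
        recon = scores @ model.components
        assert np.allclose(recon, m.matrix.toarray(), atol=1e-10)

    def test_truncated_svd_matches_dense_oracle(self):
        m = self.random_matrix()
        model = fit_decomposition(m, "truncated_svd", 5)
        dense_sv = np.linalg.svd(m.matrix.toarray(), compute_uv=False)
        assert np.allclose(model.singular_values, dense_sv[:5], atol=1e-8)

    def test_sparse_pca_matches_dense_centered_oracle(self):
        m = self.random_matrix(seed=3)
        model = fit_decomposition(m, "pca", 4)
        X = m.matrix.toarray().astype(float)
        Xc = X - X.mean(axis=0)
        dense_sv = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(np.sort(model.singular_values), np.sort(dense_sv[:4]), atol=1e-6)
        # scores agree up to per-component sign
        dense_scores = Xc @ np.linalg.svd(Xc)[2][:4].T
        scores = model.transform(m)
        for j in range(4):
            assert min(
                np.max(np.abs(scores[:, j] - dense_scores[:, j])),
                np.max(np.abs(scores[:, j] + dense_scores[:, j])),
            ) < 1e-6

    def test_agglomeration_merges_identical_columns(self):
        t = toy_table(
            surgery_type=["A"] * 6,
            day_index=range(6),
            comorbidity_codes=[("a", "b"), ("a", "b"), ("a", "b"), ("c",), ("c",), ("d",)],
        )
        m = build_onehot_matrix(t, ["a", "b", "c", "d"])
        model = fit_decomposition(m, "feature_agglomeration", 3)
        # the perfectly correlated columns a and b end up in one cluster
        assert model.cluster_of[0] == model.cluster_of[1]
        assert model.transform(m).shape == (6, 3)

    def test_k_exceeding_dimensions_rejected(self):
        m = self.random_matrix(n_rows=10, n_cols=5)
        with pytest.raises(ValueError):
            fit_decomposition(m, "truncated_svd", 6)

    def test_twelve_components_from_synthetic_vocabulary(self):
        enc, _, _ = generate_encounters(small_config(seed=4))
        vocab = select_top_n_codes(enc, 60)
        m = build_onehot_matrix(enc, vocab)
        model = fit_decomposition(m, "truncated_svd", 12)
        assert model.transform(m).shape == (len(enc), 12)


class TestTuning:
    def test_single_point_grid_selected(self):
        enc, _, _ = generate_encounters(small_config(seed=6, n_days=60))
        split = SplitSpec(train_end_day=40, val_end_day=50, n_days=60)
        tr, va, _ = chronological_split(enc, split)
        report = tune_n_and_k(tr, va, n_grid=[30], k_grid=[4])
        assert report["selected"]["n"] == 30 and report["selected"]["k"] == 4
        assert len(report["grid"]) == 1

    def test_no_code_signal_gives_flat_validation_mse(self):
        """With the comorbidity->LOS effect switched off, vocabulary size
        should not matter: validation MSE is flat in n up to forest noise."""
        for seed in range(3):
            enc, _, _ = generate_encounters(small_config(seed=seed, comorbidity_los_coef=0.0))
            split = SplitSpec(train_end_day=90, val_end_day=115, n_days=140)
            tr, va, _ = chronological_split(enc, split)
            report = tune_n_and_k(tr, va, n_grid=[5, 40], k_grid=[4], mode="joint", seed=seed)
            mses = [e["val_mse"] for e in report["grid"]]
            assert (max(mses) - min(mses)) / min(mses) < 0.15

    def test_sequential_mode_covers_k_then_n(self):
        enc, _, _ = generate_encounters(small_config(seed=6, n_days=60))
        split = SplitSpec(train_end_day=40, val_end_day=50, n_days=60)
        tr, va, _ = chronological_split(enc, split)
        report = tune_n_and_k(tr, va, n_grid=[10, 30], k_grid=[2, 4], mode="sequential")
        # k tuned at n=30 (2 points), then the remaining n at the chosen k
        assert len(report["grid"]) == 3
        assert report["selected"]["val_mse"] == min(e["val_mse"] for e in report["grid"])
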