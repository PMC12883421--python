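import numpy as np
import pandas as pd
import pytest

from mpnmorph.model import (
    Standardizer,
    assign_label,
    kruskal_wallis_select,
    predict_nos,
    repeated_cv,
    train_svm,
)
from mpnmorph.synthgen import generate_feature_cohort
from .oracles import brute_kruskal_h


# --- Kruskal-Wallis screening ------------------------------------------------

def test_kw_h_matches_hand_rank_oracle(rng):
    for _ in range(100):
        sizes = rng.integers(3, 8, size=3)
        groups = [list(np.round(rng.normal(0, 1, s), 1)) for s in sizes]
        X = pd.DataFrame({"f": np.concatenate(groups)})
        y = np.repeat(["a", "b", "c"], sizes)
        res = kruskal_wallis_select(X, y)
        assert res.table.loc["f", "H"] == pytest.approx(
            brute_kruskal_h(groups), rel=1e-9
        )


def test_kw_constant_feature_not_selected():
    X = pd.DataFrame({"const": np.ones(12), "varied": np.arange(12.0)})
    y = np.repeat(["a", "b", "c"], 4)
    res = kruskal_wallis_select(X, y)
    assert res.table.loc["const", "p"] == 1.0
    assert "const" not in res.selected


def test_kw_group_preconditions():
    X = pd.DataFrame({"f": np.arange(6.0)})
    with pytest.raises(ValueError):
        kruskal_wallis_select(X, ["a"] * 6)
    with pytest.raises(ValueError):
        kruskal_wallis_select(X, ["a", "a", "a", "a", "a", "b"])


# --- standardization ---------------------------------------------------------

def test_standardizer_round_trip_and_train_moments(rng):
    X = pd.DataFrame(rng.normal(3, 2, (30, 4)), columns=list("abcd"))
    std = Standardizer().fit(X)
    Z = std.transform(X)
    assert np.abs(Z.mean(axis=0)).max() < 1e-10
    assert Z.std(axis=0, ddof=1).to_numpy() == pytest.approx(np.ones(4))
    back = std.inverse_transform(Z)
    assert np.allclose(back.to_numpy(), X.to_numpy())


def test_standardizer_zero_variance_names_column(rng):
    X = pd.DataFrame({"ok": rng.normal(size=10), "flat": np.ones(10)})
    with pytest.raises(ValueError, match="flat"):
        Standardizer().fit(X)


def test_standardizer_feature_mismatch(rng):
    X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
    std = Standardizer().fit(X)
    with pytest.raises(ValueError):
        std.transform(X.rename(columns={"b": "c"}))


# --- SVM ---------------------------------------------------------------------

def _separable_cohort():
    rng = np.random.default_rng(0)
    centers = {"pre-PMF": (0, 0), "PV": (8, 0), "ET": (0, 8)}
    rows, labels = [], []
    for lab, (cx, cy) in centers.items():
        for _ in range(12):
            rows.append(rng.normal((cx, cy), 0.5))
            labels.append(lab)
    X = pd.DataFrame(rows, columns=["u", "v"])
    return X, np.array(labels)


def test_svm_separable_training_accuracy_and_simplex():
    X, y = _separable_cohort()
    model = train_svm(X, y, seed=0)
    preds = model.predict(X)
    assert (np.array(preds) == y).mean() == 1.0
    scores = model.score_matrix(X)
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)
    assert (scores >= 0).all()


def test_svm_single_class_rejected():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 2)))
    with pytest.raises(ValueError):
        train_svm(X, ["PV"] * 8)


def test_svm_deterministic_under_seed():
    X, y = _separable_cohort()
    s1 = train_svm(X, y, seed=5).score_matrix(X)
    s2 = train_svm(X, y, seed=5).score_matrix(X)
    assert np.array_equal(s1, s2)


# --- score assignment --------------------------------------------------------

@pytest.mark.parametrize(
    "scores,expected",
    [
        ((0.13, 0.76, 0.11), "PV"),
        ((0.30, 0.35, 0.35), "ET"),   # tie -> last maximal class
        ((1.0, 0.0, 0.0), "pre-PMF"),
        ((0.35, 0.35, 0.30), "PV"),
    ],
)
def test_assign_label_argmax_with_tie_rule(scores, expected):
    assert assign_label(scores) == expected


# --- repeated cross-validation ----------------------------------------------

@pytest.fixture(scope="module")
def cohort(default_profiles):
    return generate_feature_cohort(default_profiles, (10, 12, 14), seed=3)


def test_cv_folds_partition_cohort_each_repeat(cohort):
    X, y = cohort
    rep = repeated_cv(X, y, k=3, repeats=2, seed=0)
    for r in range(2):
        sub = rep.predictions[rep.predictions["repeat"] == r]
        assert sorted(sub["patient_id"]) == sorted(X.index)
        assert sub["patient_id"].is_unique
    assert len(rep.fold_metrics) == 6


def test_cv_deterministic_under_seed(cohort):
    X, y = cohort
    a = repeated_cv(X, y, k=3, repeats=2, seed=11)
    b = repeated_cv(X, y, k=3, repeats=2, seed=11)
    pd.testing.assert_frame_equal(a.predictions, b.predictions)
    assert a.auc_tot_mean == b.auc_tot_mean


def test_cv_rejects_k_larger_than_smallest_class(cohort):
    X, y = cohort
    with pytest.raises(ValueError, match="smaller k"):
        repeated_cv(X, y, k=11, repeats=1, seed=0)
    with pytest.raises(ValueError, match="smaller k"):
        repeated_cv(X, y, k=len(X), repeats=1, seed=0)  # leave-one-out


def test_nested_selection_uses_training_folds_only(cohort):
    """With nested selection, the per-fold feature set equals a
    recomputed Kruskal-Wallis screen on that fold's training patients."""
    X, y = cohort
    rep = repeated_cv(X, y, k=3, repeats=1, seed=2, nested_selection=True)
    for _, fold_row in rep.fold_metrics.iterrows():
        test_ids = set(
            rep.predictions.loc[
                (rep.predictions["repeat"] == fold_row["repeat"])
                & (rep.predictions["fold"] == fold_row["fold"]),
                "patient_id",
            ]
        )
        train_mask = ~X.index.isin(test_ids)
        expected = kruskal_wallis_select(X[train_mask], y[train_mask]).selected
        assert fold_row["selected"].split(";") == expected


def test_cv_discriminates_separated_cohort(cohort):
    X, y = cohort
    rep = repeated_cv(X, y, k=5, repeats=2, seed=0)
    assert rep.auc_tot_mean >= 0.8
    assert rep.accuracy_mean >= 0.8


# --- NOS prediction ----------------------------------------------------------

def test_predict_nos_scores_and_feature_mismatch(cohort):
    X, y = cohort
    model = train_svm(X, y, seed=0)
    nos = X.iloc[:4]
    scored = predict_nos(model, nos)
    assert len(scored) == 4
    for s in scored:
        assert sum(s.scores.values()) == pytest.approx(1.0)
        assert s.predicted_label == assign_label(
            [s.scores[c] for c in model.class_order]
        )
    with pytest.raises(ValueError, match="feature"):
        predict_nos(model, nos.drop(columns=["cellularity"]))
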