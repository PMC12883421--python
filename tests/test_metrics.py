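import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mpnmorph.metrics import (
    concordance,
    ks_compare,
    micro_metrics,
    ovr_auc,
    weighted_auc,
)
from mpnmorph.reference import CLASS_SIZES, REPORTED_CLASS_AUC, nos_validation_table
from .oracles import brute_ovr_auc


# --- one-vs-rest AUC ---------------------------------------------------------

def test_ovr_auc_perfect_and_degenerate_ranking():
    y = ["PV", "PV", "ET", "ET"]
    assert ovr_auc([0.9, 0.8, 0.1, 0.2], y, "PV") == 1.0
    assert ovr_auc([0.5] * 4, y, "PV") == 0.5
    with pytest.raises(ValueError):
        ovr_auc([0.1, 0.2], ["PV", "PV"], "PV")


def test_ovr_auc_six_patient_hand_example():
    scores = [0.9, 0.6, 0.6, 0.4, 0.3, 0.2]
    y = ["PV", "PV", "ET", "PV", "ET", "ET"]
    # pairs: (0.9 vs 0.6, 0.3, 0.2)=3, (0.6 vs tie 0.6=0.5, 0.3, 0.2)=2.5,
    # (0.4 vs 0.6=0, 0.3, 0.2)=2 -> 7.5 / 9
    assert ovr_auc(scores, y, "PV") == pytest.approx(7.5 / 9)
    assert ovr_auc(scores, y, "PV") == pytest.approx(
        brute_ovr_auc(scores, y, "PV")
    )


def test_ovr_auc_matches_pair_counting_and_sklearn(rng):
    for _ in range(100):
        n = int(rng.integers(4, 13))
        y = rng.choice(["PV", "other"], size=n)
        if len(set(y)) < 2:
            y[0], y[1] = "PV", "other"
        scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid -> ties
        mine = ovr_auc(scores, y, "PV")
        assert mine == pytest.approx(brute_ovr_auc(list(scores), list(y), "PV"))
        assert mine == pytest.approx(roc_auc_score((y == "PV").astype(int), scores))


# --- weighted AUC ------------------------------------------------------------

def test_weighted_auc_reproduces_reported_total():
    order = ("pre-PMF", "PV", "ET")
    total = weighted_auc(
        [REPORTED_CLASS_AUC[c] for c in order],
        [CLASS_SIZES[c] for c in order],
    )
    assert total == pytest.approx(0.7042, abs=5e-4)
    assert round(total, 2) == 0.70


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(0.0, 1.0), st.integers(1, 50)),
        min_size=1, max_size=5,
    )
)
def test_weighted_auc_is_convex_combination(pairs):
    aucs = [a for a, _ in pairs]
    counts = [n for _, n in pairs]
    tot = weighted_auc(aucs, counts)
    assert min(aucs) - 1e-12 <= tot <= max(aucs) + 1e-12


def test_weighted_auc_edge_cases():
    assert weighted_auc([0.7, 0.7], [5, 10]) == pytest.approx(0.7)
    assert weighted_auc([0.64], [13]) == pytest.approx(0.64)
    with pytest.raises(ValueError):
        weighted_auc([0.5, 0.6], [10])


# --- micro metrics -----------------------------------------------------------

def test_micro_metrics_perfect_predictions():
    cm = np.diag([5, 7, 9])
    m = micro_metrics([cm])
    assert (m.sensitivity, m.specificity, m.precision) == (1.0, 1.0, 1.0)
    assert m.f1 == 1.0 and m.gmean == 1.0 and m.accuracy == 1.0


def test_micro_metrics_all_one_class_on_balanced_set():
    cm = np.zeros((3, 3))
    cm[:, 0] = 10  # everything predicted as the first class
    m = micro_metrics([cm])
    assert m.sensitivity == pytest.approx(1 / 3)
    assert m.accuracy == pytest.approx(1 / 3)


def test_micro_identity_on_random_confusions(rng):
    """Σfp = Σfn on any single-label multiclass confusion, so micro
    precision = micro sensitivity = accuracy exactly."""
    for _ in range(200):
        k = int(rng.integers(2, 5))
        cm = rng.integers(0, 20, size=(k, k)).astype(float)
        if cm.sum() == 0:
            cm[0, 0] = 1
        m = micro_metrics([cm])
        assert m.precision == m.sensitivity == m.accuracy


def test_micro_metrics_gmean_formula_variants():
    cm = np.array([[8, 2, 0], [1, 7, 2], [0, 3, 7]], dtype=float)
    prod = micro_metrics([cm])
    root = micro_metrics([cm], gmean_sqrt=True)
    assert prod.gmean == pytest.approx(prod.sensitivity * prod.specificity)
    assert root.gmean == pytest.approx(np.sqrt(prod.sensitivity * prod.specificity))


def test_micro_metrics_zero_denominator_is_named():
    with pytest.raises(ValueError, match="sensitivity"):
        micro_metrics([np.zeros((3, 3))])


# --- Kolmogorov-Smirnov cellularity comparison -------------------------------

def test_ks_identical_and_disjoint_samples():
    same = [0.4, 0.5, 0.6, 0.7]
    res = ks_compare(same, same)
    assert res.statistic == 0.0
    assert res.mean_abs_difference == 0.0
    res2 = ks_compare([0.1, 0.2], [0.8, 0.9])
    assert res2.statistic == 1.0
    with pytest.raises(ValueError):
        ks_compare([], [0.5])


def test_ks_difference_histogram_bins():
    auto = [0.50, 0.55, 0.80, 0.45]
    ref = [0.55, 0.40, 0.45, 0.44]
    res = ks_compare(auto, ref)
    assert res.difference_histogram.sum() == 4
    assert res.difference_histogram.tolist() == [2, 1, 0, 1]


def test_ks_null_p_values_are_calibrated(rng):
    """Under the null (both samples from one distribution) the test
    rejects at alpha=0.05 about 5% of the time and p averages near 1/2."""
    from scipy.stats import binom

    ps = []
    for _ in range(200):
        ps.append(ks_compare(rng.normal(size=50), rng.normal(size=50)).p_value)
    rejections = sum(p < 0.05 for p in ps)
    upper = binom.ppf(0.995, 200, 0.05)
    assert rejections <= upper
    assert 0.35 < np.mean(ps) < 0.65


# --- concordance -------------------------------------------------------------

def test_followup_concordance_on_validation_table():
    tab = nos_validation_table()
    res = concordance(
        tab["reported_prediction"].tolist(), tab["followup"].tolist(),
        rule="followup",
    )
    assert (res.n_eligible, res.n_concordant) == (8, 4)
    assert res.rate == 0.5


def test_histology_concordance_policies_bracket_the_rules():
    tab = nos_validation_table()
    preds = tab["reported_prediction"].tolist()
    generous = concordance(preds, tab["histology"].tolist(),
                           rule="histology", histology_policy="any_listed")
    strict = concordance(preds, tab["histology"].tolist(),
                         rule="histology", histology_policy="single_label_only")
    assert generous.n_concordant == 11 and generous.n_eligible == 13
    assert strict.n_concordant == 7 and strict.n_eligible == 13


def test_concordance_edge_cases():
    assert concordance(["PV"], ["PV"], rule="followup").rate == 1.0
    with pytest.raises(ValueError):
        concordance(["PV", "ET"], ["NA", "NA"], rule="followup")
    with pytest.raises(ValueError):
        concordance(["PV"], ["XYZ"], rule="followup")
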