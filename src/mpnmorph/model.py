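"""Feature screening, linear-SVM classification and repeated CV.

The modelling stage follows the study design: a Kruskal–Wallis screen
keeps features whose distribution differs across the three subtypes
(p < 0.05), selected features are z-scored with training-set parameters,
and a linear-kernel SVM produces per-class scores mapped onto the
probability simplex (pairwise-coupling estimates), so each patient
receives three scores summing to 1.  Evaluation uses stratified 5-fold
cross-validation repeated 5 times; MPN-NOS patients are assigned to the
subtype with the highest score, ties broken by taking the *last* maximal
class in the fixed order (pre-PMF, PV, ET).

By default the screen runs once on the full cohort before CV, matching
the study; ``nested_selection=True`` instead repeats the screen inside
each training fold (no test-fold leakage).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .metrics import MicroMetrics, micro_metrics, ovr_auc, weighted_auc
from .profiles import CLASS_ORDER

__all__ = [
    "SelectionResult",
    "Standardizer",
    "ClassScores",
    "CVReport",
    "FittedModel",
    "kruskal_wallis_select",
    "train_svm",
    "assign_label",
    "repeated_cv",
    "predict_nos",
]


# ---------------------------------------------------------------------------
# Kruskal–Wallis screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    table: pd.DataFrame  # index: feature; columns: H, p
    selected: list[str]
    alpha: float


def kruskal_wallis_select(
    X: pd.DataFrame, y: Sequence[str], alpha: float = 0.05
) -> SelectionResult:
    """Per-feature Kruskal–Wallis test across label groups; keep p < alpha.

    Uses the tie-corrected H statistic with the chi-square approximation.
    A feature constant across all patients gets H = 0, p = 1.  Raises
    ``ValueError`` with fewer than two groups or a group of fewer than
    two observations.
    """
    yy = np.asarray(y)
    groups = pd.unique(yy)
    if groups.size < 2:
        raise ValueError("Kruskal-Wallis needs at least two label groups")
    counts = pd.Series(yy).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    rows = {}
    for col in X.columns:
        samples = [X.loc[yy == g, col].to_numpy() for g in groups]
        if X[col].nunique() <= 1:  # constant feature: no contrast
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        rows[col] = (float(h), float(p))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["H", "p"])
    table.index.name = "feature"
    selected = table.index[table["p"] < alpha].tolist()
    return SelectionResult(table=table, selected=selected, alpha=alpha)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Column-wise z-scoring with training-set mean/SD (n−1 denominator).

    ``fit`` raises on zero-SD columns, naming them; ``inverse_transform``
    undoes ``transform`` exactly.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd.index[sd <= 0].tolist()
        if zero:
            raise ValueError(f"zero-variance column(s) cannot be standardized: {zero}")
        self.mean_, self.sd_ = mean, sd
        return self

    def _check(self, X: pd.DataFrame) -> None:
        if self.mean_ is None:
            raise RuntimeError("Standardizer is not fitted")
        if list(X.columns) != list(self.mean_.index):
            raise ValueError("feature columns do not match the fitted standardizer")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        self._check(Z)
        return Z * self.sd_ + self.mean_


# ---------------------------------------------------------------------------
# Linear SVM with simplex scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassScores:
    """Per-class scores (summing to 1) and the assigned label."""

    patient_id: str
    scores: dict[str, float]
    predicted_label: str


def assign_label(
    scores: Sequence[float],
    class_order: Sequence[str] = CLASS_ORDER,
    tol: float = 1e-9,
) -> str:
    """Argmax over the score simplex; ties go to the *last* maximal class
    in ``class_order``."""
    s = np.asarray(scores, dtype=float)
    if s.size != len(class_order):
        raise ValueError("one score per class is required")
    m = s.max()
    idx = max(i for i, v in enumerate(s) if v >= m - tol)
    return class_order[idx]


@dataclass
class FittedModel:
    """A standardizer + linear SVM fitted on (selected) features."""

    standardizer: Standardizer
    svc: SVC
    feature_names: list[str]
    class_order: tuple[str, ...] = CLASS_ORDER

    def score_matrix(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "feature set does not match the trained model: "
                f"expected {self.feature_names}, got {list(X.columns)}"
            )
        Z = self.standardizer.transform(X)
        proba = self.svc.predict_proba(Z.to_numpy())
        order = [list(self.svc.classes_).index(c) for c in self.class_order]
        return proba[:, order]

    def predict(self, X: pd.DataFrame) -> list[str]:
        return [assign_label(row, self.class_order) for row in self.score_matrix(X)]


def train_svm(
    X: pd.DataFrame, y: Sequence[str], seed: int = 0, C: float = 1.0
) -> FittedModel:
    """Fit the standardizer + linear-kernel SVM on a cohort.

    Scores are pairwise-coupling probability estimates, so every
    patient's class scores form a simplex.  Deterministic under a fixed
    seed.  Raises ``ValueError`` on single-class input.
    """
    yy = np.asarray(y)
    if pd.unique(yy).size < 2:
        raise ValueError("training requires at least two classes")
    std = Standardizer().fit(X)
    svc = SVC(kernel="linear", C=C, probability=True,
              random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        # pairwise-coupling probability estimates are the intended score
        # mapping; sklearn 1.9 warns about the parameter's future removal
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(std.transform(X).to_numpy(), yy)
    return FittedModel(standardizer=std, svc=svc, feature_names=list(X.columns))


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold/per-repeat predictions and the aggregated study metrics."""

    predictions: pd.DataFrame  # repeat, fold, patient_id, true, predicted, scores
    fold_metrics: pd.DataFrame  # repeat, fold, per-class AUC, weighted AUC
    per_class_auc_mean: dict[str, float]
    per_class_auc_sd: dict[str, float]
    auc_tot_mean: float
    auc_tot_sd: float
    accuracy_mean: float
    accuracy_sd: float
    micro: MicroMetrics
    k: int
    repeats: int
    seed: int
    selected_features: list[str] = field(default_factory=list)
    nested_selection: bool = False

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "nested_selection": self.nested_selection,
            "selected_features": self.selected_features,
            "auc_tot_mean": self.auc_tot_mean,
            "auc_tot_sd": self.auc_tot_sd,
            "per_class_auc_mean": self.per_class_auc_mean,
            "per_class_auc_sd": self.per_class_auc_sd,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "micro_sensitivity": self.micro.sensitivity,
            "micro_specificity": self.micro.specificity,
            "micro_precision": self.micro.precision,
            "micro_f1": self.micro.f1,
            "micro_gmean": self.micro.gmean,
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def repeated_cv(
    X: pd.DataFrame,
    y: Sequence[str],
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    C: float = 1.0,
    nested_selection: bool = False,
    alpha: float = 0.05,
    gmean_sqrt: bool = False,
    class_order: Sequence[str] = CLASS_ORDER,
) -> CVReport:
    """Stratified k-fold CV repeated ``repeats`` times.

    The standardizer and SVM are fitted on training folds only; with
    ``nested_selection`` the Kruskal–Wallis screen also runs inside each
    training fold (an empty screen falls back to all columns).  AUCs are
    averaged over all folds and repeats; accuracy and the micro metrics
    over the per-repeat aggregated test predictions, as the study
    reports.  Raises ``ValueError`` when any class is smaller than k.
    """
    yy = np.asarray(y)
    present = [c for c in class_order if (yy == c).any()]
    counts = pd.Series(yy).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(
            f"class(es) {small} have fewer than k={k} members; "
            "stratified folding impossible — use a smaller k"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=k, n_repeats=repeats, random_state=int(seed) % (2**31)
    )

    pred_rows = []
    fold_rows = []
    for split_idx, (tr, te) in enumerate(splitter.split(X, yy)):
        rep, fold = divmod(split_idx, k)
        X_tr, X_te = X.iloc[tr], X.iloc[te]
        y_tr, y_te = yy[tr], yy[te]
        if nested_selection:
            sel = kruskal_wallis_select(X_tr, y_tr, alpha=alpha).selected
            if not sel:
                sel = list(X.columns)
        else:
            sel = list(X.columns)
        # columns constant within this training fold carry no signal and
        # cannot be z-scored; drop them for the fold
        sel = [c for c in sel if X_tr[c].std(ddof=1) > 0]
        if not sel:
            raise ValueError("all features are constant in a training fold")
        X_tr, X_te = X_tr[sel], X_te[sel]
        model = train_svm(X_tr, y_tr, seed=seed, C=C)
        scores = model.score_matrix(X_te)
        preds = [assign_label(row, class_order) for row in scores]

        fold_entry = {"repeat": rep, "fold": fold, "selected": ";".join(sel)}
        per_class = []
        fold_counts = []
        for ci, cls in enumerate(class_order):
            auc_c = ovr_auc(scores[:, ci], y_te, cls)
            fold_entry[f"auc_{cls}"] = auc_c
            per_class.append(auc_c)
            fold_counts.append(int((y_te == cls).sum()))
        fold_entry["auc_tot"] = weighted_auc(per_class, fold_counts)
        fold_rows.append(fold_entry)

        for i, idx in enumerate(te):
            row = {
                "repeat": rep,
                "fold": fold,
                "patient_id": str(X.index[idx]),
                "true": yy[idx],
                "predicted": preds[i],
            }
            for ci, cls in enumerate(class_order):
                row[f"score_{cls}"] = float(scores[i, ci])
            pred_rows.append(row)

    predictions = pd.DataFrame(pred_rows)
    fold_metrics = pd.DataFrame(fold_rows)

    confusions = []
    for rep in range(repeats):
        sub = predictions[predictions["repeat"] == rep]
        cm = np.zeros((len(class_order), len(class_order)), dtype=float)
        ci = {c: i for i, c in enumerate(class_order)}
        for t, p in zip(sub["true"], sub["predicted"]):
            cm[ci[t], ci[p]] += 1
        confusions.append(cm)
    micro = micro_metrics(confusions, gmean_sqrt=gmean_sqrt)

    return CVReport(
        predictions=predictions,
        fold_metrics=fold_metrics,
        per_class_auc_mean={
            c: float(fold_metrics[f"auc_{c}"].mean()) for c in class_order
        },
        per_class_auc_sd={
            c: float(fold_metrics[f"auc_{c}"].std(ddof=1)) for c in class_order
        },
        auc_tot_mean=float(fold_metrics["auc_tot"].mean()),
        auc_tot_sd=float(fold_metrics["auc_tot"].std(ddof=1)),
        accuracy_mean=micro.accuracy,
        accuracy_sd=micro.accuracy_sd,
        micro=micro,
        k=k,
        repeats=repeats,
        seed=seed,
        nested_selection=nested_selection,
    )


def predict_nos(model: FittedModel, X_nos: pd.DataFrame) -> list[ClassScores]:
    """Score MPN-NOS patients with a model trained on the 3-class cohort
    and assign each to the highest-scoring subtype (tie rule: last
    maximal class in the fixed order)."""
    score_mat = model.score_matrix(X_nos)
    out = []
    for pid, row in zip(X_nos.index, score_mat):
        out.append(
            ClassScores(
                patient_id=str(pid),
                scores={c: float(v) for c, v in zip(model.class_order, row)},
                predicted_label=assign_label(row, model.class_order),
            )
        )
    return out
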