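"""Multiclass evaluation metrics and agreement analyses.

Implements the evaluation quantities of the classification study in
their stated forms: per-class one-vs-rest rank AUC, the label-weighted
multiclass AUC, accuracy, micro-averaged sensitivity / specificity /
precision from one-vs-rest confusion counts summed over classes, micro
F1 = 2·S·P/(S+P) and micro G-mean (the stated product S·Spec by default,
with the conventional √(S·Spec) behind a flag).  Also the two-sample
Kolmogorov–Smirnov comparison of automatic vs pathologist cellularity
and label-concordance rates against histology or follow-up references.

Note: for single-label multiclass predictions the summed one-vs-rest
confusions satisfy Σfp = Σfn, so micro precision = micro sensitivity =
accuracy algebraically; this identity is asserted as a property test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata


__all__ = [
    "MicroMetrics",
    "ConcordanceResult",
    "KSResult",
    "ovr_auc",
    "weighted_auc",
    "micro_metrics",
    "ks_compare",
    "concordance",
]


def ovr_auc(scores: Sequence[float], y: Sequence[str], positive_class: str) -> float:
    """One-vs-rest AUC of the positive-class score, Mann–Whitney rank form.

    ``scores`` are the positive-class scores of every sample; the
    positive class is ranked against all other classes pooled; tied
    scores contribute 1/2.  Raises ``ValueError`` when either side is
    empty.
    """
    s = np.asarray(scores, dtype=float)
    yy = np.asarray(y)
    if s.shape[0] != yy.shape[0]:
        raise ValueError("scores and labels must have equal length")
    pos = yy == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"one-vs-rest AUC needs both {positive_class!r} and other labels"
        )
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def weighted_auc(
    per_class_auc: Sequence[float], class_counts: Sequence[int]
) -> float:
    """Label-weighted multiclass AUC: Σ AUC_c · n_c / N."""
    auc = np.asarray(per_class_auc, dtype=float)
    n = np.asarray(class_counts, dtype=float)
    if auc.shape != n.shape:
        raise ValueError("per_class_auc and class_counts length mismatch")
    if (n <= 0).any():
        raise ValueError("class counts must be positive")
    return float((auc * n / n.sum()).sum())


@dataclass(frozen=True)
class MicroMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    gmean: float
    accuracy: float
    accuracy_sd: float


def _ovr_counts(cm: np.ndarray) -> tuple[float, float, float, float]:
    """tp/fp/fn/tn summed over the per-class one-vs-rest confusions."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    tp = np.trace(cm)
    fp = (cm.sum(axis=0) - np.diag(cm)).sum()
    fn = (cm.sum(axis=1) - np.diag(cm)).sum()
    tn = cm.shape[0] * total - tp - fp - fn
    return tp, fp, fn, tn


def micro_metrics(
    confusions: Sequence[np.ndarray], gmean_sqrt: bool = False
) -> MicroMetrics:
    """Micro-averaged metrics from one confusion matrix per round.

    Sensitivity, specificity and precision are computed per round from
    the one-vs-rest counts summed over classes, then averaged over
    rounds; F1 and G-mean are composed from those means using the stated
    formulas (G-mean as the plain product unless ``gmean_sqrt``).
    Raises ``ValueError`` on negative counts or a zero denominator.
    """
    if len(confusions) == 0:
        raise ValueError("at least one confusion matrix is required")
    sens, spec, prec, accs = [], [], [], []
    for cm in confusions:
        cm = np.asarray(cm, dtype=float)
        if (cm < 0).any():
            raise ValueError("confusion counts must be non-negative")
        tp, fp, fn, tn = _ovr_counts(cm)
        for name, denom in (
            ("sensitivity", tp + fn),
            ("specificity", tn + fp),
            ("precision", tp + fp),
        ):
            if denom <= 0:
                raise ValueError(f"micro {name} undefined: zero denominator")
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
        prec.append(tp / (tp + fp))
        accs.append(tp / cm.sum())
    s, sp, p = float(np.mean(sens)), float(np.mean(spec)), float(np.mean(prec))
    if s + p <= 0:
        raise ValueError("micro F1 undefined: sensitivity + precision is zero")
    f1 = 2.0 * s * p / (s + p)
    gmean = float(np.sqrt(s * sp)) if gmean_sqrt else s * sp
    return MicroMetrics(
        sensitivity=s,
        specificity=sp,
        precision=p,
        f1=float(f1),
        gmean=float(gmean),
        accuracy=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
    )


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    mean_abs_difference: float | None
    difference_histogram: np.ndarray  # counts in |diff| bins 0–0.4 by 0.1
    histogram_bin_edges: np.ndarray


def ks_compare(
    auto_cellularity: Sequence[float],
    reference_cellularity: Sequence[float],
) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of automatic vs reference
    cellularity distributions.

    Also reports the mean absolute per-patient difference and a histogram
    of |differences| in 0.1-wide bins from 0 to 0.4 (paired quantities,
    available only when the two samples have equal length).  Reference
    ranges should be resolved to their upper bound before calling.
    """
    a = np.asarray(auto_cellularity, dtype=float)
    r = np.asarray(reference_cellularity, dtype=float)
    if a.size == 0 or r.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = sps.ks_2samp(a, r, method="asymp")
    edges = np.arange(0.0, 0.5, 0.1)
    if a.size == r.size:
        diffs = np.abs(a - r)
        mean_abs = float(diffs.mean())
        hist, _ = np.histogram(np.clip(diffs, 0.0, 0.4 - 1e-12), bins=edges)
    else:
        mean_abs = None
        hist = np.zeros(edges.size - 1, dtype=int)
    return KSResult(
        statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        mean_abs_difference=mean_abs,
        difference_histogram=hist,
        histogram_bin_edges=edges,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    n_eligible: int
    n_concordant: int
    rate: float
    rule: str


_FOLLOWUP_MAP = {"PV": "PV", "ET": "ET", "PRE-PMF": "pre-PMF", "PMF": "pre-PMF"}


def _parse_histology(token: str) -> list[str]:
    """Class labels mentioned in a histology annotation such as
    'pre-PMF-/ET-LIKE' or 'PV-LIKE'."""
    t = token.strip().upper().replace(" LIKE", "-LIKE")
    if t.endswith("-LIKE"):
        t = t[: -len("-LIKE")]
    out = []
    for part in t.split("/"):
        part = part.strip().strip("-")
        if not part:
            continue
        if part not in _FOLLOWUP_MAP:
            raise ValueError(f"unknown histology class token {part!r}")
        out.append(_FOLLOWUP_MAP[part])
    if not out:
        raise ValueError(f"empty histology annotation {token!r}")
    return out


def concordance(
    predictions: Sequence[str],
    reference: Sequence[str],
    rule: str = "followup",
    histology_policy: str = "any_listed",
) -> ConcordanceResult:
    """Agreement rate between model predictions and a reference reading.

    ``rule='followup'``: reference entries are class labels, ``NA`` or
    ``UNCHANGED...``; NA/UNCHANGED cases are ineligible and dropped, a
    ``PMF`` follow-up counts as pre-PMF, and agreement is exact label
    match.  ``rule='histology'``: reference entries are morphology
    annotations possibly naming several overlapping subtypes; the
    matching policy is configurable because no single rule is canonical —
    ``any_listed`` accepts a prediction naming any mentioned subtype,
    ``single_label_only`` accepts only unambiguous single-subtype
    annotations that match exactly.
    """
    if len(predictions) != len(reference):
        raise ValueError("predictions and reference must have equal length")
    eligible = 0
    concordant = 0
    for pred, ref in zip(predictions, reference):
        token = str(ref).strip()
        if rule == "followup":
            if token.upper() == "NA" or token.upper().startswith("UNCHANGED"):
                continue
            key = token.upper()
            if key not in _FOLLOWUP_MAP:
                raise ValueError(f"unknown follow-up token {token!r}")
            eligible += 1
            concordant += int(_FOLLOWUP_MAP[key] == pred)
        elif rule == "histology":
            classes = _parse_histology(token)
            eligible += 1
            if histology_policy == "any_listed":
                concordant += int(pred in classes)
            elif histology_policy == "single_label_only":
                concordant += int(len(classes) == 1 and classes[0] == pred)
            else:
                raise ValueError(f"unknown histology_policy {histology_policy!r}")
        else:
            raise ValueError(f"unknown rule {rule!r}")
    if eligible == 0:
        raise ValueError("no eligible cases for concordance")
    tag = rule if rule == "followup" else f"{rule}:{histology_policy}"
    return ConcordanceResult(
        n_eligible=eligible,
        n_concordant=concordant,
        rate=concordant / eligible,
        rule=tag,
    )
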