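"""Per-patient feature vectors from per-nucleus and per-ROI measurements.

Each patient contributes a fixed-order feature vector: for each nuclear
feature (area, perimeter, circularity) five summary statistics over the
megakaryocyte-filtered nuclei pooled across the patient's ROIs; the same
five statistics over the per-ROI cell-density values; and the
nucleated-area-weighted cellularity.  The full set has 21 columns; the
``paper17`` variant drops the four entropy columns (3 nuclear + 1
density), giving 17.

Summary-statistic conventions: sample SD with the n−1 denominator;
population-moment skewness g1 and excess kurtosis g2 (0 for a normal);
entropy is the Shannon entropy (natural log) of an equal-width histogram
between the sample min and max with min(10, n) bins.  Degenerate samples
(SD = 0) map skewness, kurtosis and entropy to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .morphometry import NucleusShape, cell_density, filter_megakaryocytes

__all__ = [
    "SummaryStats",
    "FeatureConfig",
    "FeaturizationError",
    "feature_columns",
    "summary_stats",
    "patient_vector",
    "cohort_table",
]

NUCLEAR_FEATURES = ("area", "perimeter", "circularity")
STAT_NAMES = ("mean", "sd", "skewness", "kurtosis", "entropy")


class SummaryStats(NamedTuple):
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy: float


class FeaturizationError(ValueError):
    """A patient cannot be featurized (e.g. no megakaryocytes found)."""


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-building policy.

    ``mk_only`` restricts nuclear statistics to megakaryocyte-filtered
    nuclei (the default analysis); ``feature_set`` chooses between the
    full 21-column vector and the 17-column variant without entropies.
    """

    n_rois: int = 3
    strict_roi_count: bool = True
    ecc_min: float = 0.8
    caliper_min_um: float = 20.0
    mk_only: bool = True
    feature_set: str = "full"  # "full" (21 cols) or "paper17" (17 cols)
    entropy_bins: int = 10


def feature_columns(feature_set: str = "full") -> list[str]:
    """Fixed, versioned column order of the patient feature vector."""
    if feature_set not in ("full", "paper17"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    stats = STAT_NAMES if feature_set == "full" else STAT_NAMES[:4]
    cols = [f"{f}_{s}" for f in NUCLEAR_FEATURES for s in stats]
    cols += [f"density_{s}" for s in stats]
    cols.append("cellularity")
    return cols


def summary_stats(values: Sequence[float], n_bins: int = 10) -> SummaryStats:
    """Mean, sample SD, skewness g1, excess kurtosis g2 and histogram
    entropy of a sample.

    Raises ``ValueError`` on an empty sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("summary_stats requires at least one value")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    # population central moments for g1/g2 (biased convention)
    m2 = float(((x - mean) ** 2).mean())
    if m2 <= 0.0:
        skew = kurt = 0.0
    else:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        entropy = 0.0
    else:
        bins = min(int(n_bins), x.size)
        counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log(p)).sum())
    return SummaryStats(mean, sd, skew, kurt, entropy)


def patient_vector(
    patient_id: str,
    roi_shapes: Sequence[Sequence[NucleusShape]],
    cellularity_per_roi: Sequence[float],
    label: str | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.Series:
    """Build the fixed-order feature vector for one patient.

    ``roi_shapes`` holds the per-ROI lists of *all* detected nucleus
    shapes; the megakaryocyte filter is applied here.  Nuclear statistics
    are computed over filtered nuclei pooled across ROIs; density
    statistics over the per-ROI density values; cellularity is the
    nucleated-area-weighted combination of the per-ROI cellularities.
    All aggregations are invariant to ROI order.

    Raises :class:`FeaturizationError` when no megakaryocyte survives the
    filter, and ``ValueError`` on an ROI-count mismatch under the strict
    policy.
    """
    n = len(roi_shapes)
    if len(cellularity_per_roi) != n:
        raise ValueError("cellularity_per_roi length must match roi_shapes")
    if config.strict_roi_count and n != config.n_rois:
        raise ValueError(
            f"expected {config.n_rois} ROIs per patient, got {n}"
        )
    if n == 0:
        raise ValueError("at least one ROI is required")

    densities = []
    pooled: list[NucleusShape] = []
    weights = []
    for shapes in roi_shapes:
        shapes = list(shapes)
        mks = filter_megakaryocytes(shapes, config.ecc_min, config.caliper_min_um)
        densities.append(cell_density(shapes, mks))
        pooled.extend(mks if config.mk_only else shapes)
        weights.append(sum(s.area_um2 for s in shapes))
    if not pooled:
        raise FeaturizationError(
            f"patient {patient_id}: no nucleus passed the megakaryocyte filter"
        )

    # sorting makes every aggregation bit-identical under ROI permutation
    out: dict[str, float] = {}
    stats_used = STAT_NAMES if config.feature_set == "full" else STAT_NAMES[:4]
    for feat, getter in (
        ("area", lambda s: s.area_um2),
        ("perimeter", lambda s: s.perimeter_um),
        ("circularity", lambda s: s.circularity),
    ):
        st = summary_stats(sorted(getter(s) for s in pooled), config.entropy_bins)
        for name in stats_used:
            out[f"{feat}_{name}"] = getattr(st, name)
    st = summary_stats(sorted(densities), config.entropy_bins)
    for name in stats_used:
        out[f"density_{name}"] = getattr(st, name)

    pairs = sorted(zip(weights, cellularity_per_roi))
    w = np.asarray([p[0] for p in pairs], dtype=float)
    c = np.asarray([p[1] for p in pairs], dtype=float)
    if w.sum() <= 0:
        raise FeaturizationError(f"patient {patient_id}: zero nucleated area")
    out["cellularity"] = float((w * c).sum() / w.sum())

    cols = feature_columns(config.feature_set)
    vec = pd.Series([out[c_] for c_ in cols], index=cols, name=patient_id)
    if label is not None:
        vec.attrs["label"] = label
    return vec


def cohort_table(vectors: Sequence[pd.Series]) -> pd.DataFrame:
    """Stack patient vectors into a cohort feature table (one row per
    patient, fixed header)."""
    df = pd.DataFrame(list(vectors))
    df.index.name = "patient_id"
    return df
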