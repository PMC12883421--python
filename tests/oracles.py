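"""Brute-force oracle implementations, independent of the package code.

Each oracle computes its quantity directly from the definition
(exhaustive pair counting, hand ranking, literal moment formulas) so the
package implementations can be checked against them on small instances.
"""

from __future__ import annotations

import math

import numpy as np


def brute_summary_stats(values):
    """Mean / sample SD / g1 skewness / excess kurtosis / histogram
    entropy computed with literal loops from the definitions."""
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    else:
        sd = 0.0
    m2 = sum((v - mean) ** 2 for v in x) / n
    if m2 <= 0:
        skew = kurt = 0.0
    else:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    lo, hi = min(x), max(x)
    if hi <= lo:
        entropy = 0.0
    else:
        bins = min(10, n)
        width = (hi - lo) / bins
        counts = [0] * bins
        for v in x:
            idx = min(int((v - lo) / width), bins - 1)
            counts[idx] += 1
        entropy = -sum(
            (c / n) * math.log(c / n) for c in counts if c > 0
        )
    return mean, sd, skew, kurt, entropy


def brute_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from hand-assigned average ranks."""
    pooled = sorted(
        (v, gi) for gi, g in enumerate(groups) for v in g
    )
    n = len(pooled)
    ranks = {}
    i = 0
    flat_ranks = [0.0] * n
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
        for k in range(i, j):
            flat_ranks[k] = avg
        i = j
    group_rank_sums = [0.0] * len(groups)
    group_sizes = [len(g) for g in groups]
    for (v, gi), r in zip(pooled, flat_ranks):
        group_rank_sums[gi] += r
    h = (12.0 / (n * (n + 1))) * sum(
        rs**2 / sz for rs, sz in zip(group_rank_sums, group_sizes)
    ) - 3 * (n + 1)
    # tie correction
    tie_term = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        tie_term += t**3 - t
        i = j
    denom = 1.0 - tie_term / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def brute_ovr_auc(scores, labels, positive):
    """Exhaustive pair counting: P(score_pos > score_neg) + ties/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_max_caliper(mask):
    """All-pairs maximum distance over every foreground pixel corner."""
    pts = []
    rr, cc = np.nonzero(mask)
    for r, c in zip(rr, cc):
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                pts.append((r + dr, c + dc))
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            if d > best:
                best = d
    return best
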