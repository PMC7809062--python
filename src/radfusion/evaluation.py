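"""ROC-based evaluation statistics for binary prognosis models.

Implements the Mann-Whitney AUC, DeLong variance estimates for a single
AUC and for the paired comparison of two correlated AUCs, the Youden-J
operating threshold, Benjamini-Hochberg step-up adjustment, and the
family-wise error rate of an uncorrected univariate screen.

Orientation convention: the positive class is "death" (label 1) and
scores are oriented so that larger means higher risk of death.  The
orientation is fixed — an AUC below 0.5 is reported as-is, never
auto-flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AUCResult",
    "roc_auc",
    "delong_ci",
    "delong_paired_test",
    "youden_threshold",
    "roc_curve_points",
    "bh_adjust",
    "fwer",
    "evaluate_scores",
]


@dataclass(frozen=True)
class AUCResult:
    """AUC with its 95% DeLong interval and the Youden operating point."""

    auc: float
    ci_low: float
    ci_high: float
    youden_threshold: float
    sensitivity: float
    specificity: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def _midranks(x: np.ndarray) -> np.ndarray:
    # rankdata's 'average' method is exactly the midrank needed by DeLong
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg).

    Equals the trapezoidal area under the empirical ROC curve.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    r = _midranks(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    # sum of positive midranks minus its minimum gives the concordance count
    return float((r[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval from the DeLong variance.

    The interval is clipped to [0, 1].  With a degenerate variance
    (perfect or null separation) the interval collapses onto the AUC.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    _, v10, v01 = _delong_components(scores, labels)
    return float(v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size)


def delong_paired_test(scores1, scores2, labels) -> float:
    """Two-sided paired DeLong test for the difference of correlated AUCs.

    Both score vectors must refer to the same samples and labels.  When
    the AUC difference and its variance are both zero (e.g. identical
    score vectors) the models are indistinguishable and p = 1.
    """
    labels = _check_binary(labels)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.shape[0] != labels.shape[0]:
        raise ValueError("score vectors and labels must have equal length")
    a1, v10_1, v01_1 = _delong_components(s1, labels)
    a2, v10_2, v01_2 = _delong_components(s2, labels)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = a1 - a2
    if var_diff <= 0:
        return 1.0 if np.isclose(diff, 0.0) else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


def roc_curve_points(scores, labels) -> np.ndarray:
    """(threshold, sensitivity, specificity) rows over all candidate cuts.

    Thresholds are midpoints between adjacent distinct scores plus
    sentinels below the minimum and above the maximum; a sample is
    called positive when score >= threshold.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    pos = labels == 1
    rows = []
    for t in cuts:
        called = scores >= t
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & ~pos).sum() / (~pos).sum()
        rows.append((t, sens, spec))
    return np.array(rows)


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints of adjacent distinct scores (plus
    the two sentinels).  Ties in J are broken in favour of higher
    sensitivity, then lower threshold.
    """
    pts = roc_curve_points(scores, labels)
    j = pts[:, 1] + pts[:, 2] - 1.0
    # lexicographic: max J, then max sensitivity, then min threshold
    order = np.lexsort((pts[:, 0], -pts[:, 1], -j))
    best = pts[order[0]]
    return float(best[0]), float(best[1]), float(best[2])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a
    cumulative minimum from the largest rank down, and cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fwer(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise error rate 1 - (1 - alpha)^n under independence.

    Quantifies the cost of screening a large feature bank one test at a
    time without multiplicity control.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(1.0 - (1.0 - alpha) ** n_tests)


def evaluate_scores(scores, labels, level: float = 0.95) -> AUCResult:
    """Full evaluation bundle for one score vector."""
    auc = roc_auc(scores, labels)
    lo, hi = delong_ci(scores, labels, level=level)
    thr, sens, spec = youden_threshold(scores, labels)
    return AUCResult(auc=auc, ci_low=lo, ci_high=hi,
                     youden_threshold=thr, sensitivity=sens, specificity=spec)
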