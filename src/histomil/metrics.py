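"""Discrimination and correlation metrics with paired comparison tests.

Benchmarking many encoders on the same cohort means every comparison is
between *correlated* performance estimates computed on identical subjects,
so the ordinary independent-sample tests do not apply.  This module
implements the appropriate paired machinery:

* ROC AUC in its Mann-Whitney form, with DeLong's structural-component
  test for comparing two correlated AUCs;
* Pearson correlation with Meng-Rosenthal-Rubin's z-test for comparing
  two dependent correlations sharing a common variable;
* Benjamini-Hochberg FDR adjustment across the family of pairwise
  comparisons versus the baseline encoder;
* Youden's J (sensitivity + specificity - 1) threshold selection on
  pooled validation predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "roc_auc",
    "delong_test",
    "pearson_r",
    "meng_z_test",
    "meng_z_from_scores",
    "bh_adjust",
    "youden_threshold",
]


@dataclass
class TestResult:
    """Outcome of a two-sided comparison test."""

    statistic: float
    p_value: float
    effect: float
    adjusted_p: float | None = None
    note: str = ""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    return labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(s+ > s-) + 1/2 P(s+ = s-) over positive-negative pairs."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    m = int(labels.sum())
    n = len(labels) - m
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_test(labels, scores_a, scores_b) -> TestResult:
    """DeLong's test for the difference of two correlated ROC AUCs.

    Both score vectors must be computed on the same subjects in the same
    order.  Returns the z statistic, two-sided normal p, and the AUC
    difference as the effect.
    """
    labels = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != labels.shape or b.shape != labels.shape:
        raise ValueError("scores and labels must be aligned on the same subjects")
    auc_a, v10_a, v01_a = _structural_components(a, labels)
    auc_b, v10_b, v01_b = _structural_components(b, labels)
    delta = auc_a - auc_b
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if np.isclose(delta, 0.0):
            return TestResult(statistic=0.0, p_value=1.0, effect=float(delta))
        warnings.warn("DeLong variance is zero with a nonzero AUC difference")
        return TestResult(statistic=np.inf, p_value=0.0, effect=float(delta), note="degenerate variance")
    z = delta / np.sqrt(var)
    return TestResult(statistic=float(z), p_value=float(2 * stats.norm.sf(abs(z))), effect=float(delta))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation (n >= 3, both variables non-constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def meng_z_test(r_a: float, r_b: float, r_ab: float, n: int) -> TestResult:
    """Meng-Rosenthal-Rubin z-test for two dependent correlations.

    ``r_a`` and ``r_b`` correlate two predictors with a shared criterion on
    the same n subjects; ``r_ab`` is the correlation between the
    predictors.  Uses the published h and f adjustment on Fisher-z
    transformed correlations.
    """
    for r in (r_a, r_b, r_ab):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)
    if z_a == z_b:
        return TestResult(statistic=0.0, p_value=1.0, effect=0.0)
    r2bar = (r_a**2 + r_b**2) / 2.0
    f = min(1.0, (1.0 - r_ab) / (2.0 * (1.0 - r2bar)))
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z_a - z_b) * np.sqrt((n - 3) / (2.0 * (1.0 - r_ab) * h))
    return TestResult(
        statistic=float(z), p_value=float(2 * stats.norm.sf(abs(z))), effect=float(r_a - r_b)
    )


def meng_z_from_scores(criterion, scores_a, scores_b) -> TestResult:
    """Convenience wrapper computing all three correlations from raw vectors.

    The predictor-predictor correlation is computed on the same rows used
    for the two criterion correlations.
    """
    r_a = pearson_r(scores_a, criterion)
    r_b = pearson_r(scores_b, criterion)
    r_ab = pearson_r(scores_a, scores_b)
    return meng_z_test(r_a, r_b, r_ab, len(np.asarray(criterion)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the unique observed scores; a score >= t is classified
    positive.  Ties on J are broken toward the smallest threshold.  Applied
    in the pipeline to validation predictions pooled across CV folds, then
    frozen for the test predictions.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    candidates = np.unique(scores)
    # tp(t) = #pos >= t, tn(t) = #neg < t; maximizing J = tp/P + tn/N - 1 is
    # equivalent to maximizing the integer tp*N + tn*P, which makes ties on J
    # exact and the smallest-threshold tie-break deterministic
    tp = len(pos) - np.searchsorted(pos, candidates, side="left")
    tn = np.searchsorted(neg, candidates, side="left")
    j_scaled = tp * len(neg) + tn * len(pos)
    return float(candidates[int(np.argmax(j_scaled))])
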