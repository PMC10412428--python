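"""Empirical ROC curves, AUROC, bootstrap CIs, paired DeLong tests, Youden cutoffs.

The AUROC estimator is the tie-aware Mann-Whitney probability: the mean
over all (positive, negative) pairs of 1 if the positive subject
out-scores the negative, 1/2 on ties. The paired DeLong test compares two
correlated AUROCs on the same subjects via mid-rank structural components
(placement values); the Youden cutoff maximizes J = sensitivity +
specificity - 1 over midpoints between adjacent distinct scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._util import check_rng
from .triage import dichotomize

__all__ = [
    "RocCurve",
    "AurocEstimate",
    "YoudenResult",
    "auroc",
    "roc_curve",
    "bootstrap_auroc_ci",
    "delong_paired_test",
    "delong_variance",
    "youden_cutoff",
    "apply_derived_cutoff",
]


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both endpoint classes must be present")
    return scores, labels, pos, neg


def auroc(scores, labels) -> float:
    """Tie-aware AUROC (Mann-Whitney probability) via mid-ranks.

    Equivalent to the mean over all positive-negative pairs of
    ``1[s_pos > s_neg] + 0.5 * 1[s_pos == s_neg]``.
    """
    scores, labels, pos, neg = _split_classes(scores, labels)
    m, n = pos.size, neg.size
    ranks = rankdata(scores)  # mid-ranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - m * (m + 1) / 2.0
    return float(u / (m * n))


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points over a descending cutoff grid."""

    cutoffs: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    n_positive: int
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "sensitivity": self.sens, "specificity": self.spec}
        )

    def trapezoidal_auc(self) -> float:
        """Area under sens vs (1 - spec) by the trapezoid rule (tie-aware).

        Integrates in the curve's own cutoff order (reversed, so the false
        positive rate ascends); re-sorting by FPR would scramble vertical
        segments at tied FPR values.
        """
        fpr = 1.0 - self.spec
        return float(np.trapezoid(self.sens[::-1], fpr[::-1]))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC: one operating point per distinct score, plus sentinels.

    Cutoffs are the distinct observed scores in increasing order with a
    -inf sentinel (everyone positive: sens = 1) and a +inf sentinel
    (nobody positive: sens = 0). Positivity is score >= cutoff.
    """
    scores, labels, pos, neg = _split_classes(scores, labels)
    cuts = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    m, n = pos.size, neg.size
    # vectorized: count pos/neg at or above each cutoff
    tp = np.array([(pos >= c).sum() for c in cuts])
    fp = np.array([(neg >= c).sum() for c in cuts])
    return RocCurve(
        cutoffs=cuts,
        sens=tp / m,
        spec=1.0 - fp / n,
        n_positive=m,
        n_negative=n,
    )


@dataclass(frozen=True)
class AurocEstimate:
    auroc: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int | None
    stratified: bool = True


_MAX_REDRAWS = 1000  # cap on redraws of single-class unstratified resamples


def bootstrap_auroc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    stratified: bool = True,
    seed=None,
) -> AurocEstimate:
    """Percentile bootstrap 95% CI for the AUROC.

    Stratified resampling (default) redraws positives and negatives
    separately, preserving class counts. Unstratified resamples that land
    on a single class are redrawn, up to a hard cap.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scores, labels, pos, neg = _split_classes(scores, labels)
    rng = check_rng(seed)
    m, n = pos.size, neg.size
    point = auroc(scores, labels)

    boots = np.empty(n_boot)
    if stratified:
        for b in range(n_boot):
            bp = pos[rng.integers(0, m, m)]
            bn = neg[rng.integers(0, n, n)]
            boots[b] = _auroc_two_sample(bp, bn)
    else:
        total = m + n
        for b in range(n_boot):
            for _ in range(_MAX_REDRAWS):
                idx = rng.integers(0, total, total)
                lab = labels[idx]
                if lab.min() != lab.max():
                    break
            else:
                raise RuntimeError("could not draw a two-class bootstrap resample")
            boots[b] = auroc(scores[idx], lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AurocEstimate(point, float(lo), float(hi), n_boot,
                         seed if isinstance(seed, int) else None, stratified)


def _auroc_two_sample(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([pos, neg]))
    m = pos.size
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return u / (m * neg.size)


def _placements(scores, labels):
    """DeLong structural components (placement values) via mid-ranks.

    V10[i] for positives: fraction of negatives out-scored by positive i
    (ties half); V01[j] likewise for negatives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUROC."""
    _split_classes(scores, labels)
    v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass(frozen=True)
class DeLongComparison:
    """Paired DeLong test result for two AUROCs on the same subjects."""

    method: str
    statistic: float
    p_value: float
    auroc_a: float
    auroc_b: float
    var_diff: float
    degenerate: bool = False


def delong_paired_test(scores_a, scores_b, labels) -> DeLongComparison:
    """Two-sided paired DeLong test of equal AUROCs.

    z = (A_a - A_b) / sqrt(var_a + var_b - 2 cov) with variance and
    covariance estimated from the placement values; p from the standard
    normal. A non-positive variance of the difference (e.g. identical
    scores) is flagged degenerate with p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    _split_classes(scores_a, labels)
    a = auroc(scores_a, labels)
    b = auroc(scores_b, labels)
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return DeLongComparison("delong", 0.0, 1.0, a, b, float(var_diff), degenerate=True)
    z = (a - b) / np.sqrt(var_diff)
    p = 2 * norm.sf(abs(z))
    return DeLongComparison("delong", float(z), float(p), a, b, float(var_diff))


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    j: float
    sens: float
    spec: float
    derivation_cohort_id: str = ""


def youden_cutoff(scores, labels, derivation_cohort_id: str = "") -> YoudenResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    scores plus -inf/+inf sentinels, so that "< cutoff" vs ">= cutoff" is
    unambiguous for every subject. Ties in J break toward the smallest
    cutoff (favouring rule-out sensitivity).
    """
    scores, labels, pos, neg = _split_classes(scores, labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    m, n = pos.size, neg.size
    sens = np.array([(pos >= c).sum() for c in candidates]) / m
    spec = 1.0 - np.array([(neg >= c).sum() for c in candidates]) / n
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first max: smallest cutoff
    return YoudenResult(
        cutoff=float(candidates[best]),
        j=float(j[best]),
        sens=float(sens[best]),
        spec=float(spec[best]),
        derivation_cohort_id=derivation_cohort_id,
    )


def apply_derived_cutoff(
    derivation: tuple,
    evaluation: tuple,
    derivation_cohort_id: str = "derivation",
    evaluation_cohort_id: str = "evaluation",
):
    """Learn the Youden cutoff on one cohort, evaluate counts on another.

    Returns ``(YoudenResult, ConfusionCounts)``: the cutoff (with its
    derivation-cohort id) and the confusion counts of score >= cutoff on
    the evaluation cohort. The evaluation cohort may be degenerate
    (single-class); downstream metrics then carry undefined markers.
    """
    d_scores, d_labels = derivation
    e_scores, e_labels = evaluation
    if len(d_scores) == 0 or len(e_scores) == 0:
        raise ValueError("both cohorts must be non-empty")
    y = youden_cutoff(d_scores, d_labels, derivation_cohort_id)
    counts = dichotomize(np.asarray(e_scores, dtype=float),
                         np.asarray(e_labels).astype(int), y.cutoff)
    return y, counts
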