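"""Dual-cutoff triage, confusion counts and Wilson continuity-corrected intervals.

A dual-cutoff (rule-out / rule-in) test stratifies patients into three
zones: below the low cutoff (endpoint considered unlikely; sensitivity and
NPV are the relevant guarantees), at or above the high cutoff (endpoint
considered likely; specificity and PPV), and an intermediate
(moderate-risk) zone in between where the test is non-committal. Metrics
at each cutoff dichotomize the *full* cohort — the intermediate zone is
not excluded — with positivity defined as score >= cutoff.

All proportions carry 95% Wilson score intervals with continuity
correction (Newcombe's closed form), the interval convention used by
DescTools' ``BinomCI(..., method="wilsoncc")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._util import round_half_up
from .scores import CutoffPolicy

__all__ = [
    "ConfusionCounts",
    "TriageTable",
    "ProportionEstimate",
    "dichotomize",
    "triage",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "prevalence",
    "wilson_cc_interval",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts at one cutoff (positive iff score >= cutoff)."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = float("nan")

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def n_test_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_test_negative(self) -> int:
        return self.tn + self.fn


@dataclass(frozen=True)
class ProportionEstimate:
    """Percent point estimate with Wilson continuity-corrected 95% limits.

    ``defined`` is False for zero-denominator metrics (e.g. PPV of a test
    that calls nobody positive); reports must render these as explicit
    markers, never as 0 or 100.
    """

    numerator: int
    denominator: int
    estimate: float  # percent
    lower: float  # percent
    upper: float  # percent
    confidence: float = 0.95
    defined: bool = True

    @classmethod
    def undefined(cls) -> "ProportionEstimate":
        nan = float("nan")
        return cls(0, 0, nan, nan, nan, defined=False)

    @classmethod
    def from_counts(cls, k: int, n: int, confidence: float = 0.95) -> "ProportionEstimate":
        if n == 0:
            return cls.undefined()
        lo, hi = wilson_cc_interval(k, n, confidence)
        return cls(k, n, 100.0 * k / n, lo, hi, confidence)

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(estimate, lower, upper) rounded half-up, table-style."""
        return (
            round_half_up(self.estimate, ndigits),
            round_half_up(self.lower, ndigits),
            round_half_up(self.upper, ndigits),
        )

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        e, lo, hi = self.rounded()
        return f"{e:.1f} ({lo:.1f}, {hi:.1f})"


def wilson_cc_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction, in percent.

    Newcombe's closed form; lower limit clipped at 0 (and exactly 0 when
    k = 0), upper clipped at 100 (exactly 100 when k = n).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    z = norm.ppf(1 - (1 - confidence) / 2)
    p = k / n
    denom = 2 * (n + z**2)
    lower = (2 * n * p + z**2 - 1 - z * np.sqrt(z**2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    upper = (2 * n * p + z**2 + 1 + z * np.sqrt(z**2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    return 100.0 * max(0.0, lower), 100.0 * min(1.0, upper)


def _check_aligned(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ in length")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values; filter the cohort first")
    labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def dichotomize(scores, labels, cutoff) -> ConfusionCounts:
    """Confusion counts with test-positive iff score >= cutoff.

    ``cutoff`` may be a scalar or a per-subject array (sex-specific ULN).
    """
    scores, labels = _check_aligned(scores, labels)
    positive = scores >= np.asarray(cutoff, dtype=float)
    tp = int(np.sum(positive & (labels == 1)))
    fp = int(np.sum(positive & (labels == 0)))
    fn = int(np.sum(~positive & (labels == 1)))
    tn = int(np.sum(~positive & (labels == 0)))
    scalar_cut = float(np.min(cutoff)) if np.ndim(cutoff) else float(cutoff)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=scalar_cut)


@dataclass(frozen=True)
class TriageTable:
    """Per-cutoff confusion counts and zone membership for one test/cohort."""

    test_name: str
    rule_out: ConfusionCounts  # dichotomized at the low cutoff
    rule_in: ConfusionCounts  # dichotomized at the high cutoff
    n_below_low: int
    n_intermediate: int
    n_above_high: int

    @property
    def n(self) -> int:
        return self.n_below_low + self.n_intermediate + self.n_above_high

    @property
    def is_single_cutoff(self) -> bool:
        return self.n_intermediate == 0 and self.rule_out.cutoff == self.rule_in.cutoff


def triage(scores, labels, policy: CutoffPolicy, sex=None, test_name: str = "") -> TriageTable:
    """Triage a scored cohort under a cutoff policy.

    Dual policies produce rule-out counts at the low cutoff, rule-in counts
    at the high cutoff, and the intermediate-zone size. Single-cutoff
    policies (including the sex-specific ALT upper limit of normal)
    populate both arms with the same dichotomy and an empty intermediate
    zone.
    """
    scores_arr, labels_arr = _check_aligned(scores, labels)
    if policy.is_dual:
        low, high = policy.low, policy.high
        rule_out = dichotomize(scores_arr, labels_arr, low)
        rule_in = dichotomize(scores_arr, labels_arr, high)
        n_below = int(np.sum(scores_arr < low))
        n_above = int(np.sum(scores_arr >= high))
        n_mid = len(scores_arr) - n_below - n_above
    else:
        cut = policy.single_cutoffs(None if sex is None else np.asarray(sex))
        rule_out = rule_in = dichotomize(scores_arr, labels_arr, cut)
        n_above = rule_in.n_test_positive
        n_below = len(scores_arr) - n_above
        n_mid = 0
    return TriageTable(
        test_name=test_name,
        rule_out=rule_out,
        rule_in=rule_in,
        n_below_low=n_below,
        n_intermediate=n_mid,
        n_above_high=n_above,
    )


def sensitivity(c: ConfusionCounts, confidence: float = 0.95) -> ProportionEstimate:
    """TP / (TP + FN)."""
    return ProportionEstimate.from_counts(c.tp, c.n_positive, confidence)


def specificity(c: ConfusionCounts, confidence: float = 0.95) -> ProportionEstimate:
    """TN / (TN + FP)."""
    return ProportionEstimate.from_counts(c.tn, c.n_negative, confidence)


def ppv(c: ConfusionCounts, confidence: float = 0.95) -> ProportionEstimate:
    """TP / (TP + FP) — predictive value of a positive call."""
    return ProportionEstimate.from_counts(c.tp, c.n_test_positive, confidence)


def npv(c: ConfusionCounts, confidence: float = 0.95) -> ProportionEstimate:
    """TN / (TN + FN) — predictive value of a negative call."""
    return ProportionEstimate.from_counts(c.tn, c.n_test_negative, confidence)


def prevalence(labels, confidence: float = 0.95) -> ProportionEstimate:
    """Percent endpoint-positive with Wilson-CC interval."""
    labels = np.asarray(labels).astype(int)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return ProportionEstimate.from_counts(int(labels.sum()), labels.size, confidence)
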