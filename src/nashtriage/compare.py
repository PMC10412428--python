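"""Head-to-head comparisons of two diagnostic tests on the same subjects.

Sensitivities and specificities of paired tests are compared with McNemar
tests on the discordant calls (restricted to endpoint-positives for
sensitivity, endpoint-negatives for specificity); intermediate-zone
proportions with McNemar-with-continuity-correction on zone-membership
indicators; and predictive values (PPV/NPV) with the generalized score
test for paired designs of Leisenring, Alonzo & Pepe (2000) — predictive
values condition on the test result, so the subjects entering the
comparison differ between tests and McNemar does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .roc import delong_paired_test, youden_cutoff
from .scores import CutoffPolicy

__all__ = [
    "PairedComparison",
    "mcnemar",
    "generalized_score_test_ppv_npv",
    "compare_tests",
]


@dataclass(frozen=True)
class PairedComparison:
    """Statistic, p-value and method tag for one head-to-head comparison.

    ``estimate_a``/``estimate_b`` are on the metric's natural reporting
    scale (percent for proportions, [0,1] for AUROC). ``degenerate`` marks
    comparisons with no information against the null (e.g. no discordant
    pairs); ``applicable`` is False where the comparison is structurally
    meaningless (e.g. intermediate-zone comparison against a single-cutoff
    test), mirroring a "—" table cell.
    """

    method: str  # mcnemar | mcnemar_cc | generalized_score | delong
    statistic: float
    p_value: float
    estimate_a: float = float("nan")
    estimate_b: float = float("nan")
    n_discordant: int | None = None
    degenerate: bool = False
    applicable: bool = True
    detail: dict = field(default_factory=dict)

    @classmethod
    def not_applicable(cls, method: str) -> "PairedComparison":
        nan = float("nan")
        return cls(method, nan, nan, applicable=False)

    def p_display(self) -> str:
        """Report-style rendering: 4 decimals, '<0.0001' below 1e-4."""
        if not self.applicable or not np.isfinite(self.p_value):
            return "—"
        if self.p_value < 1e-4:
            return "<0.0001"
        return f"{self.p_value:.4f}"


def mcnemar(
    positives_a,
    positives_b,
    continuity_correction: bool = False,
) -> PairedComparison:
    """McNemar test for equality of paired proportions.

    Discordant counts b (A-positive only) and c (B-positive only);
    statistic (|b - c| - 1)^2 / (b + c) with continuity correction,
    (b - c)^2 / (b + c) without; p from chi-square with 1 df. No
    discordant pairs -> degenerate, p = 1.
    """
    a = np.asarray(positives_a, dtype=bool)
    b_vec = np.asarray(positives_b, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("paired indicator vectors must have equal length")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    method = "mcnemar_cc" if continuity_correction else "mcnemar"
    est_a = 100.0 * a.mean()
    est_b = 100.0 * b_vec.mean()
    if b + c == 0:
        return PairedComparison(method, 0.0, 1.0, est_a, est_b, 0, degenerate=True,
                                detail={"b": b, "c": c})
    if continuity_correction:
        # unconditional (|b-c|-1)^2/(b+c), the R mcnemar.test convention
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(chi2.sf(stat, df=1))
    return PairedComparison(method, float(stat), p, est_a, est_b, b + c,
                            detail={"b": b, "c": c})


def generalized_score_test_ppv_npv(
    test_a_positive,
    test_b_positive,
    outcome,
    target: str = "ppv",
) -> PairedComparison:
    """Generalized score test of equal PPV (or NPV) for two paired tests.

    Follows the marginal-regression construction for paired predictive
    values (Leisenring, Alonzo & Pepe 2000): each subject contributes one
    record per test whose call matches the target (positive calls for
    PPV, negative for NPV) with response = disease status (complemented
    for NPV), and the score statistic tests a common predictive value
    across the two record sets. With n_a, n_b records per test and
    pooled null value p, each record carries a test indicator z (0 for
    A, 1 for B); the score for the test-indicator coefficient, with the
    intercept direction projected out, is

        U = sum_records (z - z_bar)(d - p),      z_bar = n_b / (n_a + n_b),

    referred to its cluster-robust variance V = sum_i e_i^2, where e_i
    is subject i's record sum of (z - z_bar)(d - p): subjects called by
    both tests form two-record clusters whose perfectly correlated
    responses are absorbed by the subject-level sum. The statistic
    U^2 / V is chi-square with 1 df. The robust variance is essential:
    disease probability differs between singly- and doubly-called
    subjects even when the marginal predictive values are equal, so a
    model-based binomial variance would be anticonservative.

    For disjoint call sets the clusters are singletons and the statistic
    coincides (asymptotically, and closely in finite samples) with the
    classical two-proportion score test; for identical calls U vanishes
    record-wise and the comparison is flagged degenerate with p = 1.
    """
    if target not in ("ppv", "npv"):
        raise ValueError("target must be 'ppv' or 'npv'")
    a = np.asarray(test_a_positive, dtype=bool)
    b = np.asarray(test_b_positive, dtype=bool)
    d = np.asarray(outcome).astype(int)
    if not (a.shape == b.shape == d.shape):
        raise ValueError("all vectors must have equal length")
    if target == "npv":
        a, b, d = ~a, ~b, 1 - d  # NPV of original = PPV of negated calls

    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a == 0 or n_b == 0:
        return PairedComparison("generalized_score", float("nan"), float("nan"),
                                applicable=False)
    # after negation d[a] is already the target predictive value for NPV
    pv_a = 100.0 * d[a].mean()
    pv_b = 100.0 * d[b].mean()

    n_ab = int(np.sum(a & b))
    p_pool = (d[a].sum() + d[b].sum()) / (n_a + n_b)
    z_bar = n_b / (n_a + n_b)
    resid = d - p_pool
    # subject-level cluster sums of (z - z_bar)(d - p) over the records
    e = np.where(a, -z_bar * resid, 0.0) + np.where(b, (1.0 - z_bar) * resid, 0.0)
    u = float(e.sum())
    v = float(np.sum(e * e))
    detail = {"n_called_a": n_a, "n_called_b": n_b, "n_called_both": n_ab}
    if v <= 0:
        return PairedComparison("generalized_score", 0.0, 1.0, pv_a, pv_b,
                                degenerate=True, detail=detail)
    stat = u * u / v
    p = float(chi2.sf(stat, df=1))
    return PairedComparison("generalized_score", float(stat), p, pv_a, pv_b,
                            detail=detail)


_DEFAULT_METRICS = (
    "auroc", "sensitivity", "specificity", "ppv", "npv", "intermediate_zone",
)


def compare_tests(
    scores_a,
    scores_b,
    labels,
    policy_a: CutoffPolicy,
    policy_b: CutoffPolicy,
    sex=None,
    which: Sequence[str] = _DEFAULT_METRICS,
    mcnemar_cc_sens_spec: bool = False,
    youden_derivation: tuple | None = None,
) -> dict[str, dict[str, PairedComparison]]:
    """Full comparison battery for two tests scored on the same subjects.

    Produces, per cutoff tier (``rule_out`` low, ``rule_in`` high and
    ``youden``): McNemar for sensitivity/specificity and generalized score
    for PPV/NPV; plus a tier-independent DeLong AUROC comparison and a
    McNemar-with-CC intermediate-zone-proportion comparison. Youden
    cutoffs may be derived on a different (typically larger) cohort via
    ``youden_derivation=(scores_a_deriv, scores_b_deriv, labels_deriv)``.

    Single-cutoff policies (ALT-style) are compared at their single
    threshold in every tier and yield a not-applicable marker for the
    intermediate-zone comparison.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    out: dict[str, dict[str, PairedComparison]] = {}

    if "auroc" in which:
        d = delong_paired_test(scores_a, scores_b, labels)
        out["auroc"] = {"auroc": PairedComparison(
            "delong", d.statistic, d.p_value, d.auroc_a, d.auroc_b,
            degenerate=d.degenerate, detail={"var_diff": d.var_diff},
        )}

    def _cut(policy: CutoffPolicy, tier: str, y_cut):
        # the Youden tier re-derives a single data-driven cutoff for every
        # test, including single-cutoff tests like the ALT ULN rule
        if tier == "youden":
            return y_cut
        if policy.is_dual:
            return policy.low if tier == "rule_out" else policy.high
        return policy.single_cutoffs(sex)

    if youden_derivation is not None:
        da, db, dl = youden_derivation
    else:
        da, db, dl = scores_a, scores_b, labels
    y_a = youden_cutoff(da, dl).cutoff
    y_b = youden_cutoff(db, dl).cutoff

    for tier in ("rule_out", "rule_in", "youden"):
        cut_a = _cut(policy_a, tier, y_a)
        cut_b = _cut(policy_b, tier, y_b)
        pos_a = scores_a >= np.asarray(cut_a, dtype=float)
        pos_b = scores_b >= np.asarray(cut_b, dtype=float)
        tier_out: dict[str, PairedComparison] = {}
        is_pos = labels == 1
        if "sensitivity" in which:
            tier_out["sensitivity"] = mcnemar(
                pos_a[is_pos], pos_b[is_pos], mcnemar_cc_sens_spec)
        if "specificity" in which:
            tier_out["specificity"] = mcnemar(
                ~pos_a[~is_pos], ~pos_b[~is_pos], mcnemar_cc_sens_spec)
        if "ppv" in which:
            tier_out["ppv"] = generalized_score_test_ppv_npv(pos_a, pos_b, labels, "ppv")
        if "npv" in which:
            tier_out["npv"] = generalized_score_test_ppv_npv(pos_a, pos_b, labels, "npv")
        out[tier] = tier_out

    if "intermediate_zone" in which:
        if policy_a.is_dual and policy_b.is_dual:
            in_zone_a = (scores_a >= policy_a.low) & (scores_a < policy_a.high)
            in_zone_b = (scores_b >= policy_b.low) & (scores_b < policy_b.high)
            cmp = mcnemar(in_zone_a, in_zone_b, continuity_correction=True)
        else:
            cmp = PairedComparison.not_applicable("mcnemar_cc")
        out["intermediate_zone"] = {"intermediate_zone": cmp}
    return out
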