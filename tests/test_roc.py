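import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from nashtriage.roc import (
    apply_derived_cutoff,
    auroc,
    bootstrap_auroc_ci,
    delong_paired_test,
    delong_variance,
    roc_curve,
    youden_cutoff,
)


def brute_force_auroc(scores, labels):
    """Pairwise Mann-Whitney oracle: 1 / 0.5 / 0 per (pos, neg) pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_small_tied_example(self):
        # pairs: (3>2), (3>1), (2=2), (2>1) -> (1 + 1 + 0.5 + 1) / 4
        assert auroc([3, 2, 2, 1], [1, 1, 0, 0]) == pytest.approx(0.875, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_and_sklearn(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        scores = np.round(r.normal(size=n), 1)  # coarse grid forces ties
        labels = np.zeros(n, int)
        labels[: max(1, int(r.integers(1, n)))] = 1
        r.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = auroc(scores, labels)
        assert a == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_complement_identity(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30)
        labels = r.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0, abs=1e-12)


class TestRocCurve:
    def test_trapezoid_agrees_with_mann_whitney(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 80))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            curve = roc_curve(scores, labels)
            assert curve.trapezoidal_auc() == pytest.approx(
                auroc(scores, labels), abs=1e-10
            )

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        assert curve.sens[0] == 1.0 and curve.spec[0] == 0.0
        assert curve.sens[-1] == 0.0 and curve.spec[-1] == 1.0
        assert (np.diff(curve.sens) <= 1e-12).all()  # sens falls as cutoff rises


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a = bootstrap_auroc_ci(scores, labels, n_boot=100, seed=5)
        b = bootstrap_auroc_ci(scores, labels, n_boot=100, seed=5)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_perfect_separation_degenerate_interval(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        est = bootstrap_auroc_ci(scores, labels, n_boot=50, seed=2)
        assert est.ci_lower == est.ci_upper == 1.0

    def test_unstratified_redraws_single_class(self, rng):
        scores = rng.normal(size=12)
        labels = np.zeros(12, int)
        labels[0] = 1  # unstratified resamples frequently drop the lone positive
        est = bootstrap_auroc_ci(scores, labels, n_boot=50, stratified=False, seed=3)
        assert np.isfinite(est.ci_lower) and np.isfinite(est.ci_upper)

    def test_interval_brackets_point_estimate(self, rng):
        scores = rng.normal(size=100) + np.r_[np.zeros(60), np.ones(40)]
        labels = np.r_[np.zeros(60, int), np.ones(40, int)]
        est = bootstrap_auroc_ci(scores, labels, n_boot=400, seed=9)
        assert est.ci_lower <= est.auroc <= est.ci_upper


class TestDeLong:
    def test_identical_scores_degenerate(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        res = delong_paired_test(scores, scores, labels)
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_swap_antisymmetry(self, rng):
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        a = rng.normal(size=80) + 0.8 * labels
        b = rng.normal(size=80) + 0.3 * labels
        r1 = delong_paired_test(a, b, labels)
        r2 = delong_paired_test(b, a, labels)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_detects_clear_separation(self, rng):
        labels = np.r_[np.zeros(150, int), np.ones(150, int)]
        informative = rng.normal(size=300) + 2.0 * labels
        noise = rng.normal(size=300)
        res = delong_paired_test(informative, noise, labels)
        assert res.p_value < 1e-4

    def test_variance_tracks_bootstrap_variance(self):
        # structural-component variance vs resampling variance of the AUROC
        r = np.random.default_rng(314)
        labels = np.r_[np.zeros(250, int), np.ones(250, int)]
        scores = r.normal(size=500) + 1.0 * labels
        v_delong = delong_variance(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        boots = np.empty(600)
        for i in range(600):
            bp = pos[r.integers(0, len(pos), len(pos))]
            bn = neg[r.integers(0, len(neg), len(neg))]
            boots[i] = auroc(np.r_[bp, bn], np.r_[np.ones(len(bp), int), np.zeros(len(bn), int)])
        assert v_delong == pytest.approx(boots.var(ddof=1), rel=0.25)


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
        assert res.j == 1.0
        assert 2 < res.cutoff < 8

    def test_exhaustive_small_example(self):
        res = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.cutoff == 2.5 and res.j == 1.0

    def test_tie_breaks_toward_smallest_cutoff(self):
        # J identical at several cutoffs; the smallest maximizer wins
        res = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        grid = np.r_[-np.inf, 1.5, 2.5, 3.5, np.inf]
        js = []
        for c in grid:
            s = np.array([1, 2, 3, 4]); y = np.array([0, 1, 0, 1])
            sens = np.sum((s >= c) & (y == 1)) / 2
            spec = np.sum((s < c) & (y == 0)) / 2
            js.append(sens + spec - 1)
        best = grid[np.argmax(js)]
        assert res.cutoff == best

    def test_beats_every_observed_cutoff(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 100))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = youden_cutoff(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            for c in np.unique(scores):
                j_c = (pos >= c).mean() + (neg < c).mean() - 1
                assert res.j >= j_c - 1e-12


class TestApplyDerivedCutoff:
    def test_in_sample_equals_youden_metrics(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        y, counts = apply_derived_cutoff((scores, labels), (scores, labels))
        assert counts.tp / counts.n_positive == pytest.approx(y.sens, abs=1e-12)
        assert counts.tn / counts.n_negative == pytest.approx(y.spec, abs=1e-12)

    def test_subgroup_evaluation_differs_from_in_sample(self, rng):
        labels = np.r_[np.zeros(150, int), np.ones(150, int)]
        scores = rng.normal(size=300) + labels
        sub = slice(0, 80)  # mostly-negative subgroup
        y, counts = apply_derived_cutoff((scores, labels), (scores[sub], labels[sub]))
        assert counts.n == 80
        in_sample = youden_cutoff(scores, labels)
        assert counts.tn / max(counts.n_negative, 1) != pytest.approx(in_sample.spec, abs=1e-6)

    def test_degenerate_evaluation_cohort(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        y, counts = apply_derived_cutoff(
            (scores, labels), (scores[:5], np.zeros(5, int))
        )
        assert counts.n_positive == 0  # sensitivity undefined downstream
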