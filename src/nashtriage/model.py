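"""Model/Results surface tying the pipeline together.

:class:`AtRiskTriageModel` is built from a patient-level cohort table and
a score registry; ``fit`` scores every patient, evaluates each test's
triage performance per age group (published low/high cutoffs plus Youden
cutoffs derived on the full cohort), and bootstrap AUROC intervals. The
returned :class:`TriageResults` carries the estimates with their
uncertainty, exposes head-to-head comparisons, and renders a summary
table shaped like a clinical-performance table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortFilter, EndpointSpec, endpoint_labels, filter_cohort, read_cohort_csv
from .compare import PairedComparison, compare_tests
from .roc import AurocEstimate, YoudenResult, bootstrap_auroc_ci, youden_cutoff
from .scores import (
    CutoffPolicy,
    ScoreDefinition,
    default_registry,
    score_all,
    score_frame_vectorized,
)
from .triage import (
    ConfusionCounts,
    ProportionEstimate,
    TriageTable,
    dichotomize,
    npv,
    ppv,
    prevalence,
    sensitivity,
    specificity,
    triage,
)

__all__ = ["AtRiskTriageModel", "TriageResults", "TestSubgroupResult"]


@dataclass
class TestSubgroupResult:
    """One test's full performance block on one subgroup."""

    test_name: str
    subgroup: str
    n: int
    auroc: AurocEstimate
    table: TriageTable
    youden: YoudenResult            # derived on the full cohort
    youden_counts: ConfusionCounts  # applied to this subgroup

    def metrics(self, arm: str) -> dict[str, ProportionEstimate]:
        """Sensitivity/specificity/NPV/PPV for 'rule_out', 'rule_in' or 'youden'."""
        counts = {
            "rule_out": self.table.rule_out,
            "rule_in": self.table.rule_in,
            "youden": self.youden_counts,
        }[arm]
        return {
            "sensitivity": sensitivity(counts),
            "specificity": specificity(counts),
            "npv": npv(counts),
            "ppv": ppv(counts),
        }


class AtRiskTriageModel:
    """Diagnostic-performance analysis of scored tests against at-risk NASH.

    Parameters
    ----------
    cohort
        Patient-level table (one row per patient, canonical column names).
        Filtered on construction: biopsy-blood gap <= 90 days and, by
        default, complete data for every registered test.
    registry
        Mapping of test name -> :class:`ScoreDefinition`; defaults to the
        six-test registry with published cutoffs.
    endpoint
        Histological endpoint rule (default: NAS >= 4 and F >= 2).
    cohort_filter
        Gap cap, age split and complete-case policy.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        registry: Mapping[str, ScoreDefinition] | None = None,
        endpoint: EndpointSpec = EndpointSpec(),
        cohort_filter: CohortFilter = CohortFilter(),
    ):
        self._default_registry = registry is None
        self.registry = default_registry() if registry is None else dict(registry)
        self.endpoint = endpoint
        self.cohort_filter = cohort_filter
        required = sorted({f for sd in self.registry.values() for f in sd.required_fields})
        required += ["nas", "fibrosis_stage"]
        self.cohort, self.exclusions = filter_cohort(cohort, cohort_filter, required)
        self.labels = endpoint_labels(self.cohort, endpoint)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AtRiskTriageModel":
        return cls(read_cohort_csv(path), **kwargs)

    def _score(self) -> pd.DataFrame:
        if self._default_registry:
            return score_frame_vectorized(self.cohort)
        scores, _ = score_all(self.cohort, self.registry)
        return scores

    def fit(self, n_boot: int = 1000, stratified: bool = True, seed=None) -> "TriageResults":
        """Score, triage and run ROC inference on every test and age group."""
        scores = self._score()
        age = self.cohort["age"].to_numpy()
        sex = self.cohort["sex"].to_numpy()
        split = self.cohort_filter.age_split
        subgroups = {
            "all": np.ones(len(age), dtype=bool),
            "lt65": age < split,
            "ge65": age >= split,
        }
        rng_seeds = {}
        base = 0 if seed is None else int(seed)
        results: dict[tuple[str, str], TestSubgroupResult] = {}
        youdens: dict[str, YoudenResult] = {}
        for t, name in enumerate(self.registry):
            s_full = scores[name].to_numpy()
            youdens[name] = youden_cutoff(s_full, self.labels, derivation_cohort_id="full")
            policy = self.registry[name].policy
            for g, (gname, mask) in enumerate(subgroups.items()):
                s, y = s_full[mask], self.labels[mask]
                if y.size == 0 or y.min() == y.max():
                    continue  # degenerate subgroup: no inference possible
                sub_seed = (base + 1009 * t + 7 * g) % (2**31 - 1)
                rng_seeds[(name, gname)] = sub_seed
                est = bootstrap_auroc_ci(s, y, n_boot=n_boot, stratified=stratified,
                                         seed=sub_seed)
                tab = triage(s, y, policy, sex=sex[mask], test_name=name)
                yc = dichotomize(s, y, youdens[name].cutoff)
                results[(name, gname)] = TestSubgroupResult(
                    test_name=name, subgroup=gname, n=int(mask.sum()),
                    auroc=est, table=tab, youden=youdens[name], youden_counts=yc,
                )
        return TriageResults(self, scores, results, youdens,
                             n_boot=n_boot, stratified=stratified, seed=seed)


@dataclass
class TriageResults:
    """Fitted diagnostic-performance results.

    Access per-test blocks via ``results[(test, subgroup)]`` with subgroup
    in {"all", "lt65", "ge65"}, head-to-head batteries via
    :meth:`compare`, tidy metrics via :meth:`to_frame`, and a printed
    report via :meth:`summary`.
    """

    model: AtRiskTriageModel
    scores: pd.DataFrame
    results: dict
    youden_cutoffs: dict
    n_boot: int
    stratified: bool
    seed: object = None

    def __getitem__(self, key) -> TestSubgroupResult:
        return self.results[key]

    @property
    def tests(self) -> list[str]:
        return list(self.model.registry)

    def prevalence(self, subgroup: str = "all") -> ProportionEstimate:
        mask = self._mask(subgroup)
        return prevalence(self.model.labels[mask])

    def _mask(self, subgroup: str) -> np.ndarray:
        age = self.model.cohort["age"].to_numpy()
        split = self.model.cohort_filter.age_split
        return {
            "all": np.ones(len(age), dtype=bool),
            "lt65": age < split,
            "ge65": age >= split,
        }[subgroup]

    def compare(self, test_a: str, test_b: str, subgroup: str = "ge65",
                **kwargs) -> dict[str, dict[str, PairedComparison]]:
        """Head-to-head battery: DeLong, McNemar, generalized score tests.

        Youden cutoffs are derived on the full cohort and applied to the
        requested subgroup, matching the evaluation design.
        """
        mask = self._mask(subgroup)
        sa = self.scores[test_a].to_numpy()
        sb = self.scores[test_b].to_numpy()
        labels = self.model.labels
        sex = self.model.cohort["sex"].to_numpy()
        return compare_tests(
            sa[mask], sb[mask], labels[mask],
            self.model.registry[test_a].policy,
            self.model.registry[test_b].policy,
            sex=sex[mask],
            youden_derivation=(sa, sb, labels),
            **kwargs,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(test, subgroup, arm, metric) table with CIs and counts."""
        rows = []
        for (name, gname), r in self.results.items():
            rows.append({
                "test": name, "subgroup": gname, "arm": "", "metric": "auroc",
                "estimate": r.auroc.auroc, "lower": r.auroc.ci_lower,
                "upper": r.auroc.ci_upper, "numerator": np.nan, "denominator": np.nan,
            })
            for arm in ("rule_out", "rule_in", "youden"):
                for metric, est in r.metrics(arm).items():
                    rows.append({
                        "test": name, "subgroup": gname, "arm": arm, "metric": metric,
                        "estimate": est.estimate if est.defined else np.nan,
                        "lower": est.lower if est.defined else np.nan,
                        "upper": est.upper if est.defined else np.nan,
                        "numerator": est.numerator, "denominator": est.denominator,
                    })
        return pd.DataFrame(rows)

    def summary(self, subgroup: str = "ge65") -> str:
        from .report import render_summary

        return render_summary(self, subgroup)

    def roc_csv(self, test: str, subgroup: str = "all") -> pd.DataFrame:
        """ROC operating points (cutoff, sensitivity, specificity)."""
        from .roc import roc_curve

        mask = self._mask(subgroup)
        return roc_curve(self.scores[test].to_numpy()[mask],
                         self.model.labels[mask]).to_frame()

    def plot_roc(self, subgroup: str = "ge65", ax=None):
        """Overlay the empirical ROC curves of all tests (matplotlib)."""
        import matplotlib.pyplot as plt
        from .roc import roc_curve

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        mask = self._mask(subgroup)
        for name in self.tests:
            curve = roc_curve(self.scores[name].to_numpy()[mask],
                              self.model.labels[mask])
            r = self.results.get((name, subgroup))
            label = f"{name} (AUROC {r.auroc.auroc:.2f})" if r else name
            ax.plot(1 - curve.spec, curve.sens, label=label)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax
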