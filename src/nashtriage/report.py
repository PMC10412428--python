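"""Monospace and CSV rendering of clinical-performance grids.

Every cell is formatted from values computed by the metrics operations —
no quantity is derived in this layer. Percentages print to 1 decimal,
AUROC to 2 decimals, counts as ``n (percent)``; undefined (zero-
denominator) metrics render as ``undefined`` rather than 0 or 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import round_half_up
from .triage import ProportionEstimate

__all__ = ["render_summary", "summary_frame"]

_ARM_TITLES = {
    "rule_out": "Rule-out (low risk)",
    "rule_in": "Rule-in (high risk)",
    "youden": "Youden",
}


def _fmt_count(k: int, n: int) -> str:
    pct = round_half_up(100.0 * k / n, 0) if n else float("nan")
    return f"{k} ({pct:.0f})"


def _cutoff_cell(r, arm: str) -> str:
    if arm == "youden":
        return f"<{r.youden.cutoff:.2f}"
    tab = r.table
    if tab.is_single_cutoff:
        return "ULN" if arm in ("rule_out", "rule_in") else "—"
    return (f"<{tab.rule_out.cutoff:.2f}" if arm == "rule_out"
            else f">={tab.rule_in.cutoff:.2f}")


def _zone_cell(r) -> str:
    tab = r.table
    if tab.is_single_cutoff:
        return "0 —"
    return _fmt_count(tab.n_intermediate, tab.n)


def summary_frame(results, subgroup: str) -> pd.DataFrame:
    """Table-shaped grid (rows = quantities, columns = tests) for one subgroup."""
    tests = [t for t in results.tests if (t, subgroup) in results.results]
    rows: dict[str, list[str]] = {}

    def put(row: str, vals: list[str]):
        rows[row] = vals

    put("AUROC", [
        f"{results[(t, subgroup)].auroc.auroc:.2f} "
        f"({results[(t, subgroup)].auroc.ci_lower:.2f}, "
        f"{results[(t, subgroup)].auroc.ci_upper:.2f})"
        for t in tests
    ])
    for arm in ("rule_out", "rule_in", "youden"):
        put(f"[{_ARM_TITLES[arm]}]", ["" for _ in tests])
        put(f"{arm}:cutoff", [_cutoff_cell(results[(t, subgroup)], arm) for t in tests])
        nvals = []
        for t in tests:
            r = results[(t, subgroup)]
            counts = {"rule_out": r.table.rule_out, "rule_in": r.table.rule_in,
                      "youden": r.youden_counts}[arm]
            k = counts.n_test_negative if arm in ("rule_out", "youden") else counts.n_test_positive
            nvals.append(_fmt_count(k, counts.n))
        put(f"{arm}:n (%)", nvals)
        for metric in ("sensitivity", "specificity", "npv", "ppv"):
            put(f"{arm}:{metric}", [
                str(results[(t, subgroup)].metrics(arm)[metric]) for t in tests
            ])
        if arm == "rule_out":
            put("rule_out:intermediate zone", [_zone_cell(results[(t, subgroup)]) for t in tests])
    df = pd.DataFrame(rows, index=tests).T
    df.index.name = "quantity"
    return df


def render_summary(results, subgroup: str = "ge65") -> str:
    """Monospace clinical-performance report for one age subgroup."""
    df = summary_frame(results, subgroup)
    prev = results.prevalence(subgroup)
    n = prev.denominator
    lines = [
        f"At-risk NASH triage performance — subgroup: {subgroup} (n = {n})",
        f"Endpoint prevalence: {prev}",
        f"Bootstrap: {results.n_boot} resamples"
        f" ({'stratified' if results.stratified else 'unstratified'}), seed {results.seed}",
        "",
        df.to_string(),
    ]
    return "\n".join(lines)
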