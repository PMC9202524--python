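"""Pairwise cluster comparison with FDR control.

Continuous and ordinal-scored variables are compared with two-sided
Mann-Whitney tests (exact null for small untied samples, otherwise the
normal approximation with tie and continuity corrections); discrete
presence/category variables (binary, categorical, count) with chi-square
tests on the level-by-cluster contingency table, without continuity
correction. Raw p-values are jointly adjusted across all tested variables
with the Benjamini-Hochberg step-up procedure at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClusterAssignment, CohortTable, VariableSpec

__all__ = ["bh_adjust", "compare_clusters", "PosthocResult"]

_EXACT_MAX_N = 20  # combined sample size bound for the exact Mann-Whitney null


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, boolean rejection mask). Adjusted
    p_i = min_{j >= rank(i)} m * p_(j) / j, capped at 1; the rejection set
    is exactly the step-up rule's output (reject the ``i`` with
    p_(i) <= i*q/m for i up to the largest such rank, i.e. adjusted <= q).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _chi_square(x: np.ndarray, y: np.ndarray, correction: bool) -> tuple[float, float, bool]:
    levels = np.unique(np.concatenate([x, y]))
    table = np.array(
        [[(x == lv).sum() for lv in levels], [(y == lv).sum() for lv in levels]]
    ).T
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:  # a single level observed: no association testable
        return 0.0, 1.0, False
    res = stats.chi2_contingency(table, correction=correction)
    low_expected = bool((res.expected_freq < 5).any())
    return float(res.statistic), float(res.pvalue), low_expected


@dataclass
class PosthocResult:
    """Per-variable comparison table between two clusters.

    ``table`` has one row per tested variable (test used, statistic, raw
    and BH-adjusted p, significance at the configured FDR, per-cluster
    summaries); ``excluded`` lists variables skipped for having fewer than
    two observed values in either cluster.
    """

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    fdr: float = 0.05
    cluster_a: int | None = None
    cluster_b: int | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def top_variables(self, m: int = 10) -> list[str]:
        """Variables ranked by adjusted then raw p-value."""
        ranked = self.table.sort_values(["p_adjusted", "p_raw"])
        return ranked.index[:m].tolist()


def _values_for(
    cohort: CohortTable, spec: VariableSpec, members: np.ndarray
) -> np.ndarray:
    col = cohort.data[spec.name].iloc[members]
    col = col.dropna()
    if spec.kind == "ordinal":
        mapping = {lv: float(i) for i, lv in enumerate(spec.levels)}
        return col.map(mapping).to_numpy(dtype=float)
    if spec.kind == "categorical":
        return col.to_numpy(dtype=object)
    return col.to_numpy(dtype=float)


def compare_clusters(
    cohort: CohortTable,
    specs: Sequence[VariableSpec],
    assignment: ClusterAssignment,
    cluster_a: int,
    cluster_b: int,
    fdr: float = 0.05,
    chi2_correction: bool = False,
    test_override: Mapping[str, str] | None = None,
) -> PosthocResult:
    """Compare two clusters on every variable, with joint BH correction.

    Missing values are excluded per variable; a variable with fewer than
    two observed values in either cluster is excluded and listed, not an
    error. ``test_override`` maps variable names to ``"mann-whitney"`` or
    ``"chi-square"`` to override the kind-based test choice.
    """
    if cluster_a == cluster_b:
        raise ValueError("cluster_a and cluster_b must differ")
    members_a = assignment.members(cluster_a)
    members_b = assignment.members(cluster_b)
    if members_a.size == 0 or members_b.size == 0:
        raise ValueError("both clusters must be nonempty")
    test_override = dict(test_override or {})

    rows = []
    excluded: list[str] = []
    for spec in specs:
        x = _values_for(cohort, spec, members_a)
        y = _values_for(cohort, spec, members_b)
        if x.size < 2 or y.size < 2:
            excluded.append(spec.name)
            continue
        test = test_override.get(
            spec.name,
            "mann-whitney" if spec.kind in ("continuous", "ordinal") else "chi-square",
        )
        low_expected = False
        if test == "mann-whitney":
            xf, yf = x.astype(float), y.astype(float)
            statistic, p = _mann_whitney(xf, yf)
            summary_a, summary_b = float(np.median(xf)), float(np.median(yf))
        elif test == "chi-square":
            statistic, p, low_expected = _chi_square(x, y, chi2_correction)
            if spec.kind in ("binary", "count", "continuous", "ordinal"):
                summary_a, summary_b = float(np.mean(x.astype(float))), float(np.mean(y.astype(float)))
            else:
                mode = lambda v: pd.Series(v).mode().iloc[0]
                summary_a, summary_b = mode(x), mode(y)
        else:
            raise ValueError(f"unknown test {test!r} for variable {spec.name!r}")
        rows.append(
            {
                "variable": spec.name,
                "group": spec.group,
                "test": test,
                "n_a": x.size,
                "n_b": y.size,
                "summary_a": summary_a,
                "summary_b": summary_b,
                "statistic": statistic,
                "p_raw": p,
                "low_expected_count": low_expected,
            }
        )
    table = pd.DataFrame(rows).set_index("variable") if rows else pd.DataFrame()
    if len(table):
        adjusted, reject = bh_adjust(table["p_raw"].to_numpy(), q=fdr)
        table["p_adjusted"] = adjusted
        table["significant"] = reject
    return PosthocResult(
        table=table, excluded=excluded, fdr=fdr, cluster_a=cluster_a, cluster_b=cluster_b
    )
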