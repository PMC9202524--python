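"""Test selection, exact small-sample behavior, and BH step-up correctness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from somnoclust import ClusterAssignment, VariableSpec, bh_adjust, compare_clusters

from conftest import make_cohort


def brute_force_bh(p, q=0.05):
    """Step-up rule straight from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            kmax = i
    reject[order[:kmax]] = True
    adjusted = np.empty(m)
    for idx in range(m):
        rank = int(np.where(order == idx)[0][0]) + 1
        adjusted[idx] = min(1.0, min(m * p[order[j - 1]] / j for j in range(rank, m + 1)))
    return adjusted, reject


class TestBhAdjust:
    def test_boundary_case_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        adjusted, reject = bh_adjust(p)
        assert np.allclose(adjusted, 0.05)
        assert reject.all()

    def test_none_rejected(self):
        adjusted, reject = bh_adjust([0.04, 0.5])
        assert adjusted == pytest.approx([0.08, 0.5])
        assert not reject.any()

    def test_single_p_identity(self):
        adjusted, reject = bh_adjust([0.049])
        assert adjusted[0] == pytest.approx(0.049)
        assert reject[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_bruteforce_stepup(self, pvals):
        adjusted, reject = bh_adjust(pvals)
        oracle_adj, oracle_rej = brute_force_bh(pvals)
        assert np.allclose(adjusted, oracle_adj, atol=1e-12)
        assert np.array_equal(reject, oracle_rej)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adjusted, reject = bh_adjust(p)
        sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adjusted, sm_adj, atol=1e-12)
        assert np.array_equal(reject, sm_rej)


def two_cluster_cohort(x, y, kind="continuous", levels=None):
    vals = list(x) + list(y)
    specs = [VariableSpec("v", kind, "g", levels=levels)]
    cohort = make_cohort({"v": vals})
    labels = np.array([1] * len(x) + [2] * len(y))
    return cohort, specs, ClusterAssignment(labels=labels, k=2)


class TestCompareClusters:
    def test_mann_whitney_exact_enumeration_case(self):
        """Fully separated 3-vs-3: U = 0 and exact two-sided p = 2/20."""
        cohort, specs, assignment = two_cluster_cohort([1, 2, 3], [4, 5, 6])
        res = compare_clusters(cohort, specs, assignment, 1, 2)
        row = res.table.loc["v"]
        assert row["test"] == "mann-whitney"
        assert row["statistic"] == 0.0
        assert row["p_raw"] == pytest.approx(0.1)

    def test_chi_square_closed_form_2x2(self):
        x = [1.0] * 10 + [0.0] * 20
        y = [1.0] * 20 + [0.0] * 10
        cohort, specs, assignment = two_cluster_cohort(x, y, kind="binary")
        res = compare_clusters(cohort, specs, assignment, 1, 2)
        row = res.table.loc["v"]
        assert row["test"] == "chi-square"
        assert row["statistic"] == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30 ** 4)
        assert row["statistic"] == pytest.approx(6.667, abs=1e-3)

    def test_identical_distributions_nothing_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.random(30)
        specs = [VariableSpec(f"v{i}", "continuous", "g") for i in range(5)]
        cohort = make_cohort({s.name: np.concatenate([vals, vals]) for s in specs})
        assignment = ClusterAssignment(labels=np.array([1] * 30 + [2] * 30), k=2)
        res = compare_clusters(cohort, specs, assignment, 1, 2)
        assert not res.table["significant"].any()
        assert (res.table["p_raw"] > 0.9).all()

    def test_monotone_transform_leaves_mann_whitney_invariant(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(12), rng.random(15) + 0.3
        c1, specs, assignment = two_cluster_cohort(x, y)
        c2, _, _ = two_cluster_cohort(np.exp(3 * x), np.exp(3 * y))
        p1 = compare_clusters(c1, specs, assignment, 1, 2).table.loc["v", "p_raw"]
        p2 = compare_clusters(c2, specs, assignment, 1, 2).table.loc["v", "p_raw"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_sparse_variable_excluded_not_error(self):
        cohort, specs, assignment = two_cluster_cohort(
            [1.0, np.nan, np.nan], [4.0, 5.0, 6.0]
        )
        res = compare_clusters(cohort, specs, assignment, 1, 2)
        assert res.excluded == ["v"]
        assert len(res.table) == 0

    def test_test_override_is_respected(self):
        cohort, specs, assignment = two_cluster_cohort(
            [0, 0, 1, 0, 1, 0], [1, 1, 0, 1, 1, 1], kind="binary"
        )
        res = compare_clusters(cohort, specs, assignment, 1, 2,
                               test_override={"v": "mann-whitney"})
        assert res.table.loc["v", "test"] == "mann-whitney"

    def test_same_cluster_rejected(self):
        cohort, specs, assignment = two_cluster_cohort([1, 2], [3, 4])
        with pytest.raises(ValueError):
            compare_clusters(cohort, specs, assignment, 1, 1)


def test_null_false_rejection_rate_controlled():
    """Structureless cohort with arbitrary labels: BH keeps the per-replicate
    falsely-rejected variable fraction near or below the nominal 5%."""
    rng = np.random.default_rng(42)
    n, n_vars, reps = 40, 10, 40
    specs = [VariableSpec(f"v{i}", "continuous", "g") for i in range(n_vars)]
    labels = ClusterAssignment(labels=np.array([1] * 20 + [2] * 20), k=2)
    fractions = []
    for _ in range(reps):
        cohort = make_cohort({s.name: rng.random(n) for s in specs})
        res = compare_clusters(cohort, specs, labels, 1, 2)
        fractions.append(res.table["significant"].mean())
    mc_sd = np.std(fractions, ddof=1) / np.sqrt(reps)
    assert np.mean(fractions) <= 0.05 + 2 * mc_sd + 1e-9
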