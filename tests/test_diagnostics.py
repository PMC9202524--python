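"""2x2 contingency statistics and per-cluster composition tables."""

import numpy as np
import pandas as pd
import pytest

from somnoclust import (
    ClusterAssignment,
    ContingencyStats,
    composition,
    contingency_from_fractions,
    contingency_stats,
)


def test_perfect_correspondence_all_ones():
    clusters = np.array([1, 1, 2, 2, 3, 3])
    labels = np.array(["NT2", "NT2", "IH", "IH", "NT1", "NT1"], dtype=object)
    stats = contingency_stats(clusters, labels, {1, 2}, {"NT2", "IH"})
    assert (stats.sensitivity, stats.specificity, stats.ppv, stats.npv) == (1, 1, 1, 1)


def test_published_table_reconstruction():
    """Cohort of 1,078 with 200 NT2 + 126 IH; the two non-cataplexy clusters
    (157 at 85% NT2/IH, 158 at 72%) as the test-positive set."""
    stats = contingency_from_fractions(
        cluster_sizes=[157, 158],
        positive_fraction_per_cluster=[0.45 + 0.40, 0.45 + 0.27],
        n_condition_positive=200 + 126,
        n_total=1078,
    )
    assert stats.total == pytest.approx(1078)
    assert stats.rounded() == {
        "sensitivity": 0.76,
        "specificity": 0.91,
        "ppv": 0.78,
        "npv": 0.90,
    }


@pytest.mark.parametrize("seed", range(5))
def test_aggregated_equals_per_individual_recount(seed):
    rng = np.random.default_rng(seed)
    n = 200
    clusters = rng.integers(1, 5, n)
    labels = rng.choice(["NT1", "NT2", "IH"], n).astype(object)
    pos_c, pos_l = {1, 3}, {"NT2"}
    s = contingency_stats(clusters, labels, pos_c, pos_l)
    # brute-force recount
    tp = sum(1 for c, l in zip(clusters, labels) if c in pos_c and l in pos_l)
    fp = sum(1 for c, l in zip(clusters, labels) if c in pos_c and l not in pos_l)
    fn = sum(1 for c, l in zip(clusters, labels) if c not in pos_c and l in pos_l)
    tn = n - tp - fp - fn
    assert (s.tp, s.fp, s.fn, s.tn) == (tp, fp, fn, tn)
    assert s.sensitivity == pytest.approx(tp / (tp + fn))


def test_swapping_positive_definitions_swaps_statistics():
    rng = np.random.default_rng(9)
    clusters = rng.integers(1, 4, 120)
    labels = rng.choice(["NT1", "NT2"], 120).astype(object)
    s = contingency_stats(clusters, labels, {1}, {"NT2"})
    swapped = contingency_stats(clusters, labels, {2, 3}, {"NT1"})
    assert swapped.sensitivity == pytest.approx(s.specificity)
    assert swapped.specificity == pytest.approx(s.sensitivity)
    assert swapped.ppv == pytest.approx(s.npv)
    assert swapped.npv == pytest.approx(s.ppv)


def test_zero_denominator_is_undefined_not_zero():
    s = ContingencyStats(tp=0, fp=0, fn=0, tn=10)
    assert np.isnan(s.sensitivity)
    assert np.isnan(s.ppv)
    assert s.specificity == 1.0


def test_empty_positive_clusters_rejected():
    with pytest.raises(ValueError):
        contingency_stats(np.array([1, 2]), np.array(["NT1", "NT2"], dtype=object),
                          set(), {"NT2"})


class TestComposition:
    def test_half_half_proportions(self):
        assignment = ClusterAssignment(labels=np.ones(4, dtype=int), k=1)
        comp = composition(
            assignment,
            ["NT1", "NT1", "NT2", "NT2"],
            ["definite"] * 4,
            [1, 1, 2, 2],
        )
        props = comp.cluster_diagnosis_proportions(1)
        assert props["NT1"] == pytest.approx(0.5)
        assert props["NT2"] == pytest.approx(0.5)

    def test_proportions_sum_to_one_per_cluster(self):
        rng = np.random.default_rng(2)
        n = 150
        assignment = ClusterAssignment(labels=rng.integers(1, 4, n), k=3)
        # ensure all three labels present
        lab = assignment.labels
        lab[:3] = [1, 2, 3]
        comp = composition(
            ClusterAssignment(labels=lab, k=3),
            rng.choice(["NT1", "NT2", "IH"], n),
            rng.choice(["definite", "probable"], n),
            rng.integers(1, 6, n),
        )
        for frame in (comp.diagnosis, comp.centers):
            sums = frame.groupby("cluster")["proportion"].sum()
            assert np.allclose(sums, 1.0)

    def test_length_mismatch_rejected(self):
        assignment = ClusterAssignment(labels=np.ones(3, dtype=int), k=1)
        with pytest.raises(ValueError):
            composition(assignment, ["NT1"], ["definite"], [1])


def test_study_scenario_cluster_composition(study_run):
    """The non-cataplexy clusters' diagnosis mix approximates the configured
    archetype probabilities (NT2 0.45 in both; IH 0.40 vs 0.27)."""
    scenario, cohort, truth, run = study_run
    comp = composition(run.assignment, cohort.labels["diagnosis"],
                       cohort.labels["certainty"], cohort.labels["center"])
    # clusters 3 and 4 are the 158/157 blocks (labels ordered by size)
    flags = cohort.labels["cataplexy"].to_numpy()
    fracs = {c: flags[run.assignment.members(c)].mean() for c in range(1, 8)}
    noncat = sorted(fracs, key=fracs.get)[:2]
    assert all(fracs[c] < 0.2 for c in noncat)
    for c in noncat:
        props = comp.cluster_diagnosis_proportions(c)
        n_c = run.assignment.members(c).size
        sd = np.sqrt(0.45 * 0.55 / n_c)
        assert abs(props.get("NT2", 0.0) - 0.45) <= 3.5 * sd
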