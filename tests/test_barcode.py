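"""Means and significance barcode panels: values, masks, null behavior."""

import numpy as np
import pandas as pd
import pytest

from somnoclust import (
    ClusterAssignment,
    VariableSpec,
    means_barcode,
    normalize,
    significance_barcode,
)


def normalized_from(data: dict, specs):
    return normalize(pd.DataFrame(data), specs)


def continuous(names):
    return [VariableSpec(n, "continuous", "g") for n in names]


def test_identity_partition_reproduces_column_means():
    rng = np.random.default_rng(0)
    specs = continuous(["x", "y"])
    table = normalized_from({"x": rng.random(40), "y": rng.random(40)}, specs)
    assignment = ClusterAssignment(labels=np.ones(40, dtype=int), k=1)
    panel = means_barcode(table, assignment)
    expected = table.data.mean()
    for v in ("x", "y"):
        assert panel.values.loc[1, v] == pytest.approx(expected[v], abs=1e-12)


def test_cells_under_ten_observations_are_blanked():
    specs = continuous(["x"])
    x = np.concatenate([np.full(9, 0.5), np.full(20, 0.2)])
    table = normalized_from({"x": x}, specs)
    labels = np.concatenate([np.full(9, 2), np.full(20, 1)])
    panel = means_barcode(table, ClusterAssignment(labels=labels, k=2))
    assert bool(panel.mask.loc[2, "x"])  # 9 observations: blank
    assert not bool(panel.mask.loc[1, "x"])
    assert np.isnan(panel.display_values().loc[2, "x"])


def test_mean_over_observed_values_only():
    specs = continuous(["x"])
    table = normalized_from({"x": [0.0, 0.5, np.nan, 1.0] + [0.0] * 10}, specs)
    labels = np.array([2] * 4 + [1] * 10)
    panel = means_barcode(table, ClusterAssignment(labels=labels, k=2), min_count=3)
    assert panel.values.loc[2, "x"] == pytest.approx(0.5)
    assert panel.counts.loc[2, "x"] == 3


def test_categorical_summarized_per_level_indicator():
    specs = [VariableSpec("c", "categorical", "g", levels=("a", "b"))]
    table = normalized_from({"c": ["a", "a", "b", "a"]}, specs)
    panel = means_barcode(table, ClusterAssignment(labels=np.ones(4, dtype=int), k=1), min_count=1)
    assert panel.values.loc[1, "c=a"] == pytest.approx(0.75)
    assert panel.values.loc[1, "c=b"] == pytest.approx(0.25)


class TestSignificanceBarcode:
    def make(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        specs = continuous(["x", "const"])
        table = normalized_from({"x": rng.random(n), "const": np.full(n, 0.3)}, specs)
        labels = np.array([1] * 60 + [2] * 60)
        return table, ClusterAssignment(labels=labels, k=2)

    def test_constant_variable_degenerate_null_is_masked(self):
        table, assignment = self.make()
        panel = significance_barcode(table, assignment, n_draws=50, seed=1, min_obs=5)
        assert panel.mask["const"].all()

    def test_display_requires_more_than_25_observations(self):
        rng = np.random.default_rng(3)
        specs = continuous(["x"])
        x = rng.random(100)
        x[:25] = np.nan  # cluster 1: exactly 25 observed -> blanked; cluster 2: 50
        table = normalized_from({"x": x}, specs)
        labels = np.concatenate([np.full(50, 1), np.full(50, 2)])
        panel = significance_barcode(table, ClusterAssignment(labels=labels, k=2),
                                     n_draws=100, seed=2)
        assert panel.counts.loc[1, "x"] == 25
        assert bool(panel.mask.loc[1, "x"])
        assert not bool(panel.mask.loc[2, "x"])

    def test_sign_convention_elevated_cluster_positive(self):
        specs = continuous(["x"])
        x = np.concatenate([np.full(60, 0.9), np.full(60, 0.1)])
        x += np.random.default_rng(4).normal(0, 0.01, 120)
        table = normalized_from({"x": x}, specs)
        labels = np.array([1] * 60 + [2] * 60)
        panel = significance_barcode(table, ClusterAssignment(labels=labels, k=2),
                                     n_draws=200, seed=5)
        assert panel.values.loc[1, "x"] > 0
        assert panel.values.loc[2, "x"] < 0

    def test_reproducible_from_seed(self):
        table, assignment = self.make()
        p1 = significance_barcode(table, assignment, n_draws=80, seed=11)
        p2 = significance_barcode(table, assignment, n_draws=80, seed=11)
        pd.testing.assert_frame_equal(p1.values, p2.values)

    def test_z_moves_with_cluster_not_label(self):
        """Relabeling the two (equal-sized) clusters swaps the z rows: the
        observation counts move exactly, the z values up to the independent
        Monte-Carlo noise of each pseudo-cluster slot."""
        table, assignment = self.make()
        swapped = ClusterAssignment(labels=np.where(assignment.labels == 1, 2, 1), k=2)
        p1 = significance_barcode(table, assignment, n_draws=3000, seed=7)
        p2 = significance_barcode(table, swapped, n_draws=3000, seed=7)
        assert p1.counts.loc[1, "x"] == p2.counts.loc[2, "x"]
        assert p1.values.loc[1, "x"] == pytest.approx(p2.values.loc[2, "x"], abs=0.2)
        assert p1.values.loc[2, "x"] == pytest.approx(p2.values.loc[1, "x"], abs=0.2)

    def test_whole_cohort_cluster_degenerates_to_mask(self):
        """A pseudo-cluster equal to the cohort has zero resampling spread."""
        rng = np.random.default_rng(8)
        specs = continuous(["x"])
        table = normalized_from({"x": rng.random(40)}, specs)
        assignment = ClusterAssignment(labels=np.ones(40, dtype=int), k=1)
        panel = significance_barcode(table, assignment, n_draws=60, seed=9, min_obs=5)
        assert panel.mask.loc[1, "x"].all() if hasattr(panel.mask.loc[1, "x"], "all") else bool(panel.mask.loc[1, "x"])

    def test_too_few_draws_rejected(self):
        table, assignment = self.make()
        with pytest.raises(ValueError):
            significance_barcode(table, assignment, n_draws=1)
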