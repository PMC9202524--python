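"""Relating cluster membership to external diagnosis labels.

The clustering never sees the diagnosis; only after the partition is fixed
are the labels brought in, as per-cluster composition tables (the data
behind diagnosis and center pie charts) and 2x2 contingency statistics
treating membership in a chosen set of clusters as the "test" and a chosen
set of diagnoses as the "condition". Cells may be fractional so a table
can be reconstructed from published percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ClusterAssignment, ContingencyStats

__all__ = ["contingency_stats", "contingency_from_fractions", "composition", "CompositionTable"]


def contingency_stats(
    assignment: ClusterAssignment | np.ndarray,
    labels: Sequence,
    positive_clusters: set,
    positive_labels: set,
) -> ContingencyStats:
    """2x2 statistics from per-individual cluster labels and diagnoses.

    Test-positive = membership in ``positive_clusters``; condition-positive
    = diagnosis in ``positive_labels``.
    """
    if not positive_clusters:
        raise ValueError("positive_clusters must be nonempty")
    cl = assignment.labels if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    lab = np.asarray(labels, dtype=object)
    if cl.size != lab.size:
        raise ValueError("labels must cover all individuals")
    test_pos = np.isin(cl, list(positive_clusters))
    cond_pos = np.isin(lab, list(positive_labels))
    return ContingencyStats(
        tp=float(np.sum(test_pos & cond_pos)),
        fp=float(np.sum(test_pos & ~cond_pos)),
        fn=float(np.sum(~test_pos & cond_pos)),
        tn=float(np.sum(~test_pos & ~cond_pos)),
    )


def contingency_from_fractions(
    cluster_sizes: Sequence[float],
    positive_fraction_per_cluster: Sequence[float],
    n_condition_positive: float,
    n_total: float,
) -> ContingencyStats:
    """Reconstruct a (possibly fractional) 2x2 table from published summaries.

    ``cluster_sizes`` and ``positive_fraction_per_cluster`` describe the
    test-positive clusters: each contributes size * fraction
    condition-positive members to TP. The remaining cells follow from the
    condition-positive total and the cohort size.
    """
    sizes = np.asarray(cluster_sizes, dtype=float)
    fracs = np.asarray(positive_fraction_per_cluster, dtype=float)
    if sizes.shape != fracs.shape:
        raise ValueError("one positive fraction per cluster size is required")
    test_pos = float(sizes.sum())
    tp = float((sizes * fracs).sum())
    fp = test_pos - tp
    fn = float(n_condition_positive) - tp
    tn = float(n_total) - test_pos - fn
    return ContingencyStats(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class CompositionTable:
    """Per-cluster composition by diagnosis x certainty and by center.

    ``diagnosis`` rows are (cluster, diagnosis, certainty) with counts and
    within-cluster proportions; ``centers`` likewise per center id.
    Proportions within each cluster sum to 1 — exactly the slices of the
    per-cluster pie charts.
    """

    diagnosis: pd.DataFrame
    centers: pd.DataFrame

    def cluster_diagnosis_proportions(self, cluster: int) -> pd.Series:
        sub = self.diagnosis[self.diagnosis["cluster"] == cluster]
        return sub.groupby("diagnosis")["proportion"].sum()


def composition(
    assignment: ClusterAssignment,
    diagnosis: Sequence,
    certainty: Sequence,
    centers: Sequence,
) -> CompositionTable:
    """Per-cluster diagnosis(+certainty) and center proportion tables."""
    cl = assignment.labels
    n = cl.size
    if not (len(diagnosis) == len(certainty) == len(centers) == n):
        raise ValueError("all label vectors must match the assignment length")
    frame = pd.DataFrame(
        {
            "cluster": cl,
            "diagnosis": np.asarray(diagnosis, dtype=object),
            "certainty": np.asarray(certainty, dtype=object),
            "center": np.asarray(centers),
        }
    )
    diag = (
        frame.groupby(["cluster", "diagnosis", "certainty"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cluster_sizes = frame["cluster"].value_counts()
    diag["proportion"] = diag["count"] / diag["cluster"].map(cluster_sizes)
    cent = frame.groupby(["cluster", "center"], sort=True).size().rename("count").reset_index()
    cent["proportion"] = cent["count"] / cent["cluster"].map(cluster_sizes)
    return CompositionTable(diagnosis=diag, centers=cent)
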