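"""Cluster-count evaluation metrics and the subpopulation-based choice of k.

Standard internal quality scores rarely pick a single k on heterogeneous
clinical cohorts, so alongside silhouette/Dunn/within-between metrics this
module formalizes the clinically motivated rule actually used to settle k:
walk the dendrogram cuts and find the smallest k at which a flagged
subpopulation (here: patients without cataplexy) occupies at least two
clusters that are each dominated by flagged members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .hcluster import Dendrogram, cut
from .preprocess import NormalizedTable
from .types import ClusterAssignment

__all__ = ["evaluate_k", "trace_subpopulation", "SubpopulationTrace"]


def _mean_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    vals = silhouette_samples(d, labels, metric="precomputed")
    sizes = np.bincount(labels)[labels]
    vals = np.where(sizes <= 1, 0.0, vals)  # singleton convention
    return float(vals.mean())


def _dunn(d: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max within-cluster diameter."""
    ks = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for a in ks:
        ia = labels == a
        da = d[np.ix_(ia, ia)]
        if ia.sum() > 1:
            max_within = max(max_within, float(da.max()))
        for b in ks:
            if b <= a:
                continue
            block = d[np.ix_(ia, labels == b)]
            min_between = min(min_between, float(block.min()))
    if max_within == 0.0:
        return float("inf") if np.isfinite(min_between) else 0.0
    return float(min_between / max_within)


def _within_between_ratio(d: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices_from(d, k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if within.size == 0 or between.size == 0:
        return float("nan")
    return float(within.mean() / between.mean())


def _one_hot(table: NormalizedTable) -> np.ndarray:
    """Numeric embedding for coordinate-based scores: categorical one-hot,
    missing entries filled with the column mean."""
    cols = []
    for spec in table.specs:
        col = table.data[spec.name]
        if spec.kind == "categorical":
            dummies = pd.get_dummies(col).astype(float)
            dummies[col.isna()] = np.nan
            for c in dummies.columns:
                cols.append(dummies[c])
        else:
            cols.append(col.astype(float))
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    return X


def evaluate_k(
    d: np.ndarray,
    tree: Dendrogram,
    k_range,
    table: NormalizedTable | None = None,
) -> pd.DataFrame:
    """Internal quality metrics for every cut in ``k_range``.

    Returns one row per k with silhouette (singletons scoring 0), Dunn
    index and the within/between mean-dissimilarity ratio, all computed
    from the distance matrix. When the normalized table is supplied, the
    coordinate-based Calinski-Harabasz score is reported in a separate
    column (computed on a one-hot embedding, mean-imputed).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    n = tree.n
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    X = _one_hot(table) if table is not None else None
    rows = []
    for k in ks:
        labels = cut(tree, k).labels
        row = {
            "k": k,
            "silhouette": _mean_silhouette(d, labels),
            "dunn": _dunn(d, labels),
            "within_between": _within_between_ratio(d, labels),
        }
        if X is not None:
            row["calinski_harabasz"] = float(calinski_harabasz_score(X, labels))
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


@dataclass
class SubpopulationTrace:
    """Composition of every cut by a boolean subpopulation flag.

    ``composition`` has one row per (k, cluster) with flagged/unflagged
    member counts; ``pure_members`` maps k to the member-index sets of the
    clusters whose flagged fraction reaches the purity threshold;
    ``selected_k`` is the minimal k at which the flagged individuals occupy
    at least two such clusters (None if never).
    """

    composition: pd.DataFrame
    purity_threshold: float
    pure_members: dict[int, list[frozenset]] = field(default_factory=dict)
    selected_k: int | None = None

    def n_pure(self, k: int) -> int:
        return len(self.pure_members.get(k, []))

    def stable_between(self, k_lo: int, k_hi: int) -> bool:
        """Whether the identical flagged-pure cluster member sets persist
        for every k in [k_lo, k_hi]."""
        ks = [k for k in self.pure_members if k_lo <= k <= k_hi]
        if len(ks) != k_hi - k_lo + 1:
            return False
        ref = set(self.pure_members[k_lo])
        return all(set(self.pure_members[k]) == ref for k in ks)


def trace_subpopulation(
    tree: Dendrogram,
    flags,
    k_range,
    purity_threshold: float = 0.8,
    min_size: int = 10,
) -> SubpopulationTrace:
    """Track how a flagged subpopulation is divided as k varies.

    A cluster counts as flagged-pure when it has at least ``min_size``
    members and its flagged fraction is at least ``purity_threshold``
    (required in (0.5, 1]). The selected k is the minimal k in range at
    which flagged individuals occupy >= 2 flagged-pure clusters — the
    formal counterpart of visually inspecting the clustering steps for the
    point where the subpopulation first splits into distinct groups. The
    size floor keeps stray outlier fragments from counting as groups, as a
    visual inspection naturally would.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != tree.n:
        raise ValueError("flags must have one entry per individual")
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must be in (0.5, 1]")
    ks = sorted(set(int(k) for k in k_range))
    rows = []
    pure_members: dict[int, list[frozenset]] = {}
    selected: int | None = None
    for k in ks:
        assignment = cut(tree, k)
        pure: list[frozenset] = []
        for c in range(1, k + 1):
            members = assignment.members(c)
            n_flagged = int(flags[members].sum())
            frac = n_flagged / members.size
            rows.append(
                {
                    "k": k,
                    "cluster": c,
                    "size": members.size,
                    "flagged": n_flagged,
                    "unflagged": members.size - n_flagged,
                    "flagged_fraction": frac,
                }
            )
            if n_flagged > 0 and members.size >= min_size and frac >= purity_threshold:
                pure.append(frozenset(members.tolist()))
        pure_members[k] = pure
        if selected is None and len(pure) >= 2:
            selected = k
    composition = pd.DataFrame(rows)
    return SubpopulationTrace(
        composition=composition,
        purity_threshold=purity_threshold,
        pure_members=pure_members,
        selected_k=selected,
    )
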