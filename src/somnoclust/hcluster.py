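"""Agglomerative hierarchical clustering of a precomputed dissimilarity matrix.

Every individual starts as a singleton cluster; the closest pair of
clusters is merged repeatedly under the chosen linkage until one cluster
remains. Supported linkages are average (default) and complete — both are
defined directly on dissimilarities, so they are compatible with the
non-Euclidean Gower matrix (Ward, which assumes squared Euclidean
geometry, is deliberately not offered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .types import ClusterAssignment

__all__ = ["Dendrogram", "agglomerate", "cut"]

_LINKAGES = ("average", "complete")


@dataclass
class Dendrogram:
    """The n-1 merges of an agglomeration, in SciPy linkage-matrix form.

    Row i of ``merges`` is (left id, right id, merge height, resulting
    size); leaves are ids 0..n-1 and the cluster created by row i gets id
    n+i. Heights are nondecreasing for the supported linkages.
    """

    merges: np.ndarray  # (n-1, 4) float
    n: int
    method: str

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n - 1, 4):
            raise ValueError("dendrogram must contain exactly n-1 merges")

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def leaves_of(self, node: int) -> list[int]:
        """All leaf indices under an internal or leaf node id."""
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                row = self.merges[v - self.n]
                stack.extend((int(row[0]), int(row[1])))
        return sorted(out)


def _validate_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def agglomerate(d: np.ndarray, method: str = "average") -> Dendrogram:
    """Full agglomeration of a distance matrix under average/complete linkage."""
    d = _validate_square(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals to cluster")
    if method not in _LINKAGES:
        raise ValueError(f"unsupported linkage {method!r}; use one of {_LINKAGES}")
    condensed = squareform(d, checks=False)
    merges = _scipy_linkage(condensed, method=method)
    return Dendrogram(merges=np.asarray(merges, dtype=float), n=n, method=method)


def cut(tree: Dendrogram, k: int) -> ClusterAssignment:
    """Flat partition into k clusters by undoing the last k-1 merges.

    Cluster labels 1..k are assigned in decreasing size order, ties broken
    by the smallest member position, so cluster 1 is always the largest.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):  # apply first n-k merges
        a, b = int(tree.merges[i, 0]), int(tree.merges[i, 1])
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new

    roots = np.array([find(i) for i in range(n)])
    _, inverse = np.unique(roots, return_inverse=True)
    # relabel by decreasing size; ties by smallest member position
    sizes = np.bincount(inverse)
    first_member = np.full(sizes.size, n, dtype=int)
    for i in range(n - 1, -1, -1):
        first_member[inverse[i]] = i
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], first_member[c]))
    rank = np.empty(sizes.size, dtype=int)
    rank[order] = np.arange(1, sizes.size + 1)
    return ClusterAssignment(labels=rank[inverse], k=k)
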