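"""End-to-end orchestration of the clustering chain.

`run_clustering` is the single path from a raw cohort to a flat partition
(normalize -> weight -> Gower -> agglomerate -> cut); every consumer —
the analysis drivers, the CLI, the robustness re-runs — goes through it so
variants differ only in their declared settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import gower
from .hcluster import Dendrogram, agglomerate, cut
from .preprocess import NormalizedTable, assign_weights, normalize
from .types import ClusterAssignment, CohortTable, VariableSpec

__all__ = ["PipelineConfig", "ClusterRun", "run_clustering"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one clustering run (and its downstream panels)."""

    weight_scheme: str = "grouped"
    linkage: str = "average"
    k: int = 7
    k_min: int = 2
    k_max: int = 15
    n_draws: int = 10_000
    fdr: float = 0.05
    purity_threshold: float = 0.8
    seed: int = 0

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


@dataclass
class ClusterRun:
    """All intermediate artifacts of one clustering run."""

    normalized: NormalizedTable
    weights: pd.Series
    distance: np.ndarray
    tree: Dendrogram
    assignment: ClusterAssignment
    config: PipelineConfig


def run_clustering(
    cohort: CohortTable | pd.DataFrame,
    specs: Sequence[VariableSpec],
    config: PipelineConfig | None = None,
) -> ClusterRun:
    """Normalize, weight, compute Gower distances, agglomerate, and cut at k."""
    config = config or PipelineConfig()
    normalized = normalize(cohort, specs)
    weights = assign_weights(specs, scheme=config.weight_scheme)
    d = gower(normalized, weights)
    tree = agglomerate(d, method=config.linkage)
    assignment = cut(tree, config.k)
    if isinstance(cohort, CohortTable):
        assignment.ids = cohort.ids
    return ClusterRun(
        normalized=normalized,
        weights=weights,
        distance=d,
        tree=tree,
        assignment=assignment,
        config=config,
    )
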