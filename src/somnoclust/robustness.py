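"""Cluster reproducibility under subset resampling, and re-clustering variants.

Two complementary checks that a partition is not an artifact of the exact
sample or the analysis settings:

- ``subset_stability`` re-runs the full pipeline on random subsets of the
  cohort and scores, for every original cluster, the best-match Jaccard
  similarity with any subset cluster (adjusted Rand index over the subset
  reported alongside).
- ``run_variants`` repeats the clustering under three settings changes —
  excluding individuals with cataplexy and/or hypocretin-1 deficiency
  (< 110 pg/mL), uniform variable weights, and recoding the nocturnal REM
  latency to a sleep-onset-REM-period indicator — and checks whether the
  top variables differentiating the two non-cataplexy-dominated clusters
  overlap those of the base run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .pipeline import ClusterRun, PipelineConfig, run_clustering
from .posthoc import compare_clusters
from .types import ClusterAssignment, CohortTable, VariableSpec

__all__ = [
    "StabilityReport",
    "subset_stability",
    "VariantReport",
    "run_variants",
    "best_match_jaccard",
    "HYPOCRETIN_DEFICIENCY_THRESHOLD",
    "SOREMP_REM_LATENCY_MINUTES",
]

HYPOCRETIN_DEFICIENCY_THRESHOLD = 110.0  # pg/mL, strict <
SOREMP_REM_LATENCY_MINUTES = 15.0  # REM latency <= 15 min counts as a SOREMP


def best_match_jaccard(members: set, partition: ClusterAssignment) -> float:
    """Best Jaccard similarity of a member set against any cluster of a partition."""
    best = 0.0
    for c in range(1, partition.k + 1):
        other = set(partition.members(c).tolist())
        inter = len(members & other)
        union = len(members | other)
        if union:
            best = max(best, inter / union)
    return best


@dataclass
class StabilityReport:
    """Per-original-cluster Jaccard reproducibility over subset replicates."""

    per_cluster: pd.DataFrame  # index cluster: mean_jaccard, sd_jaccard
    ari_mean: float
    ari_sd: float
    n_reps: int
    fraction: float
    seed: int | None
    skipped: int = 0


def subset_stability(
    cohort: CohortTable,
    specs: Sequence[VariableSpec],
    config: PipelineConfig | None = None,
    fraction: float = 0.8,
    n_reps: int = 50,
    seed: int | None = None,
    base_run: ClusterRun | None = None,
) -> StabilityReport:
    """Re-cluster random subsets and score agreement with the full-run clusters.

    Each replicate samples ``floor(fraction * n)`` individuals without
    replacement, re-runs the pipeline at the same k, and records per
    original cluster the best-match Jaccard between the cluster restricted
    to the subset and any subset cluster. Replicates whose subset is too
    small to form k clusters are skipped and counted.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    config = config or PipelineConfig()
    if base_run is None:
        base_run = run_clustering(cohort, specs, config)
    n = cohort.n
    m = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    k = config.k

    jaccards: dict[int, list[float]] = {c: [] for c in range(1, k + 1)}
    aris: list[float] = []
    skipped = 0
    base_labels = base_run.assignment.labels
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        if m < k:
            skipped += 1
            continue
        sub_data = cohort.data.iloc[idx]
        sub_labels = cohort.labels.iloc[idx]
        sub_cohort = CohortTable(data=sub_data, labels=sub_labels)
        try:
            sub_run = run_clustering(sub_cohort, specs, config)
        except ValueError:
            skipped += 1
            continue
        pos_of = {orig: j for j, orig in enumerate(idx)}
        for c in range(1, k + 1):
            orig_members = base_run.assignment.members(c)
            restricted = {pos_of[i] for i in orig_members if i in pos_of}
            if restricted:
                jaccards[c].append(best_match_jaccard(restricted, sub_run.assignment))
        aris.append(adjusted_rand_score(base_labels[idx], sub_run.assignment.labels))

    rows = []
    for c in range(1, k + 1):
        vals = np.array(jaccards[c]) if jaccards[c] else np.array([np.nan])
        rows.append(
            {"cluster": c, "mean_jaccard": float(np.nanmean(vals)), "sd_jaccard": float(np.nanstd(vals, ddof=1)) if vals.size > 1 else 0.0}
        )
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    aris_arr = np.array(aris) if aris else np.array([np.nan])
    return StabilityReport(
        per_cluster=per_cluster,
        ari_mean=float(np.nanmean(aris_arr)),
        ari_sd=float(np.nanstd(aris_arr, ddof=1)) if aris_arr.size > 1 else 0.0,
        n_reps=n_reps,
        fraction=fraction,
        seed=seed,
        skipped=skipped,
    )


@dataclass
class VariantResult:
    name: str
    description: str
    n_individuals: int
    cluster_sizes: tuple[int, ...]
    compared_clusters: tuple[int, int]
    top_variables: list[str]
    overlap: float


@dataclass
class VariantReport:
    """Base-run top variables and each variant's agreement with them."""

    base_top: list[str]
    base_compared: tuple[int, int]
    variants: dict[str, VariantResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": v.name,
                "description": v.description,
                "n": v.n_individuals,
                "cluster_sizes": "/".join(map(str, v.cluster_sizes)),
                "compared_clusters": f"{v.compared_clusters[0]} vs {v.compared_clusters[1]}",
                "top_variables": ";".join(v.top_variables),
                "overlap_with_base": v.overlap,
            }
            for v in self.variants.values()
        ]
        return pd.DataFrame(rows).set_index("variant")


def _noncataplexy_pair(assignment: ClusterAssignment, cataplexy: np.ndarray) -> tuple[int, int]:
    """The two clusters least dominated by cataplexy (ties: larger first)."""
    fracs = []
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        fracs.append((float(np.nanmean(cataplexy[members])), -members.size, c))
    fracs.sort()
    return fracs[0][2], fracs[1][2]


def _top_overlap(variant_top: list[str], base_top: list[str]) -> float:
    if not base_top:
        return float("nan")
    return len(set(variant_top) & set(base_top)) / len(base_top)


def run_variants(
    cohort: CohortTable,
    specs: Sequence[VariableSpec],
    config: PipelineConfig | None = None,
    top_m: int = 10,
    hypocretin_var: str = "hypocretin_1_level",
    rem_latency_var: str = "psg_rem_latency",
    base_run: ClusterRun | None = None,
) -> VariantReport:
    """The three re-clustering robustness variants against a base run.

    (a) exclude individuals with cataplexy and/or hypocretin-1 deficiency;
    (b) uniform weighting of all variables; (c) recode the continuous
    nocturnal REM latency into a binary sleep-onset-REM-period indicator.
    Each variant re-runs the clustering and re-derives the top ``top_m``
    variables differentiating its two non-cataplexy-dominated clusters;
    ``overlap`` is the fraction of the base run's top variables recovered.
    """
    config = config or PipelineConfig()
    if base_run is None:
        base_run = run_clustering(cohort, specs, config)
    cataplexy = cohort.labels["cataplexy"].to_numpy(dtype=float)

    def top_for(run: ClusterRun, coh: CohortTable, sp, cat) -> tuple[list[str], tuple[int, int]]:
        a, b = _noncataplexy_pair(run.assignment, cat)
        res = compare_clusters(coh, sp, run.assignment, a, b, fdr=config.fdr)
        return res.top_variables(top_m), (a, b)

    base_top, base_pair = top_for(base_run, cohort, specs, cataplexy)
    report = VariantReport(base_top=base_top, base_compared=base_pair)

    # (a) exclusion of cataplexy and/or hypocretin deficiency
    hcrt = cohort.data[hypocretin_var].to_numpy(dtype=float)
    drop = (cataplexy == 1) | (hcrt < HYPOCRETIN_DEFICIENCY_THRESHOLD)
    keep = ~drop
    if keep.sum() == 0:
        raise ValueError("exclusion filter removed every individual")
    sub = CohortTable(data=cohort.data.loc[keep], labels=cohort.labels.loc[keep])
    k_a = min(config.k, max(2, int(keep.sum()) - 1))
    run_a = run_clustering(sub, specs, config.with_(k=k_a))
    top_a, pair_a = top_for(run_a, sub, specs, cataplexy[keep])
    report.variants["exclude_cataplexy_hcrt"] = VariantResult(
        name="exclude_cataplexy_hcrt",
        description="exclude cataplexy and/or hypocretin-1 < 110 pg/mL",
        n_individuals=int(keep.sum()),
        cluster_sizes=tuple(run_a.assignment.sizes.tolist()),
        compared_clusters=pair_a,
        top_variables=top_a,
        overlap=_top_overlap(top_a, base_top),
    )

    # (b) uniform weights
    run_b = run_clustering(cohort, specs, config.with_(weight_scheme="uniform"))
    top_b, pair_b = top_for(run_b, cohort, specs, cataplexy)
    report.variants["uniform_weights"] = VariantResult(
        name="uniform_weights",
        description="uniform weighting for all variables",
        n_individuals=cohort.n,
        cluster_sizes=tuple(run_b.assignment.sizes.tolist()),
        compared_clusters=pair_b,
        top_variables=top_b,
        overlap=_top_overlap(top_b, base_top),
    )

    # (c) REM latency -> SOREMP indicator
    recoded_specs: list[VariableSpec] = []
    for s in specs:
        if s.name == rem_latency_var:
            recoded_specs.append(VariableSpec("psg_soremp", "binary", s.group))
        else:
            recoded_specs.append(s)
    data_c = cohort.data.copy()
    latency = pd.to_numeric(data_c.pop(rem_latency_var), errors="coerce")
    data_c["psg_soremp"] = (latency <= SOREMP_REM_LATENCY_MINUTES).astype(float).where(latency.notna())
    cohort_c = CohortTable(data=data_c, labels=cohort.labels)
    run_c = run_clustering(cohort_c, recoded_specs, config)
    top_c, pair_c = top_for(run_c, cohort_c, recoded_specs, cataplexy)
    report.variants["soremp_recoding"] = VariantResult(
        name="soremp_recoding",
        description=f"recode {rem_latency_var} to SOREMP presence (<= {SOREMP_REM_LATENCY_MINUTES:g} min)",
        n_individuals=cohort.n,
        cluster_sizes=tuple(run_c.assignment.sizes.tolist()),
        compared_clusters=pair_c,
        top_variables=top_c,
        overlap=_top_overlap(top_c, base_top),
    )
    return report
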