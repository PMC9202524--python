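"""Cluster means barcodes and resampling-based significances barcodes.

The means barcode is the clusters x variables matrix of mean normalized
values (categorical variables summarized per level indicator). The
significances barcode asks how far each cluster mean sits from what a
random grouping of the whole cohort would produce: the cohort is
repeatedly re-partitioned at random into pseudo-clusters of the observed
sizes, the per-pseudo-cluster per-variable means are collected over B
draws, and each observed cluster mean is expressed as a z-score

    z_{c,v} = (m_{c,v} - mu*_{c,v}) / sigma*_{c,v}

against the resampled mean mu* and SD sigma* (B-1 denominator), so
positive z marks a significantly elevated value. Cells supported by too
few observations are blanked: fewer than 10 for means panels, 25 or fewer
for significance panels; a degenerate null (sigma* = 0) is blanked too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedTable
from .types import ClusterAssignment

__all__ = ["BarcodePanel", "expand_indicators", "means_barcode", "significance_barcode"]

MEANS_MIN_COUNT = 10  # cells with fewer observations are blanked
SIG_MIN_OBS = 25  # display in the significance panel requires > 25 observations


@dataclass
class BarcodePanel:
    """One barcode panel: values, per-cell observation counts, blanking mask.

    ``values`` is clusters x expanded-variables (means in [0, 1] for a
    means panel, z-scores for a significance panel); ``mask`` is True where
    the cell is blanked and carries no displayed value. Significance panels
    additionally carry the resampled null mean/SD and the draw count/seed.
    """

    kind: str  # "means" | "significance"
    values: pd.DataFrame
    counts: pd.DataFrame
    mask: pd.DataFrame
    groups: pd.Series  # expanded-variable -> category group
    null_mean: pd.DataFrame | None = None
    null_sd: pd.DataFrame | None = None
    n_draws: int | None = None
    seed: int | None = None

    def display_values(self) -> pd.DataFrame:
        """Values with blanked cells set to NaN (the rendered form)."""
        return self.values.mask(self.mask)


def expand_indicators(table: NormalizedTable) -> tuple[np.ndarray, list[str], pd.Series]:
    """Expand the normalized table to a numeric matrix with NaN missingness.

    Numeric-scored columns pass through; each categorical column becomes
    one 0/1 indicator per level (``var=level``), NaN where the individual
    is missing. Returns (matrix, expanded names, name -> group map).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, str] = {}
    for spec in table.specs:
        col = table.data[spec.name]
        if spec.kind == "categorical":
            missing = col.isna().to_numpy()
            for level in spec.levels:
                x = (col == level).to_numpy(dtype=float)
                x[missing] = np.nan
                cols.append(x)
                name = f"{spec.name}={level}"
                names.append(name)
                groups[name] = spec.group
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(spec.name)
            groups[spec.name] = spec.group
    X = np.column_stack(cols)
    return X, names, pd.Series(groups)


def _cluster_means(X: np.ndarray, obs: np.ndarray, assignment: ClusterAssignment):
    k = assignment.k
    sums = np.zeros((k, X.shape[1]))
    counts = np.zeros((k, X.shape[1]))
    Xz = np.where(obs, X, 0.0)
    for c in range(1, k + 1):
        members = assignment.members(c)
        sums[c - 1] = Xz[members].sum(axis=0)
        counts[c - 1] = obs[members].sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def means_barcode(
    table: NormalizedTable,
    assignment: ClusterAssignment,
    min_count: int = MEANS_MIN_COUNT,
) -> BarcodePanel:
    """Clusters x variables mean normalized values, blanked under ``min_count``."""
    if assignment.n != table.n:
        raise ValueError("assignment does not cover the table's individuals")
    X, names, groups = expand_indicators(table)
    obs = ~np.isnan(X)
    means, counts = _cluster_means(X, obs, assignment)
    idx = pd.Index(range(1, assignment.k + 1), name="cluster")
    values = pd.DataFrame(means, index=idx, columns=names)
    cdf = pd.DataFrame(counts.astype(int), index=idx, columns=names)
    mask = cdf < min_count
    return BarcodePanel(kind="means", values=values, counts=cdf, mask=mask, groups=groups)


def significance_barcode(
    table: NormalizedTable,
    assignment: ClusterAssignment,
    n_draws: int = 10_000,
    seed: int | None = None,
    min_obs: int = SIG_MIN_OBS,
) -> BarcodePanel:
    """Resampling z-scores of cluster means against size-matched random draws.

    Each draw partitions the cohort (without replacement) into
    pseudo-clusters of exactly the observed sizes; mu* and sigma* are the
    across-draw mean and SD of the pseudo-cluster means. Cells with
    ``min_obs`` or fewer observations, or with sigma* = 0, are blanked.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if assignment.n != table.n:
        raise ValueError("assignment does not cover the table's individuals")
    X, names, groups = expand_indicators(table)
    obs = ~np.isnan(X)
    means, counts = _cluster_means(X, obs, assignment)

    sizes = assignment.sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    n, k = assignment.n, assignment.k
    Xz = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    rng = np.random.default_rng(seed)

    acc = np.zeros((k, X.shape[1]))
    acc_sq = np.zeros((k, X.shape[1]))
    for _ in range(n_draws):
        perm = rng.permutation(n)
        sums = np.add.reduceat(Xz[perm], offsets, axis=0)
        cnts = np.add.reduceat(obs_f[perm], offsets, axis=0)
        with np.errstate(invalid="ignore"):
            m = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        m = np.nan_to_num(m)  # empty pseudo-cluster cells contribute 0
        acc += m
        acc_sq += m * m
    mu = acc / n_draws
    var = (acc_sq - n_draws * mu * mu) / (n_draws - 1)
    sd = np.sqrt(np.maximum(var, 0.0))

    # constant variable or whole-cohort pseudo-cluster: the accumulated
    # variance is pure float cancellation noise (values live on [0, 1])
    degenerate = sd <= 1e-7
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(~degenerate, (means - mu) / np.where(degenerate, 1.0, sd), np.nan)

    idx = pd.Index(range(1, k + 1), name="cluster")
    values = pd.DataFrame(z, index=idx, columns=names)
    cdf = pd.DataFrame(counts.astype(int), index=idx, columns=names)
    mask = (cdf <= min_obs) | pd.DataFrame(degenerate, index=idx, columns=names)
    mask |= values.isna()
    return BarcodePanel(
        kind="significance",
        values=values,
        counts=cdf,
        mask=mask,
        groups=groups,
        null_mean=pd.DataFrame(mu, index=idx, columns=names),
        null_sd=pd.DataFrame(sd, index=idx, columns=names),
        n_draws=n_draws,
        seed=seed,
    )
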