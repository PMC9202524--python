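"""Weighted Gower dissimilarity over mixed-type variables with missingness.

For individuals i, j the dissimilarity is

    d(i, j) = sum_v w_v * delta_v(i,j) * s_v(i,j) / sum_v w_v * delta_v(i,j)

where delta_v = 1 iff both are observed on v, s_v = |x_iv - x_jv| for
numeric-scored variables (already scaled to [0, 1]) and a mismatch
indicator for categorical variables. Renormalizing by the observed weight
mass keeps the distance unbiased under missing-completely-at-random data;
a pair sharing no observed variable is an error, never a silent value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import NormalizedTable

__all__ = ["gower"]


def gower(table: NormalizedTable, weights: pd.Series) -> np.ndarray:
    """Pairwise weighted Gower dissimilarity matrix (n x n, in [0, 1])."""
    names = [s.name for s in table.specs]
    missing_w = [n for n in names if n not in weights.index]
    if missing_w:
        raise ValueError(f"weights missing for variables: {missing_w}")
    n = table.n
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for spec in table.specs:
        col = table.data[spec.name]
        w = float(weights[spec.name])
        if w == 0.0:
            continue
        if spec.kind == "categorical":
            codes = pd.Categorical(col).codes  # -1 for missing
            obs = codes >= 0
            s = (codes[:, None] != codes[None, :]).astype(float)
        else:
            x = col.to_numpy(dtype=float)
            obs = ~np.isnan(x)
            xz = np.where(obs, x, 0.0)
            s = np.abs(xz[:, None] - xz[None, :])
        delta = np.logical_and(obs[:, None], obs[None, :])
        num += (w * delta) * s
        den += w * delta
    undefined = den == 0.0
    np.fill_diagonal(undefined, False)
    if undefined.any():
        i, j = np.argwhere(undefined)[0]
        ids = table.data.index
        raise ValueError(
            f"individuals {ids[i]!r} and {ids[j]!r} share no observed variable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return (d + d.T) / 2.0  # enforce exact symmetry against float noise
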