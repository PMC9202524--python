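"""Variable normalization and the grouped/uniform weighting schemes.

All numeric-scored variables (continuous, count, ordinal-as-rank, binary)
are rescaled to [0, 1] by min-max over the non-missing values of the full
table, so cluster means live on a common blue-to-red barcode scale.
Categorical variables keep their levels and are consumed natively by the
distance as mismatch indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CohortTable, ConfigurationError, VariableSpec

__all__ = ["NormalizedTable", "normalize", "assign_weights"]


@dataclass
class NormalizedTable:
    """Normalized cohort values plus the min/max needed to invert them.

    ``data`` has the cohort's shape; numeric entries are in [0, 1] (a
    constant variable maps to 0 everywhere), categorical columns keep their
    level strings, and missingness is preserved as NaN.
    """

    data: pd.DataFrame
    specs: tuple[VariableSpec, ...]
    params: pd.DataFrame  # index: variable, columns: min, max (post rank-coding)

    @property
    def n(self) -> int:
        return len(self.data)

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def params_frame(self) -> pd.DataFrame:
        """Normalization statistics in exportable form (variable, min, max)."""
        return self.params.reset_index().rename(columns={"index": "variable"})


def _rank_code(col: pd.Series, levels: Sequence[str]) -> pd.Series:
    mapping = {lv: float(i) for i, lv in enumerate(levels)}
    return col.map(mapping)


def normalize(
    cohort: CohortTable | pd.DataFrame,
    specs: Sequence[VariableSpec],
    params: pd.DataFrame | None = None,
) -> NormalizedTable:
    """Min-max rescale a cohort to the common [0, 1] score scale.

    Ordinal levels are first mapped to their rank; binary to {0, 1};
    categorical columns are left untouched. Passing ``params`` (a frame with
    ``min``/``max`` indexed by variable, as produced by a previous call)
    reuses those statistics instead of recomputing them — used to normalize
    held-out subsets on the full-table scale.

    Raises an error naming the variable if all its values are missing.
    """
    data = cohort.data if isinstance(cohort, CohortTable) else cohort
    out: dict[str, pd.Series] = {}
    stats: dict[str, tuple[float, float]] = {}
    for spec in specs:
        col = data[spec.name]
        if spec.kind == "categorical":
            out[spec.name] = col.astype(object)
            stats[spec.name] = (np.nan, np.nan)
            continue
        if spec.kind == "ordinal":
            col = _rank_code(col, spec.levels)
        else:
            col = pd.to_numeric(col, errors="coerce")
        if col.notna().sum() == 0:
            raise ConfigurationError(
                f"variable {spec.name!r}: all values missing, cannot normalize"
            )
        if params is not None and spec.name in params.index:
            lo, hi = float(params.loc[spec.name, "min"]), float(params.loc[spec.name, "max"])
        else:
            lo, hi = float(col.min()), float(col.max())
        if hi > lo:
            scaled = (col - lo) / (hi - lo)
            scaled = scaled.clip(0.0, 1.0)
        else:
            scaled = col * 0.0  # constant variable convention
        out[spec.name] = scaled.astype(float)
        stats[spec.name] = (lo, hi)
    frame = pd.DataFrame(out, index=data.index)[[s.name for s in specs]]
    pframe = pd.DataFrame(stats, index=["min", "max"]).T
    return NormalizedTable(data=frame, specs=tuple(specs), params=pframe)


def assign_weights(specs: Sequence[VariableSpec], scheme: str = "grouped") -> pd.Series:
    """Per-variable weights summing to 1.

    ``uniform``: every variable gets 1/V. ``grouped``: every category group
    receives the same total weight, split equally among its variables — this
    gives each clinical aspect of the disorder the same influence on the
    distance regardless of how many items describe it. A variable's
    ``weight_override`` replaces its computed weight before a final
    renormalization.
    """
    if not specs:
        raise ConfigurationError("assign_weights needs at least one variable")
    if scheme not in ("grouped", "uniform"):
        raise ConfigurationError(f"unknown weighting scheme {scheme!r}")
    names = [s.name for s in specs]
    if scheme == "uniform":
        w = pd.Series(1.0 / len(specs), index=names)
    else:
        groups: dict[str, list[str]] = {}
        for s in specs:
            if not s.group:
                raise ConfigurationError(
                    f"variable {s.name!r}: grouped scheme requires a group"
                )
            groups.setdefault(s.group, []).append(s.name)
        w = pd.Series(0.0, index=names)
        per_group = 1.0 / len(groups)
        for members in groups.values():
            w[members] = per_group / len(members)
    for s in specs:
        if s.weight_override is not None:
            w[s.name] = s.weight_override
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("weights sum to zero after overrides")
    return w / total
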