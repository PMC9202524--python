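"""Core domain types shared across the pipeline.

The pipeline operates on a cohort of individuals described by mixed-type
clinical variables (binary symptom flags, categorical answers, ordinal
frequency scales, continuous measurements, bounded counts) with missing
entries, plus external labels (ICSD-3 diagnosis with physician certainty,
cataplexy flag, center of inclusion) that the clustering itself never sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VARIABLE_KINDS = ("binary", "categorical", "ordinal", "continuous", "count")

DIAGNOSES = ("NT1", "NT2", "IH")
CERTAINTIES = ("definite", "probable", "possible", "unknown")

#: Reserved cohort-table column names carrying external labels. These are
#: never clustered on; the clustering stage refuses to touch them.
LABEL_COLUMNS = ("diagnosis", "certainty", "cataplexy", "center")


class ConfigurationError(ValueError):
    """Raised when a scenario / variable configuration violates an invariant."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one clinical variable.

    Parameters
    ----------
    name : unique variable name.
    kind : one of ``binary``, ``categorical``, ``ordinal``, ``continuous``,
        ``count``.
    group : category group label (e.g. ``"nighttime sleep"``); drives the
        grouped weighting scheme and the barcode row ordering.
    levels : ordered level names; required exactly for categorical/ordinal.
    weight_override : optional nonnegative weight replacing the scheme's
        computed weight (renormalized afterwards).
    """

    name: str
    kind: str
    group: str
    levels: tuple[str, ...] | None = None
    weight_override: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ConfigurationError(
                f"variable {self.name!r}: unknown kind {self.kind!r}"
            )
        needs_levels = self.kind in ("categorical", "ordinal")
        if needs_levels and not self.levels:
            raise ConfigurationError(
                f"variable {self.name!r}: kind {self.kind!r} requires levels"
            )
        if not needs_levels and self.levels:
            raise ConfigurationError(
                f"variable {self.name!r}: kind {self.kind!r} must not carry levels"
            )
        if self.weight_override is not None and self.weight_override < 0:
            raise ConfigurationError(
                f"variable {self.name!r}: weight_override must be >= 0"
            )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_numeric(self) -> bool:
        """Whether the variable enters the distance as a scaled numeric score."""
        return self.kind in ("binary", "ordinal", "continuous", "count")


def check_unique_names(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate variable names: {sorted(dupes)}")


@dataclass
class CohortTable:
    """Individuals x variables with missing entries, plus external labels.

    ``data`` holds one column per :class:`VariableSpec` (indexed by
    individual id); ``labels`` holds the reserved columns ``diagnosis``,
    ``certainty``, ``cataplexy`` and ``center`` for the same index.
    """

    data: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ConfigurationError("individual ids must be unique")
        if not self.data.index.equals(self.labels.index):
            raise ConfigurationError("data and labels must share one index")
        overlap = set(self.data.columns) & set(LABEL_COLUMNS)
        if overlap:
            raise ConfigurationError(
                f"label columns {sorted(overlap)} may not appear among variables"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def validate(self, specs: Sequence[VariableSpec]) -> None:
        """Check every column conforms to its spec's kind and levels."""
        for spec in specs:
            if spec.name not in self.data.columns:
                raise ConfigurationError(f"missing column {spec.name!r}")
            col = self.data[spec.name].dropna()
            if spec.kind == "binary":
                bad = ~col.isin([0, 1, 0.0, 1.0, True, False])
                if bad.any():
                    raise ConfigurationError(
                        f"variable {spec.name!r}: non-binary values present"
                    )
            elif spec.kind in ("categorical", "ordinal"):
                bad = ~col.isin(spec.levels)
                if bad.any():
                    raise ConfigurationError(
                        f"variable {spec.name!r}: values outside declared levels"
                    )


@dataclass
class TrueStructure:
    """Planted ground truth: one archetype label per individual."""

    archetype: pd.Series  # index aligned with the cohort, values = labels

    def as_int_codes(self) -> np.ndarray:
        return pd.Categorical(self.archetype).codes.astype(int)


@dataclass
class ClusterAssignment:
    """Flat partition of the cohort into clusters labelled ``1..k``.

    Labels are assigned in decreasing cluster-size order (ties broken by the
    smallest member position), so cluster 1 is always the largest.
    """

    labels: np.ndarray  # int array in 1..k, one per individual
    k: int
    ids: pd.Index | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k}, got {present.tolist()}"
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes, index c-1 for cluster c."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def to_frame(self) -> pd.DataFrame:
        idx = self.ids if self.ids is not None else pd.RangeIndex(self.n)
        return pd.DataFrame({"cluster": self.labels}, index=idx)


@dataclass(frozen=True)
class ContingencyStats:
    """2x2 agreement between cluster membership (test) and diagnosis (condition).

    Cells may be fractional when reconstructed from published percentages
    rather than per-individual records. Statistics with a zero denominator
    are reported as ``nan`` (undefined), never coerced to 0.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-layer rounding; raw statistics stay full precision."""
        return {
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "ppv": round(self.ppv, ndigits),
            "npv": round(self.npv, ndigits),
        }
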