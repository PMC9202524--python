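"""Reading and writing the pipeline's on-disk artifacts.

Everything is plain text: cohort tables and sidecars as CSV (empty field =
missing), scenarios as YAML, dendrograms as linkage-table CSV. Readers
raise errors naming the offending file and column rather than silently
coercing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hcluster import Dendrogram
from .synthetic import ArchetypeConfig, ScenarioConfig
from .types import (
    LABEL_COLUMNS,
    ClusterAssignment,
    CohortTable,
    ConfigurationError,
    TrueStructure,
    VariableSpec,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_variable_specs",
    "read_variable_specs",
    "write_truth",
    "read_truth",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "write_distance",
    "read_distance",
    "write_dendrogram",
    "write_assignment",
]


def write_cohort(cohort: CohortTable, path) -> None:
    frame = pd.concat([cohort.data, cohort.labels], axis=1)
    frame.to_csv(path, index=True, index_label="id", na_rep="")


def read_cohort(path, specs: Sequence[VariableSpec], with_labels: bool = True) -> CohortTable:
    """Load a cohort CSV; label columns are split off by their reserved names.

    With ``with_labels=False`` the reserved columns are dropped unread and
    replaced by empty placeholders — used by the blinded clustering stage.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col="id", dtype=object)
    missing_cols = [s.name for s in specs if s.name not in frame.columns]
    if missing_cols:
        raise ConfigurationError(f"{path}: missing variable columns {missing_cols}")
    data = pd.DataFrame(index=frame.index)
    for spec in specs:
        col = frame[spec.name]
        if spec.kind in ("categorical", "ordinal"):
            data[spec.name] = col.astype(object)
        else:
            try:
                data[spec.name] = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                raise ConfigurationError(
                    f"{path}: column {spec.name!r}: non-numeric value ({exc})"
                ) from None
    if with_labels:
        lab_missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
        if lab_missing:
            raise ConfigurationError(f"{path}: missing label columns {lab_missing}")
        labels = frame[list(LABEL_COLUMNS)].copy()
        labels["cataplexy"] = pd.to_numeric(labels["cataplexy"])
        labels["center"] = pd.to_numeric(labels["center"])
    else:
        labels = pd.DataFrame(
            {c: pd.Series(np.nan, index=frame.index) for c in LABEL_COLUMNS}
        )
    cohort = CohortTable(data=data, labels=labels)
    cohort.validate(specs)
    return cohort


def write_variable_specs(specs: Sequence[VariableSpec], path) -> None:
    rows = [
        {
            "name": s.name,
            "kind": s.kind,
            "group": s.group,
            "levels": "|".join(s.levels) if s.levels else "",
            "weight_override": "" if s.weight_override is None else s.weight_override,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_variable_specs(path) -> list[VariableSpec]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=object).fillna("")
    required = {"name", "kind", "group"}
    if not required <= set(frame.columns):
        raise ConfigurationError(f"{path}: metadata needs columns {sorted(required)}")
    specs = []
    for i, row in frame.iterrows():
        levels = tuple(str(row.get("levels", "")).split("|")) if row.get("levels") else None
        wo = row.get("weight_override", "")
        try:
            specs.append(
                VariableSpec(
                    name=row["name"],
                    kind=row["kind"],
                    group=row["group"],
                    levels=levels,
                    weight_override=float(wo) if wo != "" else None,
                )
            )
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}, row {i + 2}: {exc}") from None
    return specs


def write_truth(truth: TrueStructure, path) -> None:
    truth.archetype.to_frame().to_csv(path, index=True, index_label="id")


def read_truth(path) -> TrueStructure:
    frame = pd.read_csv(path, index_col="id")
    return TrueStructure(archetype=frame["archetype"])


# --- scenario YAML -----------------------------------------------------------

def _spec_to_dict(s: VariableSpec) -> dict:
    d = {"name": s.name, "kind": s.kind, "group": s.group}
    if s.levels:
        d["levels"] = list(s.levels)
    if s.weight_override is not None:
        d["weight_override"] = s.weight_override
    return d


def scenario_to_yaml(scenario: ScenarioConfig, path) -> None:
    doc = {
        "seed": scenario.seed,
        "n_centers": scenario.n_centers,
        "missing_rate": (
            dict(scenario.missing_rate)
            if not isinstance(scenario.missing_rate, (int, float))
            else float(scenario.missing_rate)
        ),
        "variables": [_spec_to_dict(s) for s in scenario.variable_specs],
        "archetypes": [
            {
                "label": a.label,
                "size": a.size,
                "variables": a.variables,
                "diagnosis_probs": a.diagnosis_probs,
                "certainty_probs": a.certainty_probs,
                "cataplexy_prob": a.cataplexy_prob,
                "cataplexy_from": a.cataplexy_from,
            }
            for a in scenario.archetypes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = [
        VariableSpec(
            name=d["name"],
            kind=d["kind"],
            group=d["group"],
            levels=tuple(d["levels"]) if d.get("levels") else None,
            weight_override=d.get("weight_override"),
        )
        for d in doc["variables"]
    ]
    archetypes = []
    for a in doc["archetypes"]:
        kwargs = dict(
            label=a["label"],
            size=a["size"],
            variables=a["variables"],
            diagnosis_probs=a["diagnosis_probs"],
            cataplexy_prob=a.get("cataplexy_prob"),
            cataplexy_from=a.get("cataplexy_from"),
        )
        if a.get("certainty_probs"):
            kwargs["certainty_probs"] = a["certainty_probs"]
        archetypes.append(ArchetypeConfig(**kwargs))
    scenario = ScenarioConfig(
        archetypes=archetypes,
        variable_specs=specs,
        missing_rate=doc.get("missing_rate", 0.0),
        n_centers=doc.get("n_centers", 1),
        seed=doc.get("seed", 0),
    )
    scenario.validate()
    return scenario


# --- matrices and trees ------------------------------------------------------

def write_distance(d: np.ndarray, ids, path) -> None:
    pd.DataFrame(d, index=ids, columns=ids).to_csv(path, index_label="id")


def read_distance(path) -> np.ndarray:
    return pd.read_csv(path, index_col="id").to_numpy(dtype=float)


def write_dendrogram(tree: Dendrogram, path) -> None:
    frame = pd.DataFrame(tree.merges, columns=["left", "right", "height", "size"])
    frame.to_csv(path, index_label="merge")


def write_assignment(assignment: ClusterAssignment, path) -> None:
    assignment.to_frame().to_csv(path, index_label="id")
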