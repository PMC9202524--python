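import numpy as np
import pandas as pd
import pytest

from somnoclust import (
    CohortTable,
    PipelineConfig,
    VariableSpec,
    generate_cohort,
    normalize,
    study_scenario,
    run_clustering,
)


def make_cohort(data: dict, index=None) -> CohortTable:
    """Bare cohort from a column dict, with placeholder labels."""
    frame = pd.DataFrame(data, index=index)
    labels = pd.DataFrame(
        {"diagnosis": "NT1", "certainty": "definite", "cataplexy": 0, "center": 1},
        index=frame.index,
    )
    return CohortTable(data=frame, labels=labels)


def continuous_specs(names, group="g") -> list[VariableSpec]:
    return [VariableSpec(n, "continuous", group) for n in names]


@pytest.fixture(scope="session")
def study_cohort():
    scenario = study_scenario(seed=1)
    cohort, truth = generate_cohort(scenario)
    return scenario, cohort, truth


@pytest.fixture(scope="session")
def study_run(study_cohort):
    scenario, cohort, truth = study_cohort
    run = run_clustering(cohort, scenario.variable_specs, PipelineConfig(k=7))
    return scenario, cohort, truth, run


def mini_study_scenario(seed: int = 0):
    """The built-in scenario shrunk to 210 individuals for fast end-to-end runs."""
    scenario = study_scenario(seed=seed)
    for arch, size in zip(scenario.archetypes, (45, 40, 30, 30, 25, 25, 15)):
        arch.size = size
    return scenario


def random_mixed_table(rng, n: int, missing: float = 0.15):
    """Random mixed-type normalized table + equal-ish random weights for oracles."""
    specs = [
        VariableSpec("b1", "binary", "g1"),
        VariableSpec("b2", "binary", "g1"),
        VariableSpec("c1", "continuous", "g2"),
        VariableSpec("c2", "continuous", "g2"),
        VariableSpec("cat", "categorical", "g3", levels=("x", "y", "z")),
        VariableSpec("o1", "ordinal", "g3", levels=("lo", "mid", "hi")),
    ]
    data = {
        "b1": rng.integers(0, 2, n).astype(float),
        "b2": rng.integers(0, 2, n).astype(float),
        "c1": rng.random(n),
        "c2": rng.random(n),
        "cat": rng.choice(["x", "y", "z"], n),
        "o1": rng.choice(["lo", "mid", "hi"], n),
    }
    frame = pd.DataFrame(data)
    for col in frame.columns:
        mask = rng.random(n) < missing
        # keep row 0 fully observed so every pair shares a variable
        mask[0] = False
        if frame[col].dtype == object:
            frame[col] = frame[col].where(~mask, other=np.nan)
        else:
            frame[col] = frame[col].mask(mask)
    table = normalize(frame, specs)
    weights = pd.Series(rng.random(len(specs)) + 0.1, index=[s.name for s in specs])
    weights = weights / weights.sum()
    return table, weights, specs
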