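"""Subset-resampling stability and the three re-clustering variants."""

import numpy as np
import pandas as pd
import pytest

from somnoclust import (
    ArchetypeConfig,
    PipelineConfig,
    ScenarioConfig,
    VariableSpec,
    assign_weights,
    best_match_jaccard,
    generate_cohort,
    gower,
    normalize,
    run_variants,
    subset_stability,
)
from somnoclust.robustness import HYPOCRETIN_DEFICIENCY_THRESHOLD
from somnoclust.types import ClusterAssignment

from conftest import mini_study_scenario


def separated_scenario(seed=0, size=30):
    specs = [VariableSpec(f"v{i}", "binary", "g") for i in range(10)]
    archetypes = [
        ArchetypeConfig(label=lab, size=size,
                        variables={s.name: {"p": p} for s in specs},
                        diagnosis_probs={"NT1": 1.0}, cataplexy_prob=0.0)
        for lab, p in (("lo", 0.05), ("hi", 0.95))
    ]
    return ScenarioConfig(archetypes=archetypes, variable_specs=specs, seed=seed)


def structureless_scenario(seed=0, n=60):
    specs = [VariableSpec(f"v{i}", "binary", "g") for i in range(10)]
    arch = ArchetypeConfig(label="only", size=n,
                           variables={s.name: {"p": 0.5} for s in specs},
                           diagnosis_probs={"NT1": 1.0}, cataplexy_prob=0.0)
    return ScenarioConfig(archetypes=[arch], variable_specs=specs, seed=seed)


def test_best_match_jaccard_relabel_invariant():
    members = {0, 1, 2}
    a1 = ClusterAssignment(labels=np.array([1, 1, 1, 2, 2]), k=2)
    a2 = ClusterAssignment(labels=np.array([2, 2, 2, 1, 1]), k=2)
    assert best_match_jaccard(members, a1) == best_match_jaccard(members, a2) == 1.0


def test_separated_archetypes_perfectly_reproducible():
    scenario = separated_scenario()
    cohort, _ = generate_cohort(scenario)
    report = subset_stability(cohort, scenario.variable_specs,
                              PipelineConfig(k=2), fraction=0.8, n_reps=10, seed=1)
    assert np.allclose(report.per_cluster["mean_jaccard"], 1.0)
    assert report.ari_mean == pytest.approx(1.0)


def test_structureless_far_less_stable_than_separated():
    scenario = structureless_scenario()
    cohort, _ = generate_cohort(scenario)
    report = subset_stability(cohort, scenario.variable_specs,
                              PipelineConfig(k=4), fraction=0.8, n_reps=10, seed=2)
    assert report.per_cluster["mean_jaccard"].mean() < 0.9


def test_deterministic_given_seed():
    scenario = separated_scenario()
    cohort, _ = generate_cohort(scenario)
    kwargs = dict(fraction=0.7, n_reps=3, seed=5)
    r1 = subset_stability(cohort, scenario.variable_specs, PipelineConfig(k=2), **kwargs)
    r2 = subset_stability(cohort, scenario.variable_specs, PipelineConfig(k=2), **kwargs)
    pd.testing.assert_frame_equal(r1.per_cluster, r2.per_cluster)
    assert r1.ari_mean == r2.ari_mean


def test_invalid_parameters_rejected():
    scenario = separated_scenario()
    cohort, _ = generate_cohort(scenario)
    with pytest.raises(ValueError):
        subset_stability(cohort, scenario.variable_specs, fraction=1.2)
    with pytest.raises(ValueError):
        subset_stability(cohort, scenario.variable_specs, n_reps=1)


def test_uniform_weights_equal_grouped_for_single_group():
    """Variant (b) degeneracy: one group means identical distance matrices."""
    scenario = separated_scenario()
    cohort, _ = generate_cohort(scenario)
    specs = scenario.variable_specs  # all share group "g"
    table = normalize(cohort, specs)
    d_grouped = gower(table, assign_weights(specs, "grouped"))
    d_uniform = gower(table, assign_weights(specs, "uniform"))
    assert np.array_equal(d_grouped, d_uniform)


def test_hypocretin_filter_is_strict():
    """Threshold semantics: of 110 and 300 only values strictly below 110 drop."""
    vals = np.array([50.0, 110.0, 300.0])
    assert ((vals < HYPOCRETIN_DEFICIENCY_THRESHOLD)).tolist() == [True, False, False]


@pytest.fixture(scope="module")
def mini():
    scenario = mini_study_scenario(seed=2)
    cohort, _ = generate_cohort(scenario)
    report = run_variants(cohort, scenario.variable_specs, PipelineConfig(k=7))
    return scenario, cohort, report


class TestRunVariants:
    def test_variants_recover_base_top_variables(self, mini):
        scenario, cohort, report = mini
        assert set(report.variants) == {
            "exclude_cataplexy_hcrt", "uniform_weights", "soremp_recoding"
        }
        for v in report.variants.values():
            assert 0.0 <= v.overlap <= 1.0
        # settings changes should not upend the non-cataplexy differentiators
        overlaps = [v.overlap for v in report.variants.values()]
        assert np.mean(overlaps) >= 0.5

    def test_exclusion_filter_counts(self, mini):
        scenario, cohort, report = mini
        va = report.variants["exclude_cataplexy_hcrt"]
        cat = cohort.labels["cataplexy"].to_numpy(dtype=float)
        hcrt = cohort.data["hypocretin_1_level"].to_numpy(dtype=float)
        keep = ~((cat == 1) | (hcrt < HYPOCRETIN_DEFICIENCY_THRESHOLD))
        assert va.n_individuals == int(keep.sum())

    def test_soremp_recoding_produces_binary_variable(self, mini):
        scenario, cohort, report = mini
        vc = report.variants["soremp_recoding"]
        assert vc.n_individuals == cohort.n
        frame = report.to_frame()
        assert "soremp_recoding" in frame.index
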