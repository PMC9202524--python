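"""Synthetic cohort generator with planted archetypes.

The real cohort this package was designed around (a multi-center European
registry of central disorders of hypersomnolence) is not publicly
downloadable, so every downstream stage is exercised on generated cohorts
that reproduce its statistical shape: mixed-type clinical variables grouped
into symptom categories, archetypal patient subgroups with characteristic
symptom frequencies, missing-completely-at-random entries, and external
diagnosis/cataplexy/center labels that the clustering never consumes.

``study_scenario`` builds the default study scenario: 1,078 individuals
in 7 archetypes (sizes 231/298/92/99/157/158/43) over 97 variables spread
across ten symptom-category groups. Four archetypes are cataplexy-dominated
narcolepsy type 1 phenotypes of varying severity; two are tight,
well-separated non-cataplexy phenotypes distinguished by sleep drunkenness,
difficulty awakening, weekend-week sleep-length difference and biomarkers;
the last is a small heterogeneous mixed group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CERTAINTIES,
    DIAGNOSES,
    CohortTable,
    ConfigurationError,
    TrueStructure,
    VariableSpec,
    check_unique_names,
)

__all__ = [
    "ArchetypeConfig",
    "ScenarioConfig",
    "generate_cohort",
    "study_scenario",
]

# Certainty mix per diagnosis, normalized from the published per-diagnosis
# certainty counts (definite / probable / possible / unknown).
DEFAULT_CERTAINTY_PROBS: dict[str, dict[str, float]] = {
    "NT1": {"definite": 646 / 763, "probable": 51 / 763, "possible": 33 / 763, "unknown": 33 / 763},
    "NT2": {"definite": 132 / 200, "probable": 49 / 200, "possible": 10 / 200, "unknown": 9 / 200},
    "IH": {"definite": 83 / 126, "probable": 32 / 126, "possible": 6 / 126, "unknown": 5 / 126},
}


@dataclass
class ArchetypeConfig:
    """Generative recipe for one planted patient subgroup.

    ``variables`` maps every variable name to kind-specific parameters:

    - binary: ``{"p": success probability}``
    - categorical: ``{"probs": {level: probability}}``
    - ordinal: ``{"mean": latent mean, "sd": latent SD}`` on the 0..L-1
      level-index scale, discretized by rounding and clipping
    - continuous / count: ``{"mean", "sd", "lo", "hi"}`` — a normal truncated
      to [lo, hi] on the variable's natural scale (counts rounded to int)

    The cataplexy label is either drawn independently (``cataplexy_prob``) or
    copied from a generated binary variable (``cataplexy_from``), keeping the
    label consistent with the corresponding input variable.
    """

    label: str
    size: int
    variables: dict[str, dict]
    diagnosis_probs: dict[str, float]
    certainty_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: DEFAULT_CERTAINTY_PROBS
    )
    cataplexy_prob: float | None = None
    cataplexy_from: str | None = None

    def validate(self, specs: Sequence[VariableSpec]) -> None:
        if self.size < 1:
            raise ConfigurationError(f"archetype {self.label!r}: size must be >= 1")
        for spec in specs:
            if spec.name not in self.variables:
                raise ConfigurationError(
                    f"archetype {self.label!r}: no parameters for variable {spec.name!r}"
                )
            params = self.variables[spec.name]
            if spec.kind == "binary":
                p = params.get("p")
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"archetype {self.label!r}, variable {spec.name!r}: "
                        f"binary probability p={p!r} outside [0, 1]"
                    )
            elif spec.kind == "categorical":
                probs = params.get("probs", {})
                if set(probs) != set(spec.levels or ()):
                    raise ConfigurationError(
                        f"archetype {self.label!r}, variable {spec.name!r}: "
                        "level probabilities must cover exactly the declared levels"
                    )
                vals = np.array([probs[lv] for lv in spec.levels])
                if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"archetype {self.label!r}, variable {spec.name!r}: "
                        "level probabilities must be nonnegative and sum to 1"
                    )
            elif spec.kind == "ordinal":
                if "mean" not in params or "sd" not in params:
                    raise ConfigurationError(
                        f"archetype {self.label!r}, variable {spec.name!r}: "
                        "ordinal requires latent mean/sd"
                    )
            else:  # continuous / count
                for key in ("mean", "sd", "lo", "hi"):
                    if key not in params:
                        raise ConfigurationError(
                            f"archetype {self.label!r}, variable {spec.name!r}: "
                            f"missing parameter {key!r}"
                        )
                if params["lo"] >= params["hi"]:
                    raise ConfigurationError(
                        f"archetype {self.label!r}, variable {spec.name!r}: lo >= hi"
                    )
        pd_probs = self.diagnosis_probs
        if set(pd_probs) - set(DIAGNOSES):
            raise ConfigurationError(
                f"archetype {self.label!r}: unknown diagnosis in diagnosis_probs"
            )
        vals = np.array([pd_probs.get(d, 0.0) for d in DIAGNOSES])
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype {self.label!r}: diagnosis_probs must sum to 1"
            )
        if self.cataplexy_prob is None and self.cataplexy_from is None:
            raise ConfigurationError(
                f"archetype {self.label!r}: set cataplexy_prob or cataplexy_from"
            )
        if self.cataplexy_prob is not None and not 0.0 <= self.cataplexy_prob <= 1.0:
            raise ConfigurationError(
                f"archetype {self.label!r}: cataplexy_prob outside [0, 1]"
            )


@dataclass
class ScenarioConfig:
    """Full generative scenario: archetypes, variables, missingness, centers."""

    archetypes: list[ArchetypeConfig]
    variable_specs: list[VariableSpec]
    missing_rate: Mapping[str, float] | float = 0.0
    n_centers: int = 21
    seed: int = 0

    @property
    def n(self) -> int:
        return sum(a.size for a in self.archetypes)

    def rate_for(self, name: str) -> float:
        if isinstance(self.missing_rate, Mapping):
            return float(self.missing_rate.get(name, 0.0))
        return float(self.missing_rate)

    def validate(self) -> None:
        if not self.archetypes:
            raise ConfigurationError("scenario needs at least one archetype")
        if not self.variable_specs:
            raise ConfigurationError("scenario needs at least one variable")
        check_unique_names(self.variable_specs)
        labels = [a.label for a in self.archetypes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("archetype labels must be unique")
        for arch in self.archetypes:
            arch.validate(self.variable_specs)
        for spec in self.variable_specs:
            r = self.rate_for(spec.name)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"missing_rate for {spec.name!r} must be in [0, 1], got {r}"
                )
        if self.n_centers < 1:
            raise ConfigurationError("n_centers must be >= 1")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_column(rng, spec: VariableSpec, params: dict, size: int) -> np.ndarray:
    if spec.kind == "binary":
        return (rng.random(size) < params["p"]).astype(float)
    if spec.kind == "categorical":
        levels = list(spec.levels)
        p = np.array([params["probs"][lv] for lv in levels], dtype=float)
        p = p / p.sum()
        return rng.choice(np.array(levels, dtype=object), size=size, p=p)
    if spec.kind == "ordinal":
        latent = rng.normal(params["mean"], params["sd"], size)
        idx = np.clip(np.rint(latent), 0, len(spec.levels) - 1).astype(int)
        return np.array(spec.levels, dtype=object)[idx]
    vals = _truncated_normal(rng, params["mean"], params["sd"], params["lo"], params["hi"], size)
    if spec.kind == "count":
        vals = np.rint(vals)
    return vals.astype(float)


def generate_cohort(
    scenario: ScenarioConfig, seed: int | None = None
) -> tuple[CohortTable, TrueStructure]:
    """Draw a cohort and its planted archetype labels from a scenario.

    Individuals are drawn independently from their archetype's generative
    parameters; entries are then deleted missing-completely-at-random at
    each variable's configured rate, and center ids are assigned uniformly.
    Fully reproducible from the seed; four independent substreams are split
    off in a fixed order (values, labels, missingness, centers) so each
    stage can be regenerated without disturbing the others.
    """
    scenario.validate()
    if seed is None:
        seed = scenario.seed
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_values = np.random.default_rng(streams[0])
    rng_labels = np.random.default_rng(streams[1])
    rng_missing = np.random.default_rng(streams[2])
    rng_centers = np.random.default_rng(streams[3])

    n = scenario.n
    specs = scenario.variable_specs
    arch_labels = np.concatenate(
        [np.repeat(a.label, a.size) for a in scenario.archetypes]
    )

    # values: archetype-major, variable-minor draw order
    blocks: list[pd.DataFrame] = []
    for arch in scenario.archetypes:
        cols = {
            spec.name: _draw_column(rng_values, spec, arch.variables[spec.name], arch.size)
            for spec in specs
        }
        blocks.append(pd.DataFrame(cols))
    data = pd.concat(blocks, ignore_index=True)

    # external labels
    diagnosis = np.empty(n, dtype=object)
    certainty = np.empty(n, dtype=object)
    cataplexy = np.empty(n, dtype=float)
    offset = 0
    for arch in scenario.archetypes:
        sl = slice(offset, offset + arch.size)
        p = np.array([arch.diagnosis_probs.get(d, 0.0) for d in DIAGNOSES])
        diagnosis[sl] = rng_labels.choice(np.array(DIAGNOSES, dtype=object), size=arch.size, p=p / p.sum())
        for i in range(offset, offset + arch.size):
            cp = arch.certainty_probs[diagnosis[i]]
            pc = np.array([cp.get(c, 0.0) for c in CERTAINTIES])
            certainty[i] = rng_labels.choice(np.array(CERTAINTIES, dtype=object), p=pc / pc.sum())
        if arch.cataplexy_from is not None:
            cataplexy[sl] = data[arch.cataplexy_from].to_numpy(float)[sl]
        else:
            cataplexy[sl] = (rng_labels.random(arch.size) < arch.cataplexy_prob).astype(float)
        offset += arch.size

    # MCAR deletion, per variable
    for spec in specs:
        rate = scenario.rate_for(spec.name)
        mask = rng_missing.random(n) < rate
        if mask.any():
            col = data[spec.name]
            if col.dtype == object:
                col = col.where(~mask, other=np.nan)
            else:
                col = col.mask(mask)
            data[spec.name] = col

    centers = rng_centers.integers(1, scenario.n_centers + 1, size=n)

    ids = pd.Index([f"id{i:04d}" for i in range(1, n + 1)], name="id")
    data.index = ids
    labels = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "certainty": certainty,
            "cataplexy": cataplexy.astype(int),
            "center": centers,
        },
        index=ids,
    )
    cohort = CohortTable(data=data, labels=labels)
    truth = TrueStructure(archetype=pd.Series(arch_labels, index=ids, name="archetype"))
    return cohort, truth


# --------------------------------------------------------------------------
# Built-in study scenario
# --------------------------------------------------------------------------

#: Fixed seed for the *scenario builder* (filler-variable parameters), kept
#: separate from the cohort seed so the scenario itself is a constant.
_BUILDER_SEED = 20220607

_ARCH_LABELS = ("A1", "A2", "A3", "A4", "A5", "A6", "A7")
_ARCH_SIZES = (231, 298, 92, 99, 157, 158, 43)
#: archetypes generated with low within-group dispersion (the two distinct
#: non-cataplexy phenotypes); the rest are broader, matching the observed
#: pattern that refining the partition below the final model subdivided
#: only cataplexy-dominated groups.
_TIGHT = ("A5", "A6")
_TIGHT_SD_FACTOR = 0.5

_GROUPS = (
    ("demographics", 8),
    ("nighttime sleep", 14),
    ("difficulties waking up", 10),
    ("cataplexy", 12),
    ("hallucinations", 8),
    ("sleep paralysis", 6),
    ("sleepiness", 14),
    ("MSLT", 8),
    ("PSG", 12),
    ("biomarkers", 5),
)

# Anchor variables: (name, group, kind, per-archetype parameters, missing rate).
# Binary: 7 success probabilities; continuous/count: (means, sd, lo, hi) with
# sd scalar (halved for tight archetypes) or explicit 7-list; ordinal:
# (levels, latent means, latent sd); categorical: (levels, 7 prob tuples).
_ANCHORS: list[tuple] = [
    ("female", "demographics", "binary", (0.45, 0.42, 0.26, 0.99, 0.52, 0.48, 0.50), 0.01),
    ("age_at_evaluation", "demographics", "continuous",
     ((30, 33, 38, 32, 34, 31, 33), 11.0, 13.0, 80.0), 0.01),
    ("bmi", "demographics", "continuous", ((27, 25, 26, 25, 24, 25, 25), 4.0, 15.0, 45.0), 0.05),
    ("disturbed_nocturnal_sleep", "nighttime sleep", "binary",
     (0.72, 0.45, 0.55, 0.50, 0.35, 0.30, 0.45), 0.05),
    ("nocturnal_sleep_duration", "nighttime sleep", "continuous",
     ((7.2, 7.4, 8.0, 7.4, 8.8, 7.8, 7.5), 1.0, 4.0, 12.0), 0.08),
    ("weekend_week_sleep_difference", "nighttime sleep", "continuous",
     ((0.7, 0.8, 1.0, 0.8, 2.6, 1.0, 0.9), 0.7, 0.0, 5.0), 0.08),
    ("sleep_drunkenness", "difficulties waking up", "binary",
     (0.30, 0.20, 0.83, 0.25, 0.85, 0.20, 0.35), 0.05),
    ("subjective_difficulty_awakening", "difficulties waking up", "binary",
     (0.35, 0.25, 0.77, 0.30, 0.80, 0.25, 0.35), 0.05),
    ("refreshed_after_sleep", "difficulties waking up", "categorical",
     (("yes", "not_always", "no"),
      ((0.50, 0.30, 0.20), (0.55, 0.28, 0.17), (0.28, 0.36, 0.36), (0.50, 0.30, 0.20),
       (0.10, 0.35, 0.55), (0.45, 0.35, 0.20), (0.40, 0.35, 0.25))), 0.05),
    ("memory_complaints", "difficulties waking up", "binary",
     (0.35, 0.25, 0.45, 0.30, 0.60, 0.30, 0.35), 0.06),
    ("cataplexy_present", "cataplexy", "binary",
     (0.97, 0.95, 0.80, 0.95, 0.03, 0.08, 0.50), 0.0),
    ("cataplexy_frequency", "cataplexy", "ordinal",
     (("never", "rarely", "weekly", "daily"),
      (2.4, 1.8, 1.6, 1.7, 0.05, 0.12, 1.0), 0.8), 0.03),
    ("cataplexy_complete", "cataplexy", "binary",
     (0.75, 0.45, 0.40, 0.30, 0.01, 0.02, 0.30), 0.05),
    ("cataplexy_trigger_count", "cataplexy", "count",
     ((4.5, 2.5, 2.2, 1.8, 0.1, 0.2, 1.5), 1.6, 0.0, 8.0), 0.05),
    ("hypnagogic_hallucinations", "hallucinations", "binary",
     (0.90, 0.22, 0.55, 0.61, 0.40, 0.30, 0.85), 0.04),
    ("hallucination_frequency", "hallucinations", "ordinal",
     (("never", "monthly", "weekly", "daily"),
      (2.0, 0.5, 1.2, 1.2, 0.8, 0.6, 1.9), 0.8), 0.05),
    ("sleep_paralysis", "sleep paralysis", "binary",
     (0.82, 0.05, 0.45, 0.73, 0.30, 0.25, 0.80), 0.04),
    ("sleep_paralysis_frequency", "sleep paralysis", "ordinal",
     (("never", "monthly", "weekly", "daily"),
      (1.8, 0.2, 1.0, 1.5, 0.6, 0.5, 1.7), 0.8), 0.05),
    ("ess_score", "sleepiness", "count", ((18, 16, 16, 17, 15, 16, 16), 3.5, 0.0, 24.0), 0.10),
    ("sleep_attacks", "sleepiness", "binary",
     (0.94, 0.70, 0.72, 0.75, 0.55, 0.60, 0.70), 0.05),
    ("fatigue_complaints", "sleepiness", "binary",
     (0.70, 0.55, 0.88, 0.60, 0.75, 0.55, 0.60), 0.06),
    ("fss_score", "sleepiness", "continuous", ((48, 42, 50, 44, 47, 42, 44), 8.0, 9.0, 63.0), 0.12),
    ("mslt_mean_sleep_latency", "MSLT", "continuous",
     ((2.5, 4.0, 3.5, 3.5, 8.0, 7.5, 5.0), 2.0, 0.0, 20.0), 0.10),
    ("mslt_soremp_count", "MSLT", "count", ((3.6, 3.0, 2.8, 3.0, 0.6, 0.9, 2.0), 1.1, 0.0, 5.0), 0.10),
    ("psg_rem_latency", "PSG", "continuous",
     ((25, 40, 45, 40, 95, 90, 60), 30.0, 0.0, 250.0), 0.10),
    ("psg_sleep_efficiency", "PSG", "continuous",
     ((82, 86, 84, 85, 90, 89, 86), 7.0, 40.0, 100.0), 0.10),
    ("plmi", "PSG", "continuous", ((12, 8, 10, 8, 6, 7, 8), 6.0, 0.0, 60.0), 0.12),
    ("ahi", "PSG", "continuous", ((6, 5, 6, 5, 4, 4, 5), 4.0, 0.0, 30.0), 0.12),
    ("hypocretin_1_level", "biomarkers", "continuous",
     ((40, 60, 70, 60, 330, 240, 200), (35, 40, 45, 40, 80, 95, 110), 0.0, 600.0), 0.45),
    ("hla_dqb1_0602", "biomarkers", "binary",
     (0.97, 0.92, 0.90, 0.93, 0.25, 0.55, 0.70), 0.25),
]

_DIAGNOSIS_PROBS = {
    "A1": {"NT1": 0.97, "NT2": 0.02, "IH": 0.01},
    "A2": {"NT1": 0.94, "NT2": 0.04, "IH": 0.02},
    "A3": {"NT1": 0.88, "NT2": 0.08, "IH": 0.04},
    "A4": {"NT1": 0.95, "NT2": 0.03, "IH": 0.02},
    "A5": {"NT1": 0.15, "NT2": 0.45, "IH": 0.40},
    "A6": {"NT1": 0.28, "NT2": 0.45, "IH": 0.27},
    "A7": {"NT1": 0.50, "NT2": 0.35, "IH": 0.15},
}

_ORDINAL_FILLER_LEVELS = ("never", "sometimes", "often", "always")


def _continuous_sd(sd, arch_label: str) -> float:
    if isinstance(sd, (tuple, list)):
        return float(sd[_ARCH_LABELS.index(arch_label)])
    if arch_label in _TIGHT:
        return float(sd) * _TIGHT_SD_FACTOR
    return float(sd)


def _anchor_params(name, kind, params, arch_label) -> dict:
    i = _ARCH_LABELS.index(arch_label)
    if kind == "binary":
        return {"p": float(params[i])}
    if kind == "categorical":
        levels, prob_rows = params
        return {"probs": dict(zip(levels, prob_rows[i]))}
    if kind == "ordinal":
        _levels, means, sd = params
        lsd = sd * _TIGHT_SD_FACTOR if arch_label in _TIGHT else sd
        return {"mean": float(means[i]), "sd": float(lsd)}
    means, sd, lo, hi = params
    return {"mean": float(means[i]), "sd": _continuous_sd(sd, arch_label), "lo": lo, "hi": hi}


#: probability that the two tight non-cataplexy archetypes sit on opposite
#: extremes of a filler variable (they are the most distinctly grouped pair,
#: also from each other).
_OPPOSED_PROB = 0.2


def _filler_variable(rng, name: str, group: str) -> tuple[VariableSpec, dict[str, dict], float]:
    """One filler variable: spec, per-archetype params, missing rate."""
    kind = rng.choice(["binary", "continuous", "ordinal"], p=[0.5, 0.35, 0.15])
    missing = float(rng.uniform(0.03, 0.12))
    params: dict[str, dict] = {}
    opposed = rng.random() < _OPPOSED_PROB
    if kind == "binary":
        spec = VariableSpec(name, "binary", group)
        side5 = rng.random() < 0.5
        side6 = (not side5) if opposed else rng.random() < 0.5
        for a, side in (("A5", side5), ("A6", side6)):
            lo, hi = (0.82, 0.97) if side else (0.03, 0.18)
            params[a] = {"p": float(rng.uniform(lo, hi))}
        for a in _ARCH_LABELS:
            if a in _TIGHT:
                continue
            span = (0.20, 0.80) if a == "A7" else (0.15, 0.85)
            params[a] = {"p": float(rng.uniform(*span))}
    elif kind == "continuous":
        spec = VariableSpec(name, "continuous", group)
        m5 = float(rng.uniform(0.10, 0.90))
        m6 = 1.0 - m5 if opposed else float(rng.uniform(0.10, 0.90))
        params["A5"] = {"mean": m5, "sd": 0.07, "lo": 0.0, "hi": 1.0}
        params["A6"] = {"mean": m6, "sd": 0.07, "lo": 0.0, "hi": 1.0}
        for a in _ARCH_LABELS:
            if a in _TIGHT:
                continue
            if a == "A7":
                params[a] = {"mean": float(rng.uniform(0.15, 0.85)), "sd": 0.12, "lo": 0.0, "hi": 1.0}
            else:
                params[a] = {"mean": float(rng.uniform(0.20, 0.80)), "sd": 0.12, "lo": 0.0, "hi": 1.0}
    else:
        spec = VariableSpec(name, "ordinal", group, levels=_ORDINAL_FILLER_LEVELS)
        u5 = float(rng.uniform(0.0, 3.0))
        u6 = 3.0 - u5 if opposed else float(rng.uniform(0.0, 3.0))
        params["A5"] = {"mean": u5, "sd": 0.35}
        params["A6"] = {"mean": u6, "sd": 0.35}
        for a in _ARCH_LABELS:
            if a in _TIGHT:
                continue
            if a == "A7":
                params[a] = {"mean": float(rng.uniform(0.3, 2.7)), "sd": 0.5}
            else:
                params[a] = {"mean": float(rng.uniform(0.4, 2.6)), "sd": 0.7}
    return spec, params, missing


def study_scenario(seed: int = 0) -> ScenarioConfig:
    """The built-in study scenario: 7 archetypes, 1,078 individuals, 97 variables.

    Anchor variables carry hand-set per-archetype frequencies that follow the
    published cluster profiles (e.g. the severe cataplexy archetype has 97%
    cataplexy, 90% hypnagogic hallucinations and 82% sleep paralysis; one
    narcolepsy archetype is 99% female; one non-cataplexy archetype shows
    frequent sleep drunkenness and a large weekend-week sleep-length
    difference). Filler variables complete each category group to its size;
    their parameters are drawn once from a fixed builder seed and are
    therefore part of the scenario definition, not of the cohort randomness.

    ``seed`` sets only the cohort-generation seed stored on the scenario.
    """
    rng = np.random.default_rng(_BUILDER_SEED)
    specs: list[VariableSpec] = []
    arch_vars: dict[str, dict[str, dict]] = {a: {} for a in _ARCH_LABELS}
    missing: dict[str, float] = {}

    anchors_by_group: dict[str, list[tuple]] = {g: [] for g, _ in _GROUPS}
    for anchor in _ANCHORS:
        anchors_by_group[anchor[1]].append(anchor)

    for group, total in _GROUPS:
        anchors = anchors_by_group[group]
        for name, _g, kind, params, miss in anchors:
            levels = None
            if kind in ("categorical", "ordinal"):
                levels = tuple(params[0])
            specs.append(VariableSpec(name, kind, group, levels=levels))
            missing[name] = miss
            for a in _ARCH_LABELS:
                arch_vars[a][name] = _anchor_params(name, kind, params, a)
        stem = group.lower().replace(" ", "_")
        for j in range(total - len(anchors)):
            fname = f"{stem}_item{j + 1:02d}"
            spec, params, miss = _filler_variable(rng, fname, group)
            specs.append(spec)
            missing[fname] = miss
            for a in _ARCH_LABELS:
                arch_vars[a][fname] = params[a]

    archetypes = [
        ArchetypeConfig(
            label=a,
            size=size,
            variables=arch_vars[a],
            diagnosis_probs=_DIAGNOSIS_PROBS[a],
            cataplexy_from="cataplexy_present",
        )
        for a, size in zip(_ARCH_LABELS, _ARCH_SIZES)
    ]
    return ScenarioConfig(
        archetypes=archetypes,
        variable_specs=specs,
        missing_rate=missing,
        n_centers=21,
        seed=seed,
    )
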