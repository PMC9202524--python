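# Methods

This note documents the statistical procedures implemented in
`somnoclust`, the assumptions they make, the tunable parameters and their
defaults, what the synthetic cohort generator does and does not emulate,
and the numerical conventions adopted where the design was genuinely open.

## The clustering chain

**Normalization.** Continuous, count and (rank-coded) ordinal variables
are min–max scaled to [0, 1] using the minimum and maximum of the
*non-missing values of the full table*; binary variables map to {0, 1};
categorical variables keep their levels. Full-table statistics (rather
than per-cluster ones) are used so that cluster means are comparable on
one common scale, which is what the barcode panels display. A constant
variable maps to 0 everywhere (a convention, exercised in tests).
Min–max was chosen over z-scoring so that all numeric scores — and hence
all cluster means — live on the same bounded blue-to-red scale. The
normalization statistics are exportable and reusable, so held-out subsets
can be scored on the full-table scale. Missing values are never imputed:
they are handled inside the distance and masked in the panels.

**Weights.** The `grouped` scheme (default) gives each of the variable
category groups the same total weight, split equally within the group; a
cohort with 14 nighttime-sleep items and 2 biomarker items then lets each
aspect of the disorder, not each questionnaire item, carry equal
influence. `uniform` gives every variable weight 1/V. Per-variable
overrides replace the computed weight before a final renormalization to
sum 1.

**Distance.** Weighted Gower dissimilarity with pairwise-complete
missing-data handling: the weight mass of variables missing in either
individual is removed from both numerator and denominator. Under data
missing completely at random this renormalization is unbiased; a pair of
individuals sharing no observed variable raises an error naming both ids
rather than producing a silent value. Entries are guaranteed symmetric,
zero-diagonal and within [0, 1].

**Agglomeration.** Average (default) or complete linkage on the
precomputed distance matrix, via the standard SciPy implementation; both
linkages are defined directly on dissimilarities and are therefore valid
for the non-Euclidean Gower matrix. Ward is intentionally not offered —
it presumes squared-Euclidean geometry. Merge heights are nondecreasing
for both supported linkages. Exact distance ties (measure-zero for
mixed-type data with continuous components) resolve by the library's
deterministic ordering; the test suite verifies exact agreement of whole
merge sequences with a naive O(n³) re-scan oracle on random instances.

**Flat cuts.** The partition at k undoes the last k − 1 merges. Cluster
labels 1..k are assigned in decreasing size order (ties by smallest
member position), so "cluster 1" is always the largest — matching how
such cluster tables are conventionally presented.

## Choosing the number of clusters

Internal quality metrics (mean silhouette with singletons scoring 0, Dunn
index, within/between mean-dissimilarity ratio, plus a coordinate-based
Calinski–Harabasz score computed on a one-hot, mean-imputed embedding and
reported separately) are tabulated over k = 2..15. On heterogeneous
clinical cohorts these curves are typically flat and are reported, not
maximized.

The operative rule formalizes the clinical question "when are the
patients without cataplexy placed in distinct groups?": a
*subpopulation trace* records, at every cut, how the flagged individuals
distribute over clusters, and selects the minimal k at which they occupy
at least two clusters whose flagged fraction reaches the purity threshold
(default 0.8) and whose size reaches a floor (default 10 members). The
size floor is this package's addition: without it a stray two-person
fragment can masquerade as a "distinct group", which a visual inspection
of the dendrogram would never accept. The trace also reports whether the
flagged clusters keep identical memberships over a k-interval — the
stability statement behind fixing k = 7 in the motivating analysis.

## Barcode panels

The **means barcode** is the clusters × variables matrix of mean
normalized values over observed entries, with categorical variables
expanded to one indicator column per level. Cells supported by fewer
than 10 observations are blanked.

The **significances barcode** quantifies how far each cluster mean sits
from what random grouping would produce. Each of B draws partitions the
cohort, without replacement, into pseudo-clusters of exactly the observed
cluster sizes (a random relabeling of the cohort, not independent
resampling per cluster); per draw, pseudo-cluster and variable the mean
over observed values is recorded. With μ* and σ* the across-draw mean and
SD (B − 1 denominator),

    z_cv = (m_cv − μ*_cv) / σ*_cv ,

so positive z marks a cluster value significantly *above* the cohort.
Cells with 25 or fewer observations are blanked (display requires > 25),
as are degenerate cells where σ* vanishes (a cohort-constant variable, or
a pseudo-cluster equal to the whole cohort); σ* below 1e−7 on the [0, 1]
scale is treated as exact cancellation noise. Default B = 10,000; the
draws are reproducible from a seed. On structureless cohorts the unmasked
|z| > 1.96 fraction calibrates to ≈ 5% (verified in the acceptance suite
at 2,000 draws).

## Post-hoc testing

Two clusters are compared on every variable: continuous and
ordinal-scored variables with a two-sided Mann-Whitney test (exact null
when the pooled sample is ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections), and discrete
presence/category variables (binary, categorical, count) with a χ² test
on the level-by-cluster table, without Yates correction by default
(configurable, as is the per-variable test choice). Variables observed in
fewer than two individuals in either cluster are excluded and listed.
Raw p-values are adjusted jointly across all variables tested in the
comparison with the Benjamini–Hochberg step-up procedure; the rejection
set is exactly the step-up rule's output (adjusted p ≤ q, q = 0.05).
Expected counts below 5 are flagged in the output rather than silently
accepted.

## Diagnosis and centers

The clustering stage is blinded: it never reads the diagnosis, certainty,
cataplexy or center columns (the CLI's `cluster` subcommand refuses
metadata that references them). Afterwards, per-cluster composition
tables (diagnosis × physician certainty, and center of inclusion) provide
the pie-chart data, and 2 × 2 contingency statistics treat membership in a
chosen cluster set as the test and a chosen diagnosis set as the
condition. Cells may be fractional so that a table can be reconstructed
from published percentage summaries; statistics with a zero denominator
are reported as undefined, and rounding to two decimals happens only at
the reporting layer. Diagnostic certainty is carried through composition
but pooled in the contingency statistics.

## Robustness

**Subset stability** re-runs the full pipeline (same settings and k) on
random subsets (default fraction 0.8, 50 replicates in the library;
the analysis driver uses 25 replicates, which leaves Monte-Carlo error on
the mean Jaccard well below 0.02 at this cohort size) and scores, per
original cluster, the best-match Jaccard similarity against any subset
cluster, with the adjusted Rand index over the subset reported alongside.
Replicates too small to form k clusters are skipped and counted.

**Settings variants** re-run the clustering (a) excluding individuals
with cataplexy and/or hypocretin-1 below 110 pg/mL (strict inequality;
missing hypocretin does not exclude), (b) with uniform weights, and
(c) with the nocturnal REM-latency variable recoded to a binary
sleep-onset-REM-period indicator (latency ≤ 15 minutes, the standard
SOREMP definition; configurable). Each variant re-derives the top
differentiating variables between its two least-cataplectic clusters and
reports the fraction of the base run's top-10 variables it recovers.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
patient data. A scenario declares archetypes (per-variable generative
parameters, a diagnosis rule, a cataplexy rule), variable metadata,
per-variable MCAR missingness rates, and a center count. Draws are
reproducible from one seed, split into four fixed substreams (values,
labels, missingness, centers) so a stage can be regenerated in isolation.
Binary variables are Bernoulli; categorical variables multinomial;
ordinal variables discretize a latent normal on the level-index scale;
continuous and count variables draw from normals truncated to a plausible
range (counts rounded), which keeps min–max normalization stable.
Diagnosis labels come from archetype-level probability rules — they are
consumed only by the diagnostics stage, which treats them as given — and
the cataplexy label can be copied from a generated symptom variable so
label and variable never disagree.

The built-in scenario plants 7 archetypes of sizes 231/298/92/99/157/
158/43 over 97 variables in ten category groups (demographics, nighttime
sleep, difficulties waking up, cataplexy, hallucinations, sleep
paralysis, sleepiness, MSLT, PSG, biomarkers). Thirty anchor variables
carry hand-set frequencies following the published per-cluster profiles
(severe phenotype: 97% cataplexy, 90% hallucinations, 82% paralysis; a
99%-female archetype; a non-cataplexy archetype with frequent sleep
drunkenness and a large weekend–week sleep-length difference; biomarker
contrasts in hypocretin-1 and HLA-DQB1*0602). Filler variables complete
each group; their per-archetype parameters are drawn once from a fixed
builder seed and are part of the scenario definition, not of cohort
randomness. The two non-cataplexy archetypes are generated with low
within-group dispersion and partially opposed filler profiles, and the
cataplexy archetypes with broader dispersion; the dispersion and
opposition levels were set, once, so that the generated dendrogram
reproduces the qualitative published structure — the top split separates
cataplexy from non-cataplexy, the two non-cataplexy groups are the most
distinctly grouped (also from each other), and refining the cut from 13
to 7 clusters only subdivides cataplexy-dominated groups. Missingness is
highest for invasive or lab-bound biomarkers (45% for CSF hypocretin-1,
25% for HLA typing) and modest (3–12%) elsewhere.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: informative (non-MCAR) missingness, within-
archetype correlation beyond what the shared mean profile induces,
center- or age-driven covariate structure, measurement error models for
PSG/MSLT, and the real registry's exact variable dictionary, which is not
public. Recovery results on the synthetic cohort demonstrate the
pipeline's correctness under its own assumptions, not the clinical
validity of any particular partition.

## Numerical conventions and degenerate inputs

- Distances are clipped to [0, 1] and symmetrized against float noise;
  validation rejects asymmetric or non-zero-diagonal inputs.
- Silhouette follows the convention that members of singleton clusters
  score 0; all-equal distance matrices score 0.
- The z-score's sign is (cluster − resampled)/SD: red means elevated.
- σ* uses the B − 1 denominator.
- BH adjustment caps adjusted p at 1 and uses stable sorting, so tied
  p-values adjust identically.
- The subpopulation trace requires purity thresholds in (0.5, 1] —
  below 0.5 "dominated by the flagged group" loses its meaning.

## Problem sizes used by the shipped analyses

The analysis drivers run the full 1,078-individual scenario with
B = 10,000 significance draws and 25 stability replicates. The test and
acceptance suites use the same full-size cohort for recovery checks, and
deliberately small fixtures elsewhere (structureless cohorts of 40–500
individuals, 2,000-draw calibrations, 200 null replicates for the
empirical FDR) — sizes at which the quantities being checked have small
Monte-Carlo error while the whole suite stays fast.

## Known limitations

- Average/complete linkage only; no Ward, k-medoids or model-based
  alternatives.
- The Mann-Whitney exact path requires an untied pooled sample of ≤ 20;
  beyond that the corrected normal approximation is used.
- χ² on sparse level tables is flagged (expected counts < 5) but not
  replaced by an exact test.
- Best-match Jaccard scores cluster reproducibility one cluster at a
  time; it does not penalize a subset cluster matching two original
  clusters simultaneously (the adjusted Rand index, reported alongside,
  does).
- The minimal-k rule is sensitive to where the flagged subpopulation sits
  in the dendrogram: cohorts whose flagged groups split off very early
  yield a smaller selected k than a visual reading anchored at a
  particular published solution might.
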