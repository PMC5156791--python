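# Methods

## Scope and data model

The package analyses one condition (control vs disease) per run. Its five
inputs are plain text: a features × samples log2 expression matrix plus a
sample→group table; a two-column miRNA→gene edge list; a TF gene list; GMT
pathway gene sets; and an optional literature-reported biomarker table.
All miRNA identifiers are canonicalised on ingestion (lowercase, species
prefix `hsa-` stripped, typographic star markers collapsed to a single
trailing `*`, arm suffixes kept); star miRNAs are deliberately *not*
merged with their major arm, since candidate tables list both forms as
distinct biomarkers. Gene IDs are case-folded verbatim — no alias
resolution, which is data-version dependent and out of scope.

## Differential expression

Two-group design only, matching the motivating study designs
(control/disease per subtype); no covariates, no fold-change filter, no
array normalisation (input is assumed pre-normalised, e.g. quantile- or
ΔCt-transformed upstream; the package documents rather than guesses the
upstream transform).

Per feature: lfc = mean(case) − mean(control), pooled residual SD with
df = n − 2, unscaled SE = √(1/n₁ + 1/n₂). The variance prior (d₀, s₀²) is
estimated by the method of moments on log variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), solve
ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2)) by bracketed root-finding on the
(strictly decreasing) trigamma, and s₀² = exp(mean(e) + ψ(d₀/2) −
log(d₀/2)). When the observed dispersion does not exceed sampling noise,
d₀ = ∞ and every feature shares s₀² (normal reference distribution). This
estimator is checked in the tests against the reference R implementation
(limma) on a synthetic matrix, and by parameter recovery from scaled
inverse-χ² draws (the criterion used: median d₀ within [3, 5.5] at true
d₀ = 4, s₀² within 15%, 50 seeds × 2000 features).

Zero-variance features are kept with σ = 0 (logged) and tested through the
prior rather than dropped silently. DE calls use strict adjusted p < α,
α = 0.05 by default; the BH step-up is implemented directly (six lines,
range-validated) and cross-checked against statsmodels.

## Condition network and NOD/TFP

The condition network is the induced subgraph on DE miRNAs present in the
reference plus all their targets; genes never appear without a regulator.
NOD uniqueness is evaluated *within the condition network*: a gene counts
toward a miRNA's NOD when its condition in-degree is exactly 1. A
consequence worth stating: N, TF and TFP equal their reference-network
values for every retained miRNA (targets are never pruned), while NOD
grows as the DE set shrinks — a monotonicity property the tests verify,
along with exact NOD conservation (ΣNOD = #in-degree-1 genes) and a
brute-force oracle on small networks. TFP is stored at full precision;
two-decimal half-up rounding happens only in report tables.

## Candidate selection

The selection statistic is a per-miRNA one-sample Wilcoxon signed-rank
test: for miRNA m, the NOD values of all *other* miRNAs are tested against
location NOD(m), one-sided ("less" — are the others significantly below
m?), and likewise for TFP; m is a candidate iff both raw p-values are
below α = 0.05. No multiple-testing correction is applied to the selection
p-values — the selection threshold is a raw p cutoff by design. Candidates
are ranked by descending NOD (ties: descending TFP, then ID).

Signed-rank conventions, stated for reproducibility: zero differences
dropped; tied absolute differences get average ranks; exact null by
subset-sum enumeration (valid under ties) for ≤ 25 nonzero differences;
normal approximation with tie correction and continuity correction beyond.
The exact branch is verified against full 2ⁿ enumeration and against
scipy's exact method on tie-free data; the two branches agree within 0.01
at the boundary.

The pairing behind the original outlier-analysis selection procedure is
not fully specified by its public descriptions, so this one-sample
construction is a deliberate design choice: it is deterministic, per-miRNA
and directly operationalises "significantly large NOD and TFP". As a
sensitivity check, a permutation mode is provided (`--mode permutation`):
gene endpoints of the condition network are shuffled across edge slots
(preserving each miRNA's out-degree and the gene in-degree pool up to
collision dedup), and per-miRNA empirical p-values are computed as
(1 + #{null ≥ obs})/(iters + 1) for both statistics.

## Enrichment and coverage

Query = union of the candidates' unique-target (NOD) gene sets; universe =
all genes of the reference network by default (the sampling frame from
which targets arise), switchable to the GMT union. The hypergeometric
upper tail is summed in log space (stable at p ≈ 10⁻³⁰⁰); FDR reuses the
BH routine; "enriched" requires both p < 0.05 and FDR < 0.05. Coverage of
a candidate = fraction of enriched pathways whose gene set intersects its
unique-target set (the all-targets variant is available via
`target_mode="all"`; the unique-target default keeps coverage consistent
with the enrichment query). With no enriched pathways, coverage is an
empty table with a warning, not an error.

## Validation arithmetic

Prediction precision = 100 · |predicted ∩ reported| / |predicted|,
reported at one decimal, half-up; the denominator is always the predicted
set. Cross-condition overlap partitions two candidate lists into shared
and specific IDs after normalisation. Both are invariant to duplicates and
spelling variants by construction.

## Synthetic data generator

What it emulates: a curated bipartite target network (truncated-Poisson
out-degrees, mean 8, minimum 1; 10% of genes TF-flagged), with 10 planted
biomarker miRNAs per 200 that receive 15 private targets each (targeted by
no other miRNA — full-network NOD ≥ 15 by construction) and TF draws
topped up until ≈ 30% of their targets are TFs; a case/control log2 matrix
(20 + 20 samples) whose per-feature variances follow the scaled inverse-χ²
prior (d₀ = 4, s₀² = 0.05) with ±1.5 log2-unit shifts for 30% of miRNAs
(planted ones always DE, direction random, baseline intensities
N(7, 1)); pathway sets of 20–60 genes, one per planted miRNA built from
80% unique targets; and a literature list mixing half the planted
biomarkers with ten decoys. Defaults are chosen to be realistic for
small-array case/control miRNA studies at desk scale.

What it does not emulate: batch and background artifacts, intensity-
dependent variance, probe saturation, scale-free degree distributions,
correlated features, or miRNAs absent from the network. Passing tests
therefore demonstrate correctness of the statistics and the recovery of
planted structure under the model's own assumptions — not robustness to
real microarray pathologies.

Determinism: every generator is a pure function of its arguments; a master
seed is split into fixed per-generator substreams
(network/expression/gene-sets/reported = 0/1/2/3) via numpy
`SeedSequence(seed, spawn_key=(offset,))`, so stages are independently
reproducible. Identical seeds yield byte-identical output files; the run
report's hashed body excludes timestamps so repeat runs are verifiable.

## Numerical choices and degenerate inputs

- Trigamma inversion: Brent root-finding on [10⁻⁸, 10·2ᵏ] after geometric
  bracket expansion; d₀ = ∞ branch when excess dispersion ≤ 0.
- Duplicate expression rows collapse by mean (logged); duplicate edges
  drop (logged); TF genes outside the network drop (logged).
- A miRNA whose signed-rank test is degenerate (all other values equal to
  its own) is a non-candidate, logged — not an error for the run.
- Empty DE∩reference intersection, empty query after universe filtering,
  all-zero residual SDs: hard errors naming the cause.
- Rounding for reported numbers is decimal half-up (TFP 2 dp, precision
  1 dp, coverage percent 0 dp) to match tabular presentation conventions;
  full precision is kept internally.

## Known limitations

- The one-sample signed-rank selection treats the other miRNAs' statistic
  values as exchangeable observations; NOD values are in fact weakly
  coupled through shared targets. The permutation mode exists precisely to
  probe this assumption.
- Selection α is a raw threshold, so the candidate count grows with the
  size of the DE set; at the synthetic defaults the measured planted-truth
  recovery is median sensitivity 1.0 at median FDP 0.17 (50 seeds) — the
  acceptance suite recomputes this.
- Gene-ID matching is purely lexical; supplying network and GMT files from
  different annotation vocabularies will silently shrink overlaps.
- One condition per run: subtype comparisons (shared vs specific
  candidates) operate on two completed runs' outputs.
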