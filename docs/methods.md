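# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Count model and differential expression

Counts are modelled as negative binomial in the mean/dispersion
parameterisation, `Var(k) = μ + αμ²`, the convention of the popular
count-based DE tools. For feature *i* in sample *j*,
`μ_ij = s_j · q_i · 2^(β_i · x_j)` with library size factor `s_j`, control
mean `q_i`, log2 fold change `β_i` and treatment indicator `x_j`.

**Size factors** are median-of-ratios: over features with no zero count,
the median of `k_ij / geomean_i`, rescaled so the factors' geometric mean
is 1. The rescale fixes the otherwise arbitrary global scale and makes
factors comparable across runs; fold changes are invariant to it (up to the
pseudo-count, see below).

**Dispersion** is estimated per feature by the method of moments on
normalised counts, `α̂ = max(10⁻⁸, (v − m)/m²)` with the within-condition
pooled variance `v` and grand mean `m`. With 2–3 replicates per condition
this estimate is extremely noisy (4 residual degrees of freedom), so the
Wald test consumes a moderated value: each `α̂_i` is shrunk linearly toward
the across-feature mean with weight `resid_df / (resid_df + prior_df)`
(default prior_df = 10). The *mean* is the shrinkage centre rather than the
median because the sampling distribution of `α̂` is strongly right-skewed
at small n: the mean stays close to the underlying dispersion while the
median sits well below it, and an understated dispersion makes the Wald
test anti-conservative. With this moderation the measured type-I error at
p < 0.05 on a pure-null simulation (2000 features, 3 vs 3, α = 0.1) is
0.05–0.07; with raw per-feature estimates it is ≈ 0.12. No trend fitting,
Cox–Reid adjustment or outlier handling is attempted — exact equivalence
with any particular DE package is a non-goal; calibration and recovery are
the acceptance properties.

**Test.** `log2FC = log2((m_t + c)/(m_c + c))` on normalised condition
means with pseudo-count `c = 0.5` (configurable) so all-zero conditions are
defined; the delta-method variance is
`Var(m_g)/((m_g + c)² ln²2)` summed over the two conditions, with
`Var(m_g) = m_g Σ_j s_j⁻¹ / n_g² + α m_g² / n_g`. Two-sided p values use
the normal reference; adjustment is Benjamini–Hochberg (via
`statsmodels`). All-zero features are reported as `log2FC = 0, p = 1`.

**Filters.** All thresholds are inclusive. "Raw count ≥ 50" is interpreted
as the total over all samples (a per-sample reading would be far stricter
and is configurable). The RPM floor uses condition means — "below
threshold in either condition" excludes — computed on raw library sizes,
not normalised counts. Ties in p are left in stable feature-id order so
output files are deterministic.

## Target integration

Per-resource thresholds are inclusive exactly as published (see
`mmint/data/source_thresholds.yaml`). Consensus counts *distinct*
resources, so duplicate records from one database cannot satisfy the
two-database rule. Validated resources (strong-evidence flag) count toward
the consensus on equal footing with predicted ones; a
`validated_bypass_consensus` switch optionally admits validated-only pairs,
off by default. The anti-correlation rule keeps a pair only when the miRNA
and the gene are DE in opposite directions, which is asserted again as an
output invariant. The role-orientation refinement (down-regulated oncogenic
miRNA vs up-regulated tumour-suppressor target, and the symmetric case)
only runs when a role table is supplied, since no operational oncogene
annotation ships with the package; without one the refinement reduces to
the 12-RPM miRNA abundance floor. Pair identity is (miRNA id, gene id);
multiple binding sites on one 3′UTR are not modelled.

## Network

The zero-order subnetwork is the induced subgraph of the interactome on the
DE gene set with isolated seeds dropped (the common convention of
integrative network tools; it is what makes "nodes" mean "genes with at
least one interaction"). All edges are undirected, including miRNA–gene
edges — regulatory direction is carried as node metadata (`up`/`down`),
not edge direction. Betweenness is the standard unnormalised shortest-path
count (normalisation available by flag). Assembly is idempotent and
invariant to input edge order; edges are written canonically sorted.

## Enrichment

The test is the one-sided hypergeometric over-representation p,
`P(X ≥ k)` for overlap `k`, term size `K`, query size `n` and universe
`N`; the universe defaults to all genes of the collection (override
available) and every term is tested and corrected together. Family-wise
correction is Bonferroni step-down (Holm). Selection requires overlap ≥ 3,
attribution (overlap/term size) ≥ 0.04 and corrected p ≤ 0.05, inclusive.

Grouping: pairwise Cohen's kappa between the selected terms' binary gene
memberships, by default over the union of their overlap genes (the
reference set choice changes kappa values; the full universe is available
as an option, where shared absences inflate agreement). Terms with
κ ≥ 0.04 are linked and groups are connected components, each labelled by
its minimum-p member (ties broken lexicographically). Iterative group
merging and ontology-aware term fusion, as performed by some GUI tools, are
deliberately not reproduced: the component construction is transparent,
order-independent and monotone in the threshold (raising κ never merges
groups). The default connectivity threshold 0.04 is kept as configured in
the emulated workflow and is a flag.

## Synthetic data

The generator emulates: NB counts for two conditions with log-uniform
library factors on [0.5, 2]; planted miRNA→gene repressions in which the
two members receive opposite-sign log2 fold changes of equal magnitude;
multi-resource prediction tables where true pairs are reported with a given
sensitivity and threshold-passing scores, false pairs appear at a given
per-(resource, pair) rate with scores straddling the threshold, and a
configurable fraction (default 10%) of true validated-resource records is
strong-evidence validated; an Erdős–Rényi interactome; and random gene-set
collections, optionally seeding one term with 80% of a chosen query.

Defaults define the study conditions: 150 miRNAs, 1500 genes, 50 planted
pairs with |log2FC| = 1.5, base means log-uniform on [100, 5000] counts,
dispersion 0.05 (typical for cell-line replicates), 3 replicates per
condition, three predicted resources at sensitivity 0.9 and false-pair rate
0.002. Each gene is targeted by at most one planted miRNA so the planted
anti-correlation is always self-consistent (a miRNA may target several
genes).

Not emulated: sequence content and seed-match structure, read-level
artefacts (the pipeline starts at count matrices), GC/length biases,
between-feature count correlation, scale-free interactome topology, and
ontology structure among terms. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on data matching
the model's assumptions — not robustness to the biases of real libraries.

## Numerical choices and degenerate inputs

Dispersion floor 10⁻⁸; pseudo-count 0.5 in fold changes; p values clipped
to [0, 1]; empty prediction tables, empty networks and empty enrichment
results propagate as empty outputs with success status; normalisation
refuses matrices with no all-positive feature; concordance (Pearson r of
two log2FC maps) requires ≥ 3 shared finite features; kappa of two
constant identical membership vectors is 1 (0 if constant but different).
Every generator and the pipeline take explicit integer seeds; fixed seed
implies byte-identical outputs.

## Problem sizes

The shipped scenarios (2000-feature null calibration, 1500-gene pipeline
runs, 2000-gene enrichment universe) were chosen so the whole test suite
and the acceptance script each complete in well under a minute on a single
CPU while keeping sampling error small relative to the tested tolerances;
all sizes are parameters and scale up without code changes.

## Known limitations

- The DE engine is a transparent simplified Wald test: no shrinkage of fold
  changes, no independent filtering, no outlier moderation; at very low
  counts (base mean ≪ 50) its normal reference is approximate.
- Consensus and anti-correlation logic inherit the quality of the supplied
  prediction tables; the package never re-derives resource scores.
- Kappa grouping by connected components can chain otherwise dissimilar
  terms through intermediates at low thresholds — inherent to the
  component construction.
- The interactome model is Erdős–Rényi; degree-distribution-sensitive
  topology statistics on synthetic runs should not be over-interpreted.
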