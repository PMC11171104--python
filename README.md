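# mmint — integrated miRNA–mRNA expression and network analysis

`mmint` implements, as a tested and reusable Python pipeline, the integrated
analysis used to study how a metabolic drug perturbs microRNA-mediated gene
regulation in cancer cells: paired small-RNA and mRNA count matrices from a
two-condition experiment are analysed for differential expression, miRNA →
target-gene pairs are called by multi-resource prediction consensus plus
expression anti-correlation, the pairs are merged with a protein–protein
interactome into one integrated network, and the network's genes are tested
for pathway over-representation with kappa-score term grouping.

It is aimed at computational biologists who have count matrices (e.g. from
HTSeq) and want the downstream integration logic as a scriptable library
and CLI rather than a chain of web tools. Because raw data for such studies
are often not deposited, the package ships a synthetic-data module that
generates every input with a known ground truth, so the whole pipeline is
testable and its operating characteristics (error rates, recovery) are
measurable.

## The method

**Differential expression.** Counts `k_ij` are modelled as negative
binomial with mean `s_j · q_i` and dispersion `α_i` (Var = μ + αμ²). Size
factors `s_j` are median-of-ratios; dispersions are method-of-moments
estimates shrunk toward their across-feature mean; the Wald statistic tests
`log2FC = log2((μ̂_treated + ½)/(μ̂_control + ½))` against a normal
reference with a delta-method standard error. Features are called DE when
(all inclusive): total raw count ≥ 50, BH-adjusted p ≤ 0.05 and
|log2FC| ≥ 1. Genes additionally require a condition-mean abundance of
≥ 6 reads per million (RPM) in *both* conditions.

**Target integration.** Prediction records pass per-resource score
thresholds (TargetScan context ≤ −0.15, DIANA-microT-CDS ≥ 0.85,
miRDB ≥ 80, miRanda ≤ −1.2, miRmap ≥ 90; validated resources pass on a
strong-evidence flag). A (miRNA, gene) pair is kept when supported by ≥ 2
distinct resources and its two members are DE in opposite directions. A
stricter refinement drops pairs whose miRNA sits below 12 RPM and can
optionally require an oncogene / tumour-suppressor role orientation.

**Network.** The zero-order subnetwork of a reference interactome — the
induced subgraph on the DE genes, dropping unconnected seeds — is merged
with the miRNA–gene pairs into one undirected typed network; degree,
betweenness and components are reported.

**Enrichment.** Genes with network degree ≥ 1 are tested per term with the
one-sided hypergeometric test, corrected by Bonferroni step-down (Holm).
Terms with overlap ≥ 3, attribution ≥ 4% and corrected p ≤ 0.05 are grouped
by pairwise Cohen's kappa of their gene memberships (connectivity at
κ ≥ 0.04); each group is labelled by its most significant term.

## Worked example

```python
from mmint.pipeline import PipelineConfig, run

summary = run(PipelineConfig(seed=1), "runs/demo")
print(summary["funnel"]["anticorrelated_pairs"])  # 42
print(summary["recovery"])
```

Under the default synthetic scenario (150 miRNAs, 1500 genes, 50 planted
repressions with |log2FC| = 1.5, three prediction resources at sensitivity
0.9 and false-pair rate 0.002, 3 replicates per condition) this prints:

```
42
{'n_true_pairs': 50, 'n_reported_pairs': 42, 'true_positive_count': 42,
 'precision': 1.0, 'recall': 0.84, 'f1': 0.913...}
```

i.e. of 50 planted miRNA→gene repressions, 42 survive every filter (all of
them true positives; the 8 misses fail the DE or consensus stages under
this noise level), and the run directory contains each stage's output: DE
tables, the pair lists, the integrated network (SIF + node attributes), the
enriched-term table and `summary.json` with the full filter funnel. The
same run is available from the shell:

```bash
mmint run --seed 1 --out runs/demo
mmint simulate --seed 1 --out fixture/      # inputs + ground truth only
mmint de --counts fixture/mrna_counts.tsv --condition fixture/mrna_condition.tsv \
         --out de_mrna.tsv --rpm-floor 6
```

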