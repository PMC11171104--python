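# Default pipeline configuration: thresholds for every stage and the
# synthetic study scenario. Values here are the published study defaults;
# CLI flags override them.
seed: 0

# differential expression (inclusive thresholds)
min_total_count: 50      # total raw count over all samples
max_padj: 0.05
min_abs_lfc: 1.0
rpm_floor_mrna: 6.0      # genes: condition-mean reads-per-million floor
rpm_refine_mirna: 12.0   # miRNAs: stricter abundance floor at refinement

# target integration
min_sources: 2
validated_bypass_consensus: false
role_table_path: null

# enrichment
enrich_min_genes: 3
enrich_min_attribution: 0.04
enrich_alpha: 0.05
kappa_threshold: 0.04    # kappa connectivity for term grouping
kappa_reference: overlap-union

source_thresholds_path: null   # null -> shipped registry

simulation:
  n_mirna: 150
  n_gene: 1500
  n_pairs: 50
  lfc_magnitude: 1.5
  dispersion: 0.05
  base_mean_range: [100.0, 5000.0]
  n_rep: 3
  mean_libsize: 1.0
  sources: [TargetScan, DIANA-microT-CDS, miRDB]
  sensitivity: 0.9
  fp_rate: 0.002
  validated_fraction: 0.1
  ppi_mean_degree: 4.0
  n_terms: 50
  term_size_range: [10, 50]
  planted_fraction: 0.8
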