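"""End-to-end orchestration: simulate -> DE -> integrate -> network -> enrich.

A run is driven by a :class:`PipelineConfig` (constructed directly, or from
YAML where CLI flags override file values), writes every stage's output into
a run directory, and records the filter funnel - the number of features,
pairs, nodes and terms surviving each successive filter - in a versioned
``summary.json``. Given a seed the whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrichment, io, network, synthetic_data, target_integration
from .exceptions import ConfigurationError, StageError
from .types import CountMatrix, GeneSetCollection, GroundTruth

logger = logging.getLogger("mmint")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic scenario."""

    n_mirna: int = 150
    n_gene: int = 1500
    n_pairs: int = 50
    lfc_magnitude: float = 1.5
    dispersion: float = synthetic_data.DEFAULT_DISPERSION
    base_mean_range: tuple[float, float] = synthetic_data.DEFAULT_BASE_MEAN_RANGE
    n_rep: int = 3
    mean_libsize: float = 1.0
    sources: list[str] = field(
        default_factory=lambda: ["TargetScan", "DIANA-microT-CDS", "miRDB"]
    )
    sensitivity: float = 0.9
    fp_rate: float = 0.002
    validated_fraction: float = 0.1
    ppi_mean_degree: float = 4.0
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    planted_fraction: float = 0.8


@dataclass
class PipelineConfig:
    """Thresholds and switches for every stage; defaults are the study values."""

    seed: int = 0
    min_total_count: int = 50
    max_padj: float = 0.05
    min_abs_lfc: float = 1.0
    rpm_floor_mrna: float = 6.0
    rpm_refine_mirna: float = 12.0
    min_sources: int = 2
    validated_bypass_consensus: bool = False
    role_table_path: str | None = None
    enrich_min_genes: int = 3
    enrich_min_attribution: float = 0.04
    enrich_alpha: float = 0.05
    kappa_threshold: float = 0.04
    kappa_reference: str = "overlap-union"
    source_thresholds_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        try:
            sim = SimulationConfig(**sim_raw)
            cfg = cls(**raw, simulation=sim)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        checks = [
            (self.max_padj, 0.0, 1.0, "max_padj"),
            (self.enrich_alpha, 0.0, 1.0, "enrich_alpha"),
            (self.simulation.sensitivity, 0.0, 1.0, "sensitivity"),
            (self.simulation.fp_rate, 0.0, 1.0, "fp_rate"),
        ]
        for value, lo, hi, name in checks:
            if not lo <= value <= hi:
                raise ConfigurationError(f"{name} = {value} outside [{lo}, {hi}]")
        for name in ("min_total_count", "min_sources", "enrich_min_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class RecoveryReport:
    """Set-level comparison of reported pairs against the planted truth."""

    n_true_pairs: int
    n_reported_pairs: int
    true_positive_count: int
    precision: float
    recall: float
    f1: float


def evaluate(reported_pairs, truth: GroundTruth) -> RecoveryReport:
    """Precision/recall/F1 of reported (miRNA, gene) tuples vs the planted set."""
    if isinstance(reported_pairs, pd.DataFrame):
        reported = {(r.mirna_id, r.gene_id) for r in reported_pairs.itertuples(index=False)}
    else:
        reported = {tuple(p) for p in reported_pairs}
    true = set(truth.regulated_pairs)
    tp = len(reported & true)
    precision = tp / len(reported) if reported else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return RecoveryReport(len(true), len(reported), tp, precision, recall, f1)


def simulate_inputs(config: PipelineConfig):
    """Generate all pipeline inputs for the configured synthetic scenario."""
    sim = config.simulation
    seed = config.seed
    truth = synthetic_data.generate_ground_truth(
        sim.n_mirna, sim.n_gene, sim.n_pairs, sim.lfc_magnitude, seed,
        base_mean_range=tuple(sim.base_mean_range), dispersion=sim.dispersion,
    )
    mirna_counts, mrna_counts = synthetic_data.simulate_counts(
        truth, sim.n_rep, sim.mean_libsize, seed=seed + 1
    )
    registry = target_integration.load_source_configs(config.source_thresholds_path)
    try:
        sources = [registry[name] for name in sim.sources]
    except KeyError as exc:
        raise ConfigurationError(f"unknown prediction source {exc.args[0]!r}")
    predictions = synthetic_data.simulate_predictions(
        truth, sources, sim.sensitivity, sim.fp_rate, seed=seed + 2,
        validated_fraction=sim.validated_fraction,
    )
    ppi = synthetic_data.simulate_ppi(truth.gene_ids, sim.ppi_mean_degree, seed=seed + 3)
    planted = {g for _, g in truth.regulated_pairs}
    genesets = synthetic_data.simulate_genesets(
        truth.gene_ids, sim.n_terms, tuple(sim.term_size_range),
        planted_term=planted or None, planted_fraction=sim.planted_fraction,
        seed=seed + 4,
    )
    return truth, mirna_counts, mrna_counts, predictions, ppi, genesets


def run(
    config: PipelineConfig,
    outdir,
    inputs: tuple | None = None,
) -> dict:
    """Execute every stage, write stage outputs under ``outdir``, return the summary.

    When ``inputs`` is None the synthetic scenario in the config is
    generated first (and written alongside the outputs); otherwise it must
    be the tuple ``(truth_or_None, mirna_counts, mrna_counts, predictions,
    ppi, genesets)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}

    try:
        if inputs is None:
            truth, mirna_counts, mrna_counts, predictions, ppi, genesets = simulate_inputs(config)
            io.write_counts(mirna_counts, outdir / "mirna_counts.tsv", outdir / "mirna_condition.tsv")
            io.write_counts(mrna_counts, outdir / "mrna_counts.tsv", outdir / "mrna_condition.tsv")
            io.write_predictions(predictions, outdir / "predictions.tsv")
            io.write_ppi(ppi, outdir / "ppi.tsv", outdir / "ppi.sif")
            io.write_gmt(genesets, outdir / "genesets.gmt")
            io.write_gene_list(genesets.universe, outdir / "universe.txt")
        else:
            truth, mirna_counts, mrna_counts, predictions, ppi, genesets = inputs
    except Exception as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise StageError("simulate", str(exc)) from exc

    # ---- differential expression --------------------------------------
    try:
        de_mirna = diffexpr.de_results(
            mirna_counts, config.min_total_count, config.max_padj, config.min_abs_lfc
        )
        de_mrna = diffexpr.de_results(
            mrna_counts, config.min_total_count, config.max_padj, config.min_abs_lfc
        )
        diffexpr.write_de_results(de_mirna, outdir / "de_mirna.tsv")
        diffexpr.write_de_results(de_mrna, outdir / "de_mrna.tsv")

        mrna_rpm_kept = diffexpr.rpm_filter(mrna_counts, config.rpm_floor_mrna)
        mirna_up, mirna_down = diffexpr.filter_de(
            de_mirna, config.min_total_count, config.max_padj, config.min_abs_lfc
        )
        gene_up, gene_down = diffexpr.filter_de(
            de_mrna[de_mrna["feature_id"].isin(mrna_rpm_kept)],
            config.min_total_count, config.max_padj, config.min_abs_lfc,
        )
        funnel.update(
            mirna_features=len(de_mirna),
            mirna_de=len(mirna_up) + len(mirna_down),
            mirna_de_up=len(mirna_up),
            mirna_de_down=len(mirna_down),
            gene_features=len(de_mrna),
            gene_rpm_kept=len(mrna_rpm_kept),
            gene_de=len(gene_up) + len(gene_down),
            gene_de_up=len(gene_up),
            gene_de_down=len(gene_down),
        )
        logger.info("DE: %d/%d miRNAs, %d/%d genes pass the filters",
                    funnel["mirna_de"], funnel["mirna_features"],
                    funnel["gene_de"], funnel["gene_features"])
    except Exception as exc:
        raise StageError("diffexpr", str(exc)) from exc

    # ---- target integration -------------------------------------------
    try:
        registry = target_integration.load_source_configs(config.source_thresholds_path)
        passed = target_integration.apply_source_thresholds(predictions, registry)
        consensus = target_integration.consensus_pairs(passed, config.min_sources)
        if config.validated_bypass_consensus:
            singles = target_integration.consensus_pairs(passed, 1)
            validated_only = singles[singles["validated"] & ~singles.set_index(
                ["mirna_id", "gene_id"]).index.isin(
                consensus.set_index(["mirna_id", "gene_id"]).index)]
            consensus = pd.concat([consensus, validated_only], ignore_index=True)
        anticorr = target_integration.anticorrelation_filter(
            consensus, mirna_up, mirna_down, gene_up, gene_down
        )
        mirna_rpm12 = diffexpr.rpm_filter(mirna_counts, config.rpm_refine_mirna)
        role_table = None
        if config.role_table_path:
            roles = pd.read_csv(config.role_table_path, sep="\t")
            role_table = dict(zip(roles.iloc[:, 0], roles.iloc[:, 1]))
        else:
            logger.info("no cancer-role table supplied; skipping role orientation filter")
        refined = target_integration.refine_pairs(anticorr, mirna_rpm12, role_table)
        target_integration.write_pairs(anticorr, outdir / "pairs.tsv")
        target_integration.write_pairs(refined, outdir / "pairs_refined.tsv")
        funnel.update(
            prediction_records=len(predictions),
            records_pass_threshold=len(passed),
            consensus_pairs=len(consensus),
            anticorrelated_pairs=len(anticorr),
            refined_pairs=len(refined),
        )
        logger.info("integration: %d records -> %d consensus -> %d anti-correlated -> %d refined",
                    len(passed), len(consensus), len(anticorr), len(refined))
    except Exception as exc:
        raise StageError("target_integration", str(exc)) from exc

    # ---- network -------------------------------------------------------
    try:
        de_gene_ids = set(gene_up["feature_id"]) | set(gene_down["feature_id"])
        ppi_sub, _ = network.zero_order_subnetwork(de_gene_ids, ppi)
        mirna_dir = dict(zip(de_mirna["feature_id"], de_mirna["direction"]))
        gene_dir = dict(zip(de_mrna["feature_id"], de_mrna["direction"]))
        net = network.assemble(anticorr, ppi_sub, mirna_dir, gene_dir)
        rep = network.topology(net)
        network.write_network(net, outdir / "network.sif", outdir / "network_nodes.tsv")
        funnel.update(
            network_nodes=rep.n_nodes,
            network_mirna_nodes=rep.n_mirna_nodes,
            network_gene_nodes=rep.n_gene_nodes,
            network_edges=rep.n_edges,
            network_mirna_gene_edges=rep.n_mirna_gene_edges,
            network_gene_gene_edges=rep.n_gene_gene_edges,
        )
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    # ---- enrichment ----------------------------------------------------
    try:
        query = set(network.degree_filter(net, min_degree=1))
        io.write_gene_list(query, outdir / "enrichment_query.txt")
        enriched = enrichment.enrich(
            query, genesets,
            min_genes=config.enrich_min_genes,
            min_attribution=config.enrich_min_attribution,
            alpha=config.enrich_alpha,
            kappa_threshold=config.kappa_threshold,
            kappa_reference=config.kappa_reference,
        )
        enrichment.write_enrichment(enriched, outdir / "enriched_terms.tsv")
        funnel.update(
            enrichment_query_genes=len(query),
            enriched_terms=len(enriched),
            enriched_groups=enriched["group_id"].nunique() if len(enriched) else 0,
        )
    except Exception as exc:
        raise StageError("enrichment", str(exc)) from exc

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "funnel": funnel,
    }
    if truth is not None:
        report = evaluate(refined, truth)
        summary["recovery"] = asdict(report)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
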