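"""Generators for fully synthetic pipeline inputs with known ground truth.

The generators emulate a two-condition (control vs drug-treated) paired
miRNA/mRNA sequencing experiment: negative-binomial counts with per-sample
library-size factors, a planted set of miRNA -> target repressions whose two
members change in opposite directions, multi-resource target-prediction
tables with controllable sensitivity and false-pair rate, an Erdos-Renyi
protein-protein interaction graph, and random gene-set collections with an
optionally planted enriched term.

Every generator takes an explicit integer seed and is deterministic given
it; no global RNG state is touched. Defaults describe a typical cell-line
experiment: control-condition means log-uniform on [100, 5000] counts,
dispersion 0.05 (Var = mu + 0.05 mu^2), library factors log-uniform on
[0.5, 2], and one prediction in ten experimentally validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .target_integration import DEFAULT_SOURCES, SourceConfig
from .types import CONTROL, TREATED, CountMatrix, GeneSetCollection, GroundTruth

#: width of the simulated score band on each side of a resource's threshold
SCORE_SPANS = {
    "TargetScan": 0.15,
    "DIANA-microT-CDS": 0.10,
    "miRDB": 15.0,
    "miRanda": 0.6,
    "miRmap": 8.0,
}

DEFAULT_BASE_MEAN_RANGE = (100.0, 5000.0)
DEFAULT_DISPERSION = 0.05
DEFAULT_VALIDATED_FRACTION = 0.1


def _mirna_id(i: int) -> str:
    return f"miR-{i:04d}"


def _gene_id(i: int) -> str:
    return f"GENE{i:05d}"


def generate_ground_truth(
    n_mirna: int,
    n_gene: int,
    n_pairs: int,
    lfc_magnitude: float,
    seed: int,
    *,
    base_mean_range: tuple[float, float] = DEFAULT_BASE_MEAN_RANGE,
    dispersion: float = DEFAULT_DISPERSION,
) -> GroundTruth:
    """Plant ``n_pairs`` anti-correlated miRNA -> gene repressions.

    Each regulated miRNA receives a log2 fold change of +-``lfc_magnitude``
    (random sign, fixed once per miRNA); each of its target genes receives
    the opposite sign. Unregulated features have fold change zero. Every
    gene is targeted by at most one miRNA so the anti-correlation structure
    is always consistent, hence ``n_pairs`` may not exceed ``n_gene``.
    Control-condition means are log-uniform over ``base_mean_range`` and the
    dispersion is shared across features.
    """
    if lfc_magnitude <= 0:
        raise ValidationError("lfc_magnitude must be positive")
    if n_pairs < 0 or n_pairs > n_gene or n_pairs > n_mirna * n_gene:
        raise ValidationError(
            f"cannot plant {n_pairs} pairs with {n_mirna} miRNAs and {n_gene} genes"
        )
    rng = np.random.default_rng(seed)
    mirnas = [_mirna_id(i) for i in range(n_mirna)]
    genes = [_gene_id(i) for i in range(n_gene)]

    mirna_lfc = {m: 0.0 for m in mirnas}
    gene_lfc = {g: 0.0 for g in genes}
    pairs: set[tuple[str, str]] = set()
    if n_pairs:
        target_genes = rng.choice(n_gene, size=n_pairs, replace=False)
        reg_mirnas = rng.integers(0, n_mirna, size=n_pairs)
        signs: dict[str, float] = {}
        for mi, gi in zip(reg_mirnas, target_genes):
            m, g = mirnas[mi], genes[gi]
            if m not in signs:
                signs[m] = 1.0 if rng.random() < 0.5 else -1.0
            mirna_lfc[m] = signs[m] * lfc_magnitude
            gene_lfc[g] = -signs[m] * lfc_magnitude
            pairs.add((m, g))

    lo, hi = base_mean_range
    all_ids = mirnas + genes
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(all_ids)))
    return GroundTruth(
        regulated_pairs=frozenset(pairs),
        mirna_lfc=mirna_lfc,
        gene_lfc=gene_lfc,
        base_mean=dict(zip(all_ids, base)),
        dispersion={f: dispersion for f in all_ids},
        seed=seed,
    )


def _simulate_matrix(
    feature_ids: list[str],
    lfc: dict[str, float],
    truth: GroundTruth,
    n_rep: int,
    mean_libsize: float,
    rng: np.random.Generator,
) -> CountMatrix:
    samples = [f"{CONTROL}_{r + 1}" for r in range(n_rep)] + [
        f"{TREATED}_{r + 1}" for r in range(n_rep)
    ]
    condition = {s: CONTROL if s.startswith(CONTROL) else TREATED for s in samples}
    treated = np.array([condition[s] == TREATED for s in samples], dtype=float)
    size = mean_libsize * np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))

    q = np.array([truth.base_mean[f] for f in feature_ids])
    fc = np.array([lfc[f] for f in feature_ids])
    alpha = np.array([truth.dispersion[f] for f in feature_ids])

    mu = q[:, None] * np.power(2.0, fc[:, None] * treated[None, :]) * size[None, :]
    n_nb = 1.0 / alpha
    p_nb = n_nb[:, None] / (n_nb[:, None] + mu)
    counts = rng.negative_binomial(n_nb[:, None], p_nb)
    df = pd.DataFrame(counts, index=feature_ids, columns=samples)
    return CountMatrix(counts=df, condition=condition,
                       library_size=dict(zip(samples, size)))


def simulate_counts(
    truth: GroundTruth,
    n_rep: int,
    mean_libsize: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw NB counts for the miRNA and mRNA matrices of a two-condition design.

    Count ``k_ij ~ NB(mean = s_j * q_i * 2^(lfc_i * [treated_j]), alpha_i)``
    where ``s_j`` is the sample's library factor (log-uniform on [0.5, 2],
    scaled by ``mean_libsize``) and ``q_i`` the planted control mean. The two
    matrices get independent library factors, as the two molecule classes
    are sequenced as separate libraries.
    """
    if n_rep < 2:
        raise ValidationError("need at least 2 replicates per condition")
    rng = np.random.default_rng(seed)
    mirna = _simulate_matrix(truth.mirna_ids, truth.mirna_lfc, truth, n_rep, mean_libsize, rng)
    mrna = _simulate_matrix(truth.gene_ids, truth.gene_lfc, truth, n_rep, mean_libsize, rng)
    return mirna, mrna


def _passing_score(cfg: SourceConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    span = SCORE_SPANS[cfg.name]
    u = rng.uniform(0.0, span, size=size)
    return cfg.threshold - u if cfg.direction == "le" else cfg.threshold + u


def _straddling_score(cfg: SourceConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    span = SCORE_SPANS[cfg.name]
    return cfg.threshold + rng.uniform(-span, span, size=size)


def simulate_predictions(
    truth: GroundTruth,
    sources: list[SourceConfig] | None = None,
    sensitivity: float = 0.9,
    fp_rate: float = 0.002,
    seed: int = 0,
    validated_fraction: float = DEFAULT_VALIDATED_FRACTION,
) -> pd.DataFrame:
    """Emit a multi-resource prediction table covering the planted pairs.

    Each resource reports each true pair with probability ``sensitivity``;
    true records from predicted resources carry a threshold-passing score.
    False pairs are emitted per (resource, possible pair) with probability
    ``fp_rate`` and carry scores straddling the threshold, so roughly half
    survive score filtering. Validated resources report no score; their true
    records are strong-evidence validated with probability
    ``validated_fraction`` (false records with probability 0.5, mirroring
    the straddle).
    """
    if not 0 <= sensitivity <= 1 or not 0 <= fp_rate <= 1:
        raise ValidationError("sensitivity and fp_rate must lie in [0, 1]")
    if sources is None:
        sources = list(DEFAULT_SOURCES.values())
    rng = np.random.default_rng(seed)

    mirnas, genes = truth.mirna_ids, truth.gene_ids
    true_pairs = sorted(truth.regulated_pairs)
    true_index = {(m, g) for m, g in true_pairs}
    n_possible_false = len(mirnas) * len(genes) - len(true_pairs)

    rows = []
    for cfg in sorted(sources, key=lambda c: c.name):
        emit = rng.random(len(true_pairs)) < sensitivity
        emitted = [p for p, e in zip(true_pairs, emit) if e]
        if cfg.kind == "predicted":
            scores = _passing_score(cfg, rng, len(emitted))
            for (m, g), s in zip(emitted, scores):
                rows.append((cfg.name, m, g, float(s), False))
        else:
            flags = rng.random(len(emitted)) < validated_fraction
            for (m, g), v in zip(emitted, flags):
                rows.append((cfg.name, m, g, np.nan, bool(v)))

        n_false = rng.binomial(n_possible_false, fp_rate) if n_possible_false else 0
        seen: set[tuple[str, str]] = set()
        while len(seen) < n_false:
            mi = rng.integers(0, len(mirnas))
            gi = rng.integers(0, len(genes))
            pair = (mirnas[mi], genes[gi])
            if pair in true_index or pair in seen:
                continue
            seen.add(pair)
        false_pairs = sorted(seen)
        if cfg.kind == "predicted":
            scores = _straddling_score(cfg, rng, len(false_pairs))
            for (m, g), s in zip(false_pairs, scores):
                rows.append((cfg.name, m, g, float(s), False))
        else:
            flags = rng.random(len(false_pairs)) < 0.5
            for (m, g), v in zip(false_pairs, flags):
                rows.append((cfg.name, m, g, np.nan, bool(v)))

    return pd.DataFrame(rows, columns=["source", "mirna_id", "gene_id", "score", "validated"])


def simulate_ppi(gene_ids: list[str], mean_degree: float, seed: int) -> list[tuple[str, str]]:
    """Erdos-Renyi interactome over ``gene_ids`` with expected degree ``mean_degree``.

    Returns a sorted edge list with canonical (a < b) ordering, no
    self-loops and no duplicates.
    """
    import networkx as nx

    n = len(gene_ids)
    if n < 2 or mean_degree < 0 or mean_degree >= n - 1:
        if mean_degree == 0:
            return []
        raise ValidationError("mean_degree must lie in [0, n_genes - 1)")
    p = mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    ordered = sorted(gene_ids)
    return sorted(tuple(sorted((ordered[a], ordered[b]))) for a, b in g.edges())


def simulate_genesets(
    gene_ids: list[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 50),
    planted_term: set[str] | None = None,
    planted_fraction: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection, optionally seeding one term with DE genes.

    Terms sample members uniformly without replacement. When
    ``planted_term`` is given, the first term additionally contains
    ``planted_fraction`` of those genes (rounded down), making its
    enrichment in that query detectable downstream.
    """
    lo, hi = term_size_range
    universe = sorted(gene_ids)
    if hi > len(universe):
        raise ValidationError("term sizes cannot exceed the universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(n_terms):
        term_id = f"T{t + 1:04d}"
        name = f"synthetic term {t + 1}"
        size = int(rng.integers(lo, hi + 1))
        if t == 0 and planted_term:
            planted = sorted(set(planted_term) & set(universe))
            k = int(np.floor(planted_fraction * len(planted)))
            seeded = list(rng.choice(planted, size=k, replace=False)) if k else []
            remainder = sorted(set(universe) - set(seeded))
            fill = max(size - len(seeded), 0)
            members = seeded + list(rng.choice(remainder, size=fill, replace=False))
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[term_id] = (name, frozenset(members))
    return GeneSetCollection(sets=sets, universe=frozenset(universe))
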