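"""Zero-order interactome extraction and integrated network assembly.

The zero-order subnetwork of a reference protein-protein interactome with
respect to a seed gene set is its induced subgraph on the seeds, with seed
genes that retain no interaction dropped. miRNA-target pairs are then merged
in as typed ``mirna_gene`` edges alongside the ``gene_gene`` interactions,
producing one undirected network whose nodes carry the molecule type and the
differential-expression direction. Topology is summarised with degree,
(unnormalised) shortest-path betweenness and connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exceptions import ValidationError

MIRNA_GENE = "mg"
GENE_GENE = "pp"


def zero_order_subnetwork(
    seed_genes: set[str], ppi: list[tuple[str, str]]
) -> tuple[list[tuple[str, str]], set[str]]:
    """Induced-subgraph extraction: keep edges with both endpoints in the seeds.

    Returns the kept edge list (canonical a < b ordering, sorted) and the
    retained gene set - the endpoints of kept edges, so isolated seed genes
    are dropped.
    """
    kept = sorted(
        {tuple(sorted((a, b))) for a, b in ppi if a != b and a in seed_genes and b in seed_genes}
    )
    retained = {v for e in kept for v in e}
    return kept, retained


def assemble(
    pairs: pd.DataFrame,
    ppi_sub: list[tuple[str, str]],
    mirna_direction: dict[str, str],
    gene_direction: dict[str, str],
) -> nx.Graph:
    """Merge miRNA-target pairs and gene-gene interactions into one network.

    Nodes carry ``node_type`` (``miRNA``/``gene``) and ``regulation``
    (``up``/``down``, from the DE direction maps); edges carry ``edge_type``
    (``mg``/``pp``). An id appearing as both a miRNA and a gene is rejected.
    """
    g = nx.Graph()
    mirna_ids = set(pairs["mirna_id"]) if len(pairs) else set()
    gene_ids = ({*pairs["gene_id"]} if len(pairs) else set()) | {v for e in ppi_sub for v in e}
    clash = mirna_ids & gene_ids
    if clash:
        raise ValidationError(f"ids typed both as miRNA and gene: {sorted(clash)}")

    for m in sorted(mirna_ids):
        g.add_node(m, node_type="miRNA", regulation=mirna_direction.get(m, "ns"))
    for v in sorted(gene_ids):
        g.add_node(v, node_type="gene", regulation=gene_direction.get(v, "ns"))
    if len(pairs):
        for row in pairs.itertuples(index=False):
            if row.mirna_id != row.gene_id:
                g.add_edge(row.mirna_id, row.gene_id, edge_type=MIRNA_GENE)
    for a, b in ppi_sub:
        if a != b:
            g.add_edge(a, b, edge_type=GENE_GENE)
    return g


@dataclass
class TopologyReport:
    """Degree, betweenness, component structure and typed counts of a network."""

    degree: dict[str, int]
    betweenness: dict[str, float]
    component_sizes: list[int]
    n_nodes: int
    n_edges: int
    n_mirna_nodes: int
    n_gene_nodes: int
    n_mirna_gene_edges: int
    n_gene_gene_edges: int


def topology(g: nx.Graph, normalized_betweenness: bool = False) -> TopologyReport:
    """Standard unweighted topology metrics of the integrated network."""
    bet = nx.betweenness_centrality(g, normalized=normalized_betweenness)
    comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    types = nx.get_node_attributes(g, "node_type")
    etypes = nx.get_edge_attributes(g, "edge_type")
    return TopologyReport(
        degree=dict(g.degree()),
        betweenness=bet,
        component_sizes=comps,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_mirna_nodes=sum(1 for t in types.values() if t == "miRNA"),
        n_gene_nodes=sum(1 for t in types.values() if t == "gene"),
        n_mirna_gene_edges=sum(1 for t in etypes.values() if t == MIRNA_GENE),
        n_gene_gene_edges=sum(1 for t in etypes.values() if t == GENE_GENE),
    )


def degree_filter(g: nx.Graph, min_degree: int = 1) -> list[str]:
    """Gene-type nodes with degree >= ``min_degree`` (any edge type counts)."""
    return sorted(
        v for v, d in g.degree()
        if d >= min_degree and g.nodes[v].get("node_type") == "gene"
    )


def write_network(g: nx.Graph, sif_path, node_attr_path) -> None:
    """Write the network as SIF plus a node-attribute table with topology metrics."""
    rep = topology(g)
    edges = sorted(
        (min(a, b), g.edges[a, b]["edge_type"], max(a, b)) for a, b in g.edges()
    )
    with open(sif_path, "w") as fh:
        for a, t, b in edges:
            fh.write(f"{a}\t{t}\t{b}\n")
    rows = [
        {
            "id": v,
            "type": g.nodes[v].get("node_type", "gene"),
            "regulation": g.nodes[v].get("regulation", "ns"),
            "degree": rep.degree[v],
            "betweenness": rep.betweenness[v],
        }
        for v in sorted(g.nodes())
    ]
    pd.DataFrame(rows, columns=["id", "type", "regulation", "degree", "betweenness"]).to_csv(
        node_attr_path, sep="\t", index=False, float_format="%.10g"
    )
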