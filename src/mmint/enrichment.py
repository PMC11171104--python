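"""Over-representation analysis with kappa-score term grouping.

Each gene-set term is tested for over-representation in a query gene list
with the one-sided hypergeometric test, corrected family-wise with the
Bonferroni step-down (Holm) procedure. Terms passing the selection rules
(>= 3 overlap genes, >= 4% attribution - the fraction of the term covered
by the query - and corrected p <= 0.05, all inclusive) are then grouped by
the pairwise Cohen's kappa of their gene memberships: terms whose kappa
reaches the connectivity threshold are linked, groups are the connected
components of that term graph, and each group is labelled by its most
significant ("leading") term.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .types import GeneSetCollection

ENRICH_COLUMNS = [
    "term_id", "term_name", "term_size", "overlap", "overlap_genes",
    "attribution", "pvalue", "padj", "group_id", "is_leading",
]


def hypergeom_test(query: set[str], term: set[str], universe: set[str]) -> float:
    """One-sided over-representation p value, P(X >= |query & term|).

    X is hypergeometric with population ``|universe|``, ``|term|`` successes
    and ``|query|`` draws.
    """
    if not universe:
        raise ValidationError("the gene universe is empty")
    if not term <= universe or not query <= universe:
        raise ValidationError("query and term must be subsets of the universe")
    n_pop, n_succ, n_draw = len(universe), len(term), len(query)
    k = len(query & term)
    return float(stats.hypergeom.sf(k - 1, n_pop, n_succ, n_draw))


def bonferroni_step_down(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def select_terms(
    terms: pd.DataFrame,
    min_genes: int = 3,
    min_attribution: float = 0.04,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep terms with overlap >= min_genes, attribution >= min_attribution, padj <= alpha."""
    keep = (
        (terms["overlap"] >= min_genes)
        & (terms["attribution"] >= min_attribution)
        & (terms["padj"] <= alpha)
    )
    return terms[keep].reset_index(drop=True)


def kappa_matrix(memberships: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cohen's kappa between binary gene-membership vectors.

    ``memberships`` is a terms x genes 0/1 frame; the columns are the
    reference gene set over which agreement is scored. For a term pair,
    observed agreement ``p_o`` and chance agreement ``p_e`` come from the
    2x2 contingency margins and ``kappa = (p_o - p_e) / (1 - p_e)``. When
    ``p_e = 1`` (both vectors constant and equal margins) kappa is defined
    as 1 for identical vectors and 0 otherwise. The diagonal is 1.
    """
    m = memberships.to_numpy(dtype=float)
    t, n = m.shape
    if n == 0:
        raise ValidationError("kappa needs a non-empty reference gene set")
    both = m @ m.T                      # n11
    neither = (1 - m) @ (1 - m).T      # n00
    sizes = m.sum(axis=1)
    p_o = (both + neither) / n
    p_e = (np.outer(sizes, sizes) + np.outer(n - sizes, n - sizes)) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (p_o - p_e) / (1.0 - p_e)
    deg = np.isclose(p_e, 1.0)
    identical = np.isclose(p_o, 1.0)
    kappa[deg] = np.where(identical[deg], 1.0, 0.0)
    np.fill_diagonal(kappa, 1.0)
    return pd.DataFrame(kappa, index=memberships.index, columns=memberships.index)


@dataclass(frozen=True)
class TermGroup:
    member_term_ids: tuple[str, ...]
    leading_term_id: str
    leading_pvalue: float


def group_terms(
    kappa: pd.DataFrame, pvalues: pd.Series, threshold: float = 0.04
) -> list[TermGroup]:
    """Connected components of the kappa >= threshold term graph.

    The leading term of a group has the minimum p value (ties broken by
    lexicographic term id). Groups are returned sorted by leading p then id.
    """
    g = nx.Graph()
    g.add_nodes_from(kappa.index)
    ids = list(kappa.index)
    arr = kappa.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if arr[i, j] >= threshold:
                g.add_edge(ids[i], ids[j])
    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        leading = min(members, key=lambda t: (pvalues[t], t))
        groups.append(TermGroup(members, leading, float(pvalues[leading])))
    return sorted(groups, key=lambda gr: (gr.leading_pvalue, gr.leading_term_id))


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    min_genes: int = 3,
    min_attribution: float = 0.04,
    alpha: float = 0.05,
    kappa_threshold: float = 0.04,
    kappa_reference: str = "overlap-union",
) -> pd.DataFrame:
    """Full enrichment analysis of a query gene list against a collection.

    Every term in the collection is tested and Holm-corrected; the selected
    terms are kappa-grouped. ``kappa_reference`` chooses the gene set over
    which membership agreement is scored: ``"overlap-union"`` (union of the
    selected terms' overlap genes) or ``"universe"``.

    Returns one row per selected term with its group id (``G1``, ``G2``, ...
    ordered by group leading p value) and a leading-term flag.
    """
    if universe is None:
        universe = set(collection.universe)
    query = set(query) & universe
    term_ids = sorted(collection.sets)
    if not term_ids:
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    rows = []
    for tid in term_ids:
        name, members = collection.sets[tid]
        members = set(members) & universe
        overlap = sorted(query & members)
        p = hypergeom_test(query, members, universe) if members else 1.0
        rows.append(
            {
                "term_id": tid,
                "term_name": name,
                "term_size": len(members),
                "overlap": len(overlap),
                "overlap_genes": ",".join(overlap),
                "attribution": len(overlap) / len(members) if members else 0.0,
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bonferroni_step_down(table["pvalue"].to_numpy())

    selected = select_terms(table, min_genes, min_attribution, alpha)
    if selected.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    overlap_sets = {
        row.term_id: set(row.overlap_genes.split(",")) if row.overlap_genes else set()
        for row in selected.itertuples(index=False)
    }
    if kappa_reference == "universe":
        reference = sorted(universe)
    elif kappa_reference == "overlap-union":
        reference = sorted(set().union(*overlap_sets.values()))
    else:
        raise ValidationError(f"unknown kappa reference {kappa_reference!r}")

    if len(selected) == 1:
        selected = selected.assign(group_id="G1", is_leading=True)
        return selected.loc[:, ENRICH_COLUMNS]

    memberships = pd.DataFrame(
        [[1 if g in overlap_sets[t] else 0 for g in reference] for t in selected["term_id"]],
        index=list(selected["term_id"]),
        columns=reference,
    )
    kappa = kappa_matrix(memberships)
    pv = pd.Series(selected["pvalue"].to_numpy(), index=list(selected["term_id"]))
    groups = group_terms(kappa, pv, threshold=kappa_threshold)

    group_of, leading = {}, set()
    for i, gr in enumerate(groups, start=1):
        for t in gr.member_term_ids:
            group_of[t] = f"G{i}"
        leading.add(gr.leading_term_id)
    selected = selected.assign(
        group_id=[group_of[t] for t in selected["term_id"]],
        is_leading=[t in leading for t in selected["term_id"]],
    )
    return selected.loc[:, ENRICH_COLUMNS]


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.loc[:, ENRICH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
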