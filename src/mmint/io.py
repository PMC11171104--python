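"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header row. Gene sets use the GMT
dialect (term id, term name, then one gene per column); interaction edges
are written both as a two-column TSV and as SIF (``A pp B`` / ``A mg B``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .types import CountMatrix, GeneSetCollection

PREDICTION_COLUMNS = ["source", "mirna_id", "gene_id", "score", "validated"]


# ---------------------------------------------------------------- counts

def write_counts(cm: CountMatrix, counts_path, condition_path) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(counts_path, sep="\t")
    cond = pd.DataFrame(
        {"sample_id": list(cm.counts.columns),
         "condition": [cm.condition[s] for s in cm.counts.columns]}
    )
    cond.to_csv(condition_path, sep="\t", index=False)


def read_counts(counts_path, condition_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(condition_path, sep="\t")
    if not {"sample_id", "condition"} <= set(cond.columns):
        raise ValidationError(f"{condition_path}: expected columns sample_id, condition")
    condition = dict(zip(cond["sample_id"].astype(str), cond["condition"]))
    return CountMatrix(counts=df, condition=condition)


# ----------------------------------------------------------- predictions

def write_predictions(table: pd.DataFrame, path) -> None:
    table.loc[:, PREDICTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing prediction columns {sorted(missing)}")
    df["validated"] = df["validated"].astype(bool)
    return df


# ------------------------------------------------------------------ PPI

def write_ppi(edges, tsv_path, sif_path=None) -> None:
    """Write an undirected edge list; edges are canonicalised (a < b) and sorted."""
    canon = sorted({tuple(sorted(e)) for e in edges})
    pd.DataFrame(canon, columns=["gene_a", "gene_b"]).to_csv(tsv_path, sep="\t", index=False)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for a, b in canon:
                fh.write(f"{a}\tpp\t{b}\n")


def read_ppi(path) -> list[tuple[str, str]]:
    """Read either the 2-column TSV or the SIF dialect."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        rows = [first] if first else []
        rows += [line.rstrip("\n") for line in fh if line.strip()]
    for i, line in enumerate(rows):
        parts = line.split("\t")
        if i == 0 and parts[:2] == ["gene_a", "gene_b"]:
            continue
        if len(parts) == 3:  # SIF row: node, relation, node
            if parts[1] != "pp":
                continue
            a, b = parts[0], parts[2]
        elif len(parts) == 2:
            a, b = parts[0], parts[1]
        else:
            raise ValidationError(f"{path}: unparseable edge line {line!r}")
        if a != b:
            edges.add(tuple(sorted((a, b))))
    return sorted(edges)


# ------------------------------------------------------------------ GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection.sets):
            name, members = collection.sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file; the universe defaults to the union of all members."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: GMT line needs id, name and >=1 gene")
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    if universe is None:
        universe = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


# ----------------------------------------------------------- gene lists

def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
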