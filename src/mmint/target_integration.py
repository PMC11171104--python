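"""miRNA-target consensus filtering and expression anti-correlation.

Prediction records from multiple target resources are filtered by
per-resource score thresholds, collapsed to (miRNA, gene) pairs supported by
at least two distinct resources, and finally intersected with the
differential-expression results so that only pairs whose two members changed
in opposite directions survive - the expression signature expected of a
repressive miRNA-target interaction.

Default thresholds (inclusive, as published by each resource's recommended
stringent cut-offs): TargetScan context score <= -0.15; DIANA-microT-CDS
miTG score >= 0.85; miRDB target score >= 80; miRanda miRSV score <= -1.2;
miRmap score >= 90. miRTarBase and miRecords are validated-interaction
resources: their records pass when flagged as strong-evidence validated and
their scores are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _resources

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError

PAIR_COLUMNS = [
    "mirna_id", "gene_id", "n_sources", "sources", "validated",
    "mirna_log2fc", "gene_log2fc",
]


@dataclass(frozen=True)
class SourceConfig:
    """Score rule for one target-prediction resource.

    ``direction`` is ``"le"`` (score <= threshold passes) or ``"ge"``
    (score >= threshold passes); both comparisons are inclusive. Validated
    resources carry no score rule: their records pass on the validated flag.
    """

    name: str
    kind: str  # "predicted" | "validated"
    threshold: float | None = None
    direction: str | None = None

    def __post_init__(self):
        if self.kind not in ("predicted", "validated"):
            raise ConfigurationError(f"source {self.name}: unknown kind {self.kind!r}")
        if self.kind == "predicted":
            if self.threshold is None or self.direction not in ("le", "ge"):
                raise ConfigurationError(
                    f"source {self.name}: predicted sources need a threshold and a direction"
                )

    def passes(self, score: float, validated: bool) -> bool:
        if self.kind == "validated":
            return bool(validated)
        if score is None or np.isnan(score):
            return False
        return score <= self.threshold if self.direction == "le" else score >= self.threshold


DEFAULT_SOURCES: dict[str, SourceConfig] = {
    cfg.name: cfg
    for cfg in (
        SourceConfig("TargetScan", "predicted", -0.15, "le"),
        SourceConfig("DIANA-microT-CDS", "predicted", 0.85, "ge"),
        SourceConfig("miRDB", "predicted", 80.0, "ge"),
        SourceConfig("miRanda", "predicted", -1.2, "le"),
        SourceConfig("miRmap", "predicted", 90.0, "ge"),
        SourceConfig("miRTarBase", "validated"),
        SourceConfig("miRecords", "validated"),
    )
}


def load_source_configs(path=None) -> dict[str, SourceConfig]:
    """Load a source registry from YAML; defaults to the shipped registry file."""
    if path is None:
        text = _resources.files("mmint.data").joinpath("source_thresholds.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    configs = {}
    for name, entry in raw["sources"].items():
        configs[name] = SourceConfig(
            name=name,
            kind=entry["kind"],
            threshold=entry.get("threshold"),
            direction=entry.get("direction"),
        )
    return configs


def apply_source_thresholds(
    table: pd.DataFrame, configs: dict[str, SourceConfig] | None = None
) -> pd.DataFrame:
    """Keep prediction records that pass their resource's score rule.

    Raises
    ------
    ConfigurationError
        If the table names a resource absent from the registry.
    """
    if configs is None:
        configs = DEFAULT_SOURCES
    if table.empty:
        return table.copy()
    unknown = sorted(set(table["source"]) - set(configs))
    if unknown:
        raise ConfigurationError(f"prediction sources without a configuration: {unknown}")
    mask = [
        configs[row.source].passes(row.score, row.validated)
        for row in table.itertuples(index=False)
    ]
    return table.loc[mask].reset_index(drop=True)


def consensus_pairs(records: pd.DataFrame, min_sources: int = 2) -> pd.DataFrame:
    """Collapse threshold-passing records to pairs seen in >= min_sources resources.

    Duplicate records from one resource count once; a pair is flagged
    validated when any supporting record is validated.
    """
    cols = ["mirna_id", "gene_id", "n_sources", "sources", "validated"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    grouped = (
        records.groupby(["mirna_id", "gene_id"], sort=True)
        .agg(
            n_sources=("source", "nunique"),
            sources=("source", lambda s: ",".join(sorted(set(s)))),
            validated=("validated", "any"),
        )
        .reset_index()
    )
    kept = grouped[grouped["n_sources"] >= min_sources].reset_index(drop=True)
    return kept.loc[:, cols]


def anticorrelation_filter(
    pairs: pd.DataFrame,
    de_mirna_up: pd.DataFrame,
    de_mirna_down: pd.DataFrame,
    de_gene_up: pd.DataFrame,
    de_gene_down: pd.DataFrame,
) -> pd.DataFrame:
    """Keep pairs whose members are differentially expressed in opposite directions.

    The four arguments are the up/down record tables produced by
    :func:`mmint.diffexpr.filter_de` for each molecule class (indexed or
    keyed by ``feature_id`` with a ``log2fc`` column). Pairs whose miRNA or
    gene is not differentially expressed are dropped; survivors carry both
    log2 fold changes.
    """
    def _lfc_map(df: pd.DataFrame) -> dict[str, float]:
        if df.empty:
            return {}
        return dict(zip(df["feature_id"], df["log2fc"]))

    up_m, down_m = _lfc_map(de_mirna_up), _lfc_map(de_mirna_down)
    up_g, down_g = _lfc_map(de_gene_up), _lfc_map(de_gene_down)
    if set(up_m) & set(down_m) or set(up_g) & set(down_g):
        raise ValidationError("up and down DE lists overlap")

    rows = []
    for row in pairs.itertuples(index=False):
        m, g = row.mirna_id, row.gene_id
        if m in up_m and g in down_g:
            m_lfc, g_lfc = up_m[m], down_g[g]
        elif m in down_m and g in up_g:
            m_lfc, g_lfc = down_m[m], up_g[g]
        else:
            continue
        rows.append(
            (m, g, row.n_sources, row.sources, bool(row.validated), m_lfc, g_lfc)
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def refine_pairs(
    pairs: pd.DataFrame,
    mirna_rpm_kept: set[str],
    role_table: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the stringent pair refinement: abundance floor plus cancer-role orientation.

    Pairs whose miRNA failed the reads-per-million floor (computed upstream
    with ``rpm_filter`` at threshold 12) are dropped. When a ``role_table``
    mapping feature ids to ``"oncogene"`` / ``"tumour_suppressor"`` /
    ``"unknown"`` is supplied, a pair is retained only when a downregulated
    miRNA annotated as an oncogenic miRNA targets an upregulated tumour-
    suppressor gene, or, symmetrically, an upregulated tumour-suppressive
    miRNA targets a downregulated oncogene. Without a role table the role
    filter is skipped.
    """
    kept = pairs[pairs["mirna_id"].isin(mirna_rpm_kept)].reset_index(drop=True)
    if role_table is None:
        return kept

    def _role_ok(row) -> bool:
        m_role = role_table.get(row.mirna_id, "unknown")
        g_role = role_table.get(row.gene_id, "unknown")
        if row.mirna_log2fc < 0:  # miRNA down, gene up
            return m_role == "oncogene" and g_role == "tumour_suppressor"
        return m_role == "tumour_suppressor" and g_role == "oncogene"

    mask = [_role_ok(row) for row in kept.itertuples(index=False)]
    return kept.loc[mask].reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.loc[:, PAIR_COLUMNS].sort_values(["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing pair columns {sorted(missing)}")
    df["validated"] = df["validated"].astype(bool)
    return df
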