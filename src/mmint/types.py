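"""Core data containers for the miRNA-mRNA integration pipeline.

Count data are held as a :class:`pandas.DataFrame` (features x samples)
wrapped in :class:`CountMatrix` together with the condition labels, so every
statistical stage receives the counts and the design in one object.
:class:`GroundTruth` carries the planted regulatory structure used by the
synthetic-data generators and by recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CONTROL = "control"
TREATED = "treated"


@dataclass(frozen=True)
class GroundTruth:
    """Planted regulatory structure behind a simulated experiment.

    Attributes
    ----------
    regulated_pairs : frozenset of (str, str)
        Planted miRNA -> target-gene repressions.
    mirna_lfc, gene_lfc : dict
        Planted log2 fold change (treated vs control) per feature; zero for
        features outside any regulated pair.
    base_mean : dict
        Expected control-condition count per feature (both molecule classes).
    dispersion : dict
        Negative-binomial dispersion alpha per feature (Var = mu + alpha*mu^2).
    seed : int
        Seed the truth was generated with.
    """

    regulated_pairs: frozenset[tuple[str, str]]
    mirna_lfc: dict[str, float]
    gene_lfc: dict[str, float]
    base_mean: dict[str, float]
    dispersion: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for m, g in self.regulated_pairs:
            if m not in self.base_mean or g not in self.base_mean:
                raise ValidationError(f"regulated pair ({m}, {g}) has a member without a base mean")
            if not (self.mirna_lfc[m] * self.gene_lfc[g] < 0):
                raise ValidationError(
                    f"pair ({m}, {g}) is not anti-correlated: "
                    f"lfc {self.mirna_lfc[m]} vs {self.gene_lfc[g]}"
                )
        if any(a <= 0 for a in self.dispersion.values()):
            raise ValidationError("dispersions must be positive")

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.mirna_lfc)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_lfc)


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with condition labels.

    ``counts`` is indexed by feature id with one column per sample id;
    ``condition`` maps each sample to ``"control"`` or ``"treated"``;
    ``library_size`` records the simulation scaling factor per sample when
    the matrix was simulated (1.0 for real data).
    """

    counts: pd.DataFrame
    condition: dict[str, str]
    library_size: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.library_size:
            self.library_size = {s: 1.0 for s in self.counts.columns}
        self.validate()

    def validate(self) -> None:
        cols = list(self.counts.columns)
        if set(cols) != set(self.condition):
            raise ValidationError("condition map does not cover exactly the sample columns")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        labels = set(self.condition.values())
        if not labels <= {CONTROL, TREATED}:
            raise ValidationError(f"unknown condition labels: {labels - {CONTROL, TREATED}}")
        for lab in (CONTROL, TREATED):
            if sum(1 for v in self.condition.values() if v == lab) < 2:
                raise ValidationError(f"condition '{lab}' needs at least 2 samples")
        if any(v <= 0 for v in self.library_size.values()):
            raise ValidationError("library sizes must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == label]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) over a declared gene universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"term {term_id} is empty")
            if not members <= self.universe:
                raise ValidationError(f"term {term_id} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)


def geometric_mean(values) -> float:
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("geometric mean requires positive values")
    return float(math.exp(np.mean(np.log(arr))))
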