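"""Shared data containers for the DRESS diagnostic pipeline.

Tabular data (counts, designs, qPCR cards, DE results) travel as pandas
DataFrames with documented schemas; small structured objects (panels,
scores, confusion tables) are dataclasses.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

CONDITIONS = ("drug", "media")
GROUPS = ("allergic", "tolerant")


@dataclass
class PairedCountMatrix:
    """Integer gene counts for paired drug/media samples.

    counts : DataFrame, genes (index ``gene_id``) x samples.
    design : DataFrame indexed by sample id with columns
        ``subject``, ``condition`` (drug|media), ``group`` (allergic|tolerant).
    Every subject contributes exactly one drug and one media sample.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("empty count matrix")
        if not self.counts.index.is_unique:
            raise ValueError("gene_ids must be unique")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.counts.columns) != set(self.design.index):
            raise ValueError("count columns and design rows must match")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {bad}")
        per_subject = self.design.groupby("subject")["condition"].apply(
            lambda s: sorted(s) == sorted(CONDITIONS)
        )
        if not per_subject.all():
            missing = per_subject.index[~per_subject].tolist()
            raise ValueError(f"subjects without a full drug/media pair: {missing}")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.design["subject"].unique())

    def sample_for(self, subject: str, condition: str) -> str:
        sel = self.design[
            (self.design["subject"] == subject) & (self.design["condition"] == condition)
        ]
        return sel.index[0]


@dataclass
class NormalizedExpression:
    """TMM-normalized counts-per-million with per-sample scaling factors."""

    cpm: pd.DataFrame
    tmm_factors: pd.Series
    kept_gene_mask: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.tmm_factors))))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")
        if (np.asarray(self.cpm) < 0).any():
            raise ValueError("cpm must be non-negative")


@dataclass(frozen=True)
class SignatureGene:
    """One biomarker with its expected direction of drug-induced change."""

    gene_id: str
    direction: int  # +1 up-, -1 downregulated on drug exposure
    discovery_logfc: float | None = None
    importance: float | None = None
    source: str = "de_selected"  # de_selected | curated_immune
    direction_source: str = "stated"  # stated | unspecified

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if (
            self.source == "de_selected"
            and self.discovery_logfc is not None
            and np.sign(self.discovery_logfc) != self.direction
        ):
            raise ValueError("direction must match sign of discovery logFC")


@dataclass
class SignaturePanel:
    """Ordered biomarker genes plus the housekeeping reference."""

    genes: list[SignatureGene]
    housekeeping_gene_id: str = "YWHAZ"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must be non-empty")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("panel gene_ids must be unique")
        if self.housekeeping_gene_id in ids:
            raise ValueError("housekeeping gene cannot be a panel gene")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def directions(self) -> dict[str, int]:
        return {g.gene_id: g.direction for g in self.genes}

    def to_dict(self) -> dict:
        return {
            "housekeeping": self.housekeeping_gene_id,
            "genes": [
                {
                    "id": g.gene_id,
                    "direction": g.direction,
                    "discovery_logfc": g.discovery_logfc,
                    "importance": g.importance,
                    "source": g.source,
                    "direction_source": g.direction_source,
                }
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignaturePanel":
        genes = [
            SignatureGene(
                gene_id=g["id"],
                direction=int(g["direction"]),
                discovery_logfc=g.get("discovery_logfc"),
                importance=g.get("importance"),
                source=g.get("source", "de_selected"),
                direction_source=g.get("direction_source", "stated"),
            )
            for g in d["genes"]
        ]
        return cls(genes=genes, housekeeping_gene_id=d["housekeeping"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignaturePanel":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SubjectScore:
    """Integer concordance score for one subject."""

    subject_id: str
    score: int
    n_scored: int  # panel genes contributing a non-zero point
    call: str | None = None  # positive | negative | None (unclassified)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table; rows = allergic/tolerant, cols = positive/negative call."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> Fraction:
        """tp / (tp + fn), kept as an exact rational."""
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        """tn / (tn + fp), kept as an exact rational."""
        return Fraction(self.tn, self.tn + self.fp)


@dataclass(frozen=True)
class ComboResult:
    """One marker subset evaluated by combinatorial ROC."""

    genes: tuple[str, ...]
    auc: float
    sensitivity: float
    specificity: float
    cutoffs: dict[str, float] = field(hash=False, default_factory=dict)
    count_threshold: float = 0.0
    passes: bool = False
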