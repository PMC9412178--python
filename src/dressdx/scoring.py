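"""Directional concordance scoring — the diagnostic core.

Each subject's panel-gene log2 RQ values are compared against the
signature's expected directions of drug-induced change: a gene whose value
clears the dead zone contributes +1 when its sign matches the expected
direction and -1 when it opposes it; values inside the dead zone (|v| <=
0.25 by default, boundary inclusive) contribute nothing. The summed integer
score is thresholded into a positive/negative drug-hypersensitivity call.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ConfusionTable, SignaturePanel, SubjectScore
from .stats import fisher_exact_two_sided, mann_whitney_exact_two_sided

__all__ = [
    "signature_directions",
    "score_subject",
    "score_cohort",
    "classify",
    "evaluate_cohort",
]

DEAD_ZONE_DEFAULT = 0.25


def signature_directions(
    mean_log2rq: Mapping[str, float], discovery_logfc: Mapping[str, float]
) -> pd.DataFrame:
    """Expected direction per panel gene, with discordance QC flags.

    Direction is the sign of the discovery logFC; a gene whose cohort-mean
    qPCR change disagrees in sign is retained but flagged discordant.
    Zero logFC has no direction and is an error.
    """
    genes = sorted(discovery_logfc)
    missing = [g for g in genes if g not in mean_log2rq]
    if missing:
        raise ValueError(f"mean log2 RQ missing for panel genes: {missing}")
    rows = []
    for g in genes:
        lfc = discovery_logfc[g]
        if lfc == 0:
            raise ValueError(f"gene {g!r} has zero discovery logFC: direction undefined")
        direction = 1 if lfc > 0 else -1
        concordant = np.sign(mean_log2rq[g]) == direction
        rows.append((g, direction, float(lfc), float(mean_log2rq[g]), bool(concordant)))
    return pd.DataFrame(
        rows, columns=["gene", "direction", "discovery_logfc", "mean_log2rq", "concordant"]
    ).set_index("gene")


def score_subject(
    log2rq: Mapping[str, float],
    panel: SignaturePanel,
    dead_zone: float = DEAD_ZONE_DEFAULT,
    subject_id: str = "",
) -> SubjectScore:
    """Concordance score of one subject against the panel.

    Missing or undetermined panel genes contribute 0 (and do not count
    toward ``n_scored``); the score is bounded by the panel size.
    """
    score = 0
    n_scored = 0
    for gene in panel.genes:
        v = log2rq.get(gene.gene_id)
        if v is None or not np.isfinite(v):
            continue
        if abs(v) <= dead_zone:
            continue
        point = 1 if (v > 0) == (gene.direction > 0) else -1
        score += point
        n_scored += 1
    return SubjectScore(subject_id=subject_id, score=score, n_scored=n_scored)


def score_cohort(
    rq_by_subject: pd.DataFrame,
    panel: SignaturePanel,
    dead_zone: float = DEAD_ZONE_DEFAULT,
) -> list[SubjectScore]:
    """Score every row of a subjects x genes log2 RQ matrix."""
    return [
        score_subject(row.dropna().to_dict(), panel, dead_zone, subject_id=str(subj))
        for subj, row in rq_by_subject.iterrows()
    ]


def classify(score: int, threshold: int, inclusive: bool = True) -> str:
    """Positive/negative call; ``inclusive`` decides the boundary case
    (positive iff score >= threshold, else strictly >)."""
    positive = score >= threshold if inclusive else score > threshold
    return "positive" if positive else "negative"


def evaluate_cohort(
    allergic_scores: list[SubjectScore] | list[int],
    tolerant_scores: list[SubjectScore] | list[int],
    threshold: int,
    inclusive: bool = True,
) -> dict:
    """Diagnostic evaluation of scored allergic vs tolerant cohorts.

    Returns the confusion table, sensitivity/specificity, the two-sided
    Fisher exact p on the 2x2 call table, and the exact Mann-Whitney p
    comparing the raw scores between groups.
    """
    a = [s.score if isinstance(s, SubjectScore) else int(s) for s in allergic_scores]
    t = [s.score if isinstance(s, SubjectScore) else int(s) for s in tolerant_scores]
    if not a or not t:
        raise ValueError("both groups must be non-empty")
    a_pos = sum(classify(s, threshold, inclusive) == "positive" for s in a)
    t_pos = sum(classify(s, threshold, inclusive) == "positive" for s in t)
    table = ConfusionTable(tp=a_pos, fn=len(a) - a_pos, fp=t_pos, tn=len(t) - t_pos)
    mwu = mann_whitney_exact_two_sided(a, t)
    return {
        "confusion": table,
        "sensitivity": table.sensitivity,
        "specificity": table.specificity,
        "fisher_p": fisher_exact_two_sided((table.tp, table.fn, table.fp, table.tn)),
        "mwu_p": mwu.p,
        "threshold": threshold,
        "threshold_inclusive": inclusive,
    }
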