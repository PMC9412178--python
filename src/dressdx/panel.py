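"""Biomarker panel selection: filter cascade, random-forest importance
ranking, and combinatorial ROC evaluation of marker subsets.

The cascade keeps significant genes (q <= 0.05) with |logFC| >= 1.5 whose
expression clears abundance floors (per-gene minimum cpm >= 4 and maximum
cpm >= 100 across all samples); survivors are ranked by impurity-based
random-forest importance, and up to ten genes with |logFC| >= 2 and
importance >= 0.05 join a curated immune-gene list to form the panel.

Marker combinations are evaluated by dichotomizing each marker at its
Youden-optimal cutoff (on direction-adjusted values), counting positive
markers per subject, and sweeping that count as the ROC threshold; a
combination passes when sensitivity > 0.85, specificity > 0.85 and
AUC >= 0.8.
"""
from __future__ import annotations

import warnings
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .containers import ComboResult, SignatureGene, SignaturePanel

__all__ = [
    "candidate_filter",
    "rf_importance",
    "assemble_panel",
    "roc_auc",
    "youden_cutoff",
    "combi_roc",
    "default_panel",
]

MAX_COMBO_SIZE = 10
PASS_SENS = 0.85
PASS_SPEC = 0.85
PASS_AUC = 0.8


def candidate_filter(
    de: pd.DataFrame,
    fdr_cut: float = 0.05,
    logfc_cut: float = 1.5,
    min_cpm: float = 4.0,
    max_cpm: float = 100.0,
) -> list[str]:
    """Candidate biomarkers passing significance, effect-size, and abundance cuts."""
    if de.empty:
        return []
    keep = (
        (de["q"] <= fdr_cut)
        & (de["logfc"].abs() >= logfc_cut)
        & (de["min_cpm"] >= min_cpm)
        & (de["max_cpm"] >= max_cpm)
    )
    return list(de.index[keep])


def rf_importance(
    expr: pd.DataFrame, labels, n_trees: int = 500, seed: int | None = 0
) -> pd.Series:
    """Impurity-based random-forest importance per gene, normalized to sum 1.

    ``expr`` is genes x samples; ``labels`` is the per-sample class (e.g.
    drug/media). Deterministic given the seed. With no usable split signal
    (all-constant features) a uniform, warning-flagged vector is returned.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need two classes for importance ranking")
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    x = np.asarray(expr, dtype=float).T  # samples x genes
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(x, labels)
    imp = rf.feature_importances_
    total = imp.sum()
    if total <= 0:
        warnings.warn("no impurity signal: importances degenerate, returning uniform")
        imp = np.full(len(imp), 1.0 / len(imp))
    else:
        imp = imp / total
    return pd.Series(imp, index=expr.index, name="importance")


def assemble_panel(
    de: pd.DataFrame,
    importance: pd.Series,
    curated: list[str] | None = None,
    fc_cut: float = 2.0,
    imp_cut: float = 0.05,
    max_selected: int = 10,
    housekeeping: str = "YWHAZ",
) -> SignaturePanel:
    """Combine top DE-selected genes with the curated immune-gene list.

    DE-selected genes must reach |logFC| >= fc_cut and importance >= imp_cut;
    they are ranked by importance, ties broken by |logFC| then gene_id, and
    capped at ``max_selected``. Directions come from the discovery logFC sign
    (curated genes default to +1, marked unspecified, until measured).
    """
    curated = list(curated or [])
    cand = de.loc[de.index.intersection(importance.index)].copy()
    cand["importance"] = importance.reindex(cand.index)
    passing = cand[(cand["logfc"].abs() >= fc_cut) & (cand["importance"] >= imp_cut)].copy()
    passing["_abs_lfc"] = passing["logfc"].abs()
    passing["_gid"] = passing.index.astype(str)
    ranked = passing.sort_values(
        by=["importance", "_abs_lfc", "_gid"],
        ascending=[False, False, True],
        kind="stable",
    ).head(max_selected)
    if ranked.empty:
        warnings.warn("no genes pass the FC/importance cuts: curated-only panel")
    genes: list[SignatureGene] = []
    for gid, row in ranked.iterrows():
        genes.append(
            SignatureGene(
                gene_id=str(gid),
                direction=1 if row["logfc"] > 0 else -1,
                discovery_logfc=float(row["logfc"]),
                importance=float(row["importance"]),
                source="de_selected",
            )
        )
    selected_ids = {g.gene_id for g in genes}
    for gid in curated:
        if gid in selected_ids or gid == housekeeping:
            continue
        lfc = float(de.loc[gid, "logfc"]) if gid in de.index else None
        direction = 1 if lfc is None or lfc >= 0 else -1
        genes.append(
            SignatureGene(
                gene_id=gid,
                direction=direction,
                discovery_logfc=lfc,
                importance=float(importance.get(gid, np.nan))
                if gid in importance.index
                else None,
                source="curated_immune",
                direction_source="stated" if lfc is not None else "unspecified",
            )
        )
    if not genes:
        raise ValueError("empty panel: no selected and no curated genes")
    return SignaturePanel(genes=genes, housekeeping_gene_id=housekeeping)


def roc_auc(values, labels, direction: int = 1) -> float:
    """Rank-based AUC, P(value_pos > value_neg) with half-credit for ties.

    ``labels`` is boolean (True = positive class); ``direction=-1`` scores
    low values as positive.
    """
    values = np.asarray(values, dtype=float) * direction
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def youden_cutoff(values, labels) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity - 1 (positive iff >= cutoff).

    Ties in the Youden index are broken toward the lower (more sensitive)
    cutoff. Returns (cutoff, sensitivity, specificity).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = None
    for thr in np.sort(np.unique(values)):
        calls = values >= thr
        sens = (calls & labels).sum() / labels.sum()
        spec = (~calls & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), float(sens), float(spec))
    return best[1], best[2], best[3]


def combi_roc(
    panel_values: pd.DataFrame,
    labels,
    directions: dict[str, int] | None = None,
    max_size: int = MAX_COMBO_SIZE,
) -> list[ComboResult]:
    """Combinatorial ROC over every non-empty marker subset.

    ``panel_values`` is subjects x genes; ``labels`` boolean per subject
    (True = allergic). Each marker is direction-adjusted and dichotomized at
    its Youden cutoff; a subset's subject score is its positive-marker count,
    swept as the ROC threshold. Results are sorted by AUC (desc), then subset
    size, then name; ``passes`` flags sens > 0.85 & spec > 0.85 & AUC >= 0.8.
    """
    genes = list(panel_values.columns)
    if len(genes) > max_size:
        raise ValueError(
            f"{len(genes)} markers would enumerate 2^{len(genes)}-1 subsets; "
            f"limit is {max_size}"
        )
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("both classes must be present")
    directions = directions or {}
    adjusted = {}
    cutoffs = {}
    for g in genes:
        v = panel_values[g].to_numpy(dtype=float) * directions.get(g, 1)
        adjusted[g] = v
        cutoffs[g], _, _ = youden_cutoff(v, labels)
    marker_pos = {g: (adjusted[g] >= cutoffs[g]).astype(int) for g in genes}

    results = []
    for size in range(1, len(genes) + 1):
        for subset in combinations(genes, size):
            score = np.sum([marker_pos[g] for g in subset], axis=0)
            auc = roc_auc(score, labels)
            thr, sens, spec = youden_cutoff(score, labels)
            results.append(
                ComboResult(
                    genes=subset,
                    auc=auc,
                    sensitivity=sens,
                    specificity=spec,
                    cutoffs={g: cutoffs[g] for g in subset},
                    count_threshold=thr,
                    passes=(sens > PASS_SENS and spec > PASS_SPEC and auc >= PASS_AUC),
                )
            )
    results.sort(key=lambda r: (-r.auc, len(r.genes), r.genes))
    return results


def default_panel() -> SignaturePanel:
    """The shipped six-gene reduced panel (STAC, GPR183, CD40, CISH, CD4,
    CCL8 against YWHAZ)."""
    text = resources.files("dressdx.data").joinpath("default_panel.json").read_text()
    return SignaturePanel.from_json(text)
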