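"""Orchestration of the two diagnostic workflows.

``run_discovery`` turns a paired discovery count matrix into a biomarker
panel (filter -> normalize -> paired DE -> candidate cascade -> random-forest
ranking -> panel assembly -> combinatorial ROC); ``run_validation`` turns an
array card plus a panel into per-subject scores and a diagnostic evaluation.
The panel JSON is the only artifact crossing the discovery/validation
boundary, so marker selection never sees validation subjects.

``reproduce_reported`` recomputes the exact-test results that the study's
printed tables determine completely (comparative T-cell assay p-values and
the two confusion-table Fisher tests) and checks them at two significant
figures.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import de as de_mod
from . import expression, panel as panel_mod, qpcr, scoring
from .containers import PairedCountMatrix, SignaturePanel
from .stats import fisher_exact_two_sided, mann_whitney_exact_two_sided
from .synthetic import ifn_rank_values, table1_fixture

__all__ = ["RunConfig", "run_discovery", "run_validation", "reproduce_reported"]


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters; defaults are the study's working values."""

    min_count: int = 2  # low-expression filter floor
    fdr_cut: float = 0.05
    candidate_logfc_cut: float = 1.5
    candidate_min_cpm: float = 4.0
    candidate_max_cpm: float = 100.0
    panel_fc_cut: float = 2.0
    panel_imp_cut: float = 0.05
    rf_trees: int = 500
    max_combo_size: int = 10
    dead_zone: float = 0.25
    threshold: int = 6  # 22-gene concordance threshold; the 6-gene panel uses 0
    threshold_inclusive: bool = True
    housekeeping: str = "YWHAZ"
    de_mode: str = "auto"
    n_perm: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def run_discovery(
    pcm: PairedCountMatrix,
    config: RunConfig = RunConfig(),
    curated: list[str] | None = None,
) -> dict:
    """Discovery workflow: DE screen, candidate cascade, panel assembly,
    and drug-vs-media combinatorial ROC of the selected markers.

    Returns a dict with ``de`` (DataFrame), ``panel`` (SignaturePanel or
    None when nothing and no curated gene survives), ``combos`` (ComboResult
    list) and ``report`` (per-stage counts and parameters).
    """
    report: dict = {"stages": [], "config": config.to_dict()}

    expr = expression.normalize(pcm, min_count=config.min_count)
    report["stages"].append(
        {
            "stage": "normalize",
            "n_genes_in": int(pcm.counts.shape[0]),
            "n_genes_kept": int(expr.kept_gene_mask.sum()),
            "tmm_factors": {k: float(v) for k, v in expr.tmm_factors.items()},
        }
    )

    de = de_mod.de_table(
        pcm, expr, mode=config.de_mode, n_perm=config.n_perm, seed=config.seed
    )
    up, down = de_mod.deg_call(de, fdr_cut=config.fdr_cut)
    report["stages"].append(
        {"stage": "paired_de", "n_genes": len(de), "n_up": len(up), "n_down": len(down)}
    )

    candidates = panel_mod.candidate_filter(
        de,
        fdr_cut=config.fdr_cut,
        logfc_cut=config.candidate_logfc_cut,
        min_cpm=config.candidate_min_cpm,
        max_cpm=config.candidate_max_cpm,
    )
    report["stages"].append({"stage": "candidate_filter", "n_candidates": len(candidates)})

    sig_panel = None
    combos: list = []
    if candidates:
        cand_expr = np.log2(expr.cpm.loc[candidates] + 0.5)
        labels = pcm.design.loc[cand_expr.columns, "condition"].to_numpy()
        importance = panel_mod.rf_importance(
            cand_expr, labels, n_trees=config.rf_trees, seed=config.seed
        )
    else:
        importance = pd.Series(dtype=float)
    try:
        sig_panel = panel_mod.assemble_panel(
            de.loc[candidates],
            importance,
            curated=curated,
            fc_cut=config.panel_fc_cut,
            imp_cut=config.panel_imp_cut,
            housekeeping=config.housekeeping,
        )
    except ValueError:
        sig_panel = None  # nothing selected and no curated genes: no panel
    n_selected = (
        0 if sig_panel is None else sum(g.source == "de_selected" for g in sig_panel.genes)
    )
    report["stages"].append(
        {
            "stage": "assemble_panel",
            "n_de_selected": n_selected,
            "panel_size": 0 if sig_panel is None else len(sig_panel.genes),
        }
    )

    if sig_panel is not None and n_selected > 0:
        top = [g.gene_id for g in sig_panel.genes if g.source == "de_selected"]
        top = top[: config.max_combo_size]
        values = np.log2(expr.cpm.loc[top] + 0.5).T  # samples x genes
        is_drug = (pcm.design.loc[values.index, "condition"] == "drug").to_numpy()
        combos = panel_mod.combi_roc(values, is_drug, max_size=config.max_combo_size)
        report["stages"].append(
            {
                "stage": "combi_roc",
                "n_combos": len(combos),
                "n_passing": sum(c.passes for c in combos),
                "best_auc": combos[0].auc if combos else None,
            }
        )

    return {"de": de, "panel": sig_panel, "combos": combos, "report": report}


def run_validation(
    card: pd.DataFrame,
    sig_panel: SignaturePanel,
    threshold: int | None = None,
    config: RunConfig = RunConfig(),
    inclusive: bool | None = None,
) -> dict:
    """Validation workflow: ddCt quantification, concordance scoring, and
    exact-test evaluation of allergic vs tolerant calls.

    Subject group membership is taken from the subject id prefix written by
    the generator ('A' = allergic, 'T' = tolerant) unless the card carries a
    ``group`` column.
    """
    threshold = config.threshold if threshold is None else threshold
    inclusive = config.threshold_inclusive if inclusive is None else inclusive
    rq = qpcr.ddct_log2rq(card, housekeeping=sig_panel.housekeeping_gene_id)
    mat = qpcr.rq_matrix(rq)
    scores = scoring.score_cohort(mat, sig_panel, dead_zone=config.dead_zone)

    if "group" in card.columns:
        group_of = card.drop_duplicates("subject").set_index("subject")["group"].to_dict()
    else:
        group_of = {s.subject_id: ("allergic" if s.subject_id.startswith("A") else "tolerant")
                    for s in scores}
    allergic = [s for s in scores if group_of.get(s.subject_id) == "allergic"]
    tolerant = [s for s in scores if group_of.get(s.subject_id) == "tolerant"]
    evaluation = scoring.evaluate_cohort(allergic, tolerant, threshold, inclusive=inclusive)

    score_table = pd.DataFrame(
        {
            "subject": [s.subject_id for s in scores],
            "group": [group_of.get(s.subject_id, "unknown") for s in scores],
            "score": [s.score for s in scores],
            "n_scored": [s.n_scored for s in scores],
            "call": [scoring.classify(s.score, threshold, inclusive) for s in scores],
        }
    )
    report = {
        "stages": [
            {"stage": "qpcr_quant", "n_rq": int(len(rq)), "n_flagged": int((rq["flag"] != "").sum())},
            {
                "stage": "score",
                "threshold": threshold,
                "threshold_inclusive": inclusive,
                "n_allergic": len(allergic),
                "n_tolerant": len(tolerant),
            },
        ],
        "config": config.to_dict(),
    }
    return {"rq": rq, "scores": score_table, "evaluation": evaluation, "report": report}


# Reported values fully determined by in-study tabular inputs:
# (name, computation, printed value)
def reproduce_reported() -> dict:
    """Recompute the six exact-test p-values the printed tables determine.

    Uses only packaged fixtures (no files, no network): the comparative
    T-cell assay table for the four Mann-Whitney tests and the two reported
    confusion tables for the Fisher tests. Each value is compared with the
    printed one at two significant figures.
    """
    fx = table1_fixture()
    tol_lpa = list(fx["tolerant"].lpa_si)
    tol_ifn = ifn_rank_values(fx["tolerant"])

    computed = {
        "mwu_discovery_lpa": mann_whitney_exact_two_sided(fx["discovery"].lpa_si, tol_lpa).p,
        "mwu_discovery_ifng": mann_whitney_exact_two_sided(
            ifn_rank_values(fx["discovery"]), tol_ifn
        ).p,
        "mwu_validation_lpa": mann_whitney_exact_two_sided(fx["validation"].lpa_si, tol_lpa).p,
        "mwu_validation_ifng": mann_whitney_exact_two_sided(
            ifn_rank_values(fx["validation"]), tol_ifn
        ).p,
        "fisher_22gene": fisher_exact_two_sided((5, 1, 1, 6)),
        "fisher_6gene": fisher_exact_two_sided((6, 0, 1, 6)),
    }
    printed = {
        "mwu_discovery_lpa": 0.0025,
        "mwu_discovery_ifng": 0.0025,
        "mwu_validation_lpa": 0.0082,
        "mwu_validation_ifng": 0.0012,
        "fisher_22gene": 0.029,
        "fisher_6gene": 0.0047,
    }
    report = {}
    for name, value in computed.items():
        match = _round2sig(value) == _round2sig(printed[name])
        report[name] = {"computed": value, "printed": printed[name], "match": bool(match)}
    report["n_matching"] = sum(r["match"] for r in report.values() if isinstance(r, dict))
    report["n_total"] = len(computed)
    return report


def _round2sig(x: float) -> float:
    return float(f"{x:.2g}")
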