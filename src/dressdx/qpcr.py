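"""Relative quantification of array-card Ct measurements.

Technical replicates are collapsed by arithmetic mean (undetermined wells,
stored as NaN, are dropped; an all-undetermined well set is flagged
missing). Expression is quantified against the housekeeping gene with the
double-delta-Ct rule:

    dCt_cond  = Ct_target,cond - Ct_housekeeping,cond
    ddCt      = dCt_drug - dCt_media
    log2 RQ   = -ddCt          (RQ = 2 ** -ddCt)
"""
from __future__ import annotations

import pandas as pd

__all__ = ["collapse_replicates", "ddct_log2rq", "rq_matrix"]

HOUSEKEEPING_DEFAULT = "YWHAZ"
REPLICATE_SPREAD_QC = 1.0  # cycles; wider duplicate spread is flagged


def _validate_card(card: pd.DataFrame) -> None:
    required = {"subject", "gene", "condition", "replicate", "ct"}
    missing = required - set(card.columns)
    if missing:
        raise ValueError(f"qPCR card missing columns: {sorted(missing)}")
    bad = set(card["condition"]) - {"drug", "media"}
    if bad:
        raise ValueError(f"unknown conditions in card: {bad}")


def collapse_replicates(card: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (subject, gene, condition) with QC flags.

    Returns a DataFrame with columns ``subject, gene, condition, ct, flag``;
    flag is '' | 'replicate_dropped' | 'high_spread' | 'missing'.
    Undetermined replicates (NaN Ct) are dropped before averaging.
    """
    _validate_card(card)

    def agg(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        if len(vals) == 0:
            return pd.Series({"ct": float("nan"), "flag": "missing"})
        flag = ""
        if len(vals) < len(g):
            flag = "replicate_dropped"
        elif len(vals) > 1 and (vals.max() - vals.min()) > REPLICATE_SPREAD_QC:
            flag = "high_spread"
        return pd.Series({"ct": vals.mean(), "flag": flag})

    out = (
        card.groupby(["subject", "gene", "condition"], sort=True)["ct"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    out["ct"] = out["ct"].astype(float)
    return out


def ddct_log2rq(card: pd.DataFrame, housekeeping: str = HOUSEKEEPING_DEFAULT) -> pd.DataFrame:
    """Per-subject, per-gene log2 relative quantities against housekeeping.

    Returns a DataFrame ``subject, gene, log2_rq, flag``. A subject missing
    the housekeeping gene in either condition is an error (it anchors every
    other gene); a missing target well yields a flagged NaN row instead.
    """
    collapsed = collapse_replicates(card)
    wide = collapsed.pivot_table(
        index=["subject", "gene"], columns="condition", values="ct", aggfunc="first"
    )
    flags = (
        collapsed.groupby(["subject", "gene"])["flag"]
        .apply(lambda f: ";".join(sorted(set(x for x in f if x))))
        .rename("flag")
    )

    rows = []
    for subject, sub in wide.groupby(level="subject"):
        genes = sub.index.get_level_values("gene")
        if housekeeping not in genes:
            raise ValueError(f"housekeeping gene {housekeeping!r} absent for subject {subject!r}")
        hk = sub.xs(housekeeping, level="gene").iloc[0]
        for cond in ("drug", "media"):
            if cond not in hk.index or pd.isna(hk[cond]):
                raise ValueError(
                    f"housekeeping gene {housekeeping!r} missing for "
                    f"subject {subject!r}, condition {cond!r}"
                )
        for (subj, gene), ct in sub.iterrows():
            if gene == housekeeping:
                continue
            flag = flags.get((subj, gene), "")
            drug_ct = ct.get("drug")
            media_ct = ct.get("media")
            if pd.isna(drug_ct) or pd.isna(media_ct):
                rows.append((subj, gene, float("nan"), _add_flag(flag, "missing")))
                continue
            ddct = (drug_ct - hk["drug"]) - (media_ct - hk["media"])
            rows.append((subj, gene, -float(ddct), flag))
    return pd.DataFrame(rows, columns=["subject", "gene", "log2_rq", "flag"])


def _add_flag(flag: str, extra: str) -> str:
    parts = [x for x in flag.split(";") if x] + [extra]
    return ";".join(sorted(set(parts)))


def rq_matrix(rq: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long RQ table to subjects x genes (NaN where missing)."""
    return rq.pivot(index="subject", columns="gene", values="log2_rq")
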