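"""Paired drug-vs-media differential expression.

Each gene is summarized by its paired log2 ratio per subject,

    d_i = log2((cpm_drug,i + c) / (cpm_media,i + c)),   c = 0.5,

and tested with a sign-flip permutation of the paired t statistic
t = mean(d) / SE(d). With n pairs the exact null distribution enumerates all
2^n sign assignments (used automatically for n <= 12); larger designs use
Monte-Carlo sign flips. The identity assignment is always counted, so
p > 0 and the smallest attainable exact p is 2^(1-n).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NormalizedExpression, PairedCountMatrix

__all__ = [
    "paired_log_ratios",
    "paired_logfc",
    "paired_de_test",
    "bh_fdr",
    "de_table",
    "deg_call",
]

PSEUDO_COUNT = 0.5
EXACT_MAX_PAIRS = 12


def paired_log_ratios(
    expr: NormalizedExpression, design: pd.DataFrame, pseudo_count: float = PSEUDO_COUNT
) -> pd.DataFrame:
    """Per-gene, per-subject paired log2 cpm ratios (drug over media)."""
    if pseudo_count <= 0:
        raise ValueError("pseudo-count must be positive")
    subjects = sorted(design["subject"].unique())
    cols = {}
    for subj in subjects:
        rows = design[design["subject"] == subj]
        try:
            drug = rows.index[rows["condition"] == "drug"][0]
            media = rows.index[rows["condition"] == "media"][0]
        except IndexError:
            raise ValueError(f"subject {subj} is missing a condition") from None
        cols[subj] = np.log2(
            (expr.cpm[drug] + pseudo_count) / (expr.cpm[media] + pseudo_count)
        )
    return pd.DataFrame(cols)


def paired_logfc(
    expr: NormalizedExpression, design: pd.DataFrame, pseudo_count: float = PSEUDO_COUNT
) -> pd.Series:
    """Mean paired log2 fold-change per gene."""
    lfc = paired_log_ratios(expr, design, pseudo_count).mean(axis=1)
    lfc.name = "logfc"
    return lfc


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign assignments, identity (all +1) first."""
    grid = np.array(np.meshgrid(*([[1, -1]] * n), indexing="ij")).reshape(n, -1).T
    return grid


def paired_de_test(
    d: pd.DataFrame,
    mode: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.Series:
    """Sign-flip permutation p-values on a genes x subjects matrix of paired
    log ratios.

    p = proportion of sign assignments with |t*| >= |t|, identity included.
    Genes with all-zero differences get p = 1; non-zero constant differences
    hit the 2^(1-n) floor (only the two all-same-sign assignments reach
    |t| = inf).
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subject pairs")
    if mode not in ("auto", "exact", "montecarlo"):
        raise ValueError(f"unknown mode: {mode}")
    if mode == "exact" and n > EXACT_MAX_PAIRS:
        raise ValueError(f"exact mode enumerates 2^n flips; limit is n <= {EXACT_MAX_PAIRS}")
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_PAIRS)
    if exact:
        signs = _sign_matrix(n)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1, -1], size=(n_perm, n))
        signs[0, :] = 1  # identity assignment always counted

    # genes are processed in blocks to bound the genes x assignments matrix
    block = max(1, int(2e7) // signs.shape[0])
    p = np.empty(dm.shape[0])
    for start in range(0, dm.shape[0], block):
        sub = dm[start : start + block]
        ss = (sub**2).sum(axis=1)  # invariant under sign flips
        mean_star = sub @ signs.T / n  # genes x assignments
        var_star = np.maximum((ss[:, None] - n * mean_star**2) / (n - 1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = mean_star / np.sqrt(var_star / n)
            # 0/0 (all-zero gene) -> t = 0: every assignment ties and p = 1;
            # m/0 (constant non-zero) -> +-inf, matched only by all-same-sign flips.
            t_star = np.where(
                var_star == 0,
                np.where(mean_star == 0, 0.0, np.sign(mean_star) * np.inf),
                t_star,
            )
        t_obs = np.abs(t_star[:, 0])
        hits = (np.abs(t_star) >= t_obs[:, None] * (1 - 1e-12)).sum(axis=1)
        p[start : start + block] = hits / signs.shape[0]
    out = pd.Series(p, index=d.index if hasattr(d, "index") else None, name="p")
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(
    pcm: PairedCountMatrix,
    expr: NormalizedExpression,
    mode: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full DE screen: logFC, permutation p, BH q, and per-gene cpm range.

    Returns a DataFrame indexed by gene_id with columns
    ``logfc, p, q, min_cpm, max_cpm``.
    """
    d = paired_log_ratios(expr, pcm.design)
    logfc = d.mean(axis=1)
    p = paired_de_test(d, mode=mode, n_perm=n_perm, seed=seed)
    q = bh_fdr(p.values)
    out = pd.DataFrame(
        {
            "logfc": logfc,
            "p": p,
            "q": q,
            "min_cpm": expr.cpm.min(axis=1),
            "max_cpm": expr.cpm.max(axis=1),
        }
    )
    out.index.name = "gene_id"
    return out


def deg_call(
    results: pd.DataFrame, fdr_cut: float = 0.05, logfc_cut: float = 1.0
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated DEG sets at the given FDR and |logFC| cuts."""
    if results.empty:
        return set(), set()
    sig = results["q"] <= fdr_cut
    up = set(results.index[sig & (results["logfc"] >= logfc_cut)])
    down = set(results.index[sig & (results["logfc"] <= -logfc_cut)])
    return up, down
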