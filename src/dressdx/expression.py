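"""Between-sample normalization of paired count data.

Counts are scaled to counts-per-million against TMM-effective library sizes
(trimmed mean of M-values). The low-expression rule removes genes that fail
to reach a minimum count in at least half of the samples; the ambiguous
phrasing of that rule is resolved as *keep a gene iff it has >= min_count in
at least ceil(n_samples / 2) samples* (see docs/methods.md).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import NormalizedExpression, PairedCountMatrix

__all__ = ["low_expression_filter", "tmm_factors", "cpm", "normalize"]


def low_expression_filter(pcm: PairedCountMatrix, min_count: int = 2) -> pd.Series:
    """Boolean keep-mask: gene has >= min_count in at least half the samples."""
    counts = pcm.counts
    n = counts.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    need = math.ceil(n / 2)
    mask = (counts >= min_count).sum(axis=1) >= need
    mask.name = "kept"
    return mask


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Scaling factor of one sample against the reference.

    Genes with a zero count in either sample are excluded; the remaining
    gene-wise log-ratios M are trimmed symmetrically (trim_m of M, trim_a of
    average abundance A) and averaged with inverse asymptotic-variance
    weights (delta-method binomial variances).
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any() or w[kept].min() <= 0:
        return 1.0
    f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    pcm: PairedCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors, renormalized to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean of those fractions.
    """
    counts = np.asarray(pcm.counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        zero = [c for c, tot in zip(pcm.counts.columns, lib) if tot <= 0]
        raise ValueError(f"samples with zero total count: {zero}")
    f75 = np.quantile(counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, s], counts[:, ref_idx], lib[s], lib[ref_idx], trim_m, trim_a)
            for s in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=pcm.counts.columns, name="tmm_factor")


def cpm(pcm: PairedCountMatrix, factors: pd.Series) -> NormalizedExpression:
    """Counts per million over TMM-effective library sizes.

    cpm[g, s] = counts[g, s] / (libsize_s * factor_s) * 1e6
    """
    factors = factors.reindex(pcm.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("invalid or missing scaling factors")
    lib = pcm.counts.sum(axis=0).astype(float)
    eff = lib * factors
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    mat = pcm.counts.div(eff, axis=1) * 1e6
    mask = low_expression_filter(pcm)
    return NormalizedExpression(cpm=mat, tmm_factors=factors, kept_gene_mask=mask)


def normalize(pcm: PairedCountMatrix, min_count: int = 2) -> NormalizedExpression:
    """Filter low-expression genes, then TMM-normalize to cpm.

    TMM factors are computed on the filtered matrix (dominated by reliably
    measured genes) and applied to it; the kept-gene mask is carried along.
    """
    mask = low_expression_filter(pcm, min_count=min_count)
    filtered = PairedCountMatrix(counts=pcm.counts.loc[mask], design=pcm.design)
    factors = tmm_factors(filtered)
    expr = cpm(filtered, factors)
    expr.kept_gene_mask = mask
    return expr
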