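"""Paired DE: log fold-changes, sign-flip permutation test, BH FDR, DEG calls."""
from math import isclose

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from dressdx import PairedCountMatrix, bh_fdr, deg_call, paired_de_test, paired_logfc
from dressdx.de import de_table, paired_log_ratios
from dressdx.expression import normalize

from test_expression import make_pcm


def bh_oracle(p):
    """The step-up definition applied naively: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0)
    return q


class TestPairedLogfc:
    def test_identical_conditions_give_zero(self, small_pcm):
        counts = small_pcm.counts.copy()
        for subj in ("s1", "s2", "s3"):
            counts[f"{subj}_drug"] = counts[f"{subj}_media"]
        pcm = PairedCountMatrix(counts=counts, design=small_pcm.design)
        expr = normalize(pcm, min_count=0)
        assert np.allclose(paired_logfc(expr, pcm.design), 0.0)

    def test_fourfold_cpm_change_in_high_expression_limit(self):
        # drug cpm exactly 4x media, values >> pseudo-count of 0.5
        from dressdx.containers import NormalizedExpression

        rng = np.random.default_rng(8)
        media = rng.uniform(5_000, 50_000, size=(40, 3))
        cols, rows = {}, []
        for i in range(3):
            cols[f"s{i}_drug"] = 4 * media[:, i]
            cols[f"s{i}_media"] = media[:, i]
            rows += [(f"s{i}_drug", f"s{i}", "drug", "allergic"),
                     (f"s{i}_media", f"s{i}", "media", "allergic")]
        cpm_df = pd.DataFrame(cols, index=[f"g{i}" for i in range(40)])
        design = pd.DataFrame(
            rows, columns=["sample", "subject", "condition", "group"]
        ).set_index("sample")
        expr = NormalizedExpression(
            cpm=cpm_df,
            tmm_factors=pd.Series(1.0, index=cpm_df.columns),
            kept_gene_mask=pd.Series(True, index=cpm_df.index),
        )
        lfc = paired_logfc(expr, design)
        assert np.allclose(lfc, 2.0, atol=0.01)

    def test_hand_computed_two_subject_mean(self):
        """cpm media (10,10), drug (40,10) with c=0.5 -> mean of the two
        per-subject log-ratios."""
        from dressdx.containers import NormalizedExpression

        cpm_df = pd.DataFrame(
            {
                "a_drug": [40.0],
                "a_media": [10.0],
                "b_drug": [10.0],
                "b_media": [10.0],
            },
            index=["g0"],
        )
        design = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "condition": ["drug", "media", "drug", "media"],
                "group": ["allergic"] * 4,
            },
            index=["a_drug", "a_media", "b_drug", "b_media"],
        )
        factors = pd.Series(1.0, index=cpm_df.columns)
        expr = NormalizedExpression(
            cpm=cpm_df, tmm_factors=factors, kept_gene_mask=pd.Series([True], index=["g0"])
        )
        expected = 0.5 * (np.log2(40.5 / 10.5) + 0.0)
        assert isclose(paired_logfc(expr, design).iloc[0], expected)

    def test_missing_condition_is_an_error(self, small_pcm):
        design = small_pcm.design.copy()
        design.loc["s1_drug", "condition"] = "media"
        expr = normalize(small_pcm, min_count=0)
        with pytest.raises(ValueError, match="missing a condition"):
            paired_logfc(expr, design)


class TestSignFlipTest:
    def test_all_zero_gene_gets_p_one(self):
        d = pd.DataFrame([[0.0] * 5], index=["g0"])
        assert paired_de_test(d).iloc[0] == 1.0

    def test_constant_sign_gene_hits_exact_floor(self):
        # n=5 pairs, all d_i equal and non-zero: only +-identity reach |t|=inf
        d = pd.DataFrame([[1.3] * 5], index=["g0"])
        assert paired_de_test(d).iloc[0] == pytest.approx(2 / 32)

    def test_five_pair_enumeration_example(self):
        # equal-magnitude same-sign differences: p = 2/2^5
        d = pd.DataFrame([[0.8, 0.8, 0.8, 0.8, 0.8]], index=["g0"])
        assert paired_de_test(d, mode="exact").iloc[0] == pytest.approx(0.0625)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(19)
        d = pd.DataFrame(rng.normal(size=(30, 6)))
        p1 = paired_de_test(d)
        p2 = paired_de_test(-d)
        assert np.allclose(p1.values, p2.values)

    def test_exact_vs_montecarlo_within_3se(self):
        rng = np.random.default_rng(29)
        d = pd.DataFrame(rng.normal(0.3, 1.0, size=(50, 8)))
        p_exact = paired_de_test(d, mode="exact")
        n_perm = 10_000
        p_mc = paired_de_test(d, mode="montecarlo", n_perm=n_perm, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert (np.abs(p_mc - p_exact) <= 3 * se + 1e-9).mean() > 0.97

    def test_exact_mode_rejects_large_n(self):
        d = pd.DataFrame(np.zeros((2, 13)))
        with pytest.raises(ValueError, match="exact"):
            paired_de_test(d, mode="exact")

    def test_minimum_three_pairs(self):
        with pytest.raises(ValueError):
            paired_de_test(pd.DataFrame(np.zeros((2, 2))))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(37)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_matches_naive_definition_and_statsmodels(self):
        rng = np.random.default_rng(43)
        p = rng.uniform(size=150)
        q = bh_fdr(p)
        assert np.allclose(q, bh_oracle(p))
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(47)
        p = rng.uniform(size=60)
        perm = rng.permutation(60)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestDegCall:
    def test_rule_applications(self):
        res = pd.DataFrame(
            {
                "logfc": [1.2, 0.9, -1.5, 2.0],
                "q": [0.04, 0.04, 0.01, 0.2],
                "p": [0.01] * 4,
                "min_cpm": [5.0] * 4,
                "max_cpm": [200.0] * 4,
            },
            index=["up_ok", "low_fc", "down_ok", "not_sig"],
        )
        up, down = deg_call(res)
        assert up == {"up_ok"}
        assert down == {"down_ok"}

    def test_empty_results(self):
        up, down = deg_call(pd.DataFrame(columns=["logfc", "q"]))
        assert up == set() and down == set()

    def test_label_swap_negates_logfc_keeps_p(self, small_pcm):
        expr = normalize(small_pcm, min_count=0)
        res = de_table(small_pcm, expr)
        swapped_design = small_pcm.design.copy()
        swapped_design["condition"] = swapped_design["condition"].map(
            {"drug": "media", "media": "drug"}
        )
        pcm2 = PairedCountMatrix(counts=small_pcm.counts, design=swapped_design)
        res2 = de_table(pcm2, expr)
        assert np.allclose(res["logfc"], -res2["logfc"])
        assert np.allclose(res["p"], res2["p"])
        assert (res["min_cpm"] <= res["max_cpm"]).all()
        assert ((res["q"] >= res["p"] - 1e-15) & (res["q"] <= 1.0)).all()
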