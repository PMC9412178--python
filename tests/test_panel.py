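"""Panel selection: candidate cascade, importance ranking, ROC, combinations."""
from itertools import product
from math import isclose

import numpy as np
import pandas as pd
import pytest

from dressdx import (
    assemble_panel,
    candidate_filter,
    combi_roc,
    default_panel,
    rf_importance,
    roc_auc,
)
from dressdx.panel import youden_cutoff


def auc_oracle(values, labels):
    """Brute-force pair counting: P(pos > neg) + 0.5 P(tie)."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p, n in product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def de_frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["logfc", "q", "min_cpm", "max_cpm"]
    )
    df["p"] = df["q"] / 2
    df.index.name = "gene_id"
    return df


class TestCandidateFilter:
    def test_rule_applications(self):
        de = de_frame(
            {
                "keep": (1.6, 0.01, 5, 150),
                "min_cpm_fail": (1.6, 0.01, 3, 150),
                "max_cpm_fail": (1.6, 0.01, 5, 80),
                "fc_fail": (1.2, 0.01, 5, 150),
                "q_fail": (1.6, 0.2, 5, 150),
                "keep_down": (-2.0, 0.01, 5, 150),
            }
        )
        assert set(candidate_filter(de)) == {"keep", "keep_down"}

    def test_empty_input(self):
        assert candidate_filter(de_frame({})) == []

    def test_monotone_in_cuts(self):
        rng = np.random.default_rng(13)
        de = de_frame(
            {
                f"g{i}": (lf, q, mn, mx)
                for i, (lf, q, mn, mx) in enumerate(
                    zip(
                        rng.normal(0, 2, 100),
                        rng.uniform(0, 0.2, 100),
                        rng.uniform(0, 10, 100),
                        rng.uniform(50, 300, 100),
                    )
                )
            }
        )
        base = set(candidate_filter(de))
        for kwargs in [
            {"logfc_cut": 2.0},
            {"min_cpm": 6.0},
            {"max_cpm": 150.0},
            {"fdr_cut": 0.01},
        ]:
            assert set(candidate_filter(de, **kwargs)) <= base


class TestRfImportance:
    def test_separating_gene_ranks_first(self):
        rng = np.random.default_rng(3)
        n = 20
        labels = np.array(["drug"] * (n // 2) + ["media"] * (n // 2))
        expr = pd.DataFrame(
            rng.normal(size=(8, n)), index=[f"g{i}" for i in range(8)]
        )
        expr.loc["g3"] = np.where(labels == "drug", 5.0, -5.0) + rng.normal(0, 0.1, n)
        imp = rf_importance(expr, labels, seed=0)
        assert imp.idxmax() == "g3"
        assert isclose(imp.sum(), 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(6, 12)))
        labels = ["drug"] * 6 + ["media"] * 6
        assert rf_importance(expr, labels, seed=7).equals(rf_importance(expr, labels, seed=7))

    def test_constant_features_degenerate_flagged(self):
        expr = pd.DataFrame(np.ones((4, 10)))
        labels = ["drug"] * 5 + ["media"] * 5
        with pytest.warns(UserWarning, match="degenerate"):
            imp = rf_importance(expr, labels, seed=0)
        assert np.allclose(imp, 0.25)

    def test_single_class_rejected(self):
        expr = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            rf_importance(expr, ["drug"] * 4, seed=0)


class TestAssemblePanel:
    def test_ten_plus_curated_makes_22(self):
        de = de_frame({f"g{i}": (2.5, 0.01, 5, 150) for i in range(15)})
        imp = pd.Series(np.linspace(0.2, 0.05, 15), index=de.index)
        curated = [f"c{i}" for i in range(12)]
        panel = assemble_panel(de, imp, curated=curated)
        assert len(panel.genes) == 22
        assert sum(g.source == "de_selected" for g in panel.genes) == 10
        assert panel.housekeeping_gene_id == "YWHAZ"

    def test_importance_cut_infinite_gives_curated_only(self):
        de = de_frame({"g0": (2.5, 0.01, 5, 150)})
        imp = pd.Series([0.9], index=de.index)
        with pytest.warns(UserWarning, match="curated-only"):
            panel = assemble_panel(de, imp, curated=["c0"], imp_cut=np.inf)
        assert [g.gene_id for g in panel.genes] == ["c0"]

    def test_tie_at_rank_broken_by_abs_logfc_then_name(self):
        de = de_frame(
            {
                "b_small": (2.0, 0.01, 5, 150),
                "a_big": (-3.0, 0.01, 5, 150),
                "c_same": (3.0, 0.01, 5, 150),
            }
        )
        imp = pd.Series([0.2, 0.2, 0.2], index=de.index)
        panel = assemble_panel(de, imp, max_selected=2)
        assert [g.gene_id for g in panel.genes] == ["a_big", "c_same"]

    def test_directions_follow_discovery_logfc_sign(self):
        de = de_frame({"up": (2.5, 0.01, 5, 150), "down": (-2.5, 0.01, 5, 150)})
        imp = pd.Series([0.5, 0.5], index=de.index)
        panel = assemble_panel(de, imp)
        dirs = panel.directions
        assert dirs["up"] == 1 and dirs["down"] == -1


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([5, 6, 7, 1, 2], [True, True, True, False, False]) == 1.0

    def test_all_ties(self):
        assert roc_auc([3, 3, 3, 3], [True, True, False, False]) == 0.5

    def test_enumerated_pair_example(self):
        # positives {2,3,4} vs negatives {1,2,3}: 6 wins + 2 half-ties of 9
        values = [2, 3, 4, 1, 2, 3]
        labels = [True, True, True, False, False, False]
        assert isclose(roc_auc(values, labels), 7 / 9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            values = rng.integers(0, 6, size=12).astype(float)
            labels = rng.integers(0, 2, size=12).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert isclose(roc_auc(values, labels), auc_oracle(values, labels))

    def test_monotone_transform_and_label_flip(self):
        rng = np.random.default_rng(27)
        values = rng.normal(size=14)
        labels = np.array([True] * 6 + [False] * 8)
        a = roc_auc(values, labels)
        assert isclose(a, roc_auc(np.exp(values), labels))
        assert isclose(a, 1 - roc_auc(values, ~labels))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


class TestCombiRoc:
    def test_label_duplicating_marker_is_perfect(self):
        labels = np.array([True] * 5 + [False] * 5)
        values = pd.DataFrame({"m": np.where(labels, 3.0, -3.0)})
        combos = combi_roc(values, labels)
        assert combos[0].genes == ("m",)
        assert combos[0].auc == 1.0
        assert combos[0].sensitivity == 1.0 and combos[0].specificity == 1.0
        assert combos[0].passes

    def test_direction_adjustment(self):
        labels = np.array([True] * 4 + [False] * 4)
        values = pd.DataFrame({"down": np.where(labels, -2.0, 2.0)})
        combos = combi_roc(values, labels, directions={"down": -1})
        assert combos[0].auc == 1.0 and combos[0].passes

    def test_subset_count_and_cap(self):
        rng = np.random.default_rng(33)
        labels = np.array([True] * 4 + [False] * 4)
        values = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        combos = combi_roc(values, labels)
        assert len(combos) == 2**4 - 1
        too_many = pd.DataFrame(rng.normal(size=(8, 11)))
        with pytest.raises(ValueError, match="limit"):
            combi_roc(too_many, labels)

    def test_youden_cutoff_tie_prefers_sensitive(self):
        cut, sens, spec = youden_cutoff(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([False, False, True, True])
        )
        assert cut == 3.0 and sens == 1.0 and spec == 1.0


class TestDefaultPanel:
    def test_shipped_panel_contents(self):
        panel = default_panel()
        assert panel.housekeeping_gene_id == "YWHAZ"
        assert panel.gene_ids == ["STAC", "GPR183", "CD40", "CISH", "CD4", "CCL8"]
        dirs = panel.directions
        assert dirs["GPR183"] == -1 and dirs["CD4"] == -1
        assert dirs["STAC"] == 1 and dirs["CISH"] == 1 and dirs["CCL8"] == 1
        cd40 = [g for g in panel.genes if g.gene_id == "CD40"][0]
        assert cd40.direction_source == "unspecified"
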