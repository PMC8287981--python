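"""Signature scoring and the paCAF / tr-MSCF / myCAF-iCAF taxonomy rules."""

import numpy as np
import pandas as pd
import pytest

from cafpaths.panels import GeneSetPanel, default_panel
from cafpaths.signatures import (
    ICAF,
    MYCAF,
    NON_PACAF,
    PACAF,
    TR_MSCF,
    TR_RF,
    UNASSIGNED,
    SignatureScores,
    call_normal_taxonomy,
    call_pacaf,
    score_sets,
    subtype_pacaf,
)

from conftest import make_adata


def _random_panel(genes, rng) -> GeneSetPanel:
    sets = {}
    from cafpaths.panels import REQUIRED_SETS
    pool = list(genes)
    for name in REQUIRED_SETS:
        sets[name] = list(rng.choice(pool, size=rng.integers(1, 4),
                                     replace=False))
    # enforce the one structural invariant
    sets["icaf_signature"] = [g for g in sets["icaf_signature"]
                              if g not in sets["mycaf_signature"]] or \
        [g for g in pool if g not in sets["mycaf_signature"]][:1]
    return GeneSetPanel(sets=sets)


def _cluster_scores(values: dict) -> SignatureScores:
    """Hand-built per-cluster score table (per-cell table unused)."""
    per_cluster = pd.DataFrame(values)
    per_cluster.index = [f"T1|{i}" for i in range(len(per_cluster))]
    return SignatureScores(per_cell=pd.DataFrame(), per_cluster=per_cluster,
                           unmatched_sets=[])


class TestScoreSets:
    def test_cluster_score_is_median_of_cell_means(self):
        panel = default_panel()
        genes = panel.sets["fibroblast_markers"][:2]
        adata = make_adata(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        adata.var_names = genes
        clusters = pd.Series(["A", "A", "A"], index=adata.obs_names)
        scores = score_sets(adata, clusters, panel)
        assert scores.per_cluster.loc["A", "fibroblast_markers"] == 1.0

    def test_unexpressed_single_gene_set_scores_zero(self):
        panel = default_panel()
        adata = make_adata(np.zeros((3, 1)))
        adata.var_names = ["PRRX1"]
        clusters = pd.Series(["A"] * 3, index=adata.obs_names)
        scores = score_sets(adata, clusters, panel)
        assert (scores.per_cell["activation"] == 0).all()

    def test_zero_matched_set_is_flagged(self):
        panel = default_panel()
        adata = make_adata(np.ones((3, 1)))
        adata.var_names = ["COL1A1"]
        scores = score_sets(adata, pd.Series(["A"] * 3, index=adata.obs_names),
                            panel)
        assert "epithelial_markers" in scores.unmatched_sets
        assert scores.per_cell["epithelial_markers"].isna().all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n, g = int(rng.integers(4, 9)), int(rng.integers(6, 12))
            adata = make_adata(rng.uniform(0, 3, size=(n, g)))
            panel = _random_panel(list(adata.var_names), rng)
            clusters = pd.Series(rng.choice(["A", "B"], size=n),
                                 index=adata.obs_names)
            scores = score_sets(adata, clusters, panel)
            X = np.asarray(adata.X)
            for name, genes in panel.sets.items():
                cols = [adata.var_names.get_loc(g) for g in genes]
                cell = np.array([X[i, cols].mean() for i in range(n)])
                np.testing.assert_allclose(scores.per_cell[name], cell,
                                           atol=1e-12)
                for cid in ("A", "B"):
                    members = (clusters == cid).to_numpy()
                    if members.any():
                        np.testing.assert_allclose(
                            scores.per_cluster.loc[cid, name],
                            np.median(cell[members]), atol=1e-12)

    def test_scores_invariant_to_cell_order(self):
        rng = np.random.default_rng(4)
        adata = make_adata(rng.uniform(0, 2, size=(8, 6)))
        panel = _random_panel(list(adata.var_names), rng)
        clusters = pd.Series(rng.choice(["A", "B"], size=8),
                             index=adata.obs_names)
        ref = score_sets(adata, clusters, panel)
        perm = rng.permutation(8)
        out = score_sets(adata[perm].copy(), clusters.iloc[perm], panel)
        pd.testing.assert_frame_equal(ref.per_cluster.sort_index(),
                                      out.per_cluster.sort_index())


class TestCallPacaf:
    def test_hand_computed_margin_rule(self):
        # activation mean 1.0, SD 1.0; caf mean 0.8, SD 0.7 (margin 0.5)
        scores = _cluster_scores({"activation": [2.0, 0.0],
                                  "caf_related": [1.5, 0.1]})
        out = call_pacaf(scores, scores.per_cluster.index, high_margin_sd=0.5)
        assert list(out["label"]) == [PACAF, NON_PACAF]

    def test_identical_clusters_are_all_non_pacaf(self):
        scores = _cluster_scores({"activation": [1.0, 1.0, 1.0],
                                  "caf_related": [1.0, 1.0, 1.0]})
        out = call_pacaf(scores, scores.per_cluster.index)
        assert (out["label"] == NON_PACAF).all()

    def test_single_cluster_uses_absolute_floor(self):
        scores = _cluster_scores({"activation": [2.0], "caf_related": [1.5]})
        out = call_pacaf(scores, scores.per_cluster.index)
        assert list(out["label"]) == [PACAF]
        low = _cluster_scores({"activation": [0.1], "caf_related": [0.1]})
        assert list(call_pacaf(low, low.per_cluster.index)["label"]) == [NON_PACAF]


class TestCallNormalTaxonomy:
    def test_high_bm_msc_cluster_is_tr_mscf(self):
        scores = _cluster_scores({"bm_msc_markers": [1.8, 0.2, 0.1],
                                  "hsc_markers": [0.0, 0.0, 0.0]})
        out = call_normal_taxonomy(scores, scores.per_cluster.index,
                                   high_margin_sd=0.5)
        assert list(out["label"]) == [TR_MSCF, TR_RF, TR_RF]

    def test_hsc_expression_vetoes_tr_mscf(self):
        scores = _cluster_scores({"bm_msc_markers": [1.8, 0.2, 0.1],
                                  "hsc_markers": [0.5, 0.0, 0.0]})
        out = call_normal_taxonomy(scores, scores.per_cluster.index,
                                   low_ceiling=0.1)
        assert (out["label"] == TR_RF).all()

    def test_requires_a_normal_cluster(self):
        scores = _cluster_scores({"bm_msc_markers": [1.0],
                                  "hsc_markers": [0.0]})
        with pytest.raises(ValueError):
            call_normal_taxonomy(scores, [])


def _subtype_scores(mycaf, icaf, clusters) -> tuple[SignatureScores, pd.Series]:
    index = pd.Index([f"c{i}" for i in range(len(mycaf))], name="cell_id")
    per_cell = pd.DataFrame({"mycaf_signature": mycaf,
                             "icaf_signature": icaf}, index=index)
    ids = pd.Series(clusters, index=index)
    per_cluster = per_cell.groupby(ids).median()
    return SignatureScores(per_cell=per_cell, per_cluster=per_cluster,
                           unmatched_sets=[]), ids


class TestSubtypePacaf:
    def test_tiny_perfectly_separated_clusters_stay_unassigned(self):
        # diffs {1,2} vs {-3,-4}: exact two-sided p = 2/C(4,2) = 1/3
        scores, ids = _subtype_scores([1, 2, 0, 0], [0, 0, 3, 4],
                                      ["A", "A", "B", "B"])
        res = subtype_pacaf(scores, ids, ["A", "B"], alpha=0.05)
        assert (res.table["label"] == UNASSIGNED).all()
        assert res.table["p_value"].to_numpy() == pytest.approx([1 / 3, 1 / 3])

    def test_large_opposite_programs_are_labelled(self):
        rng = np.random.default_rng(0)
        n = 40
        my = np.concatenate([2 + 0.1 * rng.normal(size=n),
                             0.1 * np.abs(rng.normal(size=n))])
        ic = np.concatenate([0.1 * np.abs(rng.normal(size=n)),
                             2 + 0.1 * rng.normal(size=n)])
        scores, ids = _subtype_scores(my, ic, ["A"] * n + ["B"] * n)
        res = subtype_pacaf(scores, ids, ["A", "B"])
        assert res.table.loc["A", "label"] == MYCAF
        assert res.table.loc["B", "label"] == ICAF
        assert (res.table["p_value"] < 1e-6).all()

    def test_identical_clusters_are_unassigned(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=40)
        scores, ids = _subtype_scores(vals, vals[::-1], ["A", "B"] * 20)
        res = subtype_pacaf(scores, ids, ["A", "B"])
        assert (res.table["label"] == UNASSIGNED).all()

    def test_single_cluster_requires_resubcluster_flag(self):
        scores, ids = _subtype_scores([1, 2, 3], [0, 0, 0], ["A"] * 3)
        with pytest.raises(ValueError, match="resubcluster"):
            subtype_pacaf(scores, ids, ["A"], resubcluster=False)

    def test_resubcluster_splits_a_monolithic_cluster(self):
        rng = np.random.default_rng(2)
        n = 30
        my = np.concatenate([2 + 0.05 * rng.normal(size=n),
                             0.05 * np.abs(rng.normal(size=n))])
        ic = my[::-1].copy()
        scores, ids = _subtype_scores(my, ic, ["A"] * (2 * n))
        emb = pd.DataFrame(np.column_stack([my, ic]), index=ids.index)
        res = subtype_pacaf(scores, ids, ["A"], resubcluster=True,
                            embedding=emb, seed=0)
        assert set(res.table["label"]) == {MYCAF, ICAF}
        assert res.cluster_ids.nunique() == 2
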