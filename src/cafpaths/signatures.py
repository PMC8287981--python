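"""Marker-set scoring and the threshold taxonomy of fibroblast clusters.

Scores follow a median convention: a cell's score for a set is its mean
normalized expression over the set's matched genes, and a cluster's score
is the median of its member cells' scores (mean-of-means is available
behind a flag). On top of the scores sit three rules:

* **paCAF vs non-paCAF** (tumour clusters): a cluster is a perpetually
  activated CAF cluster iff both its PRRX1 activation score and its
  CAF-related score stand out from the across-tumour-cluster mean by a
  margin of standard deviations.
* **tr-MSCF vs tr-RF** (normal clusters): a cluster is a tissue-resident
  MSC-like fibroblast cluster iff its BM-MSC score stands out the same way
  *and* its hematopoietic (HSC) score stays under a ceiling; all other
  normal clusters are resting fibroblasts.
* **myCAF vs iCAF** (paCAF clusters): a cluster is labelled by the sign of
  its myCAF-minus-iCAF score, gated by a two-sided rank-sum test of the
  per-cell score difference against the other paCAF clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .panels import GeneSetPanel
from .stats import rank_sum_test

logger = logging.getLogger(__name__)

PACAF = "paCAF"
NON_PACAF = "non-paCAF"
TR_MSCF = "tr-MSCF"
TR_RF = "tr-RF"
MYCAF = "myCAF"
ICAF = "iCAF"
BM_MSC_LIKE = "BM-MSC-like"
UNASSIGNED = "unassigned"


@dataclass
class SignatureScores:
    """Per-cell and per-cluster signature scores."""

    per_cell: pd.DataFrame      # cells x sets
    per_cluster: pd.DataFrame   # clusters x sets (median of member cells)
    unmatched_sets: list[str]   # sets with zero matched genes (NaN scores)


def score_sets(norm, cluster_ids: pd.Series, panel: GeneSetPanel,
               cluster_stat: str = "median") -> SignatureScores:
    """Score every panel set per cell and per cluster.

    ``norm`` is normalized expression (AnnData or dense array aligned to
    ``cluster_ids``). A set with zero matched genes gets NaN scores and is
    flagged in ``unmatched_sets``.
    """
    if cluster_stat not in ("median", "mean"):
        raise ValueError("cluster_stat must be 'median' or 'mean'")
    if hasattr(norm, "X"):
        genes = norm.var_names
        X = norm.X
        index = norm.obs_names
    else:
        raise TypeError("score_sets expects an AnnData with named genes")
    dense = np.asarray(sp.csr_matrix(X).todense(), dtype=np.float64)
    matched = panel.match(genes)
    per_cell = {}
    unmatched = []
    for name, pos in matched.items():
        if pos.size == 0:
            logger.warning("set %r matched no genes; score undefined", name)
            per_cell[name] = np.full(dense.shape[0], np.nan)
            unmatched.append(name)
        else:
            per_cell[name] = dense[:, pos].mean(axis=1)
    cell_df = pd.DataFrame(per_cell, index=index)
    cluster_ids = cluster_ids.reindex(index)
    stat = "median" if cluster_stat == "median" else "mean"
    cluster_df = cell_df.groupby(cluster_ids, observed=True).agg(stat)
    cluster_df.index.name = "cluster_id"
    return SignatureScores(per_cell=cell_df, per_cluster=cluster_df,
                           unmatched_sets=unmatched)


def _stands_out(scores: pd.Series, margin_sd: float) -> pd.Series:
    """Margin-over-mean rule: score - mean >= margin * SD, with SD > 0."""
    mu = scores.mean()
    sd = scores.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return pd.Series(False, index=scores.index)
    return (scores - mu) >= margin_sd * sd


def call_pacaf(scores: SignatureScores, tumour_clusters,
               high_margin_sd: float = 0.5,
               single_cluster_min: float = 0.5) -> pd.DataFrame:
    """Label tumour clusters paCAF / non-paCAF.

    A cluster is paCAF iff both its activation (PRRX1) and CAF-related
    scores stand out from the across-tumour-cluster mean by
    ``high_margin_sd`` standard deviations. With fewer than two tumour
    clusters the margin rule is vacuous and an absolute floor
    (``single_cluster_min`` on both scores) is applied instead.
    """
    tumour_clusters = list(tumour_clusters)
    tab = scores.per_cluster.loc[tumour_clusters, ["activation", "caf_related"]]
    if len(tumour_clusters) >= 2:
        is_pacaf = (_stands_out(tab["activation"], high_margin_sd)
                    & _stands_out(tab["caf_related"], high_margin_sd))
    else:
        is_pacaf = ((tab["activation"] > single_cluster_min)
                    & (tab["caf_related"] > single_cluster_min))
    out = tab.copy()
    out.columns = ["activation_score", "caf_related_score"]
    out["label"] = np.where(is_pacaf, PACAF, NON_PACAF)
    return out


def call_normal_taxonomy(scores: SignatureScores, normal_clusters,
                         high_margin_sd: float = 0.5,
                         low_ceiling: float = 0.1) -> pd.DataFrame:
    """Label normal clusters tr-MSCF / tr-RF.

    tr-MSCF requires a BM-MSC score standing out across the normal
    clusters *and* an HSC score of at most ``low_ceiling``.
    """
    normal_clusters = list(normal_clusters)
    if len(normal_clusters) == 0:
        raise ValueError("call_normal_taxonomy requires at least one normal cluster")
    tab = scores.per_cluster.loc[normal_clusters, ["bm_msc_markers", "hsc_markers"]]
    high_bm = _stands_out(tab["bm_msc_markers"], high_margin_sd)
    is_mscf = high_bm & (tab["hsc_markers"] <= low_ceiling)
    out = tab.copy()
    out.columns = ["bm_msc_score", "hsc_score"]
    out["label"] = np.where(is_mscf, TR_MSCF, TR_RF)
    return out


@dataclass
class SubtypeResult:
    """myCAF/iCAF subtype calls plus the rank-sum evidence."""

    table: pd.DataFrame          # cluster_id -> label, scores, statistic, p
    cluster_ids: pd.Series       # per-cell ids, updated if resubclustered


def subtype_pacaf(scores: SignatureScores, cluster_ids: pd.Series,
                  pacaf_clusters, alpha: float = 0.05,
                  resubcluster: bool = False,
                  embedding: pd.DataFrame | None = None,
                  norm=None, seed: int = 0,
                  min_cells: int = 3) -> SubtypeResult:
    """Subtype paCAF clusters into myCAF vs iCAF with rank-sum gating.

    Each paCAF cluster's per-cell (myCAF - iCAF) score differences are
    compared against the pooled differences of the remaining paCAF
    clusters with the two-sided rank-sum test. The cluster is labelled by
    the sign of its cluster-level score difference when the test is
    significant and it has at least ``min_cells`` cells; otherwise it is
    left unassigned.

    A single paCAF cluster cannot be tested against peers; with
    ``resubcluster=True`` it is first split in two by k-means in the
    provided embedding (mirroring subgroup re-clustering of a monolithic
    CAF cluster).
    """
    pacaf_clusters = list(pacaf_clusters)
    cluster_ids = cluster_ids.copy()
    if len(pacaf_clusters) == 0:
        empty = pd.DataFrame(columns=["mycaf_score", "icaf_score", "statistic",
                                      "p_value", "label"])
        return SubtypeResult(table=empty, cluster_ids=cluster_ids)
    if len(pacaf_clusters) == 1:
        if not resubcluster:
            raise ValueError(
                "subtype_pacaf needs >= 2 paCAF clusters, or resubcluster=True"
            )
        if embedding is None and norm is None:
            raise ValueError("resubclustering requires an embedding or the "
                             "normalized expression")
        cid = pacaf_clusters[0]
        cells = cluster_ids.index[cluster_ids == cid]
        cells = cells[np.argsort(cells)]
        if norm is not None:
            # re-embed the subgroup on its own axes: within the paCAF
            # subset the most variable genes are the subtype programs, so a
            # narrow subset-HVG embedding carries the myCAF/iCAF contrast
            # that the global embedding dilutes across noise dimensions
            from .cluster import embed_pca
            sub_norm = norm[norm.obs_names.get_indexer(cells)]
            coords = embed_pca(sub_norm, n_hvg=100, n_pc=5,
                               random_state=seed).coords
        else:
            coords = embedding.loc[cells].to_numpy()
        from sklearn.cluster import KMeans
        sub = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(
            coords
        )
        new_ids = pd.Series([f"{cid}#{s}" for s in sub], index=cells)
        cluster_ids.loc[cells] = new_ids
        pacaf_clusters = sorted(new_ids.unique())

    diff = scores.per_cell["mycaf_signature"] - scores.per_cell["icaf_signature"]
    rows = []
    for cid in pacaf_clusters:
        mask = (cluster_ids == cid).to_numpy()
        own = diff[mask].to_numpy()
        other = diff[np.isin(cluster_ids.to_numpy(), [c for c in pacaf_clusters
                                                      if c != cid])].to_numpy()
        my_score = float(np.median(scores.per_cell["mycaf_signature"][mask]))
        i_score = float(np.median(scores.per_cell["icaf_signature"][mask]))
        stat = p = np.nan
        label = UNASSIGNED
        if own.size >= 1 and other.size >= 1:
            stat, p = rank_sum_test(own, other, alternative="two-sided")
            if own.size >= min_cells and p < alpha:
                label = MYCAF if my_score > i_score else ICAF
        rows.append((cid, my_score, i_score, stat, p, label))
    table = pd.DataFrame(
        rows, columns=["cluster_id", "mycaf_score", "icaf_score", "statistic",
                       "p_value", "label"],
    ).set_index("cluster_id")
    return SubtypeResult(table=table, cluster_ids=cluster_ids)
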