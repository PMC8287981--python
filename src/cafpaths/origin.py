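"""Origin tracing of tumour fibroblast clusters by centroid correlation.

Every tumour cluster's centroid profile (per-gene mean normalized
expression; a median variant exists but is degenerate at scRNA-seq
sparsity, where most per-gene medians tie at zero or one count) is
correlated, over the most variable genes, with every
normal-tissue (and optionally bone-marrow MSC) cluster centroid using
Spearman's rho. The best-correlated reference cluster is the putative
origin; the call is "exclusive" when the winner beats the runner-up by a
margin ``delta`` of correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .stats import spearman_rho

logger = logging.getLogger(__name__)


@dataclass
class OriginMap:
    """Tumour x reference Spearman matrix and the per-cluster origin calls."""

    rho: pd.DataFrame     # tumour clusters x normal/bm clusters
    calls: pd.DataFrame   # best_match, best_rho, gap, exclusive per tumour cluster
    hvg_genes: np.ndarray


def _centroids(dense: np.ndarray, cluster_ids: pd.Series,
               stat: str) -> pd.DataFrame:
    groups = {}
    for cid in pd.unique(cluster_ids):
        rows = dense[(cluster_ids == cid).to_numpy()]
        groups[cid] = np.median(rows, axis=0) if stat == "median" else rows.mean(axis=0)
    return pd.DataFrame(groups).T


def trace_origins(norm, cluster_ids: pd.Series, cluster_tissue: pd.Series,
                  n_hvg: int = 2000, delta: float = 0.05,
                  stat: str = "mean") -> OriginMap:
    """All-pairwise tumour-vs-reference centroid correlation.

    Parameters
    ----------
    norm
        Normalized expression of the clustered fibroblast cells (AnnData).
    cluster_ids
        Per-cell cluster id, aligned to ``norm``.
    cluster_tissue
        Per-cluster tissue class in {tumour, normal, bm}. Normal and bm
        clusters form the reference columns.
    n_hvg
        Correlations use the top variable genes (variance pooled over all
        fibroblast cells).
    delta
        Exclusivity margin: the call is exclusive iff
        rho(best) - rho(second best) >= delta. With a single reference
        cluster the gap is undefined and reported as NaN.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    dense = np.asarray(sp.csr_matrix(norm.X).todense(), dtype=np.float64)
    cluster_ids = cluster_ids.reindex(norm.obs_names)
    tumour = [c for c in cluster_tissue.index if cluster_tissue[c] == "tumour"]
    reference = [c for c in cluster_tissue.index if cluster_tissue[c] in ("normal", "bm")]
    if not tumour or not reference:
        raise ValueError("trace_origins needs >= 1 tumour and >= 1 normal cluster")

    variances = dense.var(axis=0)
    hvg = np.sort(np.argsort(-variances, kind="stable")[:min(n_hvg, dense.shape[1])])
    cents = _centroids(dense[:, hvg], cluster_ids, stat)

    rho = pd.DataFrame(index=tumour, columns=reference, dtype=float)
    for t in tumour:
        for r in reference:
            rho.loc[t, r] = spearman_rho(cents.loc[t].to_numpy(),
                                         cents.loc[r].to_numpy())
    calls = []
    for t in tumour:
        row = rho.loc[t].astype(float).sort_values(ascending=False)
        best, best_rho = row.index[0], float(row.iloc[0])
        if len(row) >= 2:
            gap = best_rho - float(row.iloc[1])
            exclusive = bool(gap >= delta)
        else:
            gap, exclusive = float("nan"), None
            logger.warning("single reference cluster: exclusivity undefined")
        calls.append((t, best, best_rho, gap, exclusive))
    calls = pd.DataFrame(
        calls, columns=["tumour_cluster", "best_match", "best_rho", "gap",
                        "exclusive"],
    ).set_index("tumour_cluster")
    return OriginMap(rho=rho, calls=calls, hvg_genes=hvg)
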