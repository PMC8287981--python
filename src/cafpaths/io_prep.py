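"""Reading/writing 10x-style triplets, normalization, QC and the two-step
fibroblast screen.

The fibroblast screen defines the cell universe for everything downstream
and is deliberately strict:

* **Step 1 (cluster evidence).** All cells are coarsely clustered by
  k-means on a PCA embedding; a cluster is a fibroblast candidate only if
  its mean fibroblast-marker score stands out from the across-cluster mean
  by a configurable number of standard deviations.
* **Step 2 (lineage exclusion).** Within candidate clusters, any cell
  showing appreciable normalized expression of an epithelial, immune or
  endothelial marker is excluded, with the offending marker recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .cluster import embed_pca
from .panels import EXCLUSION_SETS, GeneSetPanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Matrix Market triplet I/O (genes x cells on disk, cells x genes in memory)
# ---------------------------------------------------------------------------

def read_mtx_triplet(dir_path) -> AnnData:
    """Read ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``.

    The matrix on disk is genes x cells (10x convention); the returned
    ``AnnData`` is cells x genes with integer counts. An optional
    ``cells.tsv`` (columns ``cell_id``, ``sample_id``, ``tissue``)
    populates ``.obs``.
    """
    dir_path = Path(dir_path)
    mat = mmread(dir_path / "matrix.mtx")
    data = np.asarray(mat.data if sp.issparse(mat) else mat, dtype=float)
    if data.size and not np.all(np.mod(data, 1) == 0):
        raise ValueError("matrix.mtx contains non-integer entries")
    if data.size and data.min() < 0:
        raise ValueError("matrix.mtx contains negative entries")
    features = pd.read_csv(dir_path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(dir_path / "barcodes.tsv", sep="\t", header=None)[0]
    genes = features.iloc[:, -1].astype(str)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape}, "
            f"features/barcodes are {(len(genes), len(barcodes))}"
        )
    if barcodes.duplicated().any():
        raise ValueError("duplicate barcodes in barcodes.tsv")
    if genes.duplicated().any():
        raise ValueError("duplicate gene symbols in features.tsv")
    X = sp.csr_matrix(sp.coo_matrix(mat).T.astype(np.int64))
    obs = pd.DataFrame(index=pd.Index(barcodes.astype(str), name="cell_id"))
    meta_path = dir_path / "cells.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        obs = obs.join(meta)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if features.shape[1] >= 2:
        var["gene_id"] = features.iloc[:, 0].astype(str).to_numpy()
    return AnnData(X=X, obs=obs, var=var)


def write_mtx_triplet(adata: AnnData, dir_path) -> None:
    """Write the inverse triplet of :func:`read_mtx_triplet` (lossless)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T.astype(np.int64)
    mmwrite(str(dir_path / "matrix.mtx"), X, field="integer")
    gene_ids = adata.var["gene_id"] if "gene_id" in adata.var else adata.var_names
    pd.DataFrame({"gene_id": np.asarray(gene_ids), "gene_symbol": adata.var_names}).to_csv(
        dir_path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    cols = [c for c in ("sample_id", "tissue") if c in adata.obs]
    if cols:
        adata.obs[cols].to_csv(dir_path / "cells.tsv", sep="\t", index=True,
                               index_label="cell_id")


# ---------------------------------------------------------------------------
# Normalization and QC
# ---------------------------------------------------------------------------

def normalize(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Library-size normalize to ``target_sum`` counts per cell, then log1p.

    For cell *j* with total count :math:`T_j > 0`, value(g, j) =
    log(1 + target_sum * count(g, j) / T_j). All-zero cells pass through
    as all-zero columns with a logged warning; scale invariance under
    per-cell depth changes is exact.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("normalize: %d cell(s) with zero total counts pass "
                       "through as zeros", n_zero)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return AnnData(X=sp.csr_matrix(X), obs=adata.obs.copy(), var=adata.var.copy())


def qc_filter(adata: AnnData, min_genes_per_cell: int = 200,
              min_cells_per_gene: int = 3) -> AnnData:
    """Keep cells detecting enough genes, then genes detected in enough cells.

    Cells are filtered first, then gene detection is recounted on the
    retained cells; an empty result is returned with a warning.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("QC thresholds must be non-negative")
    X = sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    keep_cells = detected >= min_genes_per_cell
    X = X[keep_cells]
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = adata[keep_cells, keep_genes].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        warnings.warn("qc_filter produced an empty matrix", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Two-step fibroblast identification
# ---------------------------------------------------------------------------

@dataclass
class FibroblastCalls:
    """Per-cell fibroblast calls with the evidence behind them."""

    calls: pd.Series                 # {fibroblast, excluded_lineage, other}
    cluster_labels: pd.Series        # step-1 coarse cluster per cell
    cluster_scores: pd.Series        # mean fibroblast-marker score per cluster
    candidate_clusters: list[int]    # clusters passing step 1
    offending_marker: pd.Series      # step-2 exclusion evidence (NaN if none)

    @property
    def fibroblast_mask(self) -> pd.Series:
        return self.calls == "fibroblast"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "call": self.calls,
            "coarse_cluster": self.cluster_labels,
            "offending_marker": self.offending_marker,
        })


class FibroblastIdentifier(BaseEstimator):
    """Two-step fibroblast screen as a scikit-learn style estimator.

    Parameters
    ----------
    coarse_k
        Number of coarse k-means clusters over all cells (step 1).
    step1_margin
        A cluster is a fibroblast candidate iff its mean fibroblast-marker
        score exceeds the across-cluster mean by at least this many
        across-cluster standard deviations.
    step2_max_norm_expr
        A candidate-cluster cell is excluded if any epithelial / immune /
        endothelial marker exceeds this normalized expression.
    n_hvg, n_pc
        Highly variable genes and principal components for the step-1
        embedding.
    n_init, random_state
        k-means restarts and seed. Cells are processed in lexicographic
        barcode order internally, so calls do not depend on input order.

    Attributes (after ``fit``)
    --------------------------
    calls_ : :class:`FibroblastCalls`
    """

    def __init__(self, panel: GeneSetPanel | None = None, coarse_k: int = 10,
                 step1_margin: float = 1.0, step2_max_norm_expr: float = 0.25,
                 n_hvg: int = 2000, n_pc: int = 20, n_init: int = 5,
                 random_state: int = 0):
        self.panel = panel
        self.coarse_k = coarse_k
        self.step1_margin = step1_margin
        self.step2_max_norm_expr = step2_max_norm_expr
        self.n_hvg = n_hvg
        self.n_pc = n_pc
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: AnnData, y=None) -> "FibroblastIdentifier":
        if self.coarse_k < 2:
            raise ValueError("coarse_k must be at least 2")
        panel = self.panel
        if panel is None:
            from .panels import default_panel
            panel = default_panel()
        norm = X
        order = np.argsort(norm.obs_names)
        adata = norm[order].copy()
        dense = np.asarray(sp.csr_matrix(adata.X).todense())
        matched = panel.match(adata.var_names)
        fib_cols = matched["fibroblast_markers"]
        if fib_cols.size == 0:
            raise ValueError("no fibroblast markers matched the matrix genes")

        emb = embed_pca(dense, n_hvg=self.n_hvg, n_pc=self.n_pc,
                        random_state=self.random_state)
        km = KMeans(n_clusters=min(self.coarse_k, adata.n_obs),
                    n_init=self.n_init, random_state=self.random_state)
        labels = km.fit_predict(emb.coords)

        fib_score = dense[:, fib_cols].mean(axis=1)
        cluster_ids = np.arange(labels.max() + 1)
        means = np.array([fib_score[labels == c].mean() for c in cluster_ids])
        mu, sd = means.mean(), means.std()
        candidates = [int(c) for c in cluster_ids
                      if sd > 0 and means[c] - mu >= self.step1_margin * sd]

        calls = np.full(adata.n_obs, "other", dtype=object)
        offending = np.full(adata.n_obs, None, dtype=object)
        in_candidate = np.isin(labels, candidates)
        for set_name in EXCLUSION_SETS:
            pos = matched[set_name]
            if pos.size == 0:
                continue
            sub = dense[:, pos]
            worst = sub.max(axis=1)
            bad = in_candidate & (worst > self.step2_max_norm_expr)
            newly = bad & (calls != "excluded_lineage")
            idx = np.flatnonzero(newly)
            if idx.size:
                arg = sub[idx].argmax(axis=1)
                offending[idx] = adata.var_names[pos[arg]].to_numpy()
            calls[bad] = "excluded_lineage"
        calls[in_candidate & (calls == "other")] = "fibroblast"

        index = adata.obs_names
        restore = norm.obs_names
        self.calls_ = FibroblastCalls(
            calls=pd.Series(calls, index=index, name="call").reindex(restore),
            cluster_labels=pd.Series(labels, index=index,
                                     name="coarse_cluster").reindex(restore),
            cluster_scores=pd.Series(means, index=cluster_ids,
                                     name="fibroblast_score"),
            candidate_clusters=candidates,
            offending_marker=pd.Series(offending, index=index,
                                       name="offending_marker").reindex(restore),
        )
        return self

    def fit_predict(self, X: AnnData, y=None) -> pd.Series:
        return self.fit(X).calls_.calls


def identify_fibroblasts(norm: AnnData, panel: GeneSetPanel | None = None,
                         coarse_k: int = 10, step1_margin: float = 1.0,
                         step2_max_norm_expr: float = 0.25,
                         random_state: int = 0, **kwargs) -> FibroblastCalls:
    """Functional wrapper over :class:`FibroblastIdentifier`."""
    est = FibroblastIdentifier(
        panel=panel, coarse_k=coarse_k, step1_margin=step1_margin,
        step2_max_norm_expr=step2_max_norm_expr, random_state=random_state,
        **kwargs,
    )
    return est.fit(norm).calls_
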