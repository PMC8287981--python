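"""Per-sample k-means clustering of fibroblasts with SSE-elbow model choice.

The number of clusters per sample is chosen from the within-cluster
sum-of-squared-errors curve: SSE(k) is recorded over a k range, and the
chosen k is the smallest one after which every relative drop
``(SSE(k) - SSE(k+1)) / SSE(k)`` stays below a threshold. To make the
recorded curve non-increasing by construction, the best solution at k
seeds a warm-started candidate at k+1 (the previous centroids plus the
point farthest from its centroid).

Distances are Euclidean in a PCA embedding of the standardized most
variable genes, not in gene space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PCAEmbedding:
    """PCA coordinates plus the information needed to interpret them."""

    coords: np.ndarray                    # cells x n_pc
    explained_variance_ratio: np.ndarray
    genes_used: np.ndarray                # column positions of the HVGs


def _to_dense(X) -> np.ndarray:
    if hasattr(X, "X"):  # AnnData
        X = X.X
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def embed_pca(X, n_hvg: int = 2000, n_pc: int = 20,
              random_state: int = 0) -> PCAEmbedding:
    """PCA of the standardized top-``n_hvg`` most variable genes.

    Components are ordered by decreasing explained variance; signs follow
    scikit-learn's deterministic convention. Zero-variance genes among the
    selected ones are left centred but unscaled.
    """
    dense = _to_dense(X)
    n_cells, n_genes = dense.shape
    if n_cells < 3:
        raise ValueError("embed_pca requires at least 3 cells")
    variances = dense.var(axis=0)
    n_hvg = min(n_hvg, n_genes)
    hvg = np.sort(np.argsort(-variances, kind="stable")[:n_hvg])
    sub = dense[:, hvg]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)
    std[std == 0] = 1.0
    sub = (sub - mean) / std
    n_pc = min(n_pc, n_cells, len(hvg))
    pca = PCA(n_components=n_pc, svd_solver="auto", random_state=random_state)
    coords = pca.fit_transform(sub)
    return PCAEmbedding(coords=coords,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        genes_used=hvg)


def _sse(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def kmeans_sse(X, k: int, seed: int = 0, n_init: int = 10,
               warm_centers: np.ndarray | None = None):
    """Best-of-restarts k-means returning ``(labels, centers, sse)``.

    ``sse`` is recomputed in float64 from the returned assignment. An
    optional warm start (e.g. the solution at k-1 plus one split centroid)
    is evaluated as an extra candidate and kept if it wins.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can starve clusters
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        best = (km.labels_, km.cluster_centers_,
                _sse(X, km.labels_, km.cluster_centers_))
        if warm_centers is not None and warm_centers.shape[0] == k:
            km2 = KMeans(n_clusters=k, init=warm_centers, n_init=1,
                         random_state=seed).fit(X)
            cand = (km2.labels_, km2.cluster_centers_,
                    _sse(X, km2.labels_, km2.cluster_centers_))
            if cand[2] < best[2]:
                best = cand
    return best


def select_k(sse_curve: dict[int, float], drop_threshold: float = 0.10) -> int:
    """Smallest k after which every relative SSE drop stays below threshold.

    The curve must be defined on consecutive k values and be non-increasing
    (a violation indicates an upstream bug and raises). If the final
    recorded drop still meets the threshold, the largest recorded k is
    returned with a warning.
    """
    if not 0.0 < drop_threshold < 1.0:
        raise ValueError("drop_threshold must be in (0, 1)")
    ks = sorted(sse_curve)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("sse_curve must cover consecutive k values")
    sse = np.array([float(sse_curve[k]) for k in ks])
    rising = sse[1:] > sse[:-1] * (1 + 1e-9) + 1e-12
    if rising.any():
        raise ValueError("SSE curve is not non-increasing; upstream bug")
    if len(ks) == 1:
        return ks[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        drops = np.where(sse[:-1] > 0, (sse[:-1] - sse[1:]) / sse[:-1], 0.0)
    big = np.flatnonzero(drops >= drop_threshold)
    if big.size == 0:
        return ks[0]
    if big[-1] == len(ks) - 2:
        warnings.warn("SSE drops never level off; returning k_max", stacklevel=2)
        return ks[-1]
    return ks[big[-1] + 1]


class SSEKMeans(BaseEstimator, ClusterMixin):
    """k-means over a k range with SSE-elbow selection of k.

    Scans ``k_min..k_max`` with best-of-``n_init`` restarts, warm-starting
    each k from the previous best solution so the SSE curve is
    non-increasing, then picks k with :func:`select_k`.

    Attributes (after ``fit``)
    --------------------------
    sse_curve_ : dict mapping k to SSE
    chosen_k_ : selected number of clusters
    labels_, cluster_centers_ : solution at the chosen k
    """

    def __init__(self, k_min: int = 1, k_max: int = 10,
                 drop_threshold: float = 0.10, n_init: int = 10,
                 random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.drop_threshold = drop_threshold
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None) -> "SSEKMeans":
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        k_hi = min(self.k_max, n)
        solutions: dict[int, tuple] = {}
        curve: dict[int, float] = {}
        warm = None
        prev_sse = np.inf
        for k in range(self.k_min, k_hi + 1):
            labels, centers, sse = kmeans_sse(
                X, k, seed=self.random_state, n_init=self.n_init,
                warm_centers=warm,
            )
            sse = min(sse, prev_sse)  # guard float jitter in the warm start
            solutions[k] = (labels, centers)
            curve[k] = sse
            prev_sse = sse
            # split candidate: previous centroids plus the worst-fit point
            resid = ((X - centers[labels]) ** 2).sum(axis=1)
            warm = np.vstack([centers, X[int(resid.argmax())]])
        self.sse_curve_ = curve
        self.chosen_k_ = select_k(curve, self.drop_threshold)
        self.labels_, self.cluster_centers_ = solutions[self.chosen_k_]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusteringResult:
    """Sample-scoped fibroblast clusters plus the evidence behind k."""

    assignments: pd.DataFrame           # index cell_id; sample_id, cluster, cluster_id
    embedding: pd.DataFrame             # cells x PCs, aligned to assignments
    sse_curves: dict[str, dict[int, float]]
    chosen_k: dict[str, int]
    centers: dict[str, np.ndarray] = field(default_factory=dict)
    pca: PCAEmbedding | None = None

    @property
    def cluster_ids(self) -> pd.Series:
        return self.assignments["cluster_id"]


def cluster_fibroblasts(norm, sample_ids: pd.Series | None = None,
                        k_min: int = 1, k_max: int = 10,
                        drop_threshold: float = 0.10, n_hvg: int = 2000,
                        n_pc: int = 20, n_init: int = 10,
                        seed: int = 0) -> ClusteringResult:
    """Cluster fibroblasts independently per sample in a shared embedding.

    ``norm`` is the normalized expression of fibroblast cells (AnnData, or
    an array with ``sample_ids`` given explicitly). Each sample is scanned
    over the k range with :class:`SSEKMeans`; a sample with fewer cells
    than ``k_min`` gets a single cluster with a warning. Cells are
    processed in lexicographic id order within sample, so results do not
    depend on input order.
    """
    if hasattr(norm, "obs"):
        if sample_ids is None:
            sample_ids = norm.obs["sample_id"]
        cell_index = norm.obs_names
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required when norm is not AnnData")
        cell_index = pd.Index(sample_ids.index)
    sample_ids = pd.Series(np.asarray(sample_ids), index=cell_index)

    emb = embed_pca(norm, n_hvg=n_hvg, n_pc=n_pc, random_state=seed)
    coords = pd.DataFrame(
        emb.coords, index=cell_index,
        columns=[f"PC{i + 1}" for i in range(emb.coords.shape[1])],
    )

    frames = []
    sse_curves: dict[str, dict[int, float]] = {}
    chosen: dict[str, int] = {}
    centers: dict[str, np.ndarray] = {}
    for sample in sorted(sample_ids.unique()):
        cells = sample_ids.index[sample_ids == sample]
        cells = cells[np.argsort(cells)]
        X = coords.loc[cells].to_numpy()
        if len(cells) < max(k_min, 1) or len(cells) == 1:
            warnings.warn(f"sample {sample!r} has too few cells; using k=1",
                          stacklevel=2)
            labels = np.zeros(len(cells), dtype=int)
            sse_curves[sample] = {1: _sse(X, labels, X.mean(axis=0, keepdims=True))}
            chosen[sample] = 1
            centers[sample] = X.mean(axis=0, keepdims=True)
        else:
            model = SSEKMeans(k_min=k_min, k_max=min(k_max, len(cells)),
                              drop_threshold=drop_threshold, n_init=n_init,
                              random_state=seed).fit(X)
            labels = model.labels_
            sse_curves[sample] = model.sse_curve_
            chosen[sample] = model.chosen_k_
            centers[sample] = model.cluster_centers_
        frames.append(pd.DataFrame({
            "sample_id": sample,
            "cluster": labels,
            "cluster_id": [f"{sample}|{c}" for c in labels],
        }, index=cells))
    assignments = pd.concat(frames).reindex(cell_index)
    return ClusteringResult(assignments=assignments, embedding=coords,
                            sse_curves=sse_curves, chosen_k=chosen,
                            centers=centers, pca=emb)
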