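"""Principal-curve pseudotime and ordering tests along the fibroblast path.

The developmental axis (tr-MSCF -> iCAF -> myCAF, optionally rooted at
BM-MSC) is modelled as a single principal curve in the PCA embedding:
starting from the first principal component, the fitter alternates
projecting points to the current curve, re-estimating each coordinate by
a lowess smoother of coordinate against arclength, and reparameterizing
by arclength until the mean squared projection distance stabilizes.
Pseudotime is the normalized arclength of each cell's projection,
oriented so the root population sits at the low end. Label-pair ordering
claims (e.g. myCAF later than iCAF) are tested with the rank-sum test on
pseudotime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .stats import rank_sum_test

logger = logging.getLogger(__name__)


def _project_to_polyline(P: np.ndarray, V: np.ndarray,
                         chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of points ``P`` onto the polyline ``V``.

    Returns ``(arclength, sq_dist)`` per point, where arclength is measured
    along the polyline from its first vertex.
    """
    A, B = V[:-1], V[1:]
    AB = B - A
    seg_len2 = (AB ** 2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1.0
    seg_len = np.sqrt((AB ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    lam = np.empty(P.shape[0])
    d2 = np.empty(P.shape[0])
    for start in range(0, P.shape[0], chunk):
        p = P[start:start + chunk]
        diff = p[:, None, :] - A[None, :, :]
        t = np.clip((diff * AB[None]).sum(-1) / seg_len2[None], 0.0, 1.0)
        proj = A[None] + t[..., None] * AB[None]
        dist2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        seg = dist2.argmin(axis=1)
        rows = np.arange(p.shape[0])
        lam[start:start + chunk] = cum[seg] + t[rows, seg] * seg_len[seg]
        d2[start:start + chunk] = dist2[rows, seg]
    return lam, d2


class PrincipalCurve(BaseEstimator, TransformerMixin):
    """Hastie-Stuetzle style principal curve with a lowess smoother.

    Parameters
    ----------
    smooth_span
        Fraction of points in each local regression window.
    max_iter, tol
        Iteration stops when the mean squared projection distance changes
        by less than ``tol`` or after ``max_iter`` rounds.
    max_vertices
        The fitted polyline is decimated to at most this many vertices to
        keep projection cost quadratic only in small factors.
    random_state
        Unused by the deterministic fitter; kept for API uniformity.

    Attributes (after ``fit``)
    --------------------------
    curve_points_ : ordered polyline vertices in embedding space
    lambda_ : arclength of each training point's projection
    mean_sq_dist_ : final mean squared projection distance
    n_iter_ : iterations run
    """

    def __init__(self, smooth_span: float = 0.3, max_iter: int = 50,
                 tol: float = 1e-6, max_vertices: int = 512,
                 random_state: int = 0):
        self.smooth_span = smooth_span
        self.max_iter = max_iter
        self.tol = tol
        self.max_vertices = max_vertices
        self.random_state = random_state

    def fit(self, X, y=None) -> "PrincipalCurve":
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if n < 10:
            raise ValueError("principal curve needs at least 10 points")
        if d < 2:
            raise ValueError("principal curve needs >= 2 dimensions")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate embedding: all points identical")
        centre = X.mean(axis=0)
        Xc = X - centre
        # initial parameterization: projection onto the first PC
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        lam = Xc @ vt[0]
        prev_msd = np.inf
        V = None
        for it in range(1, self.max_iter + 1):
            order = np.argsort(lam, kind="stable")
            lam_s = lam[order]
            # lowess needs strictly informative x; jitter exact ties by rank
            if lam_s[-1] > lam_s[0]:
                tie_eps = (lam_s[-1] - lam_s[0]) * 1e-9
            else:
                tie_eps = 1e-9
            lam_u = lam_s + np.arange(n) * tie_eps
            smooth = np.empty((n, d))
            for j in range(d):
                smooth[:, j] = lowess(X[order, j], lam_u, frac=self.smooth_span,
                                      it=0, return_sorted=False)
            keep = np.concatenate([[True],
                                   (np.diff(smooth, axis=0) ** 2).sum(1) > 1e-24])
            V = smooth[keep]
            if V.shape[0] > self.max_vertices:
                idx = np.unique(np.linspace(0, V.shape[0] - 1,
                                            self.max_vertices).round().astype(int))
                V = V[idx]
            if V.shape[0] < 2:
                raise ValueError("curve collapsed to a point; increase span "
                                 "or check the embedding")
            lam_new, d2 = _project_to_polyline(X, V)
            msd = float(d2.mean())
            lam = lam_new
            if abs(prev_msd - msd) < self.tol:
                break
            prev_msd = msd
        self.curve_points_ = V
        self.lambda_ = lam
        self.mean_sq_dist_ = float(d2.mean())
        self.n_iter_ = it
        return self

    def transform(self, X) -> np.ndarray:
        """Arclength of each point's projection onto the fitted curve."""
        X = np.asarray(X, dtype=np.float64)
        lam, _ = _project_to_polyline(X, self.curve_points_)
        return lam


def fit_principal_curve(embedding, smooth_span: float = 0.3,
                        max_iter: int = 50, tol: float = 1e-6,
                        seed: int = 0) -> PrincipalCurve:
    """Functional wrapper over :class:`PrincipalCurve`."""
    return PrincipalCurve(smooth_span=smooth_span, max_iter=max_iter, tol=tol,
                          random_state=seed).fit(np.asarray(embedding, float))


@dataclass
class TrajectoryResult:
    """Pseudotime along the fitted curve plus ordering-test results."""

    pseudotime: pd.Series          # per cell, in [0, 1]
    labels: pd.Series              # taxonomy label per cell
    curve_points: np.ndarray
    root_population: str
    embedding: pd.DataFrame
    ordering_tests: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["later", "earlier", "statistic", "p_value", "direction"]))


def assign_pseudotime(curve: PrincipalCurve, embedding: pd.DataFrame,
                      labels: pd.Series,
                      root_population: str) -> TrajectoryResult:
    """Normalized arclength pseudotime, oriented away from the root.

    Pseudotime is min-max scaled to [0, 1]; the orientation is flipped if
    the root population's median pseudotime exceeds the median of the
    remaining cells, so the root sits at the low end regardless of how the
    embedding axes point.
    """
    labels = labels.reindex(embedding.index)
    root_mask = (labels == root_population).to_numpy()
    if not root_mask.any():
        raise ValueError(f"root population {root_population!r} absent from the "
                         "trajectory cells")
    lam = curve.transform(embedding.to_numpy())
    span = lam.max() - lam.min()
    t = (lam - lam.min()) / span if span > 0 else np.zeros_like(lam)
    if root_mask.sum() < len(t):
        if np.median(t[root_mask]) > np.median(t[~root_mask]):
            t = 1.0 - t
    return TrajectoryResult(
        pseudotime=pd.Series(t, index=embedding.index, name="pseudotime"),
        labels=labels,
        curve_points=curve.curve_points_,
        root_population=root_population,
        embedding=embedding,
    )


def test_ordering(result: TrajectoryResult, label_a: str,
                  label_b: str) -> tuple[float, float, str]:
    """Rank-sum test of pseudotime between two labels.

    Returns ``(statistic, p, direction)`` where ``direction`` names the
    label with the larger median pseudotime (or ``"tie"``). Both labels
    need at least 3 cells with pseudotime. The result is also appended to
    ``result.ordering_tests``.
    """
    t = result.pseudotime
    a = t[(result.labels == label_a).to_numpy()].to_numpy()
    b = t[(result.labels == label_b).to_numpy()].to_numpy()
    for name, vals in ((label_a, a), (label_b, b)):
        if vals.size == 0:
            raise ValueError(f"label {name!r} has no cells with pseudotime")
        if vals.size < 3:
            raise ValueError(f"label {name!r} has fewer than 3 cells")
    stat, p = rank_sum_test(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = label_a
    elif med_b > med_a:
        direction = label_b
    else:
        direction = "tie"
    later = direction if direction != "tie" else "tie"
    earlier = ({label_a, label_b} - {direction}).pop() if direction != "tie" else "tie"
    row = pd.DataFrame([{"later": later, "earlier": earlier, "statistic": stat,
                         "p_value": p, "direction": direction}])
    result.ordering_tests = pd.concat(
        [result.ordering_tests, row], ignore_index=True,
    ) if len(result.ordering_tests) else row
    return stat, p, direction


def align_background_shift(norm, batch: pd.Series, background_genes,
                           reference_batch: str):
    """Crude batch alignment: match per-batch background-gene means.

    For each non-reference batch, the per-gene mean normalized expression
    over the given background genes is shifted to the reference batch's
    mean (values floored at zero). Intended for joining bone-marrow MSC
    profiles to tissue fibroblasts before a joint embedding; it removes a
    constant per-gene offset and nothing subtler.
    """
    import scipy.sparse as sp
    from anndata import AnnData

    dense = np.asarray(sp.csr_matrix(norm.X).todense(), dtype=np.float64)
    genes = norm.var_names.get_indexer(background_genes)
    genes = genes[genes >= 0]
    batch = batch.reindex(norm.obs_names)
    ref_rows = (batch == reference_batch).to_numpy()
    if not ref_rows.any():
        raise ValueError(f"reference batch {reference_batch!r} absent")
    ref_mean = dense[np.ix_(ref_rows, genes)].mean(axis=0)
    for b in batch.unique():
        if b == reference_batch:
            continue
        rows = (batch == b).to_numpy()
        shift = ref_mean - dense[np.ix_(rows, genes)].mean(axis=0)
        dense[np.ix_(rows, genes)] += shift
    np.maximum(dense, 0.0, out=dense)
    out = AnnData(X=sp.csr_matrix(dense), obs=norm.obs.copy(),
                  var=norm.var.copy())
    return out
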