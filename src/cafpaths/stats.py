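"""Rank statistics used across the pipeline.

Both primitives operate on midranks: the rank-sum test is the Mann-Whitney
U test (exact null enumeration for small tie-free samples, tie- and
continuity-corrected normal approximation otherwise), and Spearman's rho
is the Pearson correlation of midranks.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: largest pooled sample size for which the exact null is enumerated
EXACT_MAX_N = 12


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns ``(U, p)`` where ``U`` counts, with midrank tie credit, the
    pairs in which an ``x`` value exceeds a ``y`` value. With no ties and a
    pooled size of at most ``EXACT_MAX_N`` the p-value comes from full
    enumeration of the null distribution of U (two-sided:
    ``P(|U - mu| >= |u - mu|)``, which for the symmetric null equals the
    doubled tail); otherwise from the normal approximation with tie
    correction and a 0.5 continuity correction.

    ``alternative`` is one of ``"two-sided"``, ``"greater"`` (x tends
    larger) or ``"less"``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_MAX_N and not has_ties:
        base = np.arange(1, n + 1, dtype=float)
        offset = n1 * (n1 + 1) / 2.0
        count = total = 0
        eps = 1e-9
        for comb in combinations(range(n), n1):
            u_null = base[list(comb)].sum() - offset
            total += 1
            if alternative == "two-sided":
                count += abs(u_null - mu) >= abs(u - mu) - eps
            elif alternative == "greater":
                count += u_null >= u - eps
            else:
                count += u_null <= u + eps
        return u, count / total

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return u, 1.0
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / sd
        p = 2.0 * (1.0 - ndtr(z))
    elif alternative == "greater":
        p = 1.0 - ndtr((u - mu - 0.5) / sd)
    else:
        p = float(ndtr((u - mu + 0.5) / sd))
    return u, float(min(max(p, 0.0), 1.0))


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of midranks.

    Requires at least 3 paired observations. A constant input has no rank
    ordering; the correlation is undefined and NaN is returned with a
    warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman_rho requires at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        logger.warning("spearman_rho: constant input, correlation undefined")
        return float("nan")
    rx = (rx - rx.mean()) / sx
    ry = (ry - ry.mean()) / sy
    return float(np.clip((rx * ry).mean(), -1.0, 1.0))
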