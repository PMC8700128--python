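"""Symmetric association measures: PPCor, PSpCor, dCor/pdCor and KNN MI.

All four measures treat a pair (Xi, Xj) symmetrically. PPCor and PSpCor are
partial (rank) correlations given the remaining variables; pdCor is the
partial distance correlation built on U-centered distance matrices; MI is
the bivariate Kraskov k-nearest-neighbor estimate. Parametric t tests apply
to the first two; MI and pdCor are tested by one-sided permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from ._ksg import EstimationError, ksg_mi
from .inference import SignificanceResult, corr_ttest, permutation_test
from .simulators import TimeSeriesPanel

__all__ = [
    "CorrelationEstimate",
    "ppcor",
    "pspcor",
    "dcor",
    "pdcor",
    "mi_ksg",
    "EstimationError",
]

KNN_K_DEFAULT = 10


@dataclass(frozen=True)
class CorrelationEstimate:
    pair: tuple[int, int]
    value: float
    measure: str
    conditioning: tuple[int, ...]
    significance: SignificanceResult | None = None


def _columns(panel: TimeSeriesPanel | np.ndarray) -> np.ndarray:
    if isinstance(panel, TimeSeriesPanel):
        return panel.data
    return np.asarray(panel, dtype=float)


def _default_cond(K: int, i: int, j: int) -> tuple[int, ...]:
    return tuple(v for v in range(1, K + 1) if v not in (i, j))


def _residualize(y: np.ndarray, design: np.ndarray, what: str) -> np.ndarray:
    """OLS residuals of y on [1, design]."""
    X = np.column_stack([np.ones(len(y)), design]) if design.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError(f"singular conditioning design for {what}")
    return y - X @ coef


def _partial_corr(data: np.ndarray, i: int, j: int, cond: tuple[int, ...], name: str) -> float:
    zi = data[:, [c - 1 for c in cond]] if cond else np.empty((data.shape[0], 0))
    ri = _residualize(data[:, i - 1], zi, f"{name} columns {cond}")
    rj = _residualize(data[:, j - 1], zi, f"{name} columns {cond}")
    denom = np.sqrt((ri @ ri) * (rj @ rj))
    if denom == 0:
        raise EstimationError(f"constant residual series in {name}")
    return float(np.clip((ri @ rj) / denom, -1.0, 1.0))


def ppcor(
    panel: TimeSeriesPanel | np.ndarray,
    i: int,
    j: int,
    cond: tuple[int, ...] | None = None,
    alpha: float = 0.05,
) -> CorrelationEstimate:
    """Partial Pearson correlation of Xi and Xj given ``cond`` (1-based).

    For a single conditioner this equals the textbook formula
    (r_ij - r_ic r_cj) / sqrt((1 - r_ic^2)(1 - r_cj^2)); for larger sets it
    is computed as the correlation of OLS residuals, which is algebraically
    equivalent. Defaults to conditioning on all remaining variables.
    """
    data = _columns(panel)
    if cond is None:
        cond = _default_cond(data.shape[1], i, j)
    r = _partial_corr(data, i, j, cond, "ppcor")
    sig = corr_ttest(r, data.shape[0], alpha=alpha, n_cond=len(cond))
    return CorrelationEstimate((min(i, j), max(i, j)), r, "ppcor", tuple(cond), sig)


def pspcor(
    panel: TimeSeriesPanel | np.ndarray,
    i: int,
    j: int,
    cond: tuple[int, ...] | None = None,
    alpha: float = 0.05,
) -> CorrelationEstimate:
    """Partial Spearman correlation: PPCor on rank-transformed columns."""
    data = _columns(panel)
    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    if cond is None:
        cond = _default_cond(data.shape[1], i, j)
    r = _partial_corr(ranks, i, j, cond, "pspcor")
    sig = corr_ttest(r, data.shape[0], alpha=alpha, n_cond=len(cond))
    return CorrelationEstimate((min(i, j), max(i, j)), r, "pspcor", tuple(cond), sig)


# ---------------------------------------------------------------------------
# distance correlation


def _dist_matrix(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return squareform(pdist(a))


def _double_center(D: np.ndarray) -> np.ndarray:
    return D - D.mean(axis=0) - D.mean(axis=1)[:, None] + D.mean()


def _u_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    row = D.sum(axis=1)
    A = D - row[None, :] / (n - 2) - row[:, None] / (n - 2) + D.sum() / ((n - 1) * (n - 2))
    np.fill_diagonal(A, 0.0)
    return A


def _u_inner(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    return float((A * B).sum() / (n * (n - 3)))


def dcor(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two series, in [0, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("dcor needs n >= 4")
    A = _double_center(_dist_matrix(x))
    B = _double_center(_dist_matrix(y))
    vxy = (A * B).mean()
    vx = (A * A).mean()
    vy = (B * B).mean()
    if vx == 0 or vy == 0:
        raise EstimationError("zero distance variance (constant series)")
    r2 = vxy / np.sqrt(vx * vy)
    return float(np.sqrt(max(r2, 0.0)))


def _pdcor_value(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None,
    u_centered: bool = True,
) -> float:
    center = _u_center if u_centered else _double_center
    inner = _u_inner if u_centered else (lambda A, B: float((A * B).mean()))
    A = center(_dist_matrix(x))
    B = center(_dist_matrix(y))
    if z is not None and z.size:
        C = center(_dist_matrix(z))
        cc = inner(C, C)
        if cc > 0:
            A = A - (inner(A, C) / cc) * C
            B = B - (inner(B, C) / cc) * C
    aa = inner(A, A)
    bb = inner(B, B)
    if aa <= 0 or bb <= 0:
        return 0.0
    return float(inner(A, B) / np.sqrt(aa * bb))


def pdcor(
    panel: TimeSeriesPanel | np.ndarray,
    i: int,
    j: int,
    cond: tuple[int, ...] | None = None,
    alpha: float = 0.05,
    B: int = 100,
    rng: np.random.Generator | int | None = 0,
    u_centered: bool = True,
) -> CorrelationEstimate:
    """Partial distance correlation of Xi, Xj given ``cond``.

    Conditioning variables are stacked into one multivariate Z with Euclidean
    distances; the statistic projects the U-centered distance matrices of Xi
    and Xj onto the orthogonal complement of Z's in the Hilbert space of
    U-centered matrices (``u_centered=False`` switches to plain double
    centering for cross-checks). Significance by one-sided permutation.
    """
    data = _columns(panel)
    n = len(data)
    if n < 10:
        raise ValueError("pdcor needs n >= 10")
    if cond is None:
        cond = _default_cond(data.shape[1], i, j)
    x = data[:, i - 1]
    y = data[:, j - 1]
    z = data[:, [c - 1 for c in cond]] if cond else None

    # centering commutes with relabeling the sample, so the permutation null
    # only needs the centered matrix of x re-indexed, not recomputed
    center = _u_center if u_centered else _double_center
    inner = _u_inner if u_centered else (lambda A, B: float((A * B).mean()))
    A = center(_dist_matrix(x))
    Bm = center(_dist_matrix(y))
    if z is not None and z.size:
        C = center(_dist_matrix(z))
        cc = inner(C, C)
    else:
        C, cc = None, 0.0
    if cc > 0:
        Pb = Bm - (inner(Bm, C) / cc) * C
    else:
        Pb = Bm
    aa_fixed = inner(A, A)
    bb = inner(Pb, Pb)

    def stat(idx: np.ndarray, _unused: np.ndarray) -> float:
        Ap = A[np.ix_(idx, idx)]
        ac = inner(Ap, C) if cc > 0 else 0.0
        aa = aa_fixed - (ac * ac / cc if cc > 0 else 0.0)
        if aa <= 0 or bb <= 0:
            return 0.0
        # <C, Pb> = 0 by construction, so the projection of Ap only changes
        # the numerator through Ap itself
        return inner(Ap, Pb) / np.sqrt(aa * bb)

    sig = permutation_test(stat, np.arange(n), y, B=B, alpha=alpha, rng=rng)
    return CorrelationEstimate(
        (min(i, j), max(i, j)), sig.statistic, "pdcor", tuple(cond), sig
    )


def mi_ksg(
    x: np.ndarray,
    y: np.ndarray,
    k: int = KNN_K_DEFAULT,
    jitter_seed: int = 0,
) -> float:
    """Bivariate mutual information (nats), KSG type-1 estimator, max norm."""
    return ksg_mi(x, y, k=k, jitter_seed=jitter_seed)


def mi(
    panel: TimeSeriesPanel | np.ndarray,
    i: int,
    j: int,
    k: int = KNN_K_DEFAULT,
    alpha: float = 0.05,
    B: int = 100,
    rng: np.random.Generator | int | None = 0,
    jitter_seed: int | None = None,
) -> CorrelationEstimate:
    """MI between Xi and Xj with a one-sided permutation test."""
    data = _columns(panel)
    if jitter_seed is None:
        jitter_seed = getattr(panel, "seed", None) or 0
    x = data[:, i - 1]
    y = data[:, j - 1]

    def stat(xs: np.ndarray, ys: np.ndarray) -> float:
        return ksg_mi(xs, ys, k=k, jitter_seed=jitter_seed)

    sig = permutation_test(stat, x, y, B=B, alpha=alpha, rng=rng)
    return CorrelationEstimate((min(i, j), max(i, j)), sig.statistic, "mi", (), sig)
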