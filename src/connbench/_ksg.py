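"""k-nearest-neighbor (Kraskov-type) mutual-information estimators.

Internal module. Implements the type-1 KSG estimator of mutual information
and its conditional extension (Frenzel–Pompe), both under the maximum norm:

    I(X;Y)   = psi(k) + psi(n) - < psi(n_x+1) + psi(n_y+1) >
    I(X;Y|Z) = psi(k) - < psi(n_xz+1) + psi(n_yz+1) - psi(n_z+1) >

where n_* counts points strictly closer than the distance to the k-th
neighbor in the joint space. Ties are broken by a deterministic jitter of
amplitude 1e-10 times each column's standard deviation, seeded so results
are bit-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import psi

__all__ = ["EstimationError", "ksg_mi", "ksg_cmi"]

JITTER_AMPLITUDE = 1e-10


class EstimationError(RuntimeError):
    """Raised when an estimator cannot be computed (e.g. constant input)."""


def _as_columns(a: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _jittered(blocks: list[np.ndarray], jitter_seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(jitter_seed)
    out = []
    for b in blocks:
        b = _as_columns(b)
        sd = b.std(axis=0)
        if np.any(sd == 0):
            raise EstimationError("constant column passed to KNN estimator")
        out.append(b + rng.normal(0.0, JITTER_AMPLITUDE * sd, size=b.shape))
    return out


def _knn_radius(joint: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(joint)
    dist, _ = tree.query(joint, k=k + 1, p=np.inf)
    return dist[:, -1]


def _count_within(points: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Number of points strictly closer than eps (max norm), excluding self."""
    tree = cKDTree(points)
    r = np.nextafter(eps, 0.0)  # strict inequality; jitter has removed ties
    counts = tree.query_ball_point(points, r, p=np.inf, return_length=True)
    return counts - 1


def ksg_mi(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    jitter_seed: int = 0,
) -> float:
    """KSG type-1 mutual information estimate in nats."""
    xb, yb = _jittered([x, y], jitter_seed)
    n = xb.shape[0]
    if n <= 2 * k:
        raise EstimationError("sample too small for the requested k")
    eps = _knn_radius(np.hstack([xb, yb]), k)
    nx = _count_within(xb, eps)
    ny = _count_within(yb, eps)
    return float(psi(k) + psi(n) - np.mean(psi(nx + 1) + psi(ny + 1)))


def ksg_cmi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | Sequence[np.ndarray] | None,
    k: int = 10,
    jitter_seed: int = 0,
) -> float:
    """Conditional mutual information I(X;Y|Z) in nats (Frenzel–Pompe form).

    ``z`` may be None/empty (reduces exactly to :func:`ksg_mi`), a single
    array, or a sequence of conditioning columns.
    """
    if z is None:
        return ksg_mi(x, y, k=k, jitter_seed=jitter_seed)
    if isinstance(z, (list, tuple)):
        if len(z) == 0:
            return ksg_mi(x, y, k=k, jitter_seed=jitter_seed)
        z = np.column_stack([_as_columns(c) for c in z])
    else:
        z = _as_columns(z)
        if z.shape[1] == 0:
            return ksg_mi(x, y, k=k, jitter_seed=jitter_seed)
    xb, yb, zb = _jittered([x, y, z], jitter_seed)
    n = xb.shape[0]
    if n <= 2 * k:
        raise EstimationError("sample too small for the requested k")
    eps = _knn_radius(np.hstack([xb, yb, zb]), k)
    n_xz = _count_within(np.hstack([xb, zb]), eps)
    n_yz = _count_within(np.hstack([yb, zb]), eps)
    n_z = _count_within(zb, eps)
    return float(psi(k) - np.mean(psi(n_xz + 1) + psi(n_yz + 1) - psi(n_z + 1)))
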