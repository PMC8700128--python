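"""Information-theoretic causality on non-uniform mixed embeddings.

Both PTENUE and PMIME0 first build, per target variable, a *mixed embedding*:
an ordered set of (variable, lag) terms selected greedily to explain the
target's next value. At each step the candidate with the largest conditional
mutual information given the already-selected terms is tentatively added and
kept only if its CMI beats the (1 - alpha) quantile of a null ensemble
obtained by circularly time-shifting the candidate column (100 surrogates,
minimum shift 20); selection stops at the first rejection. Because the
surrogate test is built in, a positive reported statistic *is* the
significance call — no outer test is applied.

PTENUE uses lagged candidates only (lags 1..Lmax) and reports the raw CMI of
the driver's selected terms given the rest of the embedding. PMIME0 adds
zero-lag candidates of the other variables — lag 0 means simultaneous with
the predicted sample — and reports, per ordered pair, two normalized ratios:
the lagged contribution R_lag = I(x_{t+1}; w_j^{lag} | w \\ w_j^{lag}) /
I(x_{t+1}; w) and the analogous contemporaneous contribution of the lag-0
term. Ratios for a pair are exactly zero when no term of that driver was
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._ksg import EstimationError, ksg_cmi, ksg_mi
from .simulators import TimeSeriesPanel

__all__ = [
    "MixedEmbedding",
    "InfoCausalResult",
    "cmi_ksg",
    "build_embedding",
    "ptenue",
    "ptenue_matrix",
    "pmime0",
    "pmime0_matrix",
    "EstimationError",
]

LMAX_DEFAULT = 4
KNN_K_DEFAULT = 10
N_SURROGATES_DEFAULT = 100
PTENUE_ALPHA = 0.01
PMIME0_ALPHA = 0.05
MIN_SHIFT = 20

Term = tuple[int, int]  # (variable 1-based, lag >= 0)


def cmi_ksg(
    x: np.ndarray,
    y: np.ndarray,
    cond: np.ndarray | list[np.ndarray] | None = None,
    k: int = KNN_K_DEFAULT,
    jitter_seed: int = 0,
) -> float:
    """Conditional mutual information I(x; y | cond) in nats (KNN estimator)."""
    return ksg_cmi(x, y, cond, k=k, jitter_seed=jitter_seed)


@dataclass
class MixedEmbedding:
    target: int
    terms: list[Term] = field(default_factory=list)
    cmis: list[float] = field(default_factory=list)
    mode: str = "lagged-only"
    Lmax: int = LMAX_DEFAULT

    def terms_of(self, v: int, *, lagged_only: bool = False) -> list[Term]:
        return [
            t for t in self.terms if t[0] == v and (t[1] >= 1 or not lagged_only)
        ]


@dataclass(frozen=True)
class InfoCausalResult:
    source: int
    target: int
    lagged: float
    lagged_significant: bool
    contemporaneous: float | None = None
    contemporaneous_significant: bool | None = None


def _aligned(data: np.ndarray, target: int, Lmax: int) -> tuple[np.ndarray, dict]:
    """Response vector x_{target, t} for t >= Lmax and a term-column getter."""
    response = data[Lmax:, target - 1]

    def col(term: Term) -> np.ndarray:
        v, lag = term
        n = data.shape[0]
        return data[Lmax - lag : n - lag, v - 1]

    return response, col


def build_embedding(
    panel: TimeSeriesPanel | np.ndarray,
    target: int,
    Lmax: int = LMAX_DEFAULT,
    mode: str = "lagged-only",
    n_surrogates: int = N_SURROGATES_DEFAULT,
    alpha: float = PMIME0_ALPHA,
    k: int = KNN_K_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> MixedEmbedding:
    """Greedy surrogate-tested selection of a mixed embedding for one target.

    ``mode`` is ``"lagged-only"`` (PTENUE) or ``"with-zero-lag"`` (PMIME0);
    zero-lag candidates are offered for every variable other than the target
    and are taken simultaneous with the predicted sample.
    """
    if Lmax < 1:
        raise ValueError("Lmax must be >= 1")
    if mode not in ("lagged-only", "with-zero-lag"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    rng = np.random.default_rng(rng)
    jitter_seed = int((getattr(panel, "seed", None) or 0) * 31 + target)
    K = data.shape[1]
    response, col = _aligned(data, target, Lmax)
    m = len(response)
    if m <= MIN_SHIFT * 2 + 10:
        raise ValueError("series too short for shift surrogates")

    candidates: list[Term] = [
        (v, lag) for v in range(1, K + 1) for lag in range(1, Lmax + 1)
    ]
    if mode == "with-zero-lag":
        candidates += [(v, 0) for v in range(1, K + 1) if v != target]

    emb = MixedEmbedding(target=target, mode=mode, Lmax=Lmax)
    selected_cols: list[np.ndarray] = []
    while candidates:
        best_term, best_cmi = None, -np.inf
        for term in candidates:
            val = ksg_cmi(response, col(term), selected_cols, k=k, jitter_seed=jitter_seed)
            if val > best_cmi:
                best_term, best_cmi = term, val
        c = col(best_term)
        shifts = rng.integers(MIN_SHIFT, m - MIN_SHIFT, size=n_surrogates)
        null = np.array(
            [
                ksg_cmi(response, np.roll(c, s), selected_cols, k=k, jitter_seed=jitter_seed)
                for s in shifts
            ]
        )
        if best_cmi <= np.quantile(null, 1.0 - alpha):
            break
        emb.terms.append(best_term)
        emb.cmis.append(best_cmi)
        selected_cols.append(c)
        candidates.remove(best_term)
    return emb


def _lagged_stat(
    response: np.ndarray,
    col,
    emb: MixedEmbedding,
    src_terms: list[Term],
    k: int,
    jitter_seed: int,
) -> float:
    """I(response; src terms | remaining embedding terms), floored at zero."""
    rest = [col(t) for t in emb.terms if t not in src_terms]
    src = np.column_stack([col(t) for t in src_terms])
    val = ksg_cmi(response, src, rest, k=k, jitter_seed=jitter_seed)
    return max(val, 0.0)


def _result_from_embedding(
    data: np.ndarray,
    emb: MixedEmbedding,
    src: int,
    k: int,
    jitter_seed: int,
    normalize: bool,
) -> InfoCausalResult:
    response, col = _aligned(data, emb.target, emb.Lmax)
    with_zero = emb.mode == "with-zero-lag"

    denom = None
    if normalize and emb.terms:
        w = np.column_stack([col(t) for t in emb.terms])
        denom = ksg_mi(response, w, k=k, jitter_seed=jitter_seed)
        if denom <= 0:
            warnings.warn(
                f"nonpositive I(response; embedding) for target {emb.target}; "
                "reporting zero statistics"
            )
            return InfoCausalResult(src, emb.target, 0.0, False, 0.0, False) if with_zero \
                else InfoCausalResult(src, emb.target, 0.0, False)

    def ratio(terms: list[Term]) -> float:
        if not terms:
            return 0.0
        val = _lagged_stat(response, col, emb, terms, k, jitter_seed)
        if normalize and denom:
            val = max(val / denom, 0.0)
        return val

    lag_stat = ratio(emb.terms_of(src, lagged_only=True))
    if not with_zero:
        return InfoCausalResult(src, emb.target, lag_stat, lag_stat > 0)
    zero_terms = [t for t in emb.terms if t == (src, 0)]
    con_stat = ratio(zero_terms)
    return InfoCausalResult(
        src, emb.target, lag_stat, lag_stat > 0, con_stat, con_stat > 0
    )


def ptenue(
    panel: TimeSeriesPanel | np.ndarray,
    src: int,
    dst: int,
    Lmax: int = LMAX_DEFAULT,
    k: int = KNN_K_DEFAULT,
    alpha: float = PTENUE_ALPHA,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> InfoCausalResult:
    """Partial transfer entropy of Xsrc -> Xdst on a non-uniform embedding."""
    emb = build_embedding(
        panel, dst, Lmax=Lmax, mode="lagged-only",
        n_surrogates=n_surrogates, alpha=alpha, k=k, rng=rng,
    )
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    jitter_seed = int((getattr(panel, "seed", None) or 0) * 31 + dst)
    return _result_from_embedding(data, emb, src, k, jitter_seed, normalize=False)


def ptenue_matrix(
    panel: TimeSeriesPanel | np.ndarray,
    Lmax: int = LMAX_DEFAULT,
    k: int = KNN_K_DEFAULT,
    alpha: float = PTENUE_ALPHA,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    rng: np.random.Generator | int | None = 0,
    targets: list[int] | None = None,
) -> dict[tuple[int, int], InfoCausalResult]:
    """PTENUE for all ordered pairs, building one embedding per target."""
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    K = data.shape[1]
    rng = np.random.default_rng(rng)
    out: dict[tuple[int, int], InfoCausalResult] = {}
    for i in targets or range(1, K + 1):
        emb = build_embedding(
            panel, i, Lmax=Lmax, mode="lagged-only",
            n_surrogates=n_surrogates, alpha=alpha, k=k, rng=rng,
        )
        jitter_seed = int((getattr(panel, "seed", None) or 0) * 31 + i)
        for j in range(1, K + 1):
            if j != i:
                out[(j, i)] = _result_from_embedding(
                    data, emb, j, k, jitter_seed, normalize=False
                )
    return out


def pmime0(
    panel: TimeSeriesPanel | np.ndarray,
    src: int,
    dst: int,
    Lmax: int = LMAX_DEFAULT,
    k: int = KNN_K_DEFAULT,
    alpha: float = PMIME0_ALPHA,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> InfoCausalResult:
    """PMIME with zero-lag terms: lagged and contemporaneous ratios for one pair."""
    emb = build_embedding(
        panel, dst, Lmax=Lmax, mode="with-zero-lag",
        n_surrogates=n_surrogates, alpha=alpha, k=k, rng=rng,
    )
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    jitter_seed = int((getattr(panel, "seed", None) or 0) * 31 + dst)
    return _result_from_embedding(data, emb, src, k, jitter_seed, normalize=True)


def pmime0_matrix(
    panel: TimeSeriesPanel | np.ndarray,
    Lmax: int = LMAX_DEFAULT,
    k: int = KNN_K_DEFAULT,
    alpha: float = PMIME0_ALPHA,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    rng: np.random.Generator | int | None = 0,
    targets: list[int] | None = None,
) -> dict[tuple[int, int], InfoCausalResult]:
    """PMIME0 for all ordered pairs, one with-zero-lag embedding per target."""
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    K = data.shape[1]
    rng = np.random.default_rng(rng)
    out: dict[tuple[int, int], InfoCausalResult] = {}
    for i in targets or range(1, K + 1):
        emb = build_embedding(
            panel, i, Lmax=Lmax, mode="with-zero-lag",
            n_surrogates=n_surrogates, alpha=alpha, k=k, rng=rng,
        )
        jitter_seed = int((getattr(panel, "seed", None) or 0) * 31 + i)
        for j in range(1, K + 1):
            if j != i:
                out[(j, i)] = _result_from_embedding(
                    data, emb, j, k, jitter_seed, normalize=True
                )
    return out
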