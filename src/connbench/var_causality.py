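"""VAR-model-based directed measures: CGCI, RCGCI and PDC.

The conditional Granger causality index for a driver Xj and target Xi given
the remaining variables is

    CGCI_{j->i} = ln(S_R^2 / S_U^2) >= 0,

the log-ratio of restricted (no Xj lags) to unrestricted residual variances
of per-equation OLS fits of a VAR(P); significance by the nested F test.
RCGCI replaces the full lag set with a sparse subset chosen per target by a
greedy backward-in-time BIC search: lag l+1 of a variable becomes a
candidate only once lag l has entered the model. Partial directed coherence
works on the same VAR in the frequency domain,

    PDC_{j->i}(f) = |A-bar_{i,j}(f)| / sqrt(sum_k |A-bar_{k,j}(f)|^2),

with A-bar(f) = I - sum_r A_r e^{-i 2 pi f r}, so that the squared PDC values
in each source column sum to one at every frequency. Point-wise significance
uses the asymptotic chi-squared threshold for the null of zero PDC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import SignificanceResult, granger_ftest
from .simulators import TimeSeriesPanel

__all__ = [
    "VarFit",
    "GrangerResult",
    "PdcResult",
    "fit_var",
    "cgci",
    "cgci_matrix",
    "select_terms_bts",
    "rcgci",
    "rcgci_matrix",
    "pdc",
]

PDC_FREQUENCIES_DEFAULT = 256


class EstimationError(RuntimeError):
    pass


Term = tuple[int, int]  # (variable, lag), variable 1-based, lag >= 1


@dataclass
class VarFit:
    order: int
    terms: dict[int, list[Term]]  # per-target regressor terms
    coefs: dict[int, np.ndarray]  # per-target [intercept, term coefs]
    residuals: np.ndarray  # (n - align) x K
    sse: np.ndarray  # per-equation residual sum of squares
    n_eff: int

    @property
    def sigma2(self) -> np.ndarray:
        return self.sse / self.n_eff

    def coef_matrices(self) -> np.ndarray:
        """(P, K, K) array A with A[r-1, i, j] the lag-r effect of Xj on Xi."""
        K = self.residuals.shape[1]
        A = np.zeros((self.order, K, K))
        for i in range(1, K + 1):
            for idx, (v, lag) in enumerate(self.terms[i]):
                A[lag - 1, i - 1, v - 1] = self.coefs[i][idx + 1]
        return A


def _data(panel: TimeSeriesPanel | np.ndarray) -> np.ndarray:
    if isinstance(panel, TimeSeriesPanel):
        return panel.data
    return np.asarray(panel, dtype=float)


def _design(data: np.ndarray, terms: list[Term], align: int) -> np.ndarray:
    n = data.shape[0]
    cols = [np.ones(n - align)]
    for v, lag in terms:
        cols.append(data[align - lag : n - lag, v - 1])
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError("rank-deficient regression design")
    resid = y - X @ coef
    return coef, resid, float(resid @ resid)


def fit_var(
    panel: TimeSeriesPanel | np.ndarray,
    P: int,
    terms: dict[int, list[Term]] | None = None,
    align: int | None = None,
) -> VarFit:
    """Per-equation OLS fit of a VAR(P) with intercepts.

    ``terms`` optionally restricts each target equation to a subset of
    (variable, lag) regressors; ``align`` fixes the number of leading rows
    dropped (defaults to the largest lag used) so nested fits share samples.
    """
    data = _data(panel)
    n, K = data.shape
    if terms is None:
        full = [(v, lag) for lag in range(1, P + 1) for v in range(1, K + 1)]
        terms = {i: list(full) for i in range(1, K + 1)}
    max_lag = max((lag for tl in terms.values() for _, lag in tl), default=0)
    if align is None:
        align = max(max_lag, P)
    if align < max_lag:
        raise ValueError("align smaller than the largest lag used")
    if n <= align + max(len(tl) for tl in terms.values()) + 10:
        raise ValueError("sample too short for the requested model")
    coefs: dict[int, np.ndarray] = {}
    resids = np.empty((n - align, K))
    sse = np.empty(K)
    for i in range(1, K + 1):
        X = _design(data, terms[i], align)
        y = data[align:, i - 1]
        coefs[i], resids[:, i - 1], sse[i - 1] = _ols(X, y)
    return VarFit(
        order=P, terms=terms, coefs=coefs, residuals=resids, sse=sse, n_eff=n - align
    )


@dataclass(frozen=True)
class GrangerResult:
    source: int
    target: int
    statistic: float
    significance: SignificanceResult
    selected_terms: tuple[Term, ...] = ()


def _cgci_for_target(
    data: np.ndarray, i: int, P: int, alpha: float
) -> dict[int, GrangerResult]:
    """CGCI of every source j -> fixed target i, sharing the unrestricted fit."""
    n, K = data.shape
    full = [(v, lag) for lag in range(1, P + 1) for v in range(1, K + 1)]
    Xu = _design(data, full, P)
    y = data[P:, i - 1]
    _, _, sse_u = _ols(Xu, y)
    out: dict[int, GrangerResult] = {}
    for j in range(1, K + 1):
        if j == i:
            continue
        restricted = [t for t in full if t[0] != j]
        _, _, sse_r = _ols(_design(data, restricted, P), y)
        stat = float(np.log(sse_r / sse_u)) if sse_u > 0 else np.inf
        sig = granger_ftest(
            sse_r, sse_u, q=P, n_eff=n - P, p_params=len(full) + 1, alpha=alpha
        )
        out[j] = GrangerResult(j, i, max(stat, 0.0), sig)
    return out


def cgci(
    panel: TimeSeriesPanel | np.ndarray,
    src: int,
    dst: int,
    P: int,
    alpha: float = 0.05,
) -> GrangerResult:
    """Conditional Granger causality index of Xsrc -> Xdst given the rest."""
    if src == dst:
        raise ValueError("self-causality is not scored")
    return _cgci_for_target(_data(panel), dst, P, alpha)[src]


def cgci_matrix(
    panel: TimeSeriesPanel | np.ndarray, P: int, alpha: float = 0.05
) -> dict[tuple[int, int], GrangerResult]:
    """CGCI for every ordered pair; keys are (source, target)."""
    data = _data(panel)
    out: dict[tuple[int, int], GrangerResult] = {}
    for i in range(1, data.shape[1] + 1):
        for j, res in _cgci_for_target(data, i, P, alpha).items():
            out[(j, i)] = res
    return out


def select_terms_bts(
    data: np.ndarray, target: int, Lmax: int
) -> list[Term]:
    """Greedy stepwise BIC selection of lagged terms for one target.

    Candidates are all (variable, lag) pairs with lag <= Lmax. At each step
    the candidate lowering the regression BIC most is added; ties between
    equally good candidates break toward the more recent lag (terms are
    examined backward in time). Selection stops when no candidate lowers
    the BIC.
    """
    n = data.shape[0] - Lmax
    y = data[Lmax:, target - 1]
    selected: list[Term] = []
    candidates: list[Term] = [
        (v, lag) for lag in range(1, Lmax + 1) for v in range(1, data.shape[1] + 1)
    ]

    def bic(terms: list[Term]) -> float:
        _, _, sse = _ols(_design(data, terms, Lmax), y)
        if sse <= 0:
            return -np.inf
        return n * np.log(sse / n) + (len(terms) + 1) * np.log(n)

    current = bic(selected)
    while candidates:
        scores = [(bic(selected + [c]), c[1], c[0], c) for c in candidates]
        best_bic, _, _, best = min(scores, key=lambda s: s[:3])
        if best_bic >= current:
            break
        selected.append(best)
        candidates.remove(best)
        current = best_bic
    return selected


def _rcgci_for_target(
    data: np.ndarray, i: int, Lmax: int, alpha: float
) -> dict[int, GrangerResult]:
    n, K = data.shape
    selected = select_terms_bts(data, i, Lmax)
    y = data[Lmax:, i - 1]
    _, _, sse_u = _ols(_design(data, selected, Lmax), y)
    out: dict[int, GrangerResult] = {}
    for j in range(1, K + 1):
        if j == i:
            continue
        j_terms = [t for t in selected if t[0] == j]
        if not j_terms:
            sig = SignificanceResult(0.0, 1.0, False, "granger_ftest", alpha)
            out[j] = GrangerResult(j, i, 0.0, sig, tuple(selected))
            continue
        restricted = [t for t in selected if t[0] != j]
        _, _, sse_r = _ols(_design(data, restricted, Lmax), y)
        stat = float(np.log(sse_r / sse_u)) if sse_u > 0 else np.inf
        sig = granger_ftest(
            sse_r,
            sse_u,
            q=len(j_terms),
            n_eff=n - Lmax,
            p_params=len(selected) + 1,
            alpha=alpha,
        )
        out[j] = GrangerResult(j, i, max(stat, 0.0), sig, tuple(selected))
    return out


def rcgci(
    panel: TimeSeriesPanel | np.ndarray,
    src: int,
    dst: int,
    Lmax: int = 4,
    alpha: float = 0.05,
) -> GrangerResult:
    """Restricted CGCI: CGCI on the backward-in-time-selected term subset."""
    if src == dst:
        raise ValueError("self-causality is not scored")
    return _rcgci_for_target(_data(panel), dst, Lmax, alpha)[src]


def rcgci_matrix(
    panel: TimeSeriesPanel | np.ndarray, Lmax: int = 4, alpha: float = 0.05
) -> dict[tuple[int, int], GrangerResult]:
    data = _data(panel)
    out: dict[tuple[int, int], GrangerResult] = {}
    for i in range(1, data.shape[1] + 1):
        for j, res in _rcgci_for_target(data, i, Lmax, alpha).items():
            out[(j, i)] = res
    return out


# ---------------------------------------------------------------------------
# partial directed coherence


@dataclass
class PdcResult:
    frequencies: np.ndarray  # (M,) in [0, 0.5]
    values: np.ndarray  # (M, K, K); [f, i, j] = PDC_{j->i}(f)
    significant: np.ndarray  # (M, K, K) boolean, diagonal False
    fraction_significant: np.ndarray  # (K, K); [i, j] over frequencies, j->i
    stable: bool


def _abar(A: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """(M, K, K) complex A-bar(f) = I - sum_r A_r exp(-i 2 pi f r)."""
    P, K, _ = A.shape
    M = len(freqs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, P + 1)))  # (M, P)
    out = np.broadcast_to(np.eye(K, dtype=complex), (M, K, K)).copy()
    out -= np.einsum("mp,pik->mik", phase, A.astype(complex))
    return out


def pdc(
    panel: TimeSeriesPanel | np.ndarray,
    P: int,
    M: int = PDC_FREQUENCIES_DEFAULT,
    alpha: float = 0.05,
    sqrt_denominator: bool = True,
) -> PdcResult:
    """Partial directed coherence over M frequencies in [0, 0.5].

    Values use the column-normalized form with the square root in the
    denominator (``sqrt_denominator=False`` drops it, for comparison).
    Point-wise significance tests |A-bar_{i,j}(f)|^2 against the asymptotic
    chi-squared(1) threshold with the regressor-covariance variance factor;
    an unstable fitted VAR triggers a warning but values are still returned.
    """
    data = _data(panel)
    n, K = data.shape
    fit = fit_var(data, P)
    A = fit.coef_matrices()

    companion = np.zeros((K * P, K * P))
    companion[:K, :] = np.concatenate([A[r] for r in range(P)], axis=1)
    if P > 1:
        companion[K:, :-K] = np.eye(K * (P - 1))
    stable = bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)
    if not stable:
        warnings.warn("fitted VAR is unstable; PDC values may be unreliable")

    freqs = np.linspace(0.0, 0.5, M)
    Abar = _abar(A, freqs)
    mag2 = np.abs(Abar) ** 2  # (M, K, K)
    denom2 = mag2.sum(axis=1)  # (M, K): sum over rows k for each column j
    denom = np.sqrt(denom2) if sqrt_denominator else denom2
    values = np.abs(Abar) / denom[:, None, :]

    # regressor covariance (stacked lags, order: lag r block, variable v)
    lagged = np.column_stack(
        [data[P - lag : n - lag, v] for lag in range(1, P + 1) for v in range(K)]
    )
    R = np.cov(lagged, rowvar=False)
    Rinv = np.linalg.pinv(R)
    sigma2 = fit.sigma2

    w = 2.0 * np.pi * freqs
    rlags = np.arange(1, P + 1)
    cosw = np.cos(np.outer(w, rlags))  # (M, P)
    sinw = np.sin(np.outer(w, rlags))
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    n_eff = fit.n_eff

    significant = np.zeros((M, K, K), dtype=bool)
    for j in range(K):
        idx = [r * K + j for r in range(P)]
        Hj = Rinv[np.ix_(idx, idx)]  # (P, P)
        # variance factor sum_{r,s} H_{rs} (cos r w cos s w + sin r w sin s w)
        var_fac = np.einsum("mr,rs,ms->m", cosw, Hj, cosw) + np.einsum(
            "mr,rs,ms->m", sinw, Hj, sinw
        )
        var_fac = np.maximum(var_fac, 0.0)
        for i in range(K):
            if i == j:
                continue
            thresh = sigma2[i] * var_fac * crit / n_eff
            significant[:, i, j] = mag2[:, i, j] > thresh
    frac = significant.mean(axis=0)
    return PdcResult(freqs, values, significant, frac, stable)
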