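"""Shared significance machinery.

Three test families are used by the estimator modules:

* a parametric Student-t test for (partial) correlation coefficients,
* one-sided permutation tests with the add-one rule for MI and pdCor,
* the nested-regression F test for the VAR-based Granger measures.

By convention the correlation t statistic uses n - 2 degrees of freedom
regardless of the size of the conditioning set (a ``strict_df`` switch
subtracts |cond| as well); at n = 2000 the difference is negligible.
Permutation tests shuffle one series i.i.d., which destroys autocorrelation —
a deliberate property of the benchmark: under lagged dependence it inflates
correlation detections, which is exactly the failure mode being measured.
No multiple-testing correction is applied anywhere; every comparison is at
the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = ["SignificanceResult", "corr_ttest", "permutation_test", "granger_ftest"]

ALPHA_DEFAULT = 0.05
N_PERMUTATIONS_DEFAULT = 100


@dataclass(frozen=True)
class SignificanceResult:
    statistic: float
    p_value: float
    significant: bool
    method: str
    alpha: float
    n_resamples: int = 0
    saturated: bool = False


def corr_ttest(
    r: float,
    n: int,
    alpha: float = ALPHA_DEFAULT,
    n_cond: int = 0,
    *,
    strict_df: bool = False,
) -> SignificanceResult:
    """Two-sided t test for a (partial) correlation coefficient.

    t = r * sqrt(df) / sqrt(1 - r^2) on df = n - 2 degrees of freedom
    (df = n - 2 - n_cond with ``strict_df``).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    df = n - 2 - (n_cond if strict_df else 0)
    if df <= 0:
        raise ValueError("nonpositive degrees of freedom")
    if abs(r) >= 1.0:
        return SignificanceResult(
            statistic=np.inf if r > 0 else -np.inf,
            p_value=0.0,
            significant=True,
            method="corr_ttest",
            alpha=alpha,
            saturated=True,
        )
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SignificanceResult(
        statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        method="corr_ttest",
        alpha=alpha,
    )


def permutation_test(
    stat_fn: Callable[..., float],
    x: np.ndarray,
    y: np.ndarray,
    cond: Sequence[np.ndarray] | None = None,
    B: int = N_PERMUTATIONS_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> SignificanceResult:
    """One-sided permutation test shuffling ``x`` only.

    ``stat_fn(x, y)`` (or ``stat_fn(x, y, cond)``) must return a scalar whose
    large values indicate dependence. The p-value uses the add-one rule
    p = (1 + #{null >= observed}) / (1 + B), so p is in (0, 1].
    """
    if B < 20:
        raise ValueError("B must be >= 20")
    rng = np.random.default_rng(rng)
    args = () if cond is None else (cond,)
    observed = float(stat_fn(x, y, *args))
    exceed = 0
    for _ in range(B):
        xs = rng.permutation(x)
        if float(stat_fn(xs, y, *args)) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + B)
    return SignificanceResult(
        statistic=observed,
        p_value=p,
        significant=bool(p < alpha),
        method="permutation",
        alpha=alpha,
        n_resamples=B,
    )


def granger_ftest(
    sse_r: float,
    sse_u: float,
    q: int,
    n_eff: int,
    p_params: int,
    alpha: float = ALPHA_DEFAULT,
) -> SignificanceResult:
    """Nested-regression F test.

    F = ((sse_r - sse_u)/q) / (sse_u/(n_eff - p_params)) on (q, n_eff - p_params)
    degrees of freedom, where sse_r/sse_u are restricted/unrestricted residual
    sums of squares, q the number of restrictions and p_params the number of
    parameters in the unrestricted model.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    df2 = n_eff - p_params
    if df2 <= 0:
        raise ValueError("nonpositive denominator degrees of freedom")
    if not (sse_r >= 0 and sse_u > 0):
        raise ValueError("need sse_r >= 0 and sse_u > 0")
    # OLS nesting guarantees sse_r >= sse_u; clip tiny negative rounding noise
    num = max(sse_r - sse_u, 0.0) / q
    f = num / (sse_u / df2)
    p = stats.f.sf(f, q, df2)
    return SignificanceResult(
        statistic=float(f),
        p_value=float(p),
        significant=bool(p < alpha),
        method="granger_ftest",
        alpha=alpha,
    )
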