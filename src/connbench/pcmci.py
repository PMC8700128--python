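"""Constraint-based lagged + contemporaneous causal discovery (PCMCI+ style).

The procedure has two phases. Phase 1 runs, per target variable, an
iterative lagged-parent pre-selection: every (variable, lag) candidate with
lag 1..tau_max is tested for conditional independence of the target given
the q strongest remaining candidates, with q increasing until the surviving
set stabilizes. Phase 2 applies momentary conditional-independence tests:
each surviving lagged link is re-tested conditioning on the discovered
parents of both endpoints, and every variable pair is tested at lag zero
given both endpoints' lagged parents to decide contemporaneous adjacency.
Contemporaneous edges are then oriented by collider detection on unshielded
triples with the majority rule; unresolved links stay unoriented and are
scored in both directions downstream.

Two conditional-independence tests are available: ``parcorr`` (partial
correlation with a Student-t test; exact for linear-Gaussian data) and
``cmi-knn`` (the KNN conditional mutual information with a local permutation
null that shuffles the tested variable only within neighborhoods of similar
conditioning values, preserving the dependence on the conditioners).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from ._ksg import ksg_cmi
from .simulators import TimeSeriesPanel

__all__ = ["CIDecision", "CausalGraph", "ci_test", "pcmci_plus"]

TAU_MAX_DEFAULT = 4
KNN_K_DEFAULT = 10
K_PERM_DEFAULT = 5
N_PERM_DEFAULT = 100

Term = tuple[int, int]  # (variable 1-based, lag >= 0)


@dataclass(frozen=True)
class CIDecision:
    x: Term
    y: Term
    cond: tuple[Term, ...]
    statistic: float
    p_value: float
    independent: bool


@dataclass
class CausalGraph:
    K: int
    tau_max: int
    lagged: set[tuple[int, int, int]] = field(default_factory=set)  # (src, lag, dst)
    contemporaneous: list[tuple[int, int, str]] = field(default_factory=list)
    # (a, b, mark) with mark "-->" (a to b) or "o-o" (unoriented)

    def lagged_pairs(self) -> set[tuple[int, int]]:
        return {(j, i) for j, _, i in self.lagged}

    def contemporaneous_ordered(self) -> set[tuple[int, int]]:
        """Ordered pairs implied by the contemporaneous edges.

        Directed edges count one way; unoriented edges count both ways.
        """
        out: set[tuple[int, int]] = set()
        for a, b, mark in self.contemporaneous:
            out.add((a, b))
            if mark == "o-o":
                out.add((b, a))
        return out


def _term_columns(data: np.ndarray, terms: list[Term]) -> np.ndarray:
    max_lag = max(lag for _, lag in terms)
    n = data.shape[0]
    return np.column_stack(
        [data[max_lag - lag : n - lag, v - 1] for v, lag in terms]
    )


def _local_permutation(
    x: np.ndarray,
    cond: np.ndarray | None,
    k_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permute x approximately preserving its dependence on cond."""
    n = len(x)
    if cond is None or cond.size == 0:
        return rng.permutation(x)
    tree = cKDTree(cond)
    _, nbrs = tree.query(cond, k=min(k_perm, n), p=np.inf)
    order = rng.permutation(n)
    used = np.zeros(n, dtype=bool)
    mapping = np.empty(n, dtype=int)
    for i in order:
        choices = rng.permutation(nbrs[i])
        for j in choices:
            if not used[j]:
                mapping[i] = j
                used[j] = True
                break
        else:
            mapping[i] = rng.choice(nbrs[i])
    return x[mapping]


def ci_test(
    panel: TimeSeriesPanel | np.ndarray,
    x_term: Term,
    y_term: Term,
    cond: list[Term] | tuple[Term, ...] = (),
    method: str = "parcorr",
    alpha: float = 0.05,
    k: int = KNN_K_DEFAULT,
    k_perm: int = K_PERM_DEFAULT,
    n_perm: int = N_PERM_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> CIDecision:
    """Conditional-independence test between two lagged terms.

    Terms are (variable, lag) with the y term conventionally at lag 0; all
    series are aligned on the largest lag involved before testing.
    """
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    cond = tuple(cond)
    terms = [x_term, y_term, *cond]
    cols = _term_columns(data, terms)
    if cols.shape[0] < 10:
        raise ValueError("empty or too-short aligned sample")
    x, y = cols[:, 0], cols[:, 1]
    z = cols[:, 2:] if cond else None

    if method == "parcorr":
        if z is not None:
            Z1 = np.column_stack([np.ones(len(x)), z])
            x = x - Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]
            y = y - Z1 @ np.linalg.lstsq(Z1, y, rcond=None)[0]
        denom = np.sqrt((x @ x) * (y @ y))
        r = float(np.clip((x @ y) / denom, -1.0, 1.0)) if denom > 0 else 0.0
        df = len(x) - 2 - (z.shape[1] if z is not None else 0)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df) / np.sqrt(1 - r * r)
            p = 2.0 * float(stats.t.sf(abs(t), df))
        return CIDecision(x_term, y_term, cond, r, p, p > alpha)

    if method == "cmi-knn":
        rng = np.random.default_rng(rng)
        jitter_seed = int((getattr(panel, "seed", None) or 0) * 97 + 13)
        obs = ksg_cmi(x, y, z, k=k, jitter_seed=jitter_seed)
        exceed = 0
        for _ in range(n_perm):
            xs = _local_permutation(x, z, k_perm, rng)
            if ksg_cmi(xs, y, z, k=k, jitter_seed=jitter_seed) >= obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        return CIDecision(x_term, y_term, cond, obs, p, p > alpha)

    raise ValueError(f"unknown CI test method {method!r}")


def _phase1_parents(
    panel, target: int, tau_max: int, pc_alpha: float, test_kwargs: dict
) -> list[tuple[Term, float]]:
    """PC1-style lagged candidate pruning for one target."""
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    K = data.shape[1]
    strength: dict[Term, float] = {}
    survivors: list[Term] = []
    for v in range(1, K + 1):
        for tau in range(1, tau_max + 1):
            d = ci_test(panel, (v, tau), (target, 0), (), **test_kwargs)
            if not d.independent:
                strength[(v, tau)] = abs(d.statistic)
                survivors.append((v, tau))
    q = 1
    while q <= len(survivors) - 1:
        removed = False
        for cand in sorted(survivors, key=lambda t: -strength[t]):
            others = [t for t in sorted(survivors, key=lambda t: -strength[t]) if t != cand]
            cond = tuple(others[:q])
            d = ci_test(panel, cand, (target, 0), cond, **test_kwargs)
            if d.independent:
                survivors.remove(cand)
                removed = True
            else:
                strength[cand] = abs(d.statistic)
        if not removed:
            q += 1
    return [(t, strength[t]) for t in sorted(survivors, key=lambda t: -strength[t])]


def pcmci_plus(
    panel: TimeSeriesPanel | np.ndarray,
    tau_max: int = TAU_MAX_DEFAULT,
    alpha: float = 0.05,
    method: str = "parcorr",
    pc_alpha: float | None = None,
    rule: str = "majority",
    k: int = KNN_K_DEFAULT,
    k_perm: int = K_PERM_DEFAULT,
    n_perm: int = N_PERM_DEFAULT,
    rng: np.random.Generator | int | None = 0,
) -> CausalGraph:
    """Two-phase lagged + contemporaneous causal discovery.

    Returns a :class:`CausalGraph` whose lagged edges are (source, lag,
    target) triples and whose contemporaneous edges carry an orientation
    mark (``-->`` directed from the first endpoint, ``o-o`` unoriented).
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    if rule != "majority":
        raise ValueError("only the majority rule is implemented")
    data = panel.data if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    K = data.shape[1]
    pc_alpha = alpha if pc_alpha is None else pc_alpha
    rng = np.random.default_rng(rng)
    kwargs = dict(method=method, k=k, k_perm=k_perm, n_perm=n_perm, rng=rng)

    parents: dict[int, list[Term]] = {}
    for i in range(1, K + 1):
        parents[i] = [t for t, _ in _phase1_parents(panel, i, tau_max, pc_alpha, {**kwargs, "alpha": pc_alpha})]

    graph = CausalGraph(K=K, tau_max=tau_max)

    def mci_cond(i: int, x_term: Term) -> tuple[Term, ...]:
        j, tau = x_term
        cond = [t for t in parents[i] if t != x_term]
        cond += [(v, lag + tau) for v, lag in parents[j]]
        seen, out = set(), []
        for t in cond:
            if t not in seen and t != x_term:
                seen.add(t)
                out.append(t)
        return tuple(out)

    # phase 2a: momentary CI for surviving lagged links
    for i in range(1, K + 1):
        for (j, tau) in parents[i]:
            d = ci_test(panel, (j, tau), (i, 0), mci_cond(i, (j, tau)), alpha=alpha, **kwargs)
            if not d.independent:
                graph.lagged.add((j, tau, i))

    # phase 2b: contemporaneous adjacency given both endpoints' lagged parents
    adj: dict[frozenset[int], CIDecision] = {}
    for a, b in combinations(range(1, K + 1), 2):
        cond = tuple(dict.fromkeys([*parents[b], *parents[a]]))
        d = ci_test(panel, (a, 0), (b, 0), cond, alpha=alpha, **kwargs)
        if not d.independent:
            adj[frozenset((a, b))] = d

    # orientation: collider detection with the majority rule
    neighbors = {v: {w for pair in adj for w in pair if v in pair and w != v} for v in range(1, K + 1)}
    arrow_into: dict[int, set[int]] = {v: set() for v in range(1, K + 1)}  # heads at v
    conflicted: set[frozenset[int]] = set()
    for kmid in range(1, K + 1):
        for a, b in combinations(sorted(neighbors[kmid]), 2):
            if frozenset((a, b)) in adj:
                continue  # shielded
            common = (neighbors[a] & neighbors[b]) - {a, b}
            votes_in = votes_out = 0
            base = tuple(dict.fromkeys([*parents[a], *parents[b]]))
            for size in range(len(common) + 1):
                for S in combinations(sorted(common), size):
                    cond = base + tuple((s, 0) for s in S)
                    d = ci_test(panel, (a, 0), (b, 0), cond, alpha=alpha, **kwargs)
                    if d.independent:
                        if kmid in S:
                            votes_out += 1
                        else:
                            votes_in += 1
            if votes_in + votes_out == 0:
                continue
            if votes_in > votes_out:  # k in no majority separating set: collider
                arrow_into[kmid].update((a, b))
            elif votes_in == votes_out:
                conflicted.add(frozenset((a, kmid)))
                conflicted.add(frozenset((b, kmid)))

    for pair in adj:
        a, b = sorted(pair)
        if pair in conflicted:
            graph.contemporaneous.append((a, b, "o-o"))
        elif a in arrow_into.get(b, set()) and b in arrow_into.get(a, set()):
            graph.contemporaneous.append((a, b, "o-o"))
        elif a in arrow_into.get(b, set()):
            graph.contemporaneous.append((a, b, "-->"))
        elif b in arrow_into.get(a, set()):
            graph.contemporaneous.append((b, a, "-->"))
        else:
            graph.contemporaneous.append((a, b, "o-o"))
    return graph
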