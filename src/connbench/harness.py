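"""Benchmark orchestration: realizations x systems x measures -> percentage tables.

For each system, R seeded realizations are generated (realization r uses
``base_seed + r``) and every requested measure is evaluated on the identical
panels. Each cell of a :class:`BenchmarkTable` is the percentage of
realizations in which the link was significant: upper-triangular for the
symmetric correlation measures, a full off-diagonal matrix for the directed
measures (rows drive the columns), and a contemporaneous/causal pair of
matrices for the instantaneous measures. PDC cells aggregate the fraction
of significant frequencies, so its percentage runs over (frequency,
realization) pairs.

Per-realization results can be cached to disk as JSON so interrupted sweeps
resume without recomputation; a measure failing on one realization is
recorded as missing and the cell's denominator shrinks accordingly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation, info_causality, pcmci, var_causality
from .simulators import SYSTEMS, TimeSeriesPanel, get_system, simulate, truth_of

__all__ = [
    "BenchmarkTable",
    "ScoreCard",
    "default_settings",
    "evaluate_measure",
    "run_benchmark",
    "score",
    "render_tables",
    "read_panel",
    "write_panel",
]

logger = logging.getLogger("connbench")

SYMMETRIC = ("ppcor", "pspcor", "pdcor", "mi")
DIRECTIONAL = ("cgci", "rcgci", "pdc", "ptenue")
INSTANTANEOUS = ("pmime0", "pcmci+")
ALL_MEASURES = SYMMETRIC + DIRECTIONAL + INSTANTANEOUS


def default_settings() -> dict:
    """Benchmark defaults: nominal alpha 0.05 (PTENUE termination at 0.01),
    k=10 neighbors, 100 permutations/surrogates, Lmax = tau_max = 4,
    256 PDC frequencies, VAR order taken from the system (P=1 for S1, else 3).
    """
    return {
        "alpha": 0.05,
        "k": 10,
        "B": 100,
        "Lmax": 4,
        "n_freqs": 256,
        "ptenue_alpha": 0.01,
        "pmime0_alpha": 0.05,
        "n_surrogates": 100,
        "tau_max": 4,
        "pcmci_method": "cmi-knn",
        "pcmci_n_perm": 100,
        "pcmci_k_perm": 5,
        "P": None,
    }


def _var_order(panel: TimeSeriesPanel, settings: dict) -> int:
    if settings.get("P"):
        return int(settings["P"])
    if panel.system_id in SYSTEMS:
        return SYSTEMS[panel.system_id].var_order
    return int(panel.meta.get("var_order", 3))


def _pair_rng(panel: TimeSeriesPanel, tag: int) -> np.random.Generator:
    return np.random.default_rng([(panel.seed or 0) % (2**31), tag])


def evaluate_measure(panel: TimeSeriesPanel, measure: str, settings: dict | None = None) -> dict:
    """Evaluate one measure on one panel.

    Returns ``{"kind": ..., "cells": {...}}`` (plus a ``contemporaneous``
    block for the instantaneous measures) where each cell maps a pair to
    ``{"value": float, "sig": float}`` with ``sig`` in [0, 1] (a 0/1
    significance flag, except PDC where it is the significant-frequency
    fraction).
    """
    s = {**default_settings(), **(settings or {})}
    K = panel.K
    alpha = s["alpha"]

    if measure in SYMMETRIC:
        cells = {}
        for i in range(1, K + 1):
            for j in range(i + 1, K + 1):
                if measure == "ppcor":
                    est = correlation.ppcor(panel, i, j, alpha=alpha)
                elif measure == "pspcor":
                    est = correlation.pspcor(panel, i, j, alpha=alpha)
                elif measure == "pdcor":
                    est = correlation.pdcor(
                        panel, i, j, alpha=alpha, B=s["B"], rng=_pair_rng(panel, 100 * i + j)
                    )
                else:
                    est = correlation.mi(
                        panel, i, j, k=s["k"], alpha=alpha, B=s["B"],
                        rng=_pair_rng(panel, 100 * i + j),
                    )
                cells[(i, j)] = {
                    "value": est.value,
                    "sig": float(est.significance.significant),
                }
        return {"kind": "symmetric", "cells": cells}

    if measure in ("cgci", "rcgci"):
        P = _var_order(panel, s)
        if measure == "cgci":
            res = var_causality.cgci_matrix(panel, P, alpha=alpha)
        else:
            res = var_causality.rcgci_matrix(panel, s["Lmax"], alpha=alpha)
        cells = {
            pair: {"value": r.statistic, "sig": float(r.significance.significant)}
            for pair, r in res.items()
        }
        return {"kind": "directional", "cells": cells}

    if measure == "pdc":
        P = _var_order(panel, s)
        res = var_causality.pdc(panel, P, M=s["n_freqs"], alpha=alpha)
        cells = {}
        for i in range(1, K + 1):
            for j in range(1, K + 1):
                if i != j:
                    cells[(j, i)] = {
                        "value": float(res.values[:, i - 1, j - 1].mean()),
                        "sig": float(res.fraction_significant[i - 1, j - 1]),
                    }
        return {"kind": "directional", "cells": cells}

    if measure == "ptenue":
        res = info_causality.ptenue_matrix(
            panel, Lmax=s["Lmax"], k=s["k"], alpha=s["ptenue_alpha"],
            n_surrogates=s["n_surrogates"], rng=_pair_rng(panel, 7),
        )
        cells = {
            pair: {"value": r.lagged, "sig": float(r.lagged_significant)}
            for pair, r in res.items()
        }
        return {"kind": "directional", "cells": cells}

    if measure == "pmime0":
        res = info_causality.pmime0_matrix(
            panel, Lmax=s["Lmax"], k=s["k"], alpha=s["pmime0_alpha"],
            n_surrogates=s["n_surrogates"], rng=_pair_rng(panel, 11),
        )
        causal = {
            pair: {"value": r.lagged, "sig": float(r.lagged_significant)}
            for pair, r in res.items()
        }
        contemp = {
            pair: {"value": r.contemporaneous, "sig": float(r.contemporaneous_significant)}
            for pair, r in res.items()
        }
        return {"kind": "instantaneous", "cells": causal, "contemporaneous": contemp}

    if measure == "pcmci+":
        graph = pcmci.pcmci_plus(
            panel, tau_max=s["tau_max"], alpha=alpha, method=s["pcmci_method"],
            k=s["k"], k_perm=s["pcmci_k_perm"], n_perm=s["pcmci_n_perm"],
            rng=_pair_rng(panel, 13),
        )
        lagged = graph.lagged_pairs()
        contemp_pairs = graph.contemporaneous_ordered()
        causal = {}
        contemp = {}
        for i in range(1, K + 1):
            for j in range(1, K + 1):
                if i != j:
                    causal[(j, i)] = {"value": float((j, i) in lagged), "sig": float((j, i) in lagged)}
                    contemp[(j, i)] = {
                        "value": float((j, i) in contemp_pairs),
                        "sig": float((j, i) in contemp_pairs),
                    }
        return {"kind": "instantaneous", "cells": causal, "contemporaneous": contemp}

    raise ValueError(f"unknown measure {measure!r}; expected one of {ALL_MEASURES}")


@dataclass
class BenchmarkTable:
    measure: str
    system: str
    R: int
    kind: str
    percent: np.ndarray  # K x K, NaN on diagonal (and lower triangle if symmetric)
    denominator: np.ndarray  # realizations contributing per cell
    contemporaneous: np.ndarray | None = None
    contemporaneous_denominator: np.ndarray | None = None
    settings: dict = field(default_factory=dict)


def _accumulate(tables: dict, result: dict, K: int) -> None:
    for block in ("cells", "contemporaneous"):
        if block not in result:
            continue
        key = "causal" if block == "cells" else "contemp"
        sums, counts = tables[key]
        for (a, b), cell in result[block].items():
            sums[a - 1, b - 1] += cell["sig"]
            counts[a - 1, b - 1] += 1


def _finalize(sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        pct = 100.0 * sums / counts
    pct[counts == 0] = np.nan
    return pct


def _cache_path(cache_dir: Path, system: str, measure: str, r: int) -> Path:
    safe = measure.replace("+", "plus")
    return cache_dir / system / safe / f"r{r:04d}.json"


def _serialize(result: dict) -> str:
    out = {"kind": result["kind"]}
    for block in ("cells", "contemporaneous"):
        if block in result:
            out[block] = {f"{a},{b}": c for (a, b), c in result[block].items()}
    return json.dumps(out)


def _deserialize(text: str) -> dict:
    raw = json.loads(text)
    out = {"kind": raw["kind"]}
    for block in ("cells", "contemporaneous"):
        if block in raw:
            out[block] = {
                tuple(int(s) for s in key.split(",")): c for key, c in raw[block].items()
            }
    return out


def run_benchmark(
    systems: list[str],
    measures: list[str],
    R: int = 100,
    n: int = 2000,
    base_seed: int = 0,
    settings: dict | None = None,
    cache_dir: str | Path | None = None,
) -> list[BenchmarkTable]:
    """Run the full sweep and aggregate percentage tables.

    Realization r of every system uses seed ``base_seed + r`` and the same
    panel is shared by all measures. A measure failing on one realization is
    logged and skipped; its cells then use the reduced denominator.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    s = {**default_settings(), **(settings or {})}
    cache = Path(cache_dir) if cache_dir is not None else None
    out: list[BenchmarkTable] = []
    for system in systems:
        spec = get_system(system)
        K = spec.K
        acc = {
            m: {
                "causal": (np.zeros((K, K)), np.zeros((K, K), dtype=int)),
                "contemp": (np.zeros((K, K)), np.zeros((K, K), dtype=int)),
                "kind": None,
            }
            for m in measures
        }
        for r in range(R):
            panel = None
            for m in measures:
                result = None
                path = _cache_path(cache, spec.id, m, r) if cache else None
                if path is not None and path.exists():
                    result = _deserialize(path.read_text())
                else:
                    if panel is None:
                        panel = simulate(spec, n=n, seed=base_seed + r)
                    try:
                        result = evaluate_measure(panel, m, s)
                    except Exception:
                        logger.exception(
                            "measure %s failed on %s realization %d; recorded as missing",
                            m, spec.id, r,
                        )
                        continue
                    if path is not None:
                        path.parent.mkdir(parents=True, exist_ok=True)
                        path.write_text(_serialize(result))
                acc[m]["kind"] = result["kind"]
                _accumulate(acc[m], result, K)
        for m in measures:
            kind = acc[m]["kind"]
            if kind is None:
                continue
            sums, counts = acc[m]["causal"]
            table = BenchmarkTable(
                measure=m, system=spec.id, R=R, kind=kind,
                percent=_finalize(sums, counts), denominator=counts, settings=s,
            )
            if kind == "instantaneous":
                csums, ccounts = acc[m]["contemp"]
                table.contemporaneous = _finalize(csums, ccounts)
                table.contemporaneous_denominator = ccounts
            out.append(table)
    return out


@dataclass(frozen=True)
class ScoreCard:
    measure: str
    system: str
    threshold: float
    sensitivity_contemporaneous: float | None
    fpr_contemporaneous: float | None
    sensitivity_lagged: float | None
    fpr_lagged: float | None
    spurious: tuple[tuple[int, int], ...]


def _rates(
    percent: np.ndarray, truth_pairs: set, pairs: list, threshold: float
) -> tuple[float | None, float | None, list]:
    hits = misses = fp = tn = 0
    spurious = []
    for pair in pairs:
        val = percent[pair[0] - 1, pair[1] - 1]
        if np.isnan(val):
            continue
        reported = val >= threshold
        if pair in truth_pairs:
            hits += reported
            misses += not reported
        else:
            fp += reported
            tn += not reported
            if reported:
                spurious.append(pair)
    sens = hits / (hits + misses) if hits + misses else None
    fpr = fp / (fp + tn) if fp + tn else None
    return sens, fpr, spurious


def score(table: BenchmarkTable, truth, threshold: float = 50.0) -> ScoreCard:
    """Compare a percentage table against a truth network at a threshold."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    K = table.percent.shape[0]
    if truth.contemporaneous and max(max(p) for p in truth.contemporaneous) > K:
        raise ValueError("truth network variable count exceeds table size")
    sym_pairs = [(i, j) for i in range(1, K + 1) for j in range(i + 1, K + 1)]
    dir_pairs = [(i, j) for i in range(1, K + 1) for j in range(1, K + 1) if i != j]
    lagged_truth = set(truth.lagged) | set(truth.equation_implied)
    contemp_truth = set(truth.contemporaneous)

    sc = fc = sl = fl = None
    spurious: list[tuple[int, int]] = []
    if table.kind == "symmetric":
        sc, fc, sp = _rates(table.percent, contemp_truth, sym_pairs, threshold)
        spurious += sp
    elif table.kind == "directional":
        sl, fl, sp = _rates(table.percent, lagged_truth, dir_pairs, threshold)
        spurious += sp
    else:
        sl, fl, sp = _rates(table.percent, lagged_truth, dir_pairs, threshold)
        spurious += sp
        both = contemp_truth | {(b, a) for a, b in contemp_truth}
        sc, fc, sp = _rates(table.contemporaneous, both, dir_pairs, threshold)
        spurious += sp
    return ScoreCard(
        table.measure, table.system, threshold, sc, fc, sl, fl, tuple(spurious)
    )


def _matrix_frame(percent: np.ndarray, kind: str) -> pd.DataFrame:
    K = percent.shape[0]
    labels = [str(i) for i in range(1, K + 1)]
    df = pd.DataFrame(np.round(percent).astype(object), index=labels, columns=labels)
    for i in range(K):
        for j in range(K):
            if i == j:
                df.iat[i, j] = "-"
            elif kind == "symmetric" and i > j:
                df.iat[i, j] = ""
            elif np.isnan(percent[i, j]):
                df.iat[i, j] = "NA"
            else:
                df.iat[i, j] = int(round(percent[i, j]))
    return df


def render_tables(
    tables: list[BenchmarkTable],
    fmt: str = "text",
    out_dir: str | Path | None = None,
) -> dict[str, str]:
    """Render tables as aligned text or CSV; optionally write one file each."""
    artifacts: dict[str, str] = {}
    for t in tables:
        blocks = []
        if t.kind == "instantaneous":
            blocks.append(("Contemporaneous Effects", t.contemporaneous, "directional"))
            blocks.append(("Causal Effects", t.percent, "directional"))
        else:
            blocks.append(("", t.percent, t.kind))
        pieces = []
        for title, mat, kind in blocks:
            df = _matrix_frame(mat, kind)
            if fmt == "csv":
                pieces.append((f"# {title}\n" if title else "") + df.to_csv())
            else:
                header = f"{t.measure.upper()} {t.system}" + (f" — {title}" if title else "")
                pieces.append(header + "\n" + df.to_string())
        name = f"{t.system}_{t.measure.replace('+', 'plus')}.{ 'csv' if fmt == 'csv' else 'txt'}"
        artifacts[name] = "\n\n".join(pieces) + "\n"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in artifacts.items():
            (out / name).write_text(text)
    return artifacts


def write_panel(panel: TimeSeriesPanel, path: str | Path, sep: str = "\t") -> None:
    """Write a panel as delimited text: header row of labels, no index."""
    pd.DataFrame(panel.data, columns=panel.labels).to_csv(path, sep=sep, index=False)


def read_panel(path: str | Path, sep: str | None = None) -> TimeSeriesPanel:
    """Read a delimited text panel (rows = time, columns = variables)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return TimeSeriesPanel(
        data=df.to_numpy(dtype=float), labels=[str(c) for c in df.columns]
    )
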