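import numpy as np
import pytest

import connbench as cb
from connbench import harness
from connbench.harness import (
    BenchmarkTable,
    render_tables,
    run_benchmark,
    score,
)


def test_single_realization_cells_are_zero_or_hundred():
    tables = run_benchmark(["S1"], ["pspcor"], R=1, n=500, base_seed=3)
    t = tables[0]
    vals = t.percent[~np.isnan(t.percent)]
    assert set(np.unique(vals)) <= {0.0, 100.0}


def test_symmetric_tables_are_strictly_upper_triangular():
    tables = run_benchmark(["S1"], ["ppcor"], R=2, n=500, base_seed=3)
    t = tables[0]
    K = t.percent.shape[0]
    for i in range(K):
        for j in range(K):
            if j > i:
                assert not np.isnan(t.percent[i, j])
            else:
                assert np.isnan(t.percent[i, j])


def test_stub_measure_counts_to_one_hundred(monkeypatch):
    def stub(panel, measure, settings=None):
        K = panel.K
        cells = {
            (i, j): {"value": 1.0, "sig": 1.0}
            for i in range(1, K + 1) for j in range(1, K + 1) if i != j
        }
        return {"kind": "directional", "cells": cells}

    monkeypatch.setattr(harness, "evaluate_measure", stub)
    tables = run_benchmark(["S1"], ["cgci"], R=3, n=500, base_seed=0)
    t = tables[0]
    off = ~np.isnan(t.percent)
    assert np.all(t.percent[off] == 100.0)


def test_failing_measure_recorded_as_missing(monkeypatch):
    calls = {"n": 0}
    real = harness.evaluate_measure

    def flaky(panel, measure, settings=None):
        calls["n"] += 1
        if calls["n"] == 2:
            raise RuntimeError("boom")
        return real(panel, measure, settings)

    monkeypatch.setattr(harness, "evaluate_measure", flaky)
    tables = run_benchmark(["S1"], ["pspcor"], R=3, n=500, base_seed=1)
    t = tables[0]
    assert t.denominator[0, 1] == 2  # one realization missing
    assert not np.isnan(t.percent[0, 1])


def test_cached_rerun_reproduces_tables_exactly(tmp_path):
    kw = dict(systems=["S1"], measures=["pspcor", "cgci"], R=3, n=500, base_seed=7)
    fresh = run_benchmark(**kw)
    first = run_benchmark(**kw, cache_dir=tmp_path)
    resumed = run_benchmark(**kw, cache_dir=tmp_path)  # all hits
    for a, b, c in zip(fresh, first, resumed):
        np.testing.assert_array_equal(a.percent, b.percent)
        np.testing.assert_array_equal(b.percent, c.percent)


def test_same_seed_runs_are_identical():
    a = run_benchmark(["S1"], ["ppcor"], R=2, n=500, base_seed=5)
    b = run_benchmark(["S1"], ["ppcor"], R=2, n=500, base_seed=5)
    np.testing.assert_array_equal(a[0].percent, b[0].percent)


class TestScore:
    def _table(self, percent, kind="symmetric"):
        K = percent.shape[0]
        return BenchmarkTable(
            measure="stub", system="S1", R=10, kind=kind,
            percent=percent, denominator=np.full((K, K), 10),
        )

    def test_perfect_table_scores_perfectly(self):
        truth = cb.truth_of("S1")
        percent = np.full((5, 5), np.nan)
        for i in range(5):
            for j in range(i + 1, 5):
                percent[i, j] = 100.0 if (i + 1, j + 1) in truth.contemporaneous else 0.0
        card = score(self._table(percent), truth, threshold=50)
        assert card.sensitivity_contemporaneous == 1.0
        assert card.fpr_contemporaneous == 0.0
        assert not card.spurious

    def test_all_zero_table(self):
        truth = cb.truth_of("S1")
        percent = np.zeros((5, 5))
        card = score(self._table(percent), truth, threshold=50)
        assert card.sensitivity_contemporaneous == 0.0
        assert card.fpr_contemporaneous == 0.0

    def test_threshold_validation(self):
        truth = cb.truth_of("S1")
        with pytest.raises(ValueError):
            score(self._table(np.zeros((5, 5))), truth, threshold=0)


class TestRender:
    def test_empty_input_gives_no_artifacts(self):
        assert render_tables([]) == {}

    def test_symmetric_table_has_ten_populated_cells(self):
        tables = run_benchmark(["S1"], ["ppcor"], R=1, n=500, base_seed=2)
        text = render_tables(tables)["S1_ppcor.txt"]
        cells = [tok for tok in text.split() if tok.isdigit() and len(tok) <= 3]
        # header labels 1..5 appear twice (rows+cols); 10 upper cells remain
        assert len(cells) - 10 == 10

    def test_renders_are_byte_stable_and_writable(self, tmp_path):
        tables = run_benchmark(["S1"], ["ppcor"], R=1, n=500, base_seed=2)
        a = render_tables(tables, fmt="csv", out_dir=tmp_path)
        b = render_tables(tables, fmt="csv")
        assert a == b
        assert (tmp_path / "S1_ppcor.csv").read_text() == a["S1_ppcor.csv"]

    def test_instantaneous_tables_have_two_blocks(self, monkeypatch):
        def stub(panel, measure, settings=None):
            cells = {(1, 2): {"value": 1.0, "sig": 1.0}, (2, 1): {"value": 0.0, "sig": 0.0}}
            return {"kind": "instantaneous", "cells": cells, "contemporaneous": dict(cells)}

        monkeypatch.setattr(harness, "evaluate_measure", stub)
        tables = run_benchmark(["S1"], ["pmime0"], R=1, n=500, base_seed=0)
        text = render_tables(tables)[f"S1_pmime0.txt"]
        assert "Contemporaneous Effects" in text and "Causal Effects" in text


def test_panel_roundtrip(tmp_path):
    p = cb.simulate("S1", 500, seed=4)
    path = tmp_path / "panel.tsv"
    cb.write_panel(p, path)
    q = cb.read_panel(path)
    assert q.labels == p.labels
    np.testing.assert_allclose(q.data, p.data, rtol=0, atol=1e-12)
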