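import numpy as np
import pytest

import connbench as cb
from connbench.var_causality import fit_var, select_terms_bts


def _var1_bivariate(rng, n, a11=0.5, a12=0.0, a21=0.4, a22=0.3):
    x = np.zeros((n, 2))
    e = rng.normal(size=(n, 2))
    for t in range(1, n):
        x[t, 0] = a11 * x[t - 1, 0] + a12 * x[t - 1, 1] + e[t, 0]
        x[t, 1] = a21 * x[t - 1, 0] + a22 * x[t - 1, 1] + e[t, 1]
    return x[200:]


class TestFitVar:
    def test_recovers_known_coefficients(self, rng):
        data = _var1_bivariate(rng, 100_200)
        A = fit_var(data, 1).coef_matrices()
        expected = np.array([[0.5, 0.0], [0.4, 0.3]])
        assert np.max(np.abs(A[0] - expected)) < 0.01

    def test_white_noise_coefficients_near_zero(self, rng):
        data = rng.normal(size=(3000, 3))
        fit = fit_var(data, 1)
        A = fit.coef_matrices()
        # 3 standard errors of a VAR coefficient at this size ~ 3/sqrt(n)
        assert np.max(np.abs(A)) < 3.5 / np.sqrt(fit.n_eff)

    def test_s2_equation_coefficient(self):
        p = cb.simulate("S2", 2000, seed=3)
        A = fit_var(p, 3).coef_matrices()
        assert A[2, 2, 0] == pytest.approx(0.4, abs=0.07)  # X3 eq, X1 lag 3

    def test_restricted_fit_has_larger_sse(self, rng):
        data = _var1_bivariate(rng, 2200)
        full = fit_var(data, 2)
        restricted_terms = {
            i: [t for t in full.terms[i] if t[0] != 1] for i in full.terms
        }
        restricted = fit_var(data, 2, terms=restricted_terms, align=2)
        assert np.all(restricted.sse >= full.sse - 1e-9)


class TestCgci:
    def test_matches_two_regression_oracle(self, rng):
        data = _var1_bivariate(rng, 1200)
        P = 2
        res = cb.cgci(data, 1, 2, P)
        # independent re-computation: two explicit OLS fits
        n = data.shape[0]
        rows = slice(P, n)
        y = data[rows, 1]

        def sse(cols):
            X = np.column_stack([np.ones(n - P)] + cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        lags = lambda v: [data[P - l : n - l, v] for l in range(1, P + 1)]
        sse_u = sse(lags(0) + lags(1))
        sse_r = sse(lags(1))
        assert res.statistic == pytest.approx(np.log(sse_r / sse_u), abs=1e-10)
        assert res.statistic >= 0

    def test_matches_statsmodels_bivariate_ftest(self, rng):
        sm = pytest.importorskip("statsmodels.tsa.stattools")
        x = rng.normal(size=2000)
        y = np.zeros(2000)
        y[2:] = 0.8 * x[:-2] + rng.normal(size=1998)
        res = cb.cgci(np.column_stack([x, y]), 1, 2, 2)
        ref = sm.grangercausalitytests(np.column_stack([y, x]), maxlag=[2])
        F_ref = ref[2][0]["ssr_ftest"][0]
        assert res.significance.statistic == pytest.approx(F_ref, rel=1e-9)

    def test_theoretical_value_for_simple_chain(self, rng):
        # y_t = 0.8 x_{t-1} + e: restricted variance 1.64, unrestricted 1
        x = rng.normal(size=10_000)
        y = np.zeros(10_000)
        y[1:] = 0.8 * x[:-1] + rng.normal(size=9999)
        res = cb.cgci(np.column_stack([x, y]), 1, 2, 1)
        assert res.statistic == pytest.approx(np.log(1.64), abs=0.05)
        assert res.significance.significant

    def test_null_rejection_near_nominal(self, rng):
        rej = sum(
            cb.cgci(rng.normal(size=(800, 2)), 1, 2, 1).significance.significant
            for _ in range(200)
        )
        assert abs(rej / 200 - 0.05) < 0.05

    def test_rejects_self_pair(self, rng):
        with pytest.raises(ValueError):
            cb.cgci(rng.normal(size=(500, 3)), 2, 2, 1)


class TestRcgci:
    def test_selects_active_lag_not_inactive_one(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            x = r.normal(size=2000)
            y = np.zeros(2000)
            y[2:] = 0.8 * x[:-2] + r.normal(size=1998)
            sel = select_terms_bts(np.column_stack([x, y]), 2, 2)
            hits += (1, 2) in sel and (1, 1) not in sel
        assert hits >= 8

    def test_selection_matches_exhaustive_bic_oracle(self, rng):
        """Greedy selection agrees with full-subset BIC enumeration on a
        sparse linear system."""
        from itertools import combinations

        x = rng.normal(size=1500)
        y = np.zeros(1500)
        y[2:] = 0.7 * x[:-2] + rng.normal(size=1498)
        data = np.column_stack([x, y])
        Lmax = 2
        n = 1500 - Lmax
        yv = data[Lmax:, 1]
        terms = [(v, l) for v in (1, 2) for l in (1, 2)]

        def bic(subset):
            cols = [np.ones(n)] + [data[Lmax - l : 1500 - l, v - 1] for v, l in subset]
            X = np.column_stack(cols)
            r = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
            return n * np.log((r @ r) / n) + (len(subset) + 1) * np.log(n)

        best = min(
            (s for k in range(len(terms) + 1) for s in combinations(terms, k)),
            key=bic,
        )
        assert set(select_terms_bts(data, 2, Lmax)) == set(best)

    def test_independent_panel_selects_little_and_rarely_rejects(self, rng):
        sig = 0
        for _ in range(20):
            data = rng.normal(size=(1000, 3))
            res = cb.rcgci(data, 1, 2, Lmax=3)
            sig += res.significance.significant
        assert sig <= 3

    def test_no_source_terms_gives_zero_statistic(self, rng):
        x = rng.normal(size=1500)
        y = np.zeros(1500)
        y[1:] = 0.8 * y[:-1] * 0 + rng.normal(size=1499)
        res = cb.rcgci(np.column_stack([x, y]), 1, 2, Lmax=2)
        if not res.selected_terms or all(v != 1 for v, _ in res.selected_terms):
            assert res.statistic == 0.0 and not res.significance.significant


class TestPdc:
    def test_column_normalization_identity(self, rng):
        data = _var1_bivariate(rng, 1200)
        res = cb.pdc(data, 2, M=64)
        colsums = (res.values**2).sum(axis=1)
        assert np.max(np.abs(colsums - 1.0)) < 1e-12

    def test_no_sqrt_variant_differs(self, rng):
        data = _var1_bivariate(rng, 1200)
        a = cb.pdc(data, 2, M=16)
        b = cb.pdc(data, 2, M=16, sqrt_denominator=False)
        assert not np.allclose(a.values, b.values)

    def test_null_rejection_near_nominal(self):
        # diagonal VAR: off-diagonal PDC has no true signal. With P=1 the
        # point-wise decision is constant in f, so average over replicates.
        rates = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            n = 1000
            x = np.zeros((n, 2))
            e = r.normal(size=(n, 2))
            for t in range(1, n):
                x[t] = 0.6 * x[t - 1] + e[t]
            res = cb.pdc(x[100:], 1, M=8)
            rates.append(res.fraction_significant[0, 1])
            rates.append(res.fraction_significant[1, 0])
        assert 0.01 <= np.mean(rates) <= 0.12

    def test_detects_true_directed_link(self):
        fwd, rev = [], []
        for rep in range(20):
            data = _var1_bivariate(np.random.default_rng(1000 + rep), 2200, a21=0.4)
            res = cb.pdc(data, 1, M=8)
            fwd.append(res.fraction_significant[1, 0])  # X1 -> X2
            rev.append(res.fraction_significant[0, 1])  # no X2 -> X1
        assert np.mean(fwd) >= 0.9
        assert np.mean(rev) <= 0.2
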