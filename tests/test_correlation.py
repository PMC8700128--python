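import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import connbench as cb
from connbench.correlation import EstimationError, _pdcor_value, dcor


def _random_panel(rng, n=50, K=4):
    data = rng.normal(size=(n, K))
    data[:, 1] += 0.5 * data[:, 0]
    data[:, 2] += 0.3 * data[:, 1] ** 2
    return data


class TestPartialCorrelation:
    def test_single_conditioner_equals_printed_formula(self, rng):
        data = _random_panel(rng)
        r = np.corrcoef(data, rowvar=False)
        expected = (r[0, 1] - r[0, 2] * r[2, 1]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[2, 1] ** 2)
        )
        est = cb.ppcor(data, 1, 2, cond=(3,))
        assert est.value == pytest.approx(expected, abs=1e-12)

    def test_residual_regression_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = _random_panel(rng, n=200)
        df = pd.DataFrame(data, columns=list("abcd"))
        ref = pingouin.partial_corr(df, x="a", y="b", covar=["c", "d"])
        est = cb.ppcor(data, 1, 2, cond=(3, 4))
        assert est.value == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_symmetry_and_duplicate_column(self, rng):
        data = _random_panel(rng)
        a = cb.ppcor(data, 1, 2, cond=(3, 4))
        b = cb.ppcor(data, 2, 1, cond=(3, 4))
        assert a.value == pytest.approx(b.value, abs=1e-14)
        dup = np.column_stack([data, data[:, 0]])
        est = cb.ppcor(dup, 1, 5, cond=(2, 3))
        assert est.value == pytest.approx(1.0, abs=1e-10)

    def test_singular_conditioning_raises(self, rng):
        data = _random_panel(rng)
        bad = np.column_stack([data, data[:, 2]])  # duplicated conditioner
        with pytest.raises(EstimationError, match="singular"):
            cb.ppcor(bad, 1, 2, cond=(3, 5))

    def test_pspcor_equals_ppcor_on_ranks_and_monotone_invariance(self, rng):
        data = _random_panel(rng, n=80)
        ranks = np.apply_along_axis(stats.rankdata, 0, data)
        a = cb.pspcor(data, 1, 2, cond=(3, 4)).value
        b = cb.ppcor(ranks, 1, 2, cond=(3, 4)).value
        assert a == pytest.approx(b, abs=1e-12)
        warped = data.copy()
        warped[:, 0] = np.exp(warped[:, 0])  # strictly monotone transform
        assert cb.pspcor(warped, 1, 2, cond=(3, 4)).value == pytest.approx(a, abs=1e-12)


def _dcor_bruteforce(x, y):
    """Direct double-loop evaluation of the distance correlation."""
    n = len(x)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    vxy = (A * B).mean()
    vx = (A * A).mean()
    vy = (B * B).mean()
    return np.sqrt(max(vxy, 0.0) / np.sqrt(vx * vy))


def _ucenter_bruteforce(D):
    n = D.shape[0]
    U = np.zeros_like(D)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            U[i, j] = (
                D[i, j]
                - D[i].sum() / (n - 2)
                - D[:, j].sum() / (n - 2)
                + D.sum() / ((n - 1) * (n - 2))
            )
    return U


class TestDistanceCorrelation:
    def test_dcor_matches_double_loop_oracle(self, rng):
        x, y = rng.normal(size=(2, 10))
        y = y + 0.5 * x
        assert dcor(x, y) == pytest.approx(_dcor_bruteforce(x, y), abs=1e-12)

    def test_dcor_identity_and_bounds(self, rng):
        x = rng.normal(size=30)
        assert dcor(x, x) == pytest.approx(1.0, abs=1e-12)
        y = rng.normal(size=30)
        assert 0.0 <= dcor(x, y) <= 1.0

    def test_dcor_constant_series_raises(self, rng):
        with pytest.raises(EstimationError):
            dcor(np.ones(20), rng.normal(size=20))

    def test_pdcor_matches_ucentering_oracle(self, rng):
        n = 20
        x, y = rng.normal(size=(2, n))
        z = rng.normal(size=(n, 2))
        y = y + 0.4 * x + 0.3 * z[:, 0]
        Dx = np.abs(x[:, None] - x[None, :])
        Dy = np.abs(y[:, None] - y[None, :])
        Dz = squareform(pdist(z))
        A, B, C = map(_ucenter_bruteforce, (Dx, Dy, Dz))

        def inner(P, Q):
            return (P * Q).sum() / (n * (n - 3))

        Pa = A - (inner(A, C) / inner(C, C)) * C
        Pb = B - (inner(B, C) / inner(C, C)) * C
        expected = inner(Pa, Pb) / np.sqrt(inner(Pa, Pa) * inner(Pb, Pb))
        assert _pdcor_value(x, y, z) == pytest.approx(expected, abs=1e-10)

    def test_pdcor_reduces_to_bias_corrected_dcor_without_cond(self, rng):
        x, y = rng.normal(size=(2, 25))
        no_z = _pdcor_value(x, y, None)
        empty_z = _pdcor_value(x, y, np.empty((25, 0)))
        assert no_z == pytest.approx(empty_z, abs=1e-14)

    def test_pdcor_zero_when_cond_explains_everything(self, rng):
        x = rng.normal(size=30)
        assert _pdcor_value(x, x.copy(), x.copy()) == pytest.approx(0.0, abs=1e-10)

    def test_pdcor_estimate_includes_permutation_significance(self, rng):
        data = _random_panel(rng, n=60)
        est = cb.pdcor(data, 1, 2, B=50, rng=3)
        assert est.significance.n_resamples == 50
        assert 0.0 < est.significance.p_value <= 1.0


class TestKnnMutualInformation:
    def test_independent_normals_near_zero(self, rng):
        x, y = rng.normal(size=(2, 5000))
        assert abs(cb.mi_ksg(x, y)) < 0.02

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_gaussian_closed_form(self, rho):
        rng = np.random.default_rng(42)
        z = rng.normal(size=(20000, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        truth = -0.5 * np.log(1 - rho**2)
        assert abs(cb.mi_ksg(x, y) - truth) < 0.02

    def test_symmetric_and_deterministic(self, rng):
        x, y = rng.normal(size=(2, 800))
        y = y + 0.5 * x
        assert cb.mi_ksg(x, y) == pytest.approx(cb.mi_ksg(y, x), abs=1e-9)
        assert cb.mi_ksg(x, y, jitter_seed=5) == cb.mi_ksg(x, y, jitter_seed=5)

    def test_constant_input_raises(self, rng):
        with pytest.raises(EstimationError):
            cb.mi_ksg(np.ones(100), rng.normal(size=100))
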