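import numpy as np
import pytest
from scipy import integrate, linalg

from netcca import (
    bartlett_pvalues,
    compute_cca,
    compute_pls,
    compute_rcca,
    redundancy_index,
    select_lambda,
)


def eigen_oracle(X, Y, l1=0.0, l2=0.0):
    """Canonical correlations via the generalized eigenproblem of
    S_xx^-1 S_xy S_yy^-1 S_yx — an independent route from the SVD solver."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1) + l1 * np.eye(X.shape[1])
    Syy = Yc.T @ Yc / (n - 1) + l2 * np.eye(Y.shape[1])
    Sxy = Xc.T @ Yc / (n - 1)
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    eigvals = np.sort(np.real(linalg.eigvals(M)))[::-1]
    s = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eigvals[:s], 0.0, None))


def chi2_sf_by_quadrature(x, df):
    """Upper chi-square tail by numerical integration of the density."""
    from scipy.special import gamma

    def dens(t):
        return t ** (df / 2 - 1) * np.exp(-t / 2) / (2 ** (df / 2) * gamma(df / 2))

    val, _ = integrate.quad(dens, x, np.inf)
    return val


class TestComputeCca:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((40, 2))
        res = compute_cca(X, X.copy())
        np.testing.assert_allclose(res.correlations, [1.0, 1.0], atol=1e-10)

    def test_orthogonal_blocks_correlate_zero(self, rng):
        X = rng.standard_normal((40, 3))
        Xc = X - X.mean(axis=0)
        # build Y orthogonal to X in sample space
        Q, _ = np.linalg.qr(np.column_stack([np.ones(40), Xc]))
        raw = rng.standard_normal((40, 2))
        Y = raw - Q @ (Q.T @ raw)
        res = compute_cca(X, Y)
        np.testing.assert_allclose(res.correlations, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generalized_eigenvalue_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 5))
        Y = 0.3 * X[:, :3] + rng.standard_normal((40, 3))
        res = compute_cca(X, Y)
        np.testing.assert_allclose(res.correlations, eigen_oracle(X, Y), atol=1e-8)

    def test_invariant_under_invertible_transforms(self, rng, gaussian_blocks):
        X, Y = gaussian_blocks
        base = compute_cca(X, Y).correlations
        A = rng.standard_normal((5, 5)) + 0.5 * np.eye(5)
        B = rng.standard_normal((3, 3)) + 0.5 * np.eye(3)
        res = compute_cca(X @ A, Y @ B)
        np.testing.assert_allclose(res.correlations, base, atol=1e-8)

    def test_variates_unit_variance_and_mutually_uncorrelated(self, gaussian_blocks):
        X, Y = gaussian_blocks
        res = compute_cca(X, Y)
        for scores in (res.x_scores, res.y_scores):
            cov = np.cov(scores, rowvar=False)
            np.testing.assert_allclose(cov, np.eye(scores.shape[1]), atol=1e-8)

    def test_sign_convention_largest_x_loading_positive(self, gaussian_blocks):
        X, Y = gaussian_blocks
        res = compute_cca(X, Y)
        for k in range(res.x_loadings.shape[1]):
            j = np.argmax(np.abs(res.x_loadings[:, k]))
            assert res.x_loadings[j, k] > 0

    def test_singular_covariance_directs_to_remedies(self, rng):
        X = rng.standard_normal((10, 4))
        X = np.column_stack([X, X[:, 0]])  # exactly collinear
        Y = rng.standard_normal((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match="prefilter|regularized"):
            compute_cca(X, Y)


class TestBartlett:
    def test_zero_correlations_give_p_one(self):
        p = bartlett_pvalues(np.zeros(3), n=40, p=5, q=3)
        np.testing.assert_allclose(p, 1.0)

    def test_group1_like_profile_first_significant_second_not(self):
        # correlation profile of a 20-gene, 2-metabolite group at n=40:
        # CV1 clearly significant, CV2 not
        p = bartlett_pvalues(np.array([0.95, 0.74]), n=40, p=20, q=2)
        assert p[0] < 0.01
        assert p[1] > 0.05

    def test_matches_quadrature_chi_square_oracle(self):
        r = np.array([0.5])
        n, p, q = 30, 3, 1
        got = bartlett_pvalues(r, n, p, q)[0]
        lam = 1 - 0.25
        chi2 = -(n - 1 - (p + q + 1) / 2) * np.log(lam)
        expected = chi2_sf_by_quadrature(chi2, (p) * (q))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_perfect_correlation_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="Lambda"):
            p = bartlett_pvalues(np.array([1.0, 0.2]), n=40, p=4, q=2)
        assert p[0] == 0.0


class TestRedundancy:
    def test_zero_correlations_zero_redundancy(self, rng):
        X = rng.standard_normal((40, 3))
        Xc = X - X.mean(axis=0)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(40), Xc]))
        raw = rng.standard_normal((40, 2))
        Y = raw - Q @ (Q.T @ raw)
        res = compute_cca(X, Y)
        assert redundancy_index(res, "y_given_x") == pytest.approx(0.0, abs=1e-12)

    def test_y_equal_to_an_x_column_fully_redundant(self, rng):
        X = rng.standard_normal((40, 4))
        Y = X[:, [1]].copy()
        res = compute_cca(X, Y)
        assert res.redundancy_y_given_x == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregate_equals_mean_multiple_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 6))
        Y = 0.5 * X[:, :4] + rng.standard_normal((40, 4))
        res = compute_cca(X, Y)
        Xc = X - X.mean(axis=0)
        r2 = []
        for j in range(Y.shape[1]):
            yj = Y[:, j] - Y[:, j].mean()
            beta, *_ = np.linalg.lstsq(Xc, yj, rcond=None)
            r2.append(1 - np.sum((yj - Xc @ beta) ** 2) / np.sum(yj**2))
        assert res.redundancy_y_given_x == pytest.approx(np.mean(r2), abs=1e-8)


class TestRcca:
    def test_zero_lambda_reduces_to_cca(self, gaussian_blocks):
        X, Y = gaussian_blocks
        cca = compute_cca(X, Y)
        rcca = compute_rcca(X, Y, 0.0, 0.0)
        np.testing.assert_allclose(rcca.correlations, cca.correlations, atol=1e-6)

    def test_wide_data_runs_with_published_penalties(self, rng):
        X = rng.standard_normal((40, 120))
        Y = rng.standard_normal((40, 21))
        res = compute_rcca(X, Y, 0.064, 0.008)
        assert np.all(np.isfinite(res.correlations))
        assert np.all((res.correlations >= 0) & (res.correlations <= 1))
        assert np.all(np.diff(res.correlations) <= 1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_regularized_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 6))
        Y = 0.4 * X[:, :4] + rng.standard_normal((20, 4))
        res = compute_rcca(X, Y, 0.1, 0.1)
        # the oracle gives the regularized singular values; convert the
        # realized score-pair correlations back to that scale
        oracle = eigen_oracle(X, Y, 0.1, 0.1)
        a, b = res.x_weights, res.y_weights
        n = X.shape[0]
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        Sxx = Xc.T @ Xc / (n - 1) + 0.1 * np.eye(6)
        Syy = Yc.T @ Yc / (n - 1) + 0.1 * np.eye(4)
        sv = np.abs(np.diag(a.T @ (Xc.T @ Yc / (n - 1)) @ b))
        np.testing.assert_allclose(np.sort(sv)[::-1], oracle, atol=1e-8)
        np.testing.assert_allclose(np.diag(a.T @ Sxx @ a), 1.0, atol=1e-8)

    def test_negative_lambda_rejected(self, gaussian_blocks):
        X, Y = gaussian_blocks
        with pytest.raises(ValueError):
            compute_rcca(X, Y, -0.1, 0.0)

    def test_lambda_to_zero_converges_to_cca(self, gaussian_blocks):
        X, Y = gaussian_blocks
        base = compute_cca(X, Y).correlations
        for lam, tol in ((1e-3, 1e-2), (1e-6, 1e-5)):
            got = compute_rcca(X, Y, lam, lam).correlations
            assert np.abs(got - base).max() < tol


class TestSelectLambda:
    def test_single_point_grid_returned(self, gaussian_blocks):
        X, Y = gaussian_blocks
        l1, l2, table = select_lambda(X, Y, [0.05], [0.2], n_folds=4, seed=0)
        assert (l1, l2) == (0.05, 0.2)
        assert len(table) == 1

    def test_self_paired_data_prefers_smallest_lambda(self, rng):
        X = rng.standard_normal((40, 4))
        l1, l2, _ = select_lambda(X, X.copy(), [0.0, 0.5], [0.0, 0.5], n_folds=4, seed=1)
        assert (l1, l2) == (0.0, 0.0)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 40))  # p > n noise
        Y = rng.standard_normal((30, 5))
        out1 = select_lambda(X, Y, [0.01, 0.1], [0.01, 0.1], n_folds=3, seed=9)
        out2 = select_lambda(X, Y, [0.01, 0.1], [0.01, 0.1], n_folds=3, seed=9)
        assert out1[:2] == out2[:2]
        assert out1[2].equals(out2[2])

    def test_tiny_folds_rejected(self, gaussian_blocks):
        X, Y = gaussian_blocks
        with pytest.raises(ValueError, match="3 samples"):
            select_lambda(X, Y, [0.1], [0.1], n_folds=20, seed=0)


class TestComputePls:
    def test_rank_one_identical_blocks_explain_everything(self, rng):
        t = rng.standard_normal(30)
        X = np.outer(t, [1.0, -2.0, 0.5])
        with pytest.warns(UserWarning, match="truncated"):
            res = compute_pls(X, X.copy(), 2, mode="canonical")
        assert res.n_components == 1
        assert res.explained_variance_x[0] == pytest.approx(100.0, abs=1e-8)
        assert res.explained_variance_y[0] == pytest.approx(100.0, abs=1e-8)

    @pytest.mark.parametrize("mode", ["regression", "canonical"])
    def test_first_weight_is_dominant_singular_vector(self, rng, mode):
        X = rng.standard_normal((30, 6))
        Y = 0.5 * X[:, :4] + rng.standard_normal((30, 4))
        res = compute_pls(X, Y, 2, mode=mode)
        X0 = (X - X.mean(0)) / X.std(0, ddof=1)
        Y0 = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        u = np.linalg.svd(X0.T @ Y0)[0][:, 0]
        w = res.x_weights[:, 0]
        assert min(np.abs(u - w).max(), np.abs(u + w).max()) < 1e-6

    def test_regression_scores_orthogonal(self, rng):
        X = rng.standard_normal((25, 7))
        Y = 0.4 * X[:, :2] + rng.standard_normal((25, 2))
        res = compute_pls(X, Y, 4, mode="regression")
        T = res.x_scores
        gram = T.T @ T
        off = np.abs(gram - np.diag(np.diag(gram))).max()
        assert off < 1e-10 * np.abs(np.diag(gram)).max()

    @pytest.mark.parametrize("mode", ["regression", "canonical"])
    def test_cumulative_explained_variance_valid(self, rng, mode):
        X = rng.standard_normal((30, 5))
        Y = 0.5 * X[:, :3] + rng.standard_normal((30, 3))
        ncomp = 5 if mode == "regression" else 3
        res = compute_pls(X, Y, ncomp, mode=mode)
        for ev in (res.explained_variance_x, res.explained_variance_y):
            cum = np.cumsum(ev)
            assert np.all(np.diff(cum) >= -1e-12)
            assert cum[-1] <= 100.0 + 1e-9
        # X block reaches 100% at its rank in regression mode
        if mode == "regression":
            assert np.cumsum(res.explained_variance_x)[-1] == pytest.approx(100.0, abs=1e-6)
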