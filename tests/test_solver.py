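import numpy as np
import pytest
from _oracles import penalized_objective, prox_grad_mipf

from mipflasso.exceptions import SingularityError
from mipflasso.solver import (
    SolverConfig,
    augment,
    cd_lasso,
    column_correlations,
    fit_mipf_lasso,
    fusion_penalty,
    fusion_weight_matrix,
    lambda1_max,
    ridge_fusion,
    select_features,
    soft_threshold,
    sqrt_factor,
    standardize_columns,
    tune,
)
from conftest import random_correlation


def standardized(rng, n, p):
    X, _, _ = standardize_columns(rng.standard_normal((n, p)))
    return X


class TestColumnCorrelations:
    def test_duplicated_columns_clip(self, rng):
        x = rng.standard_normal(30)
        X, _, _ = standardize_columns(np.stack([x, x], axis=1))
        fw = column_correlations(X, clip=0.999)
        assert fw.rho[0, 1] == pytest.approx(0.999)

    def test_orthogonal_columns(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        X, _, _ = standardize_columns(X)
        fw = column_correlations(X)
        assert fw.rho[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson(self, rng):
        X_raw = rng.standard_normal((40, 5))
        X, _, _ = standardize_columns(X_raw)
        fw = column_correlations(X, clip=1.0 - 1e-12)
        np.testing.assert_allclose(fw.rho, np.corrcoef(X_raw, rowvar=False),
                                   atol=1e-12)

    def test_zero_variance_column_raises(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="column"):
            standardize_columns(X)


class TestFusionPenalty:
    def test_hand_expanded_two_dim_case(self):
        # rho=0, beta=(1,1): (1-1)^2/1 + (1+1)^2/1 = 4
        rho = np.eye(2)
        assert fusion_penalty(np.array([1.0, 1.0]), rho) == pytest.approx(4.0)

    def test_zero_vector_gives_zero(self, rng):
        rho = random_correlation(5, rng)
        assert fusion_penalty(np.zeros(5), rho) == 0.0

    def test_diverges_as_correlation_approaches_one(self):
        beta = np.array([1.0, -1.0])
        vals = []
        for r in (0.9, 0.99, 0.999):
            rho = np.array([[1.0, r], [r, 1.0]])
            vals.append(fusion_penalty(beta, rho))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e3

    def test_unclipped_correlation_raises(self):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            fusion_penalty(np.ones(2), rho)


class TestFusionWeightMatrix:
    def test_two_dim_uncorrelated(self):
        W = fusion_weight_matrix(np.eye(2)).W
        np.testing.assert_allclose(W, [[2.0, 0.0], [0.0, 2.0]])
        beta = np.array([1.5, -2.0])
        assert beta @ W @ beta == pytest.approx(
            fusion_penalty(beta, np.eye(2)))

    def test_quadratic_form_equals_double_sum(self, rng):
        for _ in range(200):
            p = int(rng.integers(2, 9))
            rho = random_correlation(p, rng)
            W = fusion_weight_matrix(rho).W
            beta = rng.standard_normal(p)
            J = fusion_penalty(beta, rho)
            assert abs(beta @ W @ beta - J) < 1e-10 * (1.0 + J)

    def test_positive_semidefinite(self, rng):
        for _ in range(20):
            rho = random_correlation(6, rng)
            W = fusion_weight_matrix(rho).W
            assert np.linalg.eigvalsh(W).min() >= -1e-8 * np.abs(W).max()


class TestRidgeFusion:
    def test_orthonormal_design_reduces_to_projection(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((20, 5)))
        y = np.random.default_rng(1).standard_normal(20)
        beta = ridge_fusion(Q, y, 0.0, np.zeros((5, 5)))
        np.testing.assert_allclose(beta, Q.T @ y, atol=1e-10)

    def test_infinite_penalty_shrinks_to_zero(self, rng):
        X = standardized(rng, 30, 4)
        y = rng.standard_normal(30)
        W = fusion_weight_matrix(column_correlations(X).rho).W
        norms = [np.linalg.norm(ridge_fusion(X, y, lam2, W))
                 for lam2 in (1.0, 1e3, 1e6)]
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_p_greater_than_n_well_posed(self, rng):
        X = standardized(rng, 10, 30)
        y = rng.standard_normal(10)
        W = fusion_weight_matrix(column_correlations(X).rho).W
        beta = ridge_fusion(X, y, 1.0, W)
        assert np.all(np.isfinite(beta))

    def test_singular_without_fusion_raises(self, rng):
        X = standardized(rng, 5, 12)
        y = rng.standard_normal(5)
        with pytest.raises(SingularityError):
            ridge_fusion(X, y, 0.0, np.zeros((12, 12)))


class TestSqrtFactor:
    def test_identity(self):
        R = sqrt_factor(np.eye(3))
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)

    def test_scaled_identity(self):
        W = np.diag([2.0, 2.0])
        np.testing.assert_allclose(sqrt_factor(W).T @ sqrt_factor(W), W, atol=1e-12)

    def test_rank_deficient_eigen_path(self, rng):
        # duplicated features make W numerically semidefinite
        A = rng.standard_normal((3, 2))
        A = np.hstack([A, A[:, :1]])
        W = A.T @ A
        W[2, 2] = W[0, 0]  # exactly singular direction
        W = 0.5 * (W + W.T)
        R = sqrt_factor(W)
        np.testing.assert_allclose(R.T @ R, W, atol=1e-8 * np.abs(W).max())

    def test_random_psd_multiply_back(self, rng):
        for _ in range(10):
            rho = random_correlation(5, rng)
            W = fusion_weight_matrix(rho).W
            R = sqrt_factor(W)
            np.testing.assert_allclose(
                R.T @ R, W, atol=1e-8 * np.linalg.norm(W))

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError):
            sqrt_factor(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestAugment:
    def test_penalized_loss_identity(self, rng):
        for _ in range(50):
            n, p = int(rng.integers(5, 30)), int(rng.integers(2, 10))
            X = standardized(rng, n, p)
            y = rng.standard_normal(n)
            rho = column_correlations(X).rho
            W = fusion_weight_matrix(rho).W
            lam2 = float(rng.uniform(0.1, 5.0))
            aug = augment(X, y, lam2, sqrt_factor(W), np.ones(p))
            beta = rng.standard_normal(p)
            lhs = np.sum((aug.y_hat - aug.X_hat @ beta) ** 2)
            rhs = np.sum((y - X @ beta) ** 2) + lam2 * beta @ W @ beta
            assert abs(lhs - rhs) < 1e-10 * (1.0 + abs(rhs))

    def test_zero_lambda2_zeroes_bottom_block(self, rng):
        X = standardized(rng, 10, 3)
        aug = augment(X, np.zeros(10), 0.0, np.eye(3), np.ones(3))
        assert np.all(aug.X_hat[10:] == 0.0)

    def test_unit_alpha_identity_rescale(self, rng):
        X = standardized(rng, 10, 3)
        aug = augment(X, np.zeros(10), 1.0, np.eye(3), np.ones(3))
        np.testing.assert_array_equal(aug.X_star, aug.X_hat)

    def test_alpha_below_floor_raises(self, rng):
        X = standardized(rng, 10, 3)
        with pytest.raises(ValueError):
            augment(X, np.zeros(10), 1.0, np.eye(3), np.array([1.0, 1e-12, 1.0]))


class TestCdLasso:
    def test_unpenalized_matches_least_squares(self, rng):
        X = standardized(rng, 40, 6)
        y = rng.standard_normal(40)
        beta, _, converged = cd_lasso(X, y, 0.0, tol=1e-10)
        assert converged
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, expected, atol=1e-6)

    def test_kkt_inactivity_threshold(self, rng):
        X = standardized(rng, 30, 5)
        y = rng.standard_normal(30)
        lam1 = 2.0 * np.abs(X.T @ y).max() * (1.0 + 1e-10)
        beta, _, _ = cd_lasso(X, y, lam1)
        np.testing.assert_array_equal(beta, np.zeros(5))

    def test_one_dimensional_closed_form(self, rng):
        x = rng.standard_normal((25, 1))
        y = rng.standard_normal(25)
        lam1 = 0.7
        beta, _, _ = cd_lasso(x, y, lam1, tol=1e-12)
        expected = soft_threshold(float(x[:, 0] @ y), lam1 / 2) / float(x[:, 0] @ x[:, 0])
        assert beta[0] == pytest.approx(expected, abs=1e-12)

    def test_objective_non_increasing_across_sweeps(self, rng):
        X = standardized(rng, 30, 8)
        y = rng.standard_normal(30)
        lam1 = 0.2
        objs = []
        beta = np.zeros(8)
        for _ in range(12):
            beta, _, _ = cd_lasso(X, y, lam1, tol=0.0 + 1e-300, max_sweeps=1, beta0=beta)
            objs.append(np.sum((y - X @ beta) ** 2) + lam1 * np.abs(beta).sum())
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = standardized(rng, 20, 5)
        y = rng.standard_normal(20)
        _, sweeps, converged = cd_lasso(X, y, 0.01, tol=1e-16, max_sweeps=3)
        assert sweeps == 3 and not converged

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            cd_lasso(np.array([[np.inf]]), np.array([1.0]), 0.1)


class TestFitReductions:
    def test_plain_lasso_matches_sklearn(self, rng):
        # independent oracle: scikit-learn's coordinate descent solves
        # (1/2n)||y-Xb||^2 + a||b||_1, i.e. our objective with a = lam1/(2n)
        from sklearn.linear_model import Lasso

        n, p = 60, 10
        X = standardized(rng, n, p)
        y = rng.standard_normal(n)
        y = y - y.mean()
        lam1 = 0.5
        fit = fit_mipf_lasso(X, y, None,
                             SolverConfig(lambda1=lam1, variant="lasso",
                                          standardize=False, tol=1e-12))
        ref = Lasso(alpha=lam1 / (2 * n), fit_intercept=False,
                    tol=1e-12, max_iter=100_000).fit(X, y)
        np.testing.assert_allclose(fit.beta, ref.coef_, atol=1e-6)

    def test_lambda1_zero_matches_closed_form(self, rng):
        X = standardized(rng, 50, 10)
        y = rng.standard_normal(50)
        y = y - y.mean()
        lam2 = 2.0
        fit = fit_mipf_lasso(X, y, None,
                             SolverConfig(lambda1=0.0, lambda2=lam2,
                                          standardize=False, tol=1e-10))
        W = fusion_weight_matrix(column_correlations(X).rho).W
        np.testing.assert_allclose(fit.beta, ridge_fusion(X, y, lam2, W), atol=1e-6)

    def test_adaptive_lasso_variant_drops_fusion(self, rng):
        X = standardized(rng, 40, 6)
        y = rng.standard_normal(40)
        alpha = np.linspace(0.2, 1.0, 6)
        a = fit_mipf_lasso(X, y, alpha, SolverConfig(
            lambda1=0.3, lambda2=7.0, variant="adaptive_lasso", standardize=False))
        b = fit_mipf_lasso(X, y, alpha, SolverConfig(
            lambda1=0.3, lambda2=0.0, variant="mipf", standardize=False))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)
        assert a.lambda2 == 0.0

    def test_none_variant_keeps_everything(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        fit = fit_mipf_lasso(X, y, None, SolverConfig(variant="none"))
        assert fit.support.size == 5

    def test_full_fit_matches_prox_grad_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, p = 40, 8
            X = standardized(r, n, p)
            y = r.standard_normal(n)
            y = y - y.mean()
            alpha = np.exp(-r.uniform(0, 2, p))
            lam1, lam2 = 0.4, 1.5
            fit = fit_mipf_lasso(X, y, alpha, SolverConfig(
                lambda1=lam1, lambda2=lam2, standardize=False, tol=1e-10))
            W = fusion_weight_matrix(column_correlations(X).rho).W
            ref = prox_grad_mipf(X, y, alpha, lam1, lam2, W)
            np.testing.assert_allclose(fit.beta, ref, atol=1e-5)
            # objective values agree too
            assert penalized_objective(X, y, fit.beta, alpha, lam1, lam2, W) == \
                pytest.approx(penalized_objective(X, y, ref, alpha, lam1, lam2, W),
                              abs=1e-6)


class TestGroupingEffect:
    def duplicated_instance(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.standard_normal(n)
        X = np.stack([x, x + 1e-6 * rng.standard_normal(n),
                      rng.standard_normal(n)], axis=1)
        beta_true = np.array([1.0, 1.0, 0.0])
        y = X @ beta_true + 0.1 * rng.standard_normal(n)
        return X, y

    def test_duplicated_columns_fuse(self):
        X, y = self.duplicated_instance()
        diffs = []
        for lam2 in (0.0, 0.1, 1.0, 10.0, 100.0):
            fit = fit_mipf_lasso(X, y, None, SolverConfig(
                lambda1=0.1, lambda2=lam2, tol=1e-10))
            diffs.append(abs(fit.beta[0] - fit.beta[1]))
        assert all(a >= b - 1e-9 for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-3


class TestSelectFeatures:
    def test_null_fit_empty_support(self, rng):
        X = standardized(rng, 20, 4)
        y = rng.standard_normal(20)
        lam1 = 2.0 * np.abs(X.T @ (y - y.mean())).max() * 1.01
        fit = fit_mipf_lasso(X, y, None, SolverConfig(lambda1=lam1, variant="lasso"))
        assert select_features(fit).size == 0

    def test_definition(self, rng):
        X = standardized(rng, 20, 4)
        fit = fit_mipf_lasso(X, rng.standard_normal(20), None,
                             SolverConfig(lambda1=0.0, variant="lasso"))
        fit.beta = np.array([0.0, 3.0, 0.0, -2.0])
        np.testing.assert_array_equal(select_features(fit), [1, 3])

    def test_support_shrinks_along_lambda1_path(self, rng):
        X = standardized(rng, 50, 12)
        beta_true = np.zeros(12)
        beta_true[:3] = 2.0
        y = X @ beta_true + 0.2 * rng.standard_normal(50)
        lam_max = lambda1_max(X, y - y.mean(), np.ones(12))
        sizes = []
        for frac in (0.01, 0.05, 0.2, 0.5, 1.1):
            fit = fit_mipf_lasso(X, y, None, SolverConfig(
                lambda1=frac * lam_max, variant="lasso", standardize=False))
            sizes.append(fit.support.size)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0


class TestTune:
    def test_single_point_grid(self, rng):
        X = standardized(rng, 40, 5)
        y = rng.standard_normal(40)
        l1, l2, table = tune(X, y, None, [0.3], [0.5], k_folds=3, seed=0,
                             scoring="mse")
        assert (l1, l2) == (0.3, 0.5)
        assert len(table) == 3

    def test_deterministic_given_seed(self, rng):
        X = standardized(rng, 40, 5)
        y = rng.standard_normal(40)
        out1 = tune(X, y, None, [0.1, 0.5], [0.0, 1.0], k_folds=3, seed=4,
                    scoring="mse")
        out2 = tune(X, y, None, [0.1, 0.5], [0.0, 1.0], k_folds=3, seed=4,
                    scoring="mse")
        assert out1[:2] == out2[:2]
        assert out1[2].equals(out2[2])

    def test_pure_noise_prefers_sparsest_model(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = standardized(rng, 60, 8)
            y = rng.standard_normal(60)
            lam_max = lambda1_max(X, y - y.mean(), np.ones(8))
            grid = [0.05 * lam_max, 0.3 * lam_max, 1.05 * lam_max]
            l1, _, _ = tune(X, y, None, grid, [0.0], k_folds=5, seed=seed,
                            scoring="mse")
            wins += l1 == pytest.approx(grid[-1])
        assert wins >= 8

    def test_empty_grid_raises(self, rng):
        with pytest.raises(ValueError):
            tune(np.zeros((10, 2)), np.zeros(10), None, [], [0.0])


class TestPGreaterThanN:
    def test_finite_solution_with_fusion(self, rng):
        n, p = 20, 60
        X = standardized(rng, n, p)
        beta_true = np.zeros(p)
        beta_true[:3] = 1.5
        y = X @ beta_true + 0.1 * rng.standard_normal(n)
        fit = fit_mipf_lasso(X, y, None, SolverConfig(
            lambda1=0.1, lambda2=1.0, standardize=False))
        assert np.all(np.isfinite(fit.beta))
        assert fit.converged
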