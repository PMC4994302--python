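import numpy as np
import pytest

from ccxpen.clr_core import cond_loglik, fit_clr
from ccxpen.io_data import CaseCrossoverDataset
from ccxpen.penalized import (
    cv_elastic_net,
    cv_lasso,
    default_lambda_grid,
    fit_lasso,
    fit_path,
    lambda_max,
    make_folds,
    penalized_objective,
)

from conftest import dataset_from_counts, multi_dataset_from_counts, random_dataset


class TestLambdaMax:
    def test_single_drug_value(self):
        data = dataset_from_counts(8, 2, n11=1, n00=1)
        assert lambda_max(data) == pytest.approx(3.0)

    def test_balanced_discordances_give_zero(self):
        data = dataset_from_counts(4, 4)
        assert lambda_max(data) == 0.0

    def test_no_discordance_anywhere_raises(self):
        data = dataset_from_counts(0, 0, n11=3, n00=3)
        with pytest.raises(ValueError, match="constant"):
            lambda_max(data)

    def test_fit_above_lambda_max_is_exactly_zero(self, rng):
        data = random_dataset(rng, n=50, p=4)
        lam = lambda_max(data)
        beta = fit_lasso(data, lam * 1.01)
        np.testing.assert_array_equal(beta, np.zeros(4))


class TestFitLasso:
    def test_lambda_zero_matches_multivariable_mle(self, rng):
        data = random_dataset(rng, n=80, p=4, d=0.4)
        mle = fit_clr(data, mode="multivariable")
        assert not mle.separation_flags.any()
        beta = fit_lasso(data, 0.0)
        np.testing.assert_allclose(beta, mle.coefficients, atol=1e-4)

    def test_univariable_penalized_stationarity(self):
        # n10=8, n01=2, lam=1: the stationarity condition
        # n10 - m*sigmoid(b) = sign(b)*lam gives sigmoid(b) = 0.7
        data = dataset_from_counts(8, 2, n11=1, n00=1)
        beta = fit_lasso(data, 1.0)
        assert beta[0] == pytest.approx(np.log(7 / 3), abs=1e-3)

    def test_solution_dominates_random_perturbations(self, rng):
        data = random_dataset(rng, n=60, p=4)
        lam = 0.8
        beta = fit_lasso(data, lam)
        z = data.exposure_difference().astype(float)
        best = penalized_objective(beta, z, lam)
        for _ in range(100):
            probe = beta + rng.normal(0, 1e-3, size=4)
            assert penalized_objective(probe, z, lam) <= best + 1e-9

    def test_univariable_shrinkage_monotone_in_lambda(self):
        data = dataset_from_counts(9, 2, n11=1, n00=1)
        grid = default_lambda_grid(lambda_max(data), n_lambda=40)
        path = fit_path(data, grid)
        mags = np.abs(path.coefficients_path[:, 0])
        assert np.all(np.diff(mags) >= -1e-9)  # grid decreasing -> |b| grows

    def test_loglik_non_increasing_in_lambda(self, rng):
        data = random_dataset(rng, n=60, p=4)
        grid = default_lambda_grid(lambda_max(data), n_lambda=30)
        path = fit_path(data, grid)
        assert np.all(np.diff(path.loglik_path) >= -1e-8)

    def test_negative_penalty_rejected(self, rng):
        data = random_dataset(rng, n=10, p=2)
        with pytest.raises(ValueError):
            fit_lasso(data, -1.0)


class TestFolds:
    def test_even_blocks(self):
        folds = make_folds(10, K=5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        np.testing.assert_array_equal(np.sort(sizes), [2, 2, 2, 2, 2])

    def test_partition_and_near_equal_sizes(self):
        folds = make_folds(23, K=4, seed=1)
        assert folds.shape == (23,)
        sizes = np.bincount(folds, minlength=4)
        assert sizes.sum() == 23 and sizes.max() - sizes.min() <= 1

    def test_same_seed_same_folds(self):
        np.testing.assert_array_equal(
            make_folds(37, K=10, seed=5), make_folds(37, K=10, seed=5)
        )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(5, K=6, seed=0)


class TestCV:
    def test_degenerate_grid_zero_selects_mle(self, rng):
        data = random_dataset(rng, n=60, p=3, d=0.4)
        mle = fit_clr(data, mode="multivariable")
        assert not mle.separation_flags.any()
        cv, fit = cv_lasso(data, K=5, lambda_grid=np.array([0.0]), seed=0)
        assert cv.selected_lambda == 0.0
        np.testing.assert_allclose(fit.coefficients, mle.coefficients, atol=1e-4)

    def test_grid_above_lambda_max_gives_null_model(self, rng):
        data = random_dataset(rng, n=40, p=3)
        lam = 2 * lambda_max(data)
        cv, fit = cv_lasso(data, K=5, lambda_grid=np.array([lam]), seed=0)
        np.testing.assert_array_equal(fit.coefficients, np.zeros(3))
        assert cv.cv_loglik[0] == pytest.approx(-40 * np.log(2))

    def test_empty_grid_rejected(self, rng):
        data = random_dataset(rng, n=20, p=2)
        with pytest.raises(ValueError, match="empty"):
            cv_lasso(data, lambda_grid=np.array([]))

    def test_selected_lambda_attains_cv_maximum(self, euroscar_like):
        data, _ = euroscar_like
        cv, fit = cv_lasso(data, seed=2)
        i = np.flatnonzero(cv.lambda_grid == cv.selected_lambda)[0]
        assert cv.cv_loglik[i] == cv.cv_loglik.max()
        # selected fit is sparser than the full model and has no extremes
        assert np.count_nonzero(fit.coefficients) < data.n_drugs
        assert np.abs(fit.coefficients).max() <= 5

    def test_fold_seed_robust_signs_for_non_sparse_drugs(self, euroscar_like):
        from ccxpen.io_data import count_discordances

        data, _ = euroscar_like
        disc = count_discordances(data)
        _, fit_a = cv_lasso(data, seed=10)
        _, fit_b = cv_lasso(data, seed=77)
        stable = disc.min_discordance >= 3
        sa = np.sign(fit_a.coefficients[stable])
        sb = np.sign(fit_b.coefficients[stable])
        assert np.all((sa == sb) | (sa == 0) | (sb == 0))


class TestElasticNet:
    def test_lambda2_zero_reduces_to_lasso(self, rng):
        data = random_dataset(rng, n=60, p=4)
        cv_l, fit_l = cv_lasso(data, K=5, seed=3, n_lambda=30)
        cv_e, fit_e = cv_elastic_net(
            data, K=5, seed=3, n_lambda=30, lambda2_grid=(0.0,)
        )
        assert cv_e.selected_lambda2 == 0.0
        np.testing.assert_allclose(fit_e.coefficients, fit_l.coefficients, atol=1e-8)
        assert cv_e.selected_lambda == cv_l.selected_lambda

    def test_pure_ridge_keeps_all_discordant_drugs_nonzero(self, rng):
        # lambda1 = 0: ridge regression, no exact zeros
        for _ in range(5):
            data = random_dataset(rng, n=60, p=4, d=0.45)
            from ccxpen.io_data import count_discordances

            disc = count_discordances(data)
            if (np.minimum(disc.n10, disc.n01) >= 1).all() and (
                disc.n10 != disc.n01
            ).all():
                break
        beta = fit_lasso(data, 0.0, lam2=1.0)
        assert np.all(beta != 0.0)

    def test_ridge_ties_duplicate_columns(self):
        col_case = np.array([1, 1, 0, 0, 1, 0, 0, 0])[:, None]
        col_ref = np.array([0, 0, 1, 0, 0, 1, 0, 0])[:, None]
        data = CaseCrossoverDataset(
            [f"s{i}" for i in range(8)],
            ["a", "b"],
            np.hstack([col_case, col_case]),
            np.hstack([col_ref, col_ref]),
        )
        beta = fit_lasso(data, 0.0, lam2=0.5)
        assert beta[0] == pytest.approx(beta[1], abs=1e-6)
        assert beta[0] != 0.0
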