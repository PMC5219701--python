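"""Solver correctness against closed forms and independent oracles, path
construction, hyperparameter tuning, and prediction post-processing."""

import numpy as np
import pytest
from sklearn.linear_model import MultiTaskElasticNet

from bloodmix import CompositionModel
from bloodmix._solver import NUMBA_AVAILABLE, cd_solve, objective
from bloodmix.core import CompositionMatrix, ExpressionMatrix
from bloodmix.errors import (
    AlignmentError,
    ConfigError,
    DegenerateDataError,
    MissingFeatureError,
    ValidationError,
)
from bloodmix.train import (
    compute_lambda_path,
    fit_multitask_elasticnet,
    predict_composition,
    tune_hyperparameters,
)


def _random_problem(rng, n=30, p=8, K=3, y_scale=0.1):
    X = ExpressionMatrix([f"g{j}" for j in range(p)],
                         [f"s{i}" for i in range(n)],
                         rng.normal(7.0, 1.0, size=(p, n)))
    Y = CompositionMatrix.unchecked([f"s{i}" for i in range(n)],
                                    [f"ct{k}" for k in range(K)],
                                    rng.normal(0.2, y_scale, size=(n, K)))
    return X, Y


class TestSolverLimits:
    def test_lambda_zero_matches_ols(self, rng):
        X, Y = _random_problem(rng, n=40, p=6)
        res = fit_multitask_elasticnet(X, Y, alpha=0.5, lam=0.0)
        # per-response OLS with intercept
        A = np.column_stack([np.ones(40), X.values.T])
        for k in range(len(Y.cell_types)):
            beta, *_ = np.linalg.lstsq(A, Y.values[:, k], rcond=None)
            assert abs(res.intercepts[k] - beta[0]) < 1e-6
            assert np.max(np.abs(res.coefficients[:, k] - beta[1:])) < 1e-6

    @pytest.mark.parametrize("alpha", [1.0, 0.5, 0.1])
    def test_lambda_max_zeroes_everything(self, rng, alpha):
        X, Y = _random_problem(rng)
        path = compute_lambda_path(X, Y, alpha, n_lambda=5)
        res = fit_multitask_elasticnet(X, Y, alpha, path.lambdas[0])
        assert np.all(res.coefficients == 0.0)
        assert np.allclose(res.intercepts, Y.values.mean(axis=0))
        res2 = fit_multitask_elasticnet(X, Y, alpha, path.lambdas[0] * 2)
        assert np.all(res2.coefficients == 0.0)

    def test_ridge_matches_closed_form_on_orthonormalized_design(self, rng):
        n, p, K = 50, 5, 3
        raw = rng.normal(size=(n, p))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        Xn = Q * np.sqrt(n)  # X'X/n = I
        Y = rng.normal(size=(n, K))
        lam = 0.37
        Xm = ExpressionMatrix([f"g{j}" for j in range(p)],
                              [f"s{i}" for i in range(n)], Xn.T)
        Ym = CompositionMatrix.unchecked([f"s{i}" for i in range(n)],
                                         [f"c{k}" for k in range(K)], Y)
        res = fit_multitask_elasticnet(Xm, Ym, alpha=0.0, lam=lam,
                                       standardize=False)
        Yc = Y - Y.mean(axis=0)
        expected = np.linalg.solve(Xn.T @ Xn / n + lam * np.eye(p),
                                   Xn.T @ Yc / n)
        assert np.max(np.abs(res.coefficients - expected)) < 1e-6


class TestSolverOptimality:
    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.05), (0.5, 0.1), (0.1, 0.2)])
    def test_matches_independent_multitask_solver(self, rng, alpha, lam):
        """sklearn's MultiTaskElasticNet minimizes the identical objective;
        the two solvers must agree."""
        n, p, K = 40, 12, 3
        Xc = rng.normal(size=(n, p))
        Xc -= Xc.mean(axis=0)
        Yc = rng.normal(size=(n, K))
        Yc -= Yc.mean(axis=0)
        B = cd_solve(Xc.T @ Xc / n, Xc.T @ Yc / n, lam, alpha, tol=1e-10)
        ref = MultiTaskElasticNet(alpha=lam, l1_ratio=alpha,
                                  fit_intercept=False, tol=1e-12,
                                  max_iter=200_000).fit(Xc, Yc)
        assert np.max(np.abs(B - ref.coef_.T)) < 1e-6

    def test_random_perturbations_cannot_improve_objective(self, rng):
        n, p, K = 20, 8, 3
        Xc = rng.normal(size=(n, p))
        Xc -= Xc.mean(axis=0)
        Yc = rng.normal(size=(n, K))
        Yc -= Yc.mean(axis=0)
        lam, alpha = 0.08, 0.5
        B = cd_solve(Xc.T @ Xc / n, Xc.T @ Yc / n, lam, alpha, tol=1e-12)
        f0 = objective(Xc, Yc, B, lam, alpha)
        deltas = rng.normal(scale=1e-4, size=(10_000, p, K))
        worst = min(objective(Xc, Yc, B + d, lam, alpha) for d in deltas)
        assert f0 <= worst + 1e-12

    def test_numba_and_numpy_kernels_agree(self, rng):
        if not NUMBA_AVAILABLE:
            pytest.skip("numba not installed; single implementation")
        n, p, K = 25, 10, 4
        Xc = rng.normal(size=(n, p))
        Yc = rng.normal(size=(n, K))
        G, C = Xc.T @ Xc / n, Xc.T @ Yc / n
        a = cd_solve(G, C, 0.1, 0.5, use_numba=True)
        b = cd_solve(G, C, 0.1, 0.5, use_numba=False)
        assert np.max(np.abs(a - b)) < 1e-8


class TestGroupSparsity:
    def test_rows_all_zero_or_retained(self, rng):
        """The row-wise l2 penalty selects whole features: no partially
        zeroed coefficient row may occur at alpha > 0."""
        for trial in range(10):
            X, Y = _random_problem(rng, n=25, p=12)
            for alpha in (0.1, 0.5, 1.0):
                res = fit_multitask_elasticnet(X, Y, alpha, 0.02)
                rows = res.coefficients
                partially_zero = np.any(rows != 0, axis=1) & np.any(rows == 0, axis=1)
                assert not partially_zero.any()
                assert res.n_retained == int(np.any(rows != 0, axis=1).sum())


class TestLambdaPath:
    def test_strictly_decreasing_and_log_even(self, rng):
        X, Y = _random_problem(rng)
        path = compute_lambda_path(X, Y, 0.5, n_lambda=20)
        assert np.all(np.diff(path.lambdas) < 0)
        ratios = path.lambdas[1:] / path.lambdas[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_doubling_responses_doubles_lambda_max(self, rng):
        X, Y = _random_problem(rng, y_scale=0.05)
        Y2 = CompositionMatrix.unchecked(Y.sample_ids, Y.cell_types,
                                         Y.values * 2)
        a = compute_lambda_path(X, Y, 0.5, n_lambda=5)
        b = compute_lambda_path(X, Y2, 0.5, n_lambda=5)
        assert np.isclose(b.lambdas[0], 2 * a.lambdas[0])

    def test_constant_responses_degenerate(self, rng):
        X, _ = _random_problem(rng)
        Y = CompositionMatrix(X.sample_ids, ["A", "B"],
                              np.full((len(X.sample_ids), 2), 0.5))
        with pytest.raises(DegenerateDataError):
            compute_lambda_path(X, Y, 0.5)

    def test_min_ratio_defaults_depend_on_aspect(self, rng):
        X, Y = _random_problem(rng, n=30, p=8)   # n > p
        assert compute_lambda_path(X, Y, 1.0).min_ratio == 1e-4
        X2, Y2 = _random_problem(rng, n=6, p=8)  # n <= p
        assert compute_lambda_path(X2, Y2, 1.0).min_ratio == 1e-2

    def test_warm_path_equals_cold_fits(self, rng):
        """Warm-started path solutions must match cold fits at each
        lambda within 1e-6 in objective value."""
        n, p, K = 30, 10, 3
        Xc = rng.normal(size=(n, p))
        Xc -= Xc.mean(axis=0)
        Yc = rng.normal(size=(n, K))
        Yc -= Yc.mean(axis=0)
        G, C = Xc.T @ Xc / n, Xc.T @ Yc / n
        lambdas = np.geomspace(0.5, 0.005, 12)
        warm = None
        for lam in lambdas:
            warm = cd_solve(G, C, lam, 0.5, B0=warm, tol=1e-9)
            cold = cd_solve(G, C, lam, 0.5, tol=1e-9)
            assert abs(objective(Xc, Yc, warm, lam, 0.5)
                       - objective(Xc, Yc, cold, lam, 0.5)) < 1e-6


class TestTuning:
    def test_chosen_pair_attains_grid_minimum(self, small_ds):
        tr = tune_hyperparameters(small_ds.expression, small_ds.silver,
                                  alphas=(1.0, 0.1), k=4, seed=3, n_lambda=25)
        grid_min = tr.grid["mean_mse"].min()
        chosen = tr.grid[(tr.grid["alpha"] == tr.chosen_alpha)
                         & (tr.grid["lam"] == tr.chosen_lambda)]
        assert float(chosen["mean_mse"].iloc[0]) == grid_min

    def test_identical_seed_identical_result(self, small_ds):
        kw = dict(alphas=(1.0, 0.1), k=4, n_lambda=15)
        a = tune_hyperparameters(small_ds.expression, small_ds.silver,
                                 seed=5, **kw)
        b = tune_hyperparameters(small_ds.expression, small_ds.silver,
                                 seed=5, **kw)
        assert a.chosen_alpha == b.chosen_alpha
        assert a.chosen_lambda == b.chosen_lambda
        assert np.array_equal(a.grid["mean_mse"], b.grid["mean_mse"])

    def test_k_exceeding_samples_rejected(self, small_ds):
        with pytest.raises(ConfigError):
            tune_hyperparameters(small_ds.expression, small_ds.silver, k=999)

    def test_misaligned_samples_rejected(self, rng):
        X, Y = _random_problem(rng)
        Y_bad = CompositionMatrix.unchecked(
            [s + "_x" for s in Y.sample_ids], Y.cell_types, Y.values)
        with pytest.raises(AlignmentError):
            CompositionModel(X, Y_bad)

    def test_negative_lambda_rejected(self, rng):
        X, Y = _random_problem(rng)
        with pytest.raises(ValidationError):
            fit_multitask_elasticnet(X, Y, 0.5, -0.1)


class TestPrediction:
    def test_zero_coefficient_model_predicts_intercepts(self, rng):
        X, Y = _random_problem(rng)
        path = compute_lambda_path(X, Y, 1.0, n_lambda=3)
        res = fit_multitask_elasticnet(X, Y, 1.0, path.lambdas[0])
        pred = predict_composition(res, X)
        assert np.allclose(pred.values, res.intercepts[None, :])

    def test_missing_feature_error_lists_ids(self, rng):
        X, Y = _random_problem(rng)
        res = fit_multitask_elasticnet(X, Y, 0.5, 0.01)
        X_sub = X.subset_features(X.feature_ids[:-2])
        with pytest.raises(MissingFeatureError) as exc:
            res.predict(X_sub)
        assert set(exc.value.missing) == set(X.feature_ids[-2:])

    def test_extra_features_ignored(self, rng):
        X, Y = _random_problem(rng, p=5)
        res = fit_multitask_elasticnet(X, Y, 0.5, 0.01)
        extra = ExpressionMatrix(X.feature_ids + ["extra"], X.sample_ids,
                                 np.vstack([X.values, np.zeros(X.n_samples)]))
        assert np.allclose(res.predict(extra).values, res.predict(X).values)

    def test_clip_renorm_rows_sum_to_one(self, rng):
        X, Y = _random_problem(rng)
        res = fit_multitask_elasticnet(X, Y, 0.1, 0.001)
        pred = res.predict(X, postprocess="clip_renorm")
        assert np.allclose(pred.values.sum(axis=1), 1.0)
        assert pred.closed

    def test_unpenalized_fit_recovers_noise_free_linear_labels(self, rng):
        """When expression is exactly affine in the compositions (and
        noise-free, n > p), lambda = 0 reproduces the training labels."""
        n, p, K = 120, 10, 4
        W = rng.dirichlet(np.ones(K), size=n)
        A = rng.normal(size=(p, K))  # full column rank w.p. 1
        offs = rng.normal(7, 1, size=(p, 1))
        X = ExpressionMatrix([f"g{j}" for j in range(p)],
                             [f"s{i}" for i in range(n)],
                             A @ W.T + offs)
        Y = CompositionMatrix([f"s{i}" for i in range(n)],
                              [f"c{k}" for k in range(K)], W, closed=True)
        res = fit_multitask_elasticnet(X, Y, 0.5, 0.0)
        pred = res.predict(X)
        assert np.max(np.abs(pred.values - W)) < 1e-3

    def test_shrinkage_flattens_predicted_on_true_slope(self, recovery_study):
        """Penalized prediction exhibits regression-to-the-mean: the slope
        of predicted-on-true stays at or below one on noisy data."""
        res = recovery_study["results"]
        test = recovery_study["test"]
        pred = res.predict(test.expression)
        for k, ct in enumerate(pred.cell_types):
            t = test.truth.values[:, k]
            p = pred.values[:, k]
            slope = np.polyfit(t, p, 1)[0]
            assert slope <= 1.05, (ct, slope)


class TestSerialization:
    def test_save_load_bit_identical(self, rng, tmp_path):
        from bloodmix.model import CompositionResults

        X, Y = _random_problem(rng)
        res = fit_multitask_elasticnet(X, Y, 0.5, 0.01)
        res.save(tmp_path / "m.json")
        back = CompositionResults.load(tmp_path / "m.json")
        assert np.array_equal(back.coefficients, res.coefficients)
        assert np.array_equal(back.intercepts, res.intercepts)
        assert back.feature_ids == res.feature_ids
        assert (back.alpha, back.lam) == (res.alpha, res.lam)
        assert np.array_equal(back.predict(X).values, res.predict(X).values)

    def test_summary_mentions_hyperparameters(self, rng):
        X, Y = _random_problem(rng)
        res = fit_multitask_elasticnet(X, Y, 0.5, 0.01)
        text = res.summary()
        assert "alpha" in text and "lambda" in text
        assert str(res.n_retained) in text
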