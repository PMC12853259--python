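"""TRF estimation: lagged designs, ridge/OLS fits, cross-validation."""

import numpy as np
import pytest

from chimeratrf.trf import (
    fit_ols,
    fit_ridge,
    lag_samples,
    lagged_design,
    loo_crossval,
    precompute_trial_stats,
    predict,
)


def _simulate_trials(n_trials, T, kernels, rng, noise_sd=0.0, n_channels=2):
    """Impulse-train trials generated from known (F, L) kernels."""
    F, L = kernels.shape
    lags = np.arange(L)
    gains = np.linspace(1.0, 0.5, n_channels)
    trials = []
    for _ in range(n_trials):
        X = np.zeros((T, F))
        for f in range(F):
            idx = rng.choice(T - L, size=max(T // 40, 3), replace=False)
            X[idx, f] = 1.0
        design = lagged_design(X, lags)
        clean = design @ kernels.reshape(-1)
        Y = clean[:, None] * gains[None, :] + noise_sd * rng.standard_normal((T, n_channels))
        trials.append((design, Y))
    return trials, lags, gains


class TestLaggedDesign:
    def test_zero_lag_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(lagged_design(x, np.array([0]))[:, 0], x)

    def test_impulse_gives_shifted_identity(self):
        x = np.zeros(20)
        x[5] = 1.0
        design = lagged_design(x, np.arange(4))
        for j in range(4):
            assert design[5 + j, j] == 1.0
        assert design.sum() == 4

    def test_negative_lag_shifts_backward(self):
        x = np.zeros(10)
        x[5] = 1.0
        design = lagged_design(x, np.array([-2]))
        assert design[3, 0] == 1.0

    def test_column_count(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        assert lagged_design(X, np.arange(3)).shape == (30, 6)

    def test_lag_window_arithmetic(self):
        lags = lag_samples((-100, 800), 125.0)
        assert lags[0] == -12 and lags[-1] == 100  # -12.5 rounds to even
        with pytest.raises(ValueError, match="empty"):
            lag_samples((100, -100), 125.0)


class TestRidge:
    def test_shrinkage_monotone_in_lambda(self, rng):
        kernels = rng.standard_normal((2, 8))
        trials, lags, _ = _simulate_trials(2, 400, kernels, rng, noise_sd=0.5)
        norms = [
            np.linalg.norm(fit_ridge(trials, lam, ("a", "b"), lags).coef)
            for lam in (1e-2, 1e1, 1e4, 1e7)
        ]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-3 * norms[0]

    def test_noiseless_recovery(self, rng):
        kernels = rng.standard_normal((2, 10))
        trials, lags, gains = _simulate_trials(3, 500, kernels, rng, noise_sd=0.0)
        model = fit_ridge(trials, 1e-6, ("a", "b"), lags)
        truth = np.outer(kernels.reshape(-1), gains)
        err = np.linalg.norm(model.coef - truth) / np.linalg.norm(truth)
        assert err <= 1e-6

    def test_duplicated_trials_leave_solution_unchanged(self, rng):
        kernels = rng.standard_normal((1, 6))
        trials, lags, _ = _simulate_trials(2, 300, kernels, rng, noise_sd=0.3)
        single = fit_ridge(trials, 1.0, ("a",), lags)
        # duplication doubles the Gram; an absolute penalty must double with
        # it for exact invariance, and is near-invariant unscaled
        doubled_matched = fit_ridge(trials + trials, 2.0, ("a",), lags)
        doubled = fit_ridge(trials + trials, 1.0, ("a",), lags)
        assert np.allclose(single.coef, doubled_matched.coef, atol=1e-10)
        assert np.allclose(single.coef, doubled.coef, rtol=2e-2, atol=1e-3)
        # with the normalized penalty the invariance is exact as stated
        a = fit_ridge(trials, 1.0, ("a",), lags, normalize_lambda=True)
        b = fit_ridge(trials + trials, 1.0, ("a",), lags, normalize_lambda=True)
        assert np.allclose(a.coef, b.coef, atol=1e-10)

    def test_singular_at_zero_lambda(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([x, x])  # duplicated column
        Y = rng.standard_normal((100, 1))
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            fit_ridge([(X, Y)], 0.0, ("a", "b"), np.array([0]))


class TestLooCrossval:
    def test_grid_of_one_returns_it(self, rng):
        kernels = rng.standard_normal((1, 6))
        trials, lags, _ = _simulate_trials(3, 300, kernels, rng, noise_sd=0.5)
        report = loo_crossval(trials, lambda_grid=[0.37], feature_names=("a",), lags=lags)
        assert report.best_lambda == 0.37
        assert len(report.r_per_trial) == 3

    def test_high_snr_prefers_weak_regularization(self, rng):
        kernels = rng.standard_normal((1, 8))
        trials, lags, _ = _simulate_trials(4, 600, kernels, rng, noise_sd=0.01)
        report = loo_crossval(trials, feature_names=("a",), lags=lags)
        assert report.best_lambda <= 0.1
        assert report.mean_r >= 0.9

    def test_pure_noise_r_near_zero(self, rng):
        T = 2000
        trials = []
        lags = np.arange(5)
        for _ in range(4):
            X = np.zeros((T, 1))
            X[rng.choice(T - 5, 40, replace=False), 0] = 1.0
            trials.append((lagged_design(X, lags), rng.standard_normal((T, 2))))
        report = loo_crossval(trials, feature_names=("a",), lags=lags)
        assert abs(report.mean_r) < 2 / np.sqrt(T)

    def test_requires_three_trials(self, rng):
        kernels = rng.standard_normal((1, 4))
        trials, lags, _ = _simulate_trials(2, 200, kernels, rng)
        with pytest.raises(ValueError, match=">= 3 trials"):
            loo_crossval(trials, feature_names=("a",), lags=lags)

    def test_precomputed_stats_match_direct(self, rng):
        kernels = rng.standard_normal((2, 5))
        trials, lags, _ = _simulate_trials(4, 300, kernels, rng, noise_sd=0.4)
        stats = [precompute_trial_stats(X) for X, _ in trials]
        direct = loo_crossval(trials, feature_names=("a", "b"), lags=lags, refit=False)
        cached = loo_crossval(
            trials, feature_names=("a", "b"), lags=lags, trial_stats=stats, refit=False
        )
        assert np.allclose(direct.r_per_trial, cached.r_per_trial)
        assert direct.best_lambda == cached.best_lambda


class TestOls:
    def test_isolated_impulses_equal_epoch_average(self, rng):
        """Non-overlapping response windows: OLS kernel == mean evoked epoch."""
        T, L = 3000, 10
        lags = np.arange(L)
        onsets = np.arange(50, T - L, 60)  # spacing 60 > L: no overlap
        X = np.zeros((T, 1))
        X[onsets, 0] = 1.0
        kernel = rng.standard_normal(L)
        Y = lagged_design(X, lags) @ kernel
        Y = (Y + 0.3 * rng.standard_normal(T))[:, None]
        model = fit_ols([(lagged_design(X, lags), Y)], ("onset",), lags,
                        fit_intercept=False)
        epochs = np.stack([Y[o : o + L, 0] for o in onsets])
        assert np.abs(model.coef[:, 0] - epochs.mean(axis=0)).max() <= 1e-8

    def test_overlapping_impulses_exact_recovery(self, rng):
        kernels = rng.standard_normal((2, 12))
        trials, lags, gains = _simulate_trials(2, 400, kernels, rng, noise_sd=0.0)
        model = fit_ols(trials, ("a", "b"), lags)
        truth = np.outer(kernels.reshape(-1), gains)
        assert np.abs(model.coef - truth).max() <= 1e-8

    def test_null_extra_regressor_stays_zero(self, rng):
        """When downbeats share the onset kernel, the DB* kernel fits ~0."""
        T, L = 6000, 8
        lags = np.arange(L)
        kernel = np.array([0.0, 1.0, 2.0, 1.0, 0.3, 0.0, -0.4, 0.0])
        onset = np.zeros(T)
        idx = np.sort(rng.choice(np.arange(0, T - L, 12), 300, replace=False))
        onset[idx] = 1.0
        db = np.zeros(T)
        db[idx[::3]] = 1.0  # downbeats: a subset, same response as any onset
        Y = (lagged_design(onset, lags) @ kernel + 0.2 * rng.standard_normal(T))[:, None]
        X = lagged_design(np.column_stack([onset, db]), lags)
        model = fit_ols([(X, Y)], ("onset", "DBo"), lags)
        assert np.abs(model.kernel("DBo")).max() < 0.15
        assert np.abs(model.kernel("onset")[:, 0] - kernel).max() < 0.1

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols([(X, x[:, None])], ("a", "b"), np.array([0]))


class TestPredict:
    def test_zero_input_gives_intercept(self, rng):
        kernels = rng.standard_normal((1, 5))
        trials, lags, _ = _simulate_trials(2, 200, kernels, rng, noise_sd=0.1)
        model = fit_ridge(trials, 1.0, ("a",), lags)
        out = predict(model, {"a": np.zeros(30)})
        assert np.allclose(out, np.broadcast_to(model.intercept, out.shape))

    def test_linearity(self, rng):
        kernels = rng.standard_normal((1, 5))
        trials, lags, _ = _simulate_trials(2, 200, kernels, rng, noise_sd=0.1)
        model = fit_ridge(trials, 1.0, ("a",), lags)
        x = rng.standard_normal(100)
        base = predict(model, {"a": x})
        scaled = predict(model, {"a": 3.0 * x})
        assert np.allclose(scaled - model.intercept, 3.0 * (base - model.intercept))

    def test_name_mismatch(self, rng):
        kernels = rng.standard_normal((1, 5))
        trials, lags, _ = _simulate_trials(2, 200, kernels, rng)
        model = fit_ridge(trials, 1.0, ("a",), lags)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, {"b": np.zeros(10)})

    def test_reproduces_noiseless_training_data(self, rng):
        kernels = rng.standard_normal((1, 6))
        trials, lags, _ = _simulate_trials(1, 300, kernels, rng, noise_sd=0.0)
        model = fit_ols(trials, ("a",), lags)
        X_design, Y = trials[0]
        pred = X_design @ model.coef + model.intercept
        assert np.abs(pred - Y).max() <= 1e-8
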