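"""Temporal response function (TRF) estimation.

A TRF is a per-feature, per-channel linear kernel over time lags mapping
stimulus features to the EEG signal.  The stimulus signals are expanded
into a lagged design matrix (zero-padded at trial edges, feature-major /
lag-minor column order) and the kernels are estimated either by

* ridge regression with leave-one-out cross-validation across trials
  (expectation models; lambda grid 1e-3..1e3, chosen per participant and
  model by mean Pearson r of the predicted vs held-out EEG, averaged over
  channels), or
* ordinary least squares on all trials pooled (downbeat impulse models,
  where unpenalized weights keep the ERP-like interpretation).

Ridge fits z-score the design columns with training-fold statistics and
report kernels back on the original feature scale; OLS leaves impulse
regressors unscaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "TRFModel",
    "FitReport",
    "lag_samples",
    "lagged_design",
    "fit_ridge",
    "fit_ols",
    "loo_crossval",
    "predict",
    "TrialStats",
    "precompute_trial_stats",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_LAGS_MS",
]

DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-3, 4))
DEFAULT_LAGS_MS = (-100.0, 800.0)


def lag_samples(lags_ms: tuple[float, float], fs: float) -> np.ndarray:
    """Integer sample lags covering the window [min_ms, max_ms]."""
    lo = int(round(lags_ms[0] * fs / 1000.0))
    hi = int(round(lags_ms[1] * fs / 1000.0))
    if hi < lo:
        raise ValueError("empty lag window")
    return np.arange(lo, hi + 1)


def lagged_design(X: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Expand feature signals into time-shifted copies.

    ``X`` is (T,) or (T, F); the result is (T, F*L) with column
    ``f*L + j`` holding ``X[t - lags[j], f]`` (zero outside the trial).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    lags = np.asarray(lags, dtype=int)
    if lags.size == 0:
        raise ValueError("empty lag window")
    T, F = X.shape
    L = lags.size
    out = np.zeros((T, F * L))
    for f in range(F):
        for j, lag in enumerate(lags):
            col = out[:, f * L + j]
            if lag >= 0:
                col[lag:] = X[: T - lag, f] if lag < T else 0.0
            else:
                col[:lag] = X[-lag:, f]
    return out


def _column_names(feature_names, lags) -> list[str]:
    return [f"{name}@lag{lag}" for name in feature_names for lag in lags]


@dataclass
class TRFModel:
    """Fitted kernels (original feature scale) plus the design metadata."""

    coef: np.ndarray  # (n_cols, n_channels)
    intercept: np.ndarray  # (n_channels,)
    feature_names: tuple[str, ...]
    lags: np.ndarray  # sample lags
    fs: float
    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.coef.shape[0] != len(self.feature_names) * len(self.lags):
            raise ValueError("coefficient rows inconsistent with features x lags")

    @property
    def n_channels(self) -> int:
        return self.coef.shape[1]

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    @property
    def kernels(self) -> np.ndarray:
        """Kernels as a (feature, lag, channel) array."""
        F, L = len(self.feature_names), len(self.lags)
        return self.coef.reshape(F, L, self.n_channels)

    def kernel(self, name: str) -> np.ndarray:
        """(lag, channel) kernel of one named feature."""
        return self.kernels[self.feature_names.index(name)]


@dataclass
class FitReport:
    """Cross-validated prediction accuracy of one TRF model fit."""

    r_per_trial: np.ndarray  # Pearson r averaged over channels, per held-out trial
    best_lambda: float
    model_tag: str = ""
    participant: str = ""
    stim_category: str = ""
    lambda_grid: tuple = ()
    mean_r_by_lambda: np.ndarray | None = None
    model: TRFModel | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_per_trial)
        if np.any(r < -1 - 1e-9) or np.any(r > 1 + 1e-9):
            raise ValueError("Pearson r outside [-1, 1]")

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_per_trial))


# ---------------------------------------------------------------------------
# Sufficient statistics (shared across subjects / CV folds)
# ---------------------------------------------------------------------------


@dataclass
class TrialStats:
    """Per-trial Gram statistics of a design matrix (reused across fits)."""

    S: np.ndarray  # X'X, (p, p)
    u: np.ndarray  # X'1, (p,)
    n: int

    def subset(self, idx) -> "TrialStats":
        idx = np.asarray(idx)
        return TrialStats(self.S[np.ix_(idx, idx)], self.u[idx], self.n)


def precompute_trial_stats(X: np.ndarray) -> TrialStats:
    X = np.asarray(X, dtype=float)
    return TrialStats(X.T @ X, X.sum(axis=0), X.shape[0])


def _standardized_system(S, u, n, B, sY, standardize):
    """Gram and cross-products of the (optionally z-scored) centered system."""
    mu = u / n
    ybar = sY / n
    if standardize:
        var = np.clip(np.diag(S) / n - mu**2, 0.0, None)
        sd = np.sqrt(var)
        sd = np.where(sd < 1e-12, 1.0, sd)
    else:
        sd = np.ones_like(mu)
    G = (S - n * np.outer(mu, mu)) / np.outer(sd, sd)
    Gb = (B - np.outer(mu, sY)) / sd[:, None]
    return G, Gb, mu, sd, ybar


def _solve_ridge_eig(G, Gb, lam_values):
    e, V = np.linalg.eigh(G)
    e = np.clip(e, 0.0, None)
    VtGb = V.T @ Gb
    sols = []
    for lam in lam_values:
        if lam == 0 and e.min() <= 1e-10 * max(e.max(), 1.0):
            raise np.linalg.LinAlgError(
                "singular system at lambda=0; use lambda > 0"
            )
        sols.append(V @ (VtGb / (e + lam)[:, None]))
    return sols


def fit_ridge(
    trials,
    lam: float,
    feature_names=("feature",),
    lags=None,
    fs: float = 125.0,
    standardize: bool = True,
    normalize_lambda: bool = False,
) -> TRFModel:
    """Closed-form ridge fit on all trials pooled.

    ``trials`` is a list of ``(X_design, Y_eeg)`` pairs whose designs were
    built by :func:`lagged_design` with the given lags.  Kernels are
    reported on the original feature scale (standardization is undone).

    With ``normalize_lambda`` the penalty is ``lam * mean(diag(Z'Z))``,
    putting lambda on a data-size-free scale where the 1e-3..1e3 grid spans
    under- to over-regularized (the convention of the mTRF-style
    cross-validation); by default lambda is applied as an absolute penalty,
    so ``lam -> 0`` reduces exactly to least squares.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = trials[0][0].shape[1]
    if lags is None:
        if p % len(feature_names):
            raise ValueError("cannot infer lags: columns not divisible by features")
        lags = np.arange(p // len(feature_names))
    S = np.zeros((p, p))
    u = np.zeros(p)
    n = 0
    C = trials[0][1].shape[1] if trials[0][1].ndim > 1 else 1
    B = np.zeros((p, C))
    sY = np.zeros(C)
    for X, Y in trials:
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        S += X.T @ X
        u += X.sum(axis=0)
        n += X.shape[0]
        B += X.T @ Y
        sY += Y.sum(axis=0)
    G, Gb, mu, sd, ybar = _standardized_system(S, u, n, B, sY, standardize)
    lam_eff = lam * np.diag(G).mean() if normalize_lambda else lam
    (wz,) = _solve_ridge_eig(G, Gb, [lam_eff])
    coef = wz / sd[:, None]
    intercept = ybar - mu @ coef
    return TRFModel(coef, intercept, tuple(feature_names), np.asarray(lags), fs, lam)


def loo_crossval(
    trials,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    feature_names=("feature",),
    lags=None,
    fs: float = 125.0,
    standardize: bool = True,
    normalize_lambda: bool = True,
    trial_stats=None,
    model_tag: str = "",
    participant: str = "",
    stim_category: str = "",
    refit: bool = True,
) -> FitReport:
    """Leave-one-trial-out cross-validation over a ridge lambda grid.

    For each lambda the model is fitted on N-1 trials and the held-out
    trial's EEG is predicted; the Pearson correlation between predicted and
    recorded signal is computed per channel and averaged.  The lambda
    maximizing the mean accuracy is selected and the per-trial accuracies
    at that lambda are reported (with a refit on all trials attached).

    ``trial_stats`` may carry precomputed :class:`TrialStats` for each
    trial's design (they depend only on the stimuli, so they can be shared
    across subjects and feature-subset models).
    """
    if len(trials) < 3:
        raise ValueError("leave-one-out cross-validation requires >= 3 trials")
    lam_values = list(lambda_grid)
    p = trials[0][0].shape[1]
    if lags is None:
        if p % len(feature_names):
            raise ValueError("cannot infer lags: columns not divisible by features")
        lags = np.arange(p // len(feature_names))
    if trial_stats is None:
        trial_stats = [precompute_trial_stats(X) for X, _ in trials]
    Ys = [np.atleast_2d(np.asarray(Y, dtype=float).T).T for _, Y in trials]
    C = Ys[0].shape[1]
    Bs = [X.T @ Y for (X, _), Y in zip(trials, Ys)]
    sYs = [Y.sum(axis=0) for Y in Ys]

    S_tot = sum(st.S for st in trial_stats)
    u_tot = sum(st.u for st in trial_stats)
    n_tot = sum(st.n for st in trial_stats)
    B_tot = sum(Bs)
    sY_tot = sum(sYs)

    n_folds = len(trials)
    r_grid = np.zeros((n_folds, len(lam_values)))
    warned_constant = False
    for j in range(n_folds):
        S = S_tot - trial_stats[j].S
        u = u_tot - trial_stats[j].u
        n = n_tot - trial_stats[j].n
        B = B_tot - Bs[j]
        sY = sY_tot - sYs[j]
        G, Gb, mu, sd, ybar = _standardized_system(S, u, n, B, sY, standardize)
        scale = np.diag(G).mean() if normalize_lambda else 1.0
        sols = _solve_ridge_eig(G, Gb, [lam * scale for lam in lam_values])
        Xj, Yj = trials[j][0], Ys[j]
        Zj = (Xj - mu) / sd
        Yc = Yj - Yj.mean(axis=0)
        y_sd = Yj.std(axis=0)
        const_y = y_sd < 1e-15
        for li, wz in enumerate(sols):
            pred = Zj @ wz  # + ybar, irrelevant for correlation
            pred_c = pred - pred.mean(axis=0)
            p_sd = pred_c.std(axis=0)
            denom = p_sd * y_sd * Xj.shape[0]
            valid = (p_sd > 1e-15) & ~const_y
            r = np.zeros(C)
            r[valid] = (pred_c[:, valid] * Yc[:, valid]).sum(axis=0) / denom[valid]
            if np.any(~valid) and not warned_constant:
                warnings.warn("constant channel in held-out trial: r set to 0", stacklevel=2)
                warned_constant = True
            r_grid[j, li] = r.mean()
    mean_r = r_grid.mean(axis=0)
    best = int(np.argmax(mean_r))
    best_lambda = float(lam_values[best])
    model = None
    if refit:
        model = fit_ridge(
            trials, best_lambda, feature_names, lags, fs, standardize, normalize_lambda
        )
    return FitReport(
        r_per_trial=r_grid[:, best],
        best_lambda=best_lambda,
        model_tag=model_tag,
        participant=participant,
        stim_category=stim_category,
        lambda_grid=tuple(lam_values),
        mean_r_by_lambda=mean_r,
        model=model,
    )


def fit_ols(
    trials,
    feature_names=("feature",),
    lags=None,
    fs: float = 125.0,
    fit_intercept: bool = True,
) -> TRFModel:
    """Ordinary least squares TRF on all trials pooled (impulse models).

    Regressors are left unscaled so the kernels read directly as evoked
    responses per unit impulse.  A rank-deficient design raises an error
    naming the collinear columns (found by pivoted QR).
    """
    X = np.vstack([X for X, _ in trials])
    Y = np.vstack([np.atleast_2d(np.asarray(Y, dtype=float).T).T for _, Y in trials])
    p = X.shape[1]
    if lags is None:
        if p % len(feature_names):
            raise ValueError("cannot infer lags: columns not divisible by features")
        lags = np.arange(p // len(feature_names))
    A = np.column_stack([X, np.ones(X.shape[0])]) if fit_intercept else X
    coef_full, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < A.shape[1]:
        _, R, piv = sla.qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = sorted(piv[np.flatnonzero(diag < tol)])
        names = _column_names(feature_names, lags) + (
            ["intercept"] if fit_intercept else []
        )
        bad_names = [names[b] for b in bad if b < len(names)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad_names}")
    if fit_intercept:
        coef, intercept = coef_full[:-1], coef_full[-1]
    else:
        coef, intercept = coef_full, np.zeros(Y.shape[1])
    return TRFModel(coef, intercept, tuple(feature_names), np.asarray(lags), fs, 0.0)


def predict(model: TRFModel, X) -> np.ndarray:
    """Predict EEG from feature signals.

    ``X`` is either a dict of named signals (checked against the model's
    feature names) or a (T, F) array in the model's feature order.
    """
    if isinstance(X, dict):
        missing = [n for n in model.feature_names if n not in X]
        if missing:
            raise ValueError(f"feature name mismatch: missing {missing}")
        X = np.column_stack([X[n] for n in model.feature_names])
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
    design = lagged_design(X, model.lags)
    return design @ model.coef + model.intercept
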