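"""End-to-end analyses on simulated (or externally supplied) studies.

Glue between the synthetic generator and the TRF/stats layers:

* :func:`fit_expectation_models` -- per subject and stimulus category, fit
  the acoustic baseline (A: flux + onset) and the expectation models
  (AM: + Sp/Ep/St/Et; AMp: + Sp/Ep; AMt: + St/Et) by ridge regression with
  leave-one-out cross-validation, returning :class:`~chimeratrf.trf.FitReport`
  rows ready for Δr tables.
* :func:`fit_downbeat_models` -- per subject and category, unpenalized OLS
  TRFs on the impulse regressors (onset + DBo for originals; onset + DBct +
  DBcp + DBcpt for chimeras).

Design matrices and their Gram statistics depend only on the stimuli, so
they are computed once and shared across subjects and nested feature
subsets; subjects are estimated jointly by stacking their EEG channels,
which is algebraically identical to separate per-subject fits.
"""

from __future__ import annotations

import numpy as np

from .stats import delta_r_table
from .synthetic_data import SimStudy
from .trf import (
    DEFAULT_LAMBDA_GRID,
    FitReport,
    TRFModel,
    fit_ols,
    lag_samples,
    lagged_design,
    loo_crossval,
    precompute_trial_stats,
)

__all__ = [
    "MODEL_FEATURES",
    "fit_expectation_models",
    "fit_downbeat_models",
    "downbeat_kernel_stack",
    "expectation_delta_r",
]

_ACOUSTIC = ("flux", "onset")
_EXPECTATION = ("Sp", "Ep", "St", "Et")

#: Feature sets of the four expectation-encoding TRF models.
MODEL_FEATURES: dict[str, tuple[str, ...]] = {
    "A": _ACOUSTIC,
    "AM": _ACOUSTIC + _EXPECTATION,
    "AMp": _ACOUSTIC + ("Sp", "Ep"),
    "AMt": _ACOUSTIC + ("St", "Et"),
}


def _available_features(study: SimStudy, names) -> tuple[str, ...]:
    present = study.trials[0].regressors.signals
    return tuple(n for n in names if n in present)


def fit_expectation_models(
    study: SimStudy,
    model_tags=("A", "AM", "AMp", "AMt"),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    lags_ms: tuple[float, float] | None = None,
    categories=("original", "chimeric"),
) -> list[FitReport]:
    """Cross-validated ridge fits of the expectation-encoding models.

    Returns one report per subject x category x model; lambda is selected
    per subject and model, as in the source analysis.
    """
    fs = study.config.fs
    lags = lag_samples(lags_ms or study.config.lags_ms, fs)
    L = len(lags)
    full = _available_features(study, MODEL_FEATURES["AM"])
    col_idx = {
        tag: np.concatenate(
            [np.arange(full.index(f) * L, (full.index(f) + 1) * L) for f in names
             if f in full]
        )
        for tag, names in MODEL_FEATURES.items()
        if tag in model_tags
    }
    reports: list[FitReport] = []
    for category in categories:
        idx = study.trial_indices(category)
        designs = [
            lagged_design(study.trials[i].regressors.matrix(full), lags) for i in idx
        ]
        stats_full = [precompute_trial_stats(X) for X in designs]
        for tag in model_tags:
            cols = col_idx[tag]
            feats = tuple(f for f in MODEL_FEATURES[tag] if f in full)
            sub_designs = [X[:, cols] for X in designs]
            sub_stats = [st.subset(cols) for st in stats_full]
            for s in range(study.n_subjects):
                trials = [
                    (X, study.eeg[s][i]) for X, i in zip(sub_designs, idx)
                ]
                reports.append(
                    loo_crossval(
                        trials,
                        lambda_grid=lambda_grid,
                        feature_names=feats,
                        lags=lags,
                        fs=fs,
                        trial_stats=sub_stats,
                        model_tag=tag,
                        participant=study.subjects.iloc[s]["participant"],
                        stim_category=category,
                        refit=False,
                    )
                )
    return reports


def fit_downbeat_models(
    study: SimStudy,
    lags_ms: tuple[float, float] | None = None,
    categories=("original", "chimeric"),
) -> dict[str, list[TRFModel]]:
    """Per-subject OLS TRFs on the downbeat impulse regressors.

    All subjects share the stimuli, so their EEG channels are stacked and
    fitted in a single pooled OLS solve per category, then split back into
    per-subject models (identical to fitting each subject separately).
    """
    fs = study.config.fs
    lags = lag_samples(lags_ms or study.config.lags_ms, fs)
    feature_sets = {
        "original": ("onset", "DBo"),
        "chimeric": ("onset", "DBct", "DBcp", "DBcpt"),
    }
    out: dict[str, list[TRFModel]] = {}
    for category in categories:
        names = feature_sets[category]
        idx = study.trial_indices(category)
        trials = []
        for i in idx:
            X = lagged_design(study.trials[i].regressors.matrix(names), lags)
            Y = np.concatenate([study.eeg[s][i] for s in range(study.n_subjects)], axis=1)
            trials.append((X, Y))
        pooled = fit_ols(trials, feature_names=names, lags=lags, fs=fs)
        n_ch = study.eeg[0][idx[0]].shape[1]
        models = []
        for s in range(study.n_subjects):
            sl = slice(s * n_ch, (s + 1) * n_ch)
            models.append(
                TRFModel(
                    pooled.coef[:, sl],
                    pooled.intercept[sl],
                    pooled.feature_names,
                    pooled.lags,
                    fs,
                    0.0,
                )
            )
        out[category] = models
    return out


def downbeat_kernel_stack(models: list[TRFModel], feature: str) -> np.ndarray:
    """Per-subject kernels of one regressor as (subjects, channels, lags)."""
    return np.stack([m.kernel(feature).T for m in models])


def expectation_delta_r(study: SimStudy, reports: list[FitReport] | None = None, **kwargs):
    """Δr table of a study (fitting the models first if needed)."""
    if reports is None:
        reports = fit_expectation_models(study, **kwargs)
    musicianship = dict(
        zip(study.subjects["participant"], study.subjects["musicianship_years"])
    )
    return delta_r_table(reports, musicianship=musicianship)
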