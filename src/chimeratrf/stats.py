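"""Statistical layer: Δr contrasts, Holm-corrected paired tests, TFCE
sign-flip permutation inference, and peak-amplitude correlations with FDR.

The group-level inference on channel x lag TRF weight maps follows the
standard sensor-space recipe: a one-sample t map across subjects is
enhanced with threshold-free cluster enhancement (TFCE) over a
spatiotemporal adjacency graph (neighboring sensors, consecutive time
points), and family-wise error is controlled by comparing the observed
scores against the distribution of the maximum enhanced score under
subject-level sign-flipping permutations.  Two-sided tests enhance the +t
and -t maps separately and compare |score| against the max-|score| null.

The linear mixed-effects models of the original analysis are deliberately
not fitted here; :func:`mixed_model_table` exports the long-format table
(r / Δr with model, category, musicianship, preference, participant and
stimulus-set columns) that any standard mixed-model tool consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats as ss
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .trf import FitReport

__all__ = [
    "MONTAGE_32_POSITIONS",
    "MONTAGE_32_CHANNELS",
    "channel_adjacency",
    "spatiotemporal_adjacency",
    "TFCEResult",
    "delta_r_table",
    "mixed_model_table",
    "paired_tests_holm",
    "tfce",
    "signflip_permutation",
    "peak_correlation_fdr",
]

# ---------------------------------------------------------------------------
# 10-20 montage fixture (32 active channels, schematic 2D head positions)
# ---------------------------------------------------------------------------

#: Approximate 2D positions (x toward the right ear, y toward the nasion) of
#: the 32-channel 10-20 layout used by the synthetic studies.  Injectable:
#: every stats function takes an adjacency, so other montages plug in freely.
MONTAGE_32_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.75, 0.50), "F3": (-0.40, 0.52), "Fz": (0.0, 0.55),
    "F4": (0.40, 0.52), "F8": (0.75, 0.50),
    "FC5": (-0.60, 0.25), "FC1": (-0.20, 0.28), "FC2": (0.20, 0.28), "FC6": (0.60, 0.25),
    "T7": (-0.90, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T8": (0.90, 0.0),
    "TP9": (-1.00, -0.30), "CP5": (-0.60, -0.25), "CP1": (-0.20, -0.28),
    "CP2": (0.20, -0.28), "CP6": (0.60, -0.25), "TP10": (1.00, -0.30),
    "P7": (-0.75, -0.50), "P3": (-0.40, -0.52), "Pz": (0.0, -0.55),
    "P4": (0.40, -0.52), "P8": (0.75, -0.50),
    "PO9": (-0.85, -0.75), "O1": (-0.31, -0.90), "Oz": (0.0, -0.92),
    "O2": (0.31, -0.90), "PO10": (0.85, -0.75),
}

MONTAGE_32_CHANNELS: tuple[str, ...] = tuple(MONTAGE_32_POSITIONS)


def channel_adjacency(
    channels=MONTAGE_32_CHANNELS,
    positions: dict | None = None,
    radius: float = 0.55,
) -> sparse.csr_matrix:
    """Sensor neighbor graph: channels within ``radius`` are adjacent."""
    if positions is None:
        positions = MONTAGE_32_POSITIONS
    pos = np.array([positions[c] for c in channels])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d <= radius) & ~np.eye(len(channels), dtype=bool)
    return sparse.csr_matrix(adj)


def spatiotemporal_adjacency(ch_adj: sparse.spmatrix, n_lags: int) -> sparse.csr_matrix:
    """Adjacency over (channel, lag) nodes, C-order flattening of (C, L).

    Neighbors are adjacent channels at the same lag plus the same channel at
    consecutive lags.
    """
    ch_adj = sparse.csr_matrix(ch_adj)
    if (ch_adj != ch_adj.T).nnz:
        raise ValueError("channel adjacency must be symmetric")
    n_ch = ch_adj.shape[0]
    eye_l = sparse.identity(n_lags, format="csr")
    chain = sparse.diags([np.ones(n_lags - 1)] * 2, offsets=[1, -1], format="csr")
    eye_c = sparse.identity(n_ch, format="csr")
    return (sparse.kron(ch_adj, eye_l) + sparse.kron(eye_c, chain)).tocsr()


# ---------------------------------------------------------------------------
# Δr tables
# ---------------------------------------------------------------------------


def delta_r_table(
    reports: list[FitReport],
    musicianship: dict | None = None,
    preference: dict | None = None,
    baseline_tag: str = "A",
) -> pd.DataFrame:
    """Expectation-effect table: Δr = r(model) - r(A) per participant x category.

    One row per participant x stimulus category x contrast (model - A),
    computed from matched :class:`FitReport` objects.  Optional per-
    participant musicianship years and per-(participant, category)
    preference ratings are attached for downstream mixed-model fitting.
    """
    by_key = {(r.participant, r.stim_category, r.model_tag): r for r in reports}
    if len(by_key) != len(reports):
        raise ValueError("duplicate (participant, category, model) reports")
    rows = []
    for (part, cat, tag), rep in sorted(by_key.items()):
        if tag == baseline_tag:
            continue
        base = by_key.get((part, cat, baseline_tag))
        if base is None:
            raise ValueError(f"no baseline '{baseline_tag}' report for {part}/{cat}")
        rows.append(
            {
                "participant": part,
                "stim_category": cat,
                "contrast": f"{tag}-{baseline_tag}",
                "delta_r": rep.mean_r - base.mean_r,
                "musicianship_years": (musicianship or {}).get(part, np.nan),
                "preference": (preference or {}).get((part, cat), np.nan),
            }
        )
    if not rows:
        raise ValueError("no non-baseline reports to contrast")
    return pd.DataFrame(rows)


def mixed_model_table(
    reports: list[FitReport],
    musicianship: dict | None = None,
    preference: dict | None = None,
    stimset_by_trial: list | None = None,
) -> pd.DataFrame:
    """Long-format per-trial prediction accuracies for mixed-model software.

    Columns mirror the terms of the standard formula
    ``r ~ TRFmodel + stimcategory + musicianship + preference + (1|participant)
    + (1|stimset)``.
    """
    rows = []
    for rep in reports:
        for t, r in enumerate(rep.r_per_trial):
            rows.append(
                {
                    "r": float(r),
                    "TRFmodel": rep.model_tag,
                    "stimcategory": rep.stim_category,
                    "musicianship": (musicianship or {}).get(rep.participant, np.nan),
                    "preference": (preference or {}).get(
                        (rep.participant, rep.stim_category), np.nan
                    ),
                    "participant": rep.participant,
                    "trial": t,
                    "stimset": stimset_by_trial[t] if stimset_by_trial else t,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired tests with Holm correction
# ---------------------------------------------------------------------------


def paired_tests_holm(values_by_condition: dict) -> pd.DataFrame:
    """Two-sided paired t tests with Holm-Bonferroni step-down adjustment.

    ``values_by_condition`` maps a comparison label to a pair ``(x, y)`` of
    equal-length paired samples.  Identical vectors give t = 0, p = 1;
    nonzero constant differences have an undefined p (reported as NaN and
    never rejected).
    """
    labels, t_vals, p_raw = [], [], []
    for label, (x, y) in values_by_condition.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size < 3:
            raise ValueError(f"'{label}': paired samples of equal length >= 3 required")
        d = x - y
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        elif np.std(d, ddof=1) < 1e-15:
            warnings.warn(f"'{label}': zero variance of differences; p undefined", stacklevel=2)
            t, p = np.inf if d.mean() > 0 else -np.inf, np.nan
        else:
            t, p = ss.ttest_rel(x, y)
        labels.append(label)
        t_vals.append(float(t))
        p_raw.append(float(p))
    p_raw = np.asarray(p_raw)
    p_holm = np.full_like(p_raw, np.nan)
    reject = np.zeros(len(p_raw), dtype=bool)
    valid = ~np.isnan(p_raw)
    if valid.any():
        rej, adj, _, _ = multipletests(p_raw[valid], alpha=0.05, method="holm")
        p_holm[valid] = adj
        reject[valid] = rej
    return pd.DataFrame(
        {"comparison": labels, "t": t_vals, "p_raw": p_raw, "p_holm": p_holm, "reject": reject}
    )


# ---------------------------------------------------------------------------
# TFCE and sign-flip permutation
# ---------------------------------------------------------------------------


def _st_edges(adjacency: sparse.spmatrix, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge list of the spatiotemporal graph."""
    coo = spatiotemporal_adjacency(adjacency, n_lags).tocoo()
    keep = coo.row < coo.col
    return coo.row[keep], coo.col[keep]


def _tfce_batch(
    t_maps: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
    E: float,
    H: float,
    dh: float,
) -> np.ndarray:
    """TFCE scores of a batch of flattened t maps sharing one graph.

    Positive and negative parts are enhanced separately (clusters never
    cross a sign change), which is done in a single sweep over |t| with
    edges restricted to same-sign node pairs.  All maps in the batch are
    processed jointly per threshold on a block-diagonal graph.
    """
    B, N = t_maps.shape
    vals = np.abs(t_maps)
    pos = t_maps >= 0
    out = np.zeros((B, N))
    same_sign = pos[:, ei] == pos[:, ej]
    offsets = (np.arange(B) * N)[:, None]
    vmax = vals.max()
    n_steps = int(math.floor(vmax / dh + 1e-9))
    for k in range(1, n_steps + 1):
        h = k * dh
        active = vals >= h
        n_active = active.sum()
        if n_active == 0:
            break
        edge_on = active[:, ei] & active[:, ej] & same_sign
        rows = (offsets + ei[None, :])[edge_on]
        cols = (offsets + ej[None, :])[edge_on]
        graph = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(B * N, B * N)
        )
        _, labels = connected_components(graph, directed=False)
        sizes = np.bincount(labels, weights=active.ravel())
        flat_active = active.ravel()
        out.ravel()[flat_active] += sizes[labels[flat_active]] ** E * h**H * dh
    return np.where(pos, out, -out)


def tfce(
    stat_map: np.ndarray,
    adjacency: sparse.spmatrix,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (channel, lag) statistic map.

    Each point accumulates ``extent(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2*dh, ... <= |t|``, with clusters formed on the spatiotemporal
    graph (``adjacency`` is the channel neighbor graph; consecutive lags are
    linked implicitly).  Positive and negative parts are enhanced separately
    and returned signed, so ``abs()`` gives the two-sided scores.  ``dh``
    defaults to ``max|t| / 50``.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.size == 0:
        raise ValueError("empty statistic map")
    if stat_map.ndim != 2:
        raise ValueError("stat_map must be (channels, lags)")
    n_ch, n_lags = stat_map.shape
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / 50.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    ei, ej = _st_edges(adjacency, n_lags)
    return _tfce_batch(stat_map.reshape(1, -1), ei, ej, E, H, dh).reshape(stat_map.shape)


@dataclass
class TFCEResult:
    """Corrected p-values and observed TFCE scores of a sign-flip test."""

    p_map: np.ndarray  # (channels, lags), family-wise corrected
    observed_tfce: np.ndarray  # signed TFCE scores
    t_map: np.ndarray
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.p_map <= 0) or np.any(self.p_map > 1):
            raise ValueError("p-values must lie in (0, 1]")

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_map < alpha


def _t_map(data: np.ndarray) -> np.ndarray:
    """One-sample t across the subject axis; zero-variance points give t=0."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def signflip_permutation(
    data: np.ndarray,
    adjacency: sparse.spmatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> TFCEResult:
    """Two-sided one-sample sign-flip permutation test with TFCE.

    ``data`` is (subjects, channels, lags) of per-subject effects tested
    against zero.  The observed one-sample t map is TFCE-enhanced; the null
    is the distribution of the maximum |TFCE| over the map under random
    per-subject sign flips, giving family-wise corrected p-values
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.  ``dh`` is fixed from
    the observed map and reused for every permutation so scores are
    comparable.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, channels, lags)")
    n_sub, n_ch, n_lags = data.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_sub < 6:
        warnings.warn("fewer than 6 subjects: permutation null is coarse", stacklevel=2)
    if n_perm < 100:
        warnings.warn("n_perm < 100: p-value resolution is poor", stacklevel=2)
    t_obs = _t_map(data)
    if dh is None:
        vmax = np.abs(t_obs).max()
        dh = vmax / 50.0 if vmax > 0 else None
    if dh is None:  # observed map identically zero
        return TFCEResult(np.ones((n_ch, n_lags)), np.zeros((n_ch, n_lags)), t_obs, n_perm, seed)
    ei, ej = _st_edges(adjacency, n_lags)
    obs = _tfce_batch(t_obs.reshape(1, -1), ei, ej, E, H, dh).reshape(n_ch, n_lags)

    # vectorized sign-flip t maps: the per-point sum of squares is invariant
    # under sign flips, so only the mean depends on the permutation
    flat = data.reshape(n_sub, -1)
    sumsq = (flat**2).sum(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_sub))
    null_max = np.empty(n_perm)
    chunk = max(1, int(2_000_000 // max(flat.shape[1], 1)))
    for start in range(0, n_perm, chunk):
        s = signs[start : start + chunk]
        mean = (s @ flat) / n_sub
        var = np.clip((sumsq[None, :] / n_sub - mean**2) * n_sub / (n_sub - 1), 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var > 0, mean / np.sqrt(var / n_sub), 0.0)
        scores = _tfce_batch(t_perm, ei, ej, E, H, dh)
        null_max[start : start + len(s)] = np.abs(scores).max(axis=1)
    exceed = (null_max[None, None, :] >= np.abs(obs)[:, :, None]).sum(axis=-1)
    p_map = (1.0 + exceed) / (1.0 + n_perm)
    return TFCEResult(p_map, obs, t_obs, n_perm, seed)


# ---------------------------------------------------------------------------
# Peak-amplitude correlations
# ---------------------------------------------------------------------------


def peak_correlation_fdr(
    kernels: np.ndarray,
    covariate,
    window_ms: tuple[float, float],
    lags_ms: np.ndarray,
    channel_names=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate per-subject peak kernel amplitudes with a covariate.

    ``kernels`` is (subjects, channels, lags); within ``window_ms`` the
    maximum amplitude per subject and channel is taken, correlated with the
    covariate (Pearson) per channel, and Benjamini-Hochberg corrected
    across channels.
    """
    kernels = np.asarray(kernels, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if kernels.ndim != 3 or kernels.shape[0] != cov.size:
        raise ValueError("kernels must be (subjects, channels, lags) matching covariate")
    if np.std(cov) < 1e-15:
        raise ValueError("constant covariate")
    lags_ms = np.asarray(lags_ms, dtype=float)
    sel = (lags_ms >= window_ms[0]) & (lags_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window outside the lag range")
    peaks = kernels[:, :, sel].max(axis=2)  # (subjects, channels)
    n_ch = peaks.shape[1]
    r = np.empty(n_ch)
    p = np.empty(n_ch)
    for c in range(n_ch):
        r[c], p[c] = ss.pearsonr(peaks[:, c], cov)
    _, p_fdr, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    names = list(channel_names) if channel_names is not None else list(range(n_ch))
    return pd.DataFrame(
        {"channel": names, "r": r, "p": p, "p_fdr": p_fdr, "significant": p_fdr < alpha}
    )
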