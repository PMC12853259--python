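"""Seeded synthetic studies: melodies, ground-truth kernels, simulated EEG.

The generator emulates the statistical structure the TRF analysis assumes:
monophonic folk-song-like melodies on a metrical grid, stimulus sets of two
cross-meter originals plus their two chimeras, and multichannel EEG formed
by convolving known kernels with the trial's regressors, projecting the
result through a frontocentral channel weight map, and adding 1/f-shaped
noise at a requested SNR.  Every quantity is reproducible from (config,
seed), and because the EEG is generated with the package's own lag
conventions, fitting a TRF on noiseless output recovers the kernel bank
exactly -- the module's central oracle.

Default kernel morphology follows the canonical auditory evoked response:
the note-onset kernel has positive P1 (~80 ms) and P2 (~185 ms) deflections
and the downbeat kernel a ~185 ms peak with a negative ~650 ms dip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import features as ft
from .chimera import StimulusSet, build_stimulus_set
from .expectation import (
    ExpectationConfig,
    quantize_iois,
    stimulus_set_expectations,
    train,
)
from .melody_io import DownbeatMask, Note, NoteSequence, annotate_downbeats, viewpoints
from .stats import MONTAGE_32_CHANNELS, MONTAGE_32_POSITIONS
from .trf import lag_samples, lagged_design

__all__ = [
    "KernelConfig",
    "KernelBank",
    "StudyConfig",
    "SimStudy",
    "TrialRecord",
    "generate_melody",
    "default_kernels",
    "one_over_f_noise",
    "simulate_trial",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# Melodies
# ---------------------------------------------------------------------------

_DIATONIC = np.array([60, 62, 64, 65, 67, 69, 71, 72, 74, 76])  # C major, 2 octaves
_IOI_CHOICES_BEATS = np.array([0.5, 1.0, 1.5, 2.0])
_IOI_PROBS = np.array([0.35, 0.40, 0.15, 0.10])


def generate_melody(
    time_signature: tuple[int, int] = (4, 4),
    n_notes: int = 60,
    tempo_bpm: float = 120.0,
    seed=None,
    label: str = "",
    pitch_markov_scale: float = 1.5,
) -> NoteSequence:
    """Generate a folk-song-like monophonic melody on a metrical grid.

    Inter-onset intervals are random subdivisions of the beat on a
    half-beat grid; an interval that would straddle a barline is clipped to
    land on it, so every measure starts with a note (the folk-song norm)
    and downbeats are exact.  Pitches follow a seeded first-order Markov
    chain over a diatonic set favouring small steps.
    """
    if n_notes < 4:
        raise ValueError("n_notes must be >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    num, den = time_signature
    beat_s = (60.0 / tempo_bpm) * (4.0 / den)
    onsets_beats = [0.0]
    pos = 0.0
    while len(onsets_beats) < n_notes:
        ioi = float(rng.choice(_IOI_CHOICES_BEATS, p=_IOI_PROBS))
        next_bar = (np.floor(pos / num + 1e-9) + 1) * num
        if pos + ioi > next_bar + 1e-9:
            ioi = float(next_bar - pos)
        pos += ioi
        onsets_beats.append(pos)
    onsets_beats = np.asarray(onsets_beats)
    iois_beats = np.diff(onsets_beats)
    onsets = onsets_beats * beat_s
    durations = np.concatenate([iois_beats, [1.0]]) * beat_s * 0.9

    # pitch random walk: transition weight decays with interval size
    dist = np.abs(np.arange(len(_DIATONIC))[:, None] - np.arange(len(_DIATONIC))[None, :])
    trans = np.exp(-dist / pitch_markov_scale)
    trans /= trans.sum(axis=1, keepdims=True)
    pitches = np.empty(n_notes, dtype=int)
    state = rng.integers(len(_DIATONIC))
    for i in range(n_notes):
        pitches[i] = _DIATONIC[state]
        state = rng.choice(len(_DIATONIC), p=trans[state])

    notes = tuple(
        Note(float(o), float(d), int(p)) for o, d, p in zip(onsets, durations, pitches)
    )
    return NoteSequence(notes=notes, time_signature=time_signature, tempo_bpm=tempo_bpm, label=label)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelConfig:
    """Latencies (ms), amplitudes (a.u.) and widths of the ground-truth kernels."""

    p1_ms: float = 80.0
    p1_amp: float = 0.6
    p1_width_ms: float = 18.0
    p2_ms: float = 185.0
    p2_amp: float = 1.0
    p2_width_ms: float = 32.0
    db_peak_ms: float = 185.0
    db_peak_amp: float = 0.8
    db_peak_width_ms: float = 30.0
    db_dip_ms: float = 650.0
    db_dip_amp: float = 0.5
    db_dip_width_ms: float = 70.0
    dbcp_amp: float = 0.0  # pitch-only downbeat response (none by default)
    interaction: bool = False
    interaction_ms: float = 185.0
    interaction_amp: float = 0.6
    interaction_width_ms: float = 30.0
    flux_amp: float = 0.15
    expectation_amp: float = 1.0


@dataclass
class KernelBank:
    """Ground-truth kernels over the lag grid plus the channel weight map."""

    fs: float
    lags: np.ndarray  # sample lags
    kernels: dict[str, np.ndarray]  # name -> (n_lags,)
    channel_map: np.ndarray  # (n_channels,), max 1
    channel_names: tuple[str, ...]
    onset_p1: np.ndarray | None = None  # P1/P2 parts of the onset kernel, for
    onset_p2: np.ndarray | None = None  # per-subject P2 gain scaling

    def __post_init__(self) -> None:
        L = len(self.lags)
        for name, k in self.kernels.items():
            if len(k) != L:
                raise ValueError(f"kernel '{name}' length != lag grid")
        if abs(self.channel_map.max() - 1.0) > 1e-9:
            raise ValueError("channel map must be normalized to max 1")

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    def scaled(self, scale_by_name: dict[str, float]) -> "KernelBank":
        """A copy with per-kernel multiplicative scalings applied."""
        kernels = {
            n: k * scale_by_name.get(n, 1.0) for n, k in self.kernels.items()
        }
        return replace(self, kernels=kernels)


def _bump(lags_ms: np.ndarray, center_ms: float, width_ms: float, amp: float) -> np.ndarray:
    out = amp * np.exp(-0.5 * ((lags_ms - center_ms) / width_ms) ** 2)
    out[lags_ms < 0] = 0.0  # causal kernels
    return out


def default_kernels(
    fs: float = 125.0,
    lags_ms: tuple[float, float] = (-100.0, 800.0),
    config: KernelConfig = KernelConfig(),
    channel_names=MONTAGE_32_CHANNELS,
) -> KernelBank:
    """Build the ground-truth kernel bank from the morphology config."""
    if not (lags_ms[0] <= 0 and lags_ms[1] >= 700):
        raise ValueError("lag window must cover 0-700 ms")
    for lat in (config.p1_ms, config.p2_ms, config.db_peak_ms, config.db_dip_ms):
        if not (lags_ms[0] <= lat <= lags_ms[1]):
            raise ValueError(f"kernel latency {lat} ms outside the lag window")
    lags = lag_samples(lags_ms, fs)
    t = lags * 1000.0 / fs
    c = config
    p1 = _bump(t, c.p1_ms, c.p1_width_ms, c.p1_amp)
    p2 = _bump(t, c.p2_ms, c.p2_width_ms, c.p2_amp)
    downbeat = _bump(t, c.db_peak_ms, c.db_peak_width_ms, c.db_peak_amp) - _bump(
        t, c.db_dip_ms, c.db_dip_width_ms, c.db_dip_amp
    )
    a = c.expectation_amp
    kernels = {
        "flux": _bump(t, 120.0, 50.0, c.flux_amp) - _bump(t, 300.0, 80.0, 0.5 * c.flux_amp),
        "onset": p1 + p2,
        "Sp": a * (_bump(t, 200.0, 45.0, 1.0) - _bump(t, 400.0, 70.0, 0.5)),
        "Ep": a * (-_bump(t, 150.0, 35.0, 0.7) + _bump(t, 330.0, 60.0, 0.8)),
        "St": a * (_bump(t, 180.0, 40.0, 0.9) - _bump(t, 450.0, 80.0, 0.4)),
        "Et": a * (_bump(t, 250.0, 50.0, 0.6) - _bump(t, 500.0, 90.0, 0.6)),
        "DBo": downbeat,
        "DBct": downbeat.copy(),
        "DBcp": _bump(t, 260.0, 50.0, c.dbcp_amp),
        "DBcpt": (
            _bump(t, c.interaction_ms, c.interaction_width_ms, c.interaction_amp)
            if c.interaction
            else np.zeros_like(t)
        ),
    }
    pos = np.array([MONTAGE_32_POSITIONS[ch] for ch in channel_names])
    w = np.exp(-(pos[:, 0] ** 2 + (pos[:, 1] - 0.35) ** 2) / (2 * 0.45**2))
    w /= w.max()
    return KernelBank(
        fs=fs,
        lags=lags,
        kernels=kernels,
        channel_map=w,
        channel_names=tuple(channel_names),
        onset_p1=p1,
        onset_p2=p2,
    )


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------


def one_over_f_noise(
    n_samples: int,
    n_channels: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    spatial_corr: float = 0.3,
) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise with a shared spatial component.

    Each channel mixes an independent and a common 1/f series with weights
    ``sqrt(1-rho)`` and ``sqrt(rho)``, giving pairwise channel correlation
    ``rho``.  Channels are normalized to unit variance.
    """

    def shaped(cols: int) -> np.ndarray:
        white = rng.standard_normal((n_samples, cols))
        spec = np.fft.rfft(white, axis=0)
        f = np.fft.rfftfreq(n_samples)
        f[0] = f[1] if len(f) > 1 else 1.0
        spec *= (1.0 / f ** (exponent / 2.0))[:, None]
        x = np.fft.irfft(spec, n=n_samples, axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return x / sd

    indep = shaped(n_channels)
    shared = shaped(1)
    return np.sqrt(1.0 - spatial_corr) * indep + np.sqrt(spatial_corr) * shared


def simulate_trial(
    regressors: ft.RegressorSet,
    kernels: KernelBank,
    snr_db: float = 0.0,
    seed=None,
    noise_exponent: float = 1.0,
    spatial_corr: float = 0.3,
    return_clean: bool = False,
):
    """Forward-simulate one trial: EEG = sum_f conv(x_f, k_f) x map + noise.

    Only features present in both the regressor set and the kernel bank
    drive the signal.  Noise is scaled so that the ratio of clean to noise
    variance, averaged over channels, equals ``snr_db``; with an all-zero
    clean signal the noise has unit variance.
    """
    if abs(regressors.fs - kernels.fs) > 1e-9:
        raise ValueError("regressors and kernels must share the sampling rate")
    names = [n for n in kernels.kernels if n in regressors.signals]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch = len(kernels.channel_map)
    T = regressors.n_samples
    if names:
        design = lagged_design(regressors.matrix(names), kernels.lags)
        w = np.concatenate([kernels.kernels[n] for n in names])
        clean_1d = design @ w
    else:
        clean_1d = np.zeros(T)
    clean = clean_1d[:, None] * kernels.channel_map[None, :]
    noise = one_over_f_noise(T, n_ch, rng, noise_exponent, spatial_corr)
    var_clean = clean.var(axis=0).mean()
    var_noise = noise.var(axis=0).mean()
    if var_clean > 0:
        target = var_clean / 10.0 ** (snr_db / 10.0)
        noise = noise * np.sqrt(target / var_noise)
    else:
        noise = noise / np.sqrt(var_noise)
    eeg = clean + noise
    return (eeg, clean) if return_clean else eeg


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale emulation of the 27-subject, 132-trial listening study.

    Defaults: 10 subjects x 3 stimulus sets (12 trials of ~30 s) at 125 Hz
    over the 32-channel montage, SNR 0 dB.  Expectation kernels are
    attenuated by ``chimeric_attenuation`` for chimeric trials (the
    generative analogue of a weaker expectation effect), the subject's P2
    gain grows linearly with musicianship years, and the pitch x time
    interaction kernel is on by default.
    """

    n_subjects: int = 10
    n_sets: int = 3
    n_notes: int = 60
    tempo_bpm: float = 120.0
    fs: float = 125.0
    snr_db: float = 0.0
    lags_ms: tuple[float, float] = (-100.0, 800.0)
    kernel_config: KernelConfig = field(
        default_factory=lambda: KernelConfig(interaction=True, interaction_amp=0.5)
    )
    chimeric_attenuation: float = 0.5
    p2_gain_per_year: float = 0.05
    max_musicianship_years: int = 11
    subject_scale_sd: float = 0.1
    include_flux: bool = True
    include_expectation: bool = True
    #: restrict the generative model to these kernels (None = all); used to
    #: study one encoding model in isolation, e.g. downbeat-only EEG
    active_kernels: tuple[str, ...] | None = None
    audio_fs: float = 48_000.0
    ltm_corpus_size: int = 8
    ltm_corpus_notes: int = 40
    expectation_order: int = 10
    expectation_mode: str = "both"
    zscore_expectation: bool = True
    noise_exponent: float = 1.0
    spatial_corr: float = 0.3
    pad_s: float = 1.0


@dataclass
class TrialRecord:
    """One stimulus trial: melody, category and its regressor signals."""

    set_index: int
    name: str  # original_1 / original_2 / chimeric_a / chimeric_b
    category: str  # original / chimeric
    melody: NoteSequence
    regressors: ft.RegressorSet


@dataclass
class SimStudy:
    """A complete seeded synthetic dataset with its ground truth."""

    config: StudyConfig
    seed: int | None
    sets: list[StimulusSet]
    trials: list[TrialRecord]
    eeg: list[list[np.ndarray]]  # [subject][trial] -> (T, C)
    subjects: "object"  # pandas DataFrame: participant, musicianship_years, ...
    kernels: KernelBank

    @property
    def n_subjects(self) -> int:
        return len(self.eeg)

    def trial_indices(self, category: str) -> list[int]:
        return [i for i, t in enumerate(self.trials) if t.category == category]

    def subject_kernel_bank(self, subject: int, category: str) -> KernelBank:
        """The ground-truth kernels that generated this subject's EEG."""
        row = self.subjects.iloc[subject]
        return _subject_bank(self.kernels, self.config, row["p2_gain"], row["scale"], category)


def _subject_bank(
    base: KernelBank, config: StudyConfig, p2_gain: float, scale: float, category: str
) -> KernelBank:
    kernels = dict(base.kernels)
    kernels["onset"] = base.onset_p1 + p2_gain * base.onset_p2
    att = config.chimeric_attenuation if category == "chimeric" else 1.0
    for name in ("Sp", "Ep", "St", "Et"):
        kernels[name] = kernels[name] * att
    if config.active_kernels is not None:
        kernels = {n: k for n, k in kernels.items() if n in config.active_kernels}
    kernels = {n: k * scale for n, k in kernels.items()}
    return replace(base, kernels=kernels)


def _melody_masks(sset: StimulusSet) -> dict[str, dict[str, DownbeatMask]]:
    m1 = annotate_downbeats(sset.original_1)
    m2 = annotate_downbeats(sset.original_2)
    return {
        "original_1": {"own": m1},
        "original_2": {"own": m2},
        "chimeric_a": {"pitch": m1, "time": m2},
        "chimeric_b": {"pitch": m2, "time": m1},
    }


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _trial_regressors(
    melody: NoteSequence,
    name: str,
    masks: dict[str, DownbeatMask],
    feats,
    config: StudyConfig,
) -> ft.RegressorSet:
    duration = melody.total_duration_s + config.pad_s
    fs = config.fs
    reg = ft.RegressorSet(fs=fs, duration_s=duration)
    if config.include_flux:
        audio = ft.render_tones(melody, config.audio_fs)
        reg.add("flux", ft.spectral_flux(audio, config.audio_fs, fs, duration))
    if feats is not None:
        vals = {
            k: np.asarray(getattr(feats, k), dtype=float) for k in ("Sp", "Ep", "St", "Et")
        }
        if config.zscore_expectation:
            vals = {k: _zscore(v) for k, v in vals.items()}
        for k in ("Sp", "Ep", "St", "Et"):
            reg.add(k, ft.scaled_impulse_train(melody, vals[k], fs, duration))
    if name.startswith("original"):
        reg.signals.update(ft.downbeat_regressors_original(melody, masks["own"], fs, duration))
    else:
        reg.signals.update(
            ft.downbeat_regressors_chimeric(melody, masks["pitch"], masks["time"], fs, duration)
        )
    return reg


def simulate_study(config: StudyConfig = StudyConfig(), seed: int | None = 0) -> SimStudy:
    """Generate a full synthetic study (melodies, regressors, EEG, truth)."""
    import pandas as pd

    rng = np.random.default_rng(seed)

    # --- stimuli -----------------------------------------------------------
    sets: list[StimulusSet] = []
    for s in range(config.n_sets):
        triple = generate_melody(
            (3, 4), config.n_notes, config.tempo_bpm, rng, label=f"set{s}_triple"
        )
        duple = generate_melody(
            (4, 4), config.n_notes, config.tempo_bpm, rng, label=f"set{s}_duple"
        )
        sets.append(build_stimulus_set(triple, duple))

    # --- long-term model corpus -------------------------------------------
    if config.include_expectation:
        corpus = [
            generate_melody(
                (3, 4) if i % 2 else (4, 4),
                config.ltm_corpus_notes,
                config.tempo_bpm,
                rng,
                label=f"ltm{i}",
            )
            for i in range(config.ltm_corpus_size)
        ]
        ltm_pitch = train(
            [viewpoints(m).pitch_seq for m in corpus], config.expectation_order
        )
        ltm_ioi = train(
            [quantize_iois(viewpoints(m).ioi_seq) for m in corpus],
            config.expectation_order,
        )
        exp_config = ExpectationConfig(
            mode=config.expectation_mode, order_bound=config.expectation_order
        )

    # --- trials ------------------------------------------------------------
    trials: list[TrialRecord] = []
    for s, sset in enumerate(sets):
        if config.include_expectation:
            feats = stimulus_set_expectations(sset, ltm_pitch, ltm_ioi, exp_config)
        else:
            feats = {name: None for name in sset.melodies}
        masks = _melody_masks(sset)
        for name, melody in sset.melodies.items():
            category = "original" if name.startswith("original") else "chimeric"
            reg = _trial_regressors(melody, name, masks[name], feats[name], config)
            trials.append(TrialRecord(s, name, category, melody, reg))

    # --- subjects and EEG --------------------------------------------------
    base = default_kernels(config.fs, config.lags_ms, config.kernel_config)
    years = rng.integers(0, config.max_musicianship_years + 1, size=config.n_subjects)
    scales = np.exp(rng.normal(0.0, config.subject_scale_sd, size=config.n_subjects))
    gains = 1.0 + config.p2_gain_per_year * years
    subjects = pd.DataFrame(
        {
            "participant": [f"S{i:02d}" for i in range(config.n_subjects)],
            "musicianship_years": years,
            "p2_gain": gains,
            "scale": scales,
        }
    )
    eeg: list[list[np.ndarray]] = []
    for i in range(config.n_subjects):
        rows: list[np.ndarray] = []
        for trial in trials:
            bank = _subject_bank(base, config, gains[i], scales[i], trial.category)
            rows.append(
                simulate_trial(
                    trial.regressors,
                    bank,
                    config.snr_db,
                    rng,
                    config.noise_exponent,
                    config.spatial_corr,
                )
            )
        eeg.append(rows)
    return SimStudy(config, seed, sets, trials, eeg, subjects, base)
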