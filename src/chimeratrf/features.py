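"""Time-aligned regressor signals on the EEG sample grid.

Melodies, their expectation features and rendered audio are converted to
named signals sampled at the EEG rate (default 125 samples/s):

* ``onset`` -- unit impulse train at note onsets;
* ``Sp``/``Ep``/``St``/``Et`` -- impulse trains whose amplitudes are the
  per-note expectation features (IOI features start at note 2; note 1 is 0);
* ``DBo`` (originals) and ``DBct``/``DBcp``/``DBcpt`` (chimeric) -- downbeat
  indicator trains.  The nonzero samples of every downbeat train are a
  subset of the onset train, and ``DBcpt`` is the elementwise minimum of
  ``DBcp`` and ``DBct``;
* ``flux`` -- spectral flux of the rendered audio, resampled to the EEG
  grid and z-scored.

Onsets are mapped to samples with round-half-up; at 125 Hz a bin is 8 ms
wide, so two notes landing in one bin are rejected rather than merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .melody_io import DownbeatMask, NoteSequence

__all__ = [
    "RegressorSet",
    "impulse_train",
    "scaled_impulse_train",
    "downbeat_regressors_original",
    "downbeat_regressors_chimeric",
    "spectral_flux",
    "render_tones",
]

DEFAULT_FS = 125.0


@dataclass
class RegressorSet:
    """Named, equal-length feature signals on one trial's sample grid."""

    fs: float
    duration_s: float
    signals: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def __post_init__(self) -> None:
        for name, sig in self.signals.items():
            if len(sig) != self.n_samples:
                raise ValueError(
                    f"signal '{name}' has {len(sig)} samples, expected {self.n_samples}"
                )

    def add(self, name: str, sig: np.ndarray) -> None:
        sig = np.asarray(sig, dtype=float)
        if len(sig) != self.n_samples:
            raise ValueError(f"signal '{name}' has wrong length")
        self.signals[name] = sig

    def matrix(self, names) -> np.ndarray:
        """Stack the named signals as columns (time x feature)."""
        return np.column_stack([self.signals[n] for n in names])


def _sample_index(onsets_s: np.ndarray, fs: float) -> np.ndarray:
    return np.floor(np.asarray(onsets_s) * fs + 0.5).astype(int)  # round half up


def impulse_train(
    seq: NoteSequence,
    mask=None,
    fs: float = DEFAULT_FS,
    duration_s: float | None = None,
) -> np.ndarray:
    """Unit impulse train at (masked) note onsets.

    ``mask`` may be a :class:`DownbeatMask` or a boolean array per note;
    default is all notes.  Two notes mapping to the same sample raise an
    error (raise ``fs`` or reject the stimulus).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s is None:
        duration_s = seq.total_duration_s
    n = int(round(fs * duration_s))
    idx = _sample_index(seq.onsets, fs)
    if idx[-1] >= n:
        raise ValueError("duration does not cover the last onset")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("two notes map to one sample; raise fs or reject stimulus")
    if mask is None:
        m = np.ones(len(seq), dtype=bool)
    elif isinstance(mask, DownbeatMask):
        m = mask.mask
    else:
        m = np.asarray(mask, dtype=bool)
    if len(m) != len(seq):
        raise ValueError("mask length must equal note count")
    out = np.zeros(n)
    out[idx[m]] = 1.0
    return out


def scaled_impulse_train(
    seq: NoteSequence,
    values,
    fs: float = DEFAULT_FS,
    duration_s: float | None = None,
) -> np.ndarray:
    """Impulse train whose amplitudes are per-note feature values.

    ``values`` may have length n (one per note) or n-1 (IOI-aligned
    features for notes 2..n; note 1 gets amplitude 0).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == len(seq) - 1:
        values = np.concatenate([[0.0], values])
    elif len(values) != len(seq):
        raise ValueError(
            f"values length {len(values)} does not align to {len(seq)} notes"
        )
    out = impulse_train(seq, None, fs, duration_s)
    idx = _sample_index(seq.onsets, fs)
    out[idx] = values
    return out


def downbeat_regressors_original(
    seq: NoteSequence,
    mask: DownbeatMask,
    fs: float = DEFAULT_FS,
    duration_s: float | None = None,
) -> dict[str, np.ndarray]:
    """Onset and downbeat (DBo) impulse trains for an original piece."""
    if len(mask) != len(seq):
        raise ValueError("mask must align to the melody")
    return {
        "onset": impulse_train(seq, None, fs, duration_s),
        "DBo": impulse_train(seq, mask, fs, duration_s),
    }


def downbeat_regressors_chimeric(
    chim: NoteSequence,
    pitch_src_mask: DownbeatMask,
    time_src_mask: DownbeatMask,
    fs: float = DEFAULT_FS,
    duration_s: float | None = None,
) -> dict[str, np.ndarray]:
    """Onset, DBct, DBcp and DBcpt impulse trains for a chimeric piece.

    Note i of the chimera is a downbeat-time note if note i of the time
    source was a downbeat, and a downbeat-pitch note if note i of the pitch
    source was; the interaction train marks notes that are both.  Note
    alignment is positional (the fusion starts at the beginning).
    """
    m = len(chim)
    if len(pitch_src_mask) < m or len(time_src_mask) < m:
        raise ValueError("source masks shorter than the chimeric melody")
    mp = pitch_src_mask.mask[:m]
    mt = time_src_mask.mask[:m]
    return {
        "onset": impulse_train(chim, None, fs, duration_s),
        "DBct": impulse_train(chim, mt, fs, duration_s),
        "DBcp": impulse_train(chim, mp, fs, duration_s),
        "DBcpt": impulse_train(chim, mp & mt, fs, duration_s),
    }


# ---------------------------------------------------------------------------
# Audio: tone rendering and spectral flux
# ---------------------------------------------------------------------------


def render_tones(
    seq: NoteSequence,
    fs_audio: float = 48_000.0,
    n_harmonics: int = 8,
    target_rms: float = 0.01,
) -> np.ndarray:
    """Render a melody as exponentially damped harmonic tones.

    Each note is a sum of ``n_harmonics`` partials with 1/h amplitudes and
    an exponential decay scaled to the note duration; all notes have equal
    velocity and the waveform is normalized to an RMS of 0.01, mirroring the
    loudness normalization of the experimental stimuli.
    """
    if len(seq) == 0:
        raise ValueError("empty melody")
    total = seq.total_duration_s + 0.5
    out = np.zeros(int(round(total * fs_audio)))
    for note in seq.notes:
        f0 = 440.0 * 2 ** ((note.pitch - 69) / 12)
        dur = min(note.duration_s + 0.1, total - note.onset_s)
        t = np.arange(int(round(dur * fs_audio))) / fs_audio
        env = np.exp(-3.0 * t / max(note.duration_s, 1e-3))
        tone = np.zeros_like(t)
        for h in range(1, n_harmonics + 1):
            if h * f0 < fs_audio / 2:
                tone += np.sin(2 * np.pi * h * f0 * t) / h
        start = int(round(note.onset_s * fs_audio))
        seg = env * tone
        out[start : start + len(seg)] += seg
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= target_rms / rms
    return out


def spectral_flux(
    audio: np.ndarray,
    fs_audio: float,
    fs_out: float = DEFAULT_FS,
    duration_s: float | None = None,
    n_fft: int = 1024,
    zscore: bool = True,
) -> np.ndarray:
    """Half-wave-rectified spectral flux resampled to the regressor grid.

    Magnitude spectrogram with Hann windows of ``n_fft`` samples and 50%
    overlap; positive frame-to-frame differences summed over frequency,
    linearly interpolated onto the output sample grid, then z-scored per
    trial.  Silent audio yields an all-zero signal with a warning.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if duration_s is None:
        duration_s = len(audio) / fs_audio
    n_out = int(round(fs_out * duration_s))
    if not np.any(audio):
        warnings.warn("silent audio: spectral flux is all-zero", stacklevel=2)
        return np.zeros(n_out)
    hop = n_fft // 2
    f, t, z = sps.stft(
        audio, fs=fs_audio, window="hann", nperseg=n_fft, noverlap=n_fft - hop,
        boundary=None, padded=False,
    )
    mag = np.abs(z)
    diff = np.diff(mag, axis=1)
    flux = np.clip(diff, 0, None).sum(axis=0)
    frame_times = t[1:]
    out_times = np.arange(n_out) / fs_out
    out = np.interp(out_times, frame_times, flux, left=0.0, right=0.0)
    if zscore:
        sd = out.std()
        if sd > 0:
            out = (out - out.mean()) / sd
    return out
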