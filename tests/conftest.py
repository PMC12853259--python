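import numpy as np
import pytest

from chimeratrf.melody_io import Note, NoteSequence


def make_seq(onsets, pitches, time_signature=(4, 4), tempo_bpm=120.0,
             durations=None, label="test"):
    """Build a NoteSequence from onset/pitch lists (durations fill the IOIs)."""
    onsets = list(onsets)
    if durations is None:
        iois = np.diff(onsets)
        durations = list(iois * 0.9) + [0.4]
    notes = tuple(
        Note(float(o), float(d), int(p))
        for o, d, p in zip(onsets, durations, pitches)
    )
    return NoteSequence(notes=notes, time_signature=time_signature,
                        tempo_bpm=tempo_bpm, label=label)


@pytest.fixture
def quarter_melody():
    """12 isochronous quarter notes at 120 BPM in 4/4 (0.5 s IOI)."""
    onsets = np.arange(12) * 0.5
    pitches = [60, 62, 64, 65, 67, 69, 71, 72, 71, 69, 67, 65]
    return make_seq(onsets, pitches)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
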