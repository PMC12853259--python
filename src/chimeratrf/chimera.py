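"""Chimeric-melody construction.

A chimeric melody fuses the pitch sequence of one piece with the note-time
(onset/duration) sequence of another, decoupling the pitch and temporal
structure of natural music while preserving each dimension's marginal
statistics.  Pieces are paired across the two beat-structure groups --
triple (3/4, 3/8, 6/8) vs duple/quadruple (2/4, 4/4, 4/8) -- with close to
the same number of notes, and the note matching always starts at the
beginning so that the within-dimension context is identical between an
original piece and its chimeric counterpart.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .melody_io import Note, NoteSequence

__all__ = [
    "BeatGroup",
    "StimulusSet",
    "beat_group",
    "pair_collection",
    "fuse_chimeric",
    "build_stimulus_set",
    "filter_min_duration",
]


class BeatGroup(enum.Enum):
    TRIPLE = "triple"
    DUPLE_QUAD = "duple_quad"


_TRIPLE_SIGNATURES = {(3, 4), (3, 8), (6, 8)}
_DUPLE_SIGNATURES = {(2, 4), (4, 4), (4, 8)}


def beat_group(seq: NoteSequence) -> BeatGroup:
    """Classify a melody's time signature into the beat-group taxonomy."""
    sig = tuple(seq.time_signature)
    if sig in _TRIPLE_SIGNATURES:
        return BeatGroup.TRIPLE
    if sig in _DUPLE_SIGNATURES:
        return BeatGroup.DUPLE_QUAD
    raise ValueError(f"time signature {sig[0]}/{sig[1]} outside beat-group taxonomy")


def filter_min_duration(pieces: list[NoteSequence], min_duration_s: float = 25.0) -> list[NoteSequence]:
    """Keep only pieces at least ``min_duration_s`` long (stimulus length filter)."""
    return [p for p in pieces if p.total_duration_s >= min_duration_s]


def pair_collection(
    pieces: list[NoteSequence], max_note_count_diff: int = 5
) -> list[tuple[NoteSequence, NoteSequence]]:
    """Pair pieces across beat groups, matching note counts greedily.

    Candidate cross-group pairs are considered in order of increasing
    note-count difference ``|n1 - n2|``; a pair is accepted if neither piece
    is already used and the difference is within ``max_note_count_diff``.
    Each returned pair is ``(triple_piece, duple_quad_piece)``.
    """
    triples = [p for p in pieces if beat_group(p) is BeatGroup.TRIPLE]
    duples = [p for p in pieces if beat_group(p) is BeatGroup.DUPLE_QUAD]
    candidates = sorted(
        ((abs(len(a) - len(b)), i, j) for i, a in enumerate(triples) for j, b in enumerate(duples)),
        key=lambda c: c[0],
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs: list[tuple[NoteSequence, NoteSequence]] = []
    for diff, i, j in candidates:
        if diff > max_note_count_diff:
            break
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        pairs.append((triples[i], duples[j]))
    if not pairs:
        warnings.warn("no admissible cross-group pair found", stacklevel=2)
    return pairs


def fuse_chimeric(pitch_source: NoteSequence, time_source: NoteSequence) -> NoteSequence:
    """Fuse one melody's pitches with another's note times.

    The result has ``m = min(n_pitch, n_time)`` notes; note ``i`` takes its
    pitch from ``pitch_source`` and its onset and duration from
    ``time_source`` (durations travel with the rhythm so the time source's
    envelope is preserved).  Time signature and tempo are inherited from the
    time source, since downbeats are temporally defined.
    """
    if len(pitch_source) < 2 or len(time_source) < 2:
        raise ValueError("both sources must have at least 2 notes")
    m = min(len(pitch_source), len(time_source))
    notes = tuple(
        Note(t.onset_s, t.duration_s, p.pitch)
        for p, t in zip(pitch_source.notes[:m], time_source.notes[:m])
    )
    return NoteSequence(
        notes=notes,
        time_signature=time_source.time_signature,
        tempo_bpm=time_source.tempo_bpm,
        label=f"pitch:{pitch_source.label}|time:{time_source.label}",
    )


@dataclass(frozen=True)
class StimulusSet:
    """Two cross-group originals and their two chimeric counterparts.

    ``chimeric_a`` carries the pitch of ``original_1`` and the time of
    ``original_2``; ``chimeric_b`` the converse.
    """

    original_1: NoteSequence
    original_2: NoteSequence
    chimeric_a: NoteSequence
    chimeric_b: NoteSequence
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if beat_group(self.original_1) is beat_group(self.original_2):
            raise ValueError("originals must come from different beat groups")
        m = min(len(self.original_1), len(self.original_2))
        if len(self.chimeric_a) != m or len(self.chimeric_b) != m:
            raise ValueError("chimeric length must equal min of original lengths")
        if tuple(self.chimeric_a.pitches) != tuple(self.original_1.pitches[:m]):
            raise ValueError("chimeric_a pitches must be a prefix of original_1's")
        if tuple(self.chimeric_a.onsets) != tuple(self.original_2.onsets[:m]):
            raise ValueError("chimeric_a onsets must be a prefix of original_2's")

    @property
    def melodies(self) -> dict[str, NoteSequence]:
        return {
            "original_1": self.original_1,
            "original_2": self.original_2,
            "chimeric_a": self.chimeric_a,
            "chimeric_b": self.chimeric_b,
        }


def build_stimulus_set(p1: NoteSequence, p2: NoteSequence) -> StimulusSet:
    """Build the four-melody stimulus set from a cross-group pair."""
    if beat_group(p1) is beat_group(p2):
        raise ValueError("same-group pair: stimulus sets require one piece per beat group")
    return StimulusSet(
        original_1=p1,
        original_2=p2,
        chimeric_a=fuse_chimeric(p1, p2),
        chimeric_b=fuse_chimeric(p2, p1),
        provenance=(p1.label, p2.label),
    )
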