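"""Monophonic melody I/O and symbolic viewpoints.

A melody is an ordered sequence of notes, each with an onset time (seconds),
a duration (seconds) and a MIDI pitch.  From it we derive the two symbolic
*viewpoints* used for expectation modelling -- chromatic pitch (``cpitch``)
and inter-onset interval (``ioi``) -- and a metrical *downbeat mask* marking
the notes that fall on the first beat of a measure.

Melodies are read from and written to Standard MIDI Files with a small
self-contained SMF codec (type 0 written, types 0/1 read, monophonic
subset).  Onsets are stored as absolute seconds with half-open note
intervals ``[onset, onset + duration)``; note indexing is 0-based.
"""

from __future__ import annotations

import io
import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Note",
    "NoteSequence",
    "ViewpointSequences",
    "DownbeatMask",
    "PolyphonyError",
    "read_midi",
    "write_midi",
    "viewpoints",
    "annotate_downbeats",
    "note_table_tsv",
]

#: Time-signature numerators/denominators accepted by the beat-group taxonomy.
VALID_NUMERATORS = (2, 3, 4, 6)
VALID_DENOMINATORS = (4, 8)

_ONSET_MERGE_TOL_S = 1e-3  # two onsets closer than this are treated as a chord


class PolyphonyError(ValueError):
    """Raised when a MIDI file contains simultaneous notes."""


@dataclass(frozen=True)
class Note:
    onset_s: float
    duration_s: float
    pitch: int


@dataclass(frozen=True)
class NoteSequence:
    """A monophonic melody with a time signature and a fixed tempo.

    ``tempo_bpm`` is the quarter-note tempo resolved at read time; together
    with the time signature it defines the measure grid in seconds.
    """

    notes: tuple[Note, ...]
    time_signature: tuple[int, int]
    tempo_bpm: float = 120.0
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.notes) == 0:
            raise ValueError("empty melody")
        num, den = self.time_signature
        if num not in VALID_NUMERATORS or den not in VALID_DENOMINATORS:
            raise ValueError(
                f"unsupported time signature {num}/{den}; "
                f"numerator must be in {VALID_NUMERATORS}, denominator in {VALID_DENOMINATORS}"
            )
        if self.tempo_bpm <= 0:
            raise ValueError("tempo must be positive")
        prev = -np.inf
        for n in self.notes:
            if n.duration_s <= 0:
                raise ValueError(f"non-positive duration at onset {n.onset_s}")
            if not (0 <= n.pitch <= 127):
                raise ValueError(f"pitch {n.pitch} outside MIDI range 0-127")
            if n.onset_s <= prev:
                raise ValueError("onsets must be strictly increasing (monophonic)")
            prev = n.onset_s

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([n.onset_s for n in self.notes], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([n.duration_s for n in self.notes], dtype=float)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch for n in self.notes], dtype=int)

    @property
    def total_duration_s(self) -> float:
        last = self.notes[-1]
        return last.onset_s + last.duration_s

    @property
    def beat_duration_s(self) -> float:
        """Duration of one notated beat (the denominator note value)."""
        num, den = self.time_signature
        return (60.0 / self.tempo_bpm) * (4.0 / den)

    @property
    def measure_duration_s(self) -> float:
        num, _ = self.time_signature
        return num * self.beat_duration_s

    def with_label(self, label: str) -> "NoteSequence":
        return replace(self, label=label)


@dataclass(frozen=True)
class ViewpointSequences:
    """Symbolic viewpoints of a melody.

    ``pitch_seq`` has one symbol per note; ``ioi_seq`` has ``n - 1``
    entries aligned to notes 2..n (the first note has no IOI).
    """

    pitch_seq: tuple[int, ...]
    ioi_seq: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ioi_seq) != len(self.pitch_seq) - 1:
            raise ValueError("ioi_seq must have exactly n-1 entries")
        if any(ioi <= 0 for ioi in self.ioi_seq):
            raise ValueError("all IOIs must be positive")


@dataclass(frozen=True)
class DownbeatMask:
    is_downbeat: tuple[bool, ...]
    measure_duration_s: float

    def __len__(self) -> int:
        return len(self.is_downbeat)

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.is_downbeat, dtype=bool)


def viewpoints(seq: NoteSequence) -> ViewpointSequences:
    """Derive the cpitch and ioi viewpoint sequences of a melody."""
    if len(seq) < 2:
        raise ValueError("viewpoints require at least 2 notes")
    onsets = seq.onsets
    return ViewpointSequences(
        pitch_seq=tuple(int(p) for p in seq.pitches),
        ioi_seq=tuple(float(d) for d in np.diff(onsets)),
    )


def annotate_downbeats(
    seq: NoteSequence,
    tolerance_s: float = 1e-3,
    anacrusis_offset_s: float = 0.0,
) -> DownbeatMask:
    """Mark notes whose onsets fall on a measure boundary.

    The measure grid is anchored at the onset of the first note (t = 0 of the
    melody) and can be shifted by ``anacrusis_offset_s`` for pieces with a
    pickup measure.  A note is a downbeat iff its onset is within
    ``tolerance_s`` of the nearest measure boundary.  The default 1 ms
    tolerance is appropriate for exact symbolic input; raise it for
    humanized MIDI.
    """
    if tolerance_s >= 0.5 * seq.beat_duration_s:
        raise ValueError("tolerance too coarse: must be < half the beat period")
    measure = seq.measure_duration_s
    rel = seq.onsets - anacrusis_offset_s
    # distance to nearest multiple of the measure duration
    frac = np.abs(rel - np.round(rel / measure) * measure)
    mask = frac <= tolerance_s
    return DownbeatMask(tuple(bool(m) for m in mask), measure)


def note_table_tsv(seq: NoteSequence, mask: DownbeatMask | None = None) -> str:
    """Render the note table (index, onset, duration, pitch, downbeat) as TSV."""
    if mask is not None and len(mask) != len(seq):
        raise ValueError("mask length must equal note count")
    lines = ["index\tonset_s\tduration_s\tpitch\tis_downbeat"]
    for i, n in enumerate(seq.notes):
        db = "" if mask is None else str(int(mask.is_downbeat[i]))
        lines.append(f"{i}\t{n.onset_s:.6f}\t{n.duration_s:.6f}\t{n.pitch}\t{db}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Standard MIDI File codec (monophonic subset)
# ---------------------------------------------------------------------------

_PPQ = 480  # ticks per quarter note used when writing


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_varlen(buf: io.BytesIO) -> int:
    value = 0
    while True:
        b = buf.read(1)
        if not b:
            raise ValueError("truncated variable-length quantity")
        value = (value << 7) | (b[0] & 0x7F)
        if not b[0] & 0x80:
            return value


def write_midi(seq: NoteSequence, path) -> None:
    """Write a melody as a type-0 Standard MIDI File.

    The file carries the time signature and tempo meta events so that
    :func:`read_midi` inverts it within the tick quantization (< 1 ms at the
    480-PPQ resolution used here).
    """
    tempo_us = int(round(60_000_000 / seq.tempo_bpm))
    sec_per_tick = tempo_us / 1e6 / _PPQ
    num, den = seq.time_signature

    events: list[tuple[int, bytes]] = []  # (absolute tick, event bytes)
    events.append((0, bytes([0xFF, 0x58, 0x04, num, int(np.log2(den)), 24, 8])))
    events.append((0, bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big")))
    for n in seq.notes:
        on_tick = int(round(n.onset_s / sec_per_tick))
        off_tick = int(round((n.onset_s + n.duration_s) / sec_per_tick))
        off_tick = max(off_tick, on_tick + 1)
        events.append((on_tick, bytes([0x90, n.pitch, 64])))
        events.append((off_tick, bytes([0x80, n.pitch, 0])))
    # stable sort: note-offs precede note-ons at equal tick via event ordering key
    events.sort(key=lambda e: (e[0], e[1][0] == 0x90))

    track = bytearray()
    prev_tick = 0
    for tick, ev in events:
        track += _write_varlen(tick - prev_tick)
        track += ev
        prev_tick = tick
    track += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, _PPQ)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"MTrk" + struct.pack(">I", len(track)))
        fh.write(bytes(track))


def _parse_track(data: bytes):
    """Yield (abs_tick, status, payload) triples from one MTrk chunk."""
    buf = io.BytesIO(data)
    tick = 0
    running = None
    while True:
        try:
            delta = _read_varlen(buf)
        except ValueError:
            return
        tick += delta
        b = buf.read(1)
        if not b:
            return
        status = b[0]
        if status == 0xFF:  # meta
            mtype = buf.read(1)[0]
            length = _read_varlen(buf)
            payload = buf.read(length)
            yield tick, (0xFF, mtype), payload
            if mtype == 0x2F:
                return
            continue
        if status in (0xF0, 0xF7):  # sysex
            length = _read_varlen(buf)
            buf.read(length)
            continue
        if status & 0x80:
            running = status
            first = buf.read(1)[0]
        else:  # running status
            if running is None:
                raise ValueError("dangling data byte in MIDI track")
            first = status
            status = running
        kind = status & 0xF0
        if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
            second = buf.read(1)[0]
            yield tick, (kind, status & 0x0F), bytes([first, second])
        elif kind in (0xC0, 0xD0):
            yield tick, (kind, status & 0x0F), bytes([first])
        else:
            raise ValueError(f"unsupported MIDI status byte 0x{status:02x}")


def read_midi(
    path,
    tempo_policy: str = "embedded",
    default_tempo_bpm: float = 120.0,
    time_signature: tuple[int, int] | None = None,
    label: str | None = None,
) -> NoteSequence:
    """Read a Standard MIDI File containing one monophonic melody.

    Parameters
    ----------
    tempo_policy
        ``"embedded"`` uses the tempo meta events in the file (the first one
        defines ``tempo_bpm``; later changes are honoured when converting
        ticks to seconds).  ``"fixed"`` ignores embedded tempi and uses
        ``default_tempo_bpm`` throughout.
    time_signature
        Overrides/supplies the time signature; required if the file carries
        none.

    Overlapping notes are truncated at the next onset (monophonic
    enforcement); two onsets within 1 ms are rejected as polyphonic.
    """
    if tempo_policy not in ("embedded", "fixed"):
        raise ValueError("tempo_policy must be 'embedded' or 'fixed'")
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    pos = 8 + hlen
    events = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed MIDI file: missing MTrk chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        chunk = data[pos + 8 : pos + 8 + tlen]
        events.extend(_parse_track(chunk))
        pos += 8 + tlen
    events.sort(key=lambda e: e[0])

    default_us = 60_000_000 / default_tempo_bpm
    embedded_tempos: list[tuple[int, float]] = []
    sig = time_signature
    for tick, kind, payload in events:
        if kind == (0xFF, 0x51):
            embedded_tempos.append((tick, float(int.from_bytes(payload, "big"))))
        elif kind == (0xFF, 0x58) and sig is None:
            sig = (payload[0], 2 ** payload[1])
    if sig is None:
        raise ValueError("missing time signature: none embedded and none supplied")

    # tempo map: (tick, us_per_quarter), default tempo until the first change
    tempo_changes = [(0, float(default_us))]
    if tempo_policy == "embedded":
        tempo_changes.extend(sorted(embedded_tempos))

    def tick_to_seconds(t: int) -> float:
        sec = 0.0
        prev_tick, us = tempo_changes[0]
        for ct, cus in tempo_changes[1:]:
            if ct >= t:
                break
            sec += (ct - prev_tick) * us / 1e6 / division
            prev_tick, us = ct, cus
        return sec + (t - prev_tick) * us / 1e6 / division

    notes: list[Note] = []
    active: dict[int, float] = {}  # pitch -> onset seconds
    for tick, kind, payload in events:
        if kind[0] == 0x90 and payload[1] > 0:
            onset = tick_to_seconds(tick)
            if active:
                # monophonic enforcement: truncate the sounding note here
                for p, t0 in list(active.items()):
                    if onset - t0 < _ONSET_MERGE_TOL_S:
                        raise PolyphonyError(
                            f"polyphonic input: simultaneous onsets at {t0:.4f} s"
                        )
                    notes.append(Note(t0, onset - t0, p))
                    del active[p]
            active[payload[0]] = onset
        elif kind[0] == 0x80 or (kind[0] == 0x90 and payload[1] == 0):
            p = payload[0]
            if p in active:
                t0 = active.pop(p)
                end = tick_to_seconds(tick)
                if end > t0:
                    notes.append(Note(t0, end - t0, p))
    for p, t0 in active.items():  # unterminated notes get a one-beat duration
        notes.append(Note(t0, 60.0 / default_tempo_bpm, p))
    notes.sort(key=lambda n: n.onset_s)
    if not notes:
        raise ValueError("empty melody: no notes found")
    for a, b in zip(notes, notes[1:]):
        if b.onset_s - a.onset_s < _ONSET_MERGE_TOL_S:
            raise PolyphonyError(
                f"polyphonic input: onsets {a.onset_s:.4f} and {b.onset_s:.4f} coincide"
            )

    if tempo_policy == "embedded" and embedded_tempos:
        tempo_bpm = 60_000_000 / sorted(embedded_tempos)[0][1]
    else:
        tempo_bpm = default_tempo_bpm

    return NoteSequence(
        notes=tuple(notes),
        time_signature=sig,
        tempo_bpm=tempo_bpm,
        label=label if label is not None else str(path),
    )
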