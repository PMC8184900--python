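"""Grid geometry, trial timeline, and row-to-pitch mapping.

The sonification maps a rectangular grid of object locations to sound:
the horizontal axis becomes time inside a left-to-right sweep bounded by
two beeps, and the vertical axis becomes the fundamental pitch of the
spoken word.  This module holds the coordinate conventions and the
timeline/pitch constants everything else is built on.

Conventions (serialized data states them explicitly):

* cell addresses are ``(row, col)``;
* ``row 0`` is the *bottom* of the grid, so pitch increases with the
  row index;
* ``col 0`` is the *left* edge, so onset time increases with the column
  index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GridSpec",
    "Cell",
    "TimingProfile",
    "PitchMap",
    "note_to_frequency",
    "onset_for_col",
    "pitch_for_row",
    "chance_level",
    "get_timing_preset",
    "TIMING_PRESETS",
    "DEFAULT_PRESET",
    "default_pitch_map",
]


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the localization grid (default 3 x 3, nine cells)."""

    n_rows: int = 3
    n_cols: int = 3

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True, order=True)
class Cell:
    """A grid cell address; row 0 = bottom, col 0 = left."""

    row: int
    col: int

    def validate(self, grid: GridSpec) -> "Cell":
        if not (0 <= self.row < grid.n_rows):
            raise IndexError(f"row {self.row} outside [0, {grid.n_rows})")
        if not (0 <= self.col < grid.n_cols):
            raise IndexError(f"col {self.col} outside [0, {grid.n_cols})")
        return self


@dataclass(frozen=True)
class TimingProfile:
    """Trial timeline segments, all in milliseconds.

    A trial is: silence (``pre_delay``), start beep, gap, ``n_cols``
    contiguous word slots of ``word_dur`` each (the word plays in the
    slot of its column), gap, end beep, silence.  The segment sum must
    equal ``total_dur``; this is asserted at construction.
    """

    pre_delay: float
    start_beep_dur: float
    post_start_gap: float
    word_dur: float
    pre_end_gap: float
    end_beep_dur: float
    post_delay: float
    n_cols: int = 3
    total_dur: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        segs = (
            self.pre_delay,
            self.start_beep_dur,
            self.post_start_gap,
            self.word_dur,
            self.pre_end_gap,
            self.end_beep_dur,
            self.post_delay,
        )
        if any(s <= 0 for s in segs):
            raise ValueError("all timeline segments must be positive")
        computed = (
            self.pre_delay
            + self.start_beep_dur
            + self.post_start_gap
            + self.n_cols * self.word_dur
            + self.pre_end_gap
            + self.end_beep_dur
            + self.post_delay
        )
        if self.total_dur is None:
            object.__setattr__(self, "total_dur", computed)
        elif abs(self.total_dur - computed) > 1e-9:
            raise ValueError(
                f"total_dur {self.total_dur} != segment sum {computed}"
            )

    def scaled(self, factor: float) -> "TimingProfile":
        """A profile with every segment multiplied by ``factor``."""
        return TimingProfile(
            self.pre_delay * factor,
            self.start_beep_dur * factor,
            self.post_start_gap * factor,
            self.word_dur * factor,
            self.pre_end_gap * factor,
            self.end_beep_dur * factor,
            self.post_delay * factor,
            n_cols=self.n_cols,
        )


# The published segment durations (5, 10, 10, 50, 10, 10, 5 ms) sum to
# 200 ms, while the accompanying text describes a 2-s trial.  Both
# readings ship as presets; the default is the 2-s one ("paper-total",
# every printed value x10), under which a word slot is 500 ms -- a
# realistic duration for a two-syllable word.
_PRINTED = TimingProfile(5, 10, 10, 50, 10, 10, 5)
TIMING_PRESETS: dict[str, TimingProfile] = {
    "printed": _PRINTED,
    "paper-total": _PRINTED.scaled(10),
}
DEFAULT_PRESET = "paper-total"


def get_timing_preset(name: str = DEFAULT_PRESET) -> TimingProfile:
    try:
        return TIMING_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown timing preset {name!r}; available: {sorted(TIMING_PRESETS)}"
        ) from None


_NOTE_SEMITONES = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_NOTE_RE = re.compile(r"^([A-G])([#b]?)(-?\d+)$")


def note_to_frequency(name: str, a4: float = 440.0) -> float:
    """Frequency of a note in scientific pitch notation, 12-TET.

    ``f = a4 * 2**((m - 69) / 12)`` with MIDI number ``m``;
    ``note_to_frequency("A4") == 440.0``, ``"C3"`` -> 130.81 Hz.
    """
    m = _NOTE_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse note name {name!r}")
    letter, accidental, octave = m.groups()
    semitone = _NOTE_SEMITONES[letter] + {"#": 1, "b": -1, "": 0}[accidental]
    midi = 12 * (int(octave) + 1) + semitone
    return a4 * 2.0 ** ((midi - 69) / 12.0)


@dataclass(frozen=True)
class PitchMap:
    """Row -> musical pitch assignment, bottom row first.

    Frequencies must increase strictly with the row index: higher on
    the grid means higher in pitch.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("pitch map needs at least one row")
        freqs = [f for _, f in self.entries]
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must increase strictly with row index")

    @classmethod
    def from_names(cls, names: list[str] | tuple[str, ...], a4: float = 440.0) -> "PitchMap":
        return cls(tuple((n, note_to_frequency(n, a4)) for n in names))

    @property
    def n_rows(self) -> int:
        return len(self.entries)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)


def default_pitch_map() -> PitchMap:
    """The published three-note map: low C, low A#, middle G#.

    "Low" and "middle" octaves are not pinned down in the source
    description; this package reads them as octave 3 and octave 4
    (C3, A#3, G#4), a documented and configurable default.
    """
    return PitchMap.from_names(["C3", "A#3", "G#4"])


def onset_for_col(col: int, profile: TimingProfile) -> float:
    """Word onset time (ms from trial start) for a column.

    With the "printed" preset this gives 25 / 75 / 125 ms for the
    left / central / right columns; the word window is
    ``[onset, onset + word_dur)``.
    """
    if not (0 <= col < profile.n_cols):
        raise IndexError(f"col {col} outside [0, {profile.n_cols})")
    return (
        profile.pre_delay
        + profile.start_beep_dur
        + profile.post_start_gap
        + col * profile.word_dur
    )


def pitch_for_row(row: int, pitchmap: PitchMap) -> tuple[str, float]:
    """(note name, frequency in Hz) sonifying a grid row."""
    if not (0 <= row < pitchmap.n_rows):
        raise IndexError(f"row {row} outside [0, {pitchmap.n_rows})")
    return pitchmap.entries[row]


def chance_level(grid: GridSpec) -> float:
    """Probability of a correct localization under uniform guessing."""
    return 1.0 / grid.n_cells
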