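"""Trial sonification: grid cell -> audio waveform.

A trial waveform contains a start beep, a word token placed in the time
slot of its column and pitched at the frequency of its row, and an end
beep, inside the timeline of a :class:`~topospeech.core.TimingProfile`.

The original stimuli were natural two-syllable words sung at the three
target pitches; this package ships a synthetic word renderer (a seeded
harmonic complex under a syllabic amplitude envelope) so that trials
can be generated, decoded and round-trip tested without recordings.
A file-based provider can substitute user-supplied WAV clips.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import Cell, GridSpec, PitchMap, TimingProfile, onset_for_col, pitch_for_row

__all__ = [
    "WordToken",
    "TrialSpec",
    "Waveform",
    "BeepSpec",
    "DEFAULT_START_BEEP",
    "DEFAULT_END_BEEP",
    "DEFAULT_SAMPLE_RATE",
    "render_word",
    "render_beep",
    "encode_trial",
    "fit_clip",
]

DEFAULT_SAMPLE_RATE = 44100

BiasFlag = Literal["none", "high", "low"]


@dataclass(frozen=True)
class WordToken:
    """A spoken-object stimulus: a short, graspable-object word.

    ``bias_flag`` records whether a spatial-bias screen associated the
    word with the upper ("high") or lower ("low") part of space; test
    pools admit only unbiased tokens.
    """

    token_id: str
    label: str = ""
    n_syllables: int = 2
    bias_flag: BiasFlag = "none"

    def __post_init__(self) -> None:
        if not self.token_id:
            raise ValueError("token_id must be non-empty")
        if self.n_syllables < 1:
            raise ValueError("n_syllables must be >= 1")
        if not self.label:
            object.__setattr__(self, "label", self.token_id)


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus presentation: a word token at a grid cell."""

    word: WordToken
    cell: Cell
    condition: Literal["forward", "backward"] = "forward"
    phase: Literal["training", "test"] = "test"


@dataclass
class Waveform:
    """Sampled mono audio; amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        peak = np.max(np.abs(self.samples))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed [-1, 1] (peak {peak:.4f})")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeepSpec:
    """A pure-tone marker beep with raised-cosine on/off ramps."""

    frequency: float = 1000.0
    amplitude: float = 0.8
    ramp_ms: float = 2.0


# The source only requires the two boundary beeps to be "easily
# distinguishable"; defaults separate them by 7 semitones.
DEFAULT_START_BEEP = BeepSpec(frequency=1000.0)
DEFAULT_END_BEEP = BeepSpec(frequency=1500.0)


def _n_samples(dur_ms: float, sample_rate: int) -> int:
    return int(round(dur_ms * sample_rate / 1000.0))


def _token_rng(token_id: str, seed: int) -> np.random.Generator:
    # stable per-token timbre: crc32 keeps the stream independent of
    # Python's randomized str hash
    return np.random.default_rng([zlib.crc32(token_id.encode("utf-8")), seed & 0x7FFFFFFF])


def render_beep(spec: BeepSpec, dur_ms: float, sample_rate: int) -> np.ndarray:
    n = _n_samples(dur_ms, sample_rate)
    t = np.arange(n) / sample_rate
    y = spec.amplitude * np.sin(2 * np.pi * spec.frequency * t)
    n_ramp = min(_n_samples(spec.ramp_ms, sample_rate), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        y[:n_ramp] *= ramp
        y[-n_ramp:] *= ramp[::-1]
    return y


def _syllable_envelope(n: int, n_syllables: int) -> np.ndarray:
    """Amplitude envelope with one raised-cosine bump per syllable."""
    env = np.zeros(n)
    seg = n / n_syllables
    for k in range(n_syllables):
        a, b = int(round(k * seg)), int(round((k + 1) * seg))
        m = b - a
        # 90% duty cycle inside each syllable slot leaves an audible dip
        core = int(round(0.9 * m))
        x = np.arange(core) / max(core - 1, 1)
        env[a : a + core] = 0.5 * (1 - np.cos(2 * np.pi * x))
    return env


def render_word(
    token: WordToken,
    f0: float,
    dur_ms: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    n_harmonics: int = 6,
    amplitude: float = 0.8,
) -> Waveform:
    """Synthesize a word token as a pitched harmonic complex.

    The voiced portion is a sum of the first ``n_harmonics`` harmonics
    of ``f0`` with per-token harmonic amplitudes (deterministic in
    ``(token_id, seed)``), shaped by an envelope with one energy bump
    per syllable.  Output length is exactly
    ``round(dur_ms * sample_rate / 1000)`` samples.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if dur_ms <= 0:
        raise ValueError("dur_ms must be positive")
    n = _n_samples(dur_ms, sample_rate)
    rng = _token_rng(token.token_id, seed)
    # fundamental dominates so pitch trackers lock to f0, not a harmonic
    weights = np.concatenate(([1.0], rng.uniform(0.1, 0.5, size=n_harmonics - 1)))
    weights /= weights.sum()
    t = np.arange(n) / sample_rate
    y = np.zeros(n)
    nyquist = sample_rate / 2
    for h, w in enumerate(weights, start=1):
        if h * f0 < nyquist:
            y += w * np.sin(2 * np.pi * h * f0 * t)
    y *= _syllable_envelope(n, token.n_syllables)
    peak = np.max(np.abs(y))
    if peak > 0:
        y *= amplitude / peak
    return Waveform(y, sample_rate)


def fit_clip(clip: Waveform, dur_ms: float, sample_rate: int) -> np.ndarray:
    """Fit a user-supplied clip to a word slot by truncation/zero-padding."""
    if clip.sample_rate != sample_rate:
        raise ValueError(
            f"clip sample rate {clip.sample_rate} != target {sample_rate}; resampling is out of scope"
        )
    n = _n_samples(dur_ms, sample_rate)
    y = clip.samples[:n]
    if y.size < n:
        y = np.pad(y, (0, n - y.size))
    return y


def encode_trial(
    spec: TrialSpec,
    profile: TimingProfile,
    pitchmap: PitchMap,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    grid: GridSpec | None = None,
    start_beep: BeepSpec = DEFAULT_START_BEEP,
    end_beep: BeepSpec = DEFAULT_END_BEEP,
    seed: int = 0,
    word_audio: Waveform | None = None,
) -> Waveform:
    """Render a full trial: beep, column-timed pitched word, beep.

    The word occupies ``[onset_for_col, onset + word_dur)`` at the
    frequency ``pitch_for_row`` assigns to the cell's row; the start
    beep occupies ``[pre_delay, pre_delay + start_beep_dur)`` and the
    end beep the window ending ``total_dur - post_delay``.  Everything
    else is silence.  Pass ``word_audio`` to substitute a natural
    recording for the synthetic token (it is fitted to the slot by
    truncation/padding; no pitch shifting).
    """
    if grid is None:
        grid = GridSpec(n_rows=pitchmap.n_rows, n_cols=profile.n_cols)
    spec.cell.validate(grid)
    n_total = _n_samples(profile.total_dur, sample_rate)
    y = np.zeros(n_total)

    def place(segment: np.ndarray, onset_ms: float) -> None:
        i = _n_samples(onset_ms, sample_rate)
        y[i : i + segment.size] += segment[: max(0, n_total - i)]

    place(render_beep(start_beep, profile.start_beep_dur, sample_rate), profile.pre_delay)
    end_onset = profile.total_dur - profile.post_delay - profile.end_beep_dur
    place(render_beep(end_beep, profile.end_beep_dur, sample_rate), end_onset)

    _, f0 = pitch_for_row(spec.cell.row, pitchmap)
    if word_audio is not None:
        word = fit_clip(word_audio, profile.word_dur, sample_rate)
    else:
        word = render_word(spec.word, f0, profile.word_dur, sample_rate, seed=seed).samples
    place(word, onset_for_col(spec.cell.col, profile))

    # segments cannot overlap by the timeline invariant; the clip guard
    # is purely defensive
    np.clip(y, -1.0, 1.0, out=y)
    return Waveform(y, sample_rate)
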