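"""Recover the encoded grid cell from a trial waveform.

The decoder is the machine analogue of the listener's task: locate the
two boundary beeps, measure when the word starts between them (column =
nearest slot onset) and its fundamental frequency (row = nearest pitch
in log-frequency).  It exists to round-trip verify the sonification and
to characterize its robustness to noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import Cell, PitchMap, TimingProfile, onset_for_col
from .encoder import Waveform

__all__ = [
    "DecodedTrial",
    "NoPitchError",
    "TrialStructureError",
    "EmptyTrialError",
    "estimate_f0",
    "decode_trial",
    "add_noise",
]


class NoPitchError(ValueError):
    """Raised when no periodic component can be found."""


class TrialStructureError(ValueError):
    """Raised when the boundary beeps cannot be located."""


class EmptyTrialError(ValueError):
    """Raised when no word energy is found between the beeps."""


@dataclass(frozen=True)
class DecodedTrial:
    cell: Cell
    measured_onset_ms: float
    measured_f0_hz: float
    confidence: Literal["clean", "marginal"]


def estimate_f0(
    w: Waveform,
    fmin: float = 80.0,
    fmax: float = 600.0,
    energy_threshold: float = 1e-4,
) -> float:
    """Fundamental frequency of the dominant periodic component (Hz).

    Autocorrelation over the full input with parabolic interpolation of
    the peak lag, searched in the [fmin, fmax] band.  Raises
    :class:`NoPitchError` on silent or aperiodic input.
    """
    x = w.samples - np.mean(w.samples)
    if np.sqrt(np.mean(x**2)) < energy_threshold:
        raise NoPitchError("input below energy threshold")
    n = x.size
    # FFT-based autocorrelation (O(n log n))
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    lag_min = max(2, int(np.floor(w.sample_rate / fmax)))
    lag_max = int(np.ceil(w.sample_rate / fmin))
    if lag_max >= n - 1:
        lag_max = n - 2
    if lag_max <= lag_min:
        raise NoPitchError("input too short for the search band")
    band = r[lag_min : lag_max + 1]
    k = int(np.argmax(band)) + lag_min
    if r[k] <= 0.3 * r[0]:
        raise NoPitchError("no periodic component in the search band")
    # parabolic refinement around the peak lag
    y0, y1, y2 = r[k - 1], r[k], r[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    lag = k + float(np.clip(delta, -0.5, 0.5))
    return w.sample_rate / lag


def _energy_frames(x: np.ndarray, frame: int) -> np.ndarray:
    n_frames = x.size // frame
    return np.add.reduce(
        (x[: n_frames * frame] ** 2).reshape(n_frames, frame), axis=1
    ) / frame


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of the True runs in a boolean mask."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((int(a), int(b)))
    return out


def decode_trial(
    w: Waveform,
    profile: TimingProfile,
    pitchmap: PitchMap,
    hop_ms: float = 5.0,
    floor_ratio: float = 10.0,
) -> DecodedTrial:
    """Decode the grid cell encoded in a trial waveform.

    Short-time energy (``hop_ms`` frames) is thresholded at
    ``floor_ratio`` times the noise floor estimated from the pre-delay
    segment.  The first and last supra-threshold runs are the boundary
    beeps; the word onset is the first supra-threshold instant between
    them.  Column = nearest slot onset; row = nearest pitch-map entry
    in log2 frequency, ties toward the lower index.
    """
    sr = w.sample_rate
    frame = max(1, int(round(hop_ms * sr / 1000.0)))
    energy = _energy_frames(w.samples, frame)
    if energy.size < 3:
        raise TrialStructureError("waveform too short for the trial timeline")

    n_floor = max(1, int(profile.pre_delay // hop_ms))
    floor = float(np.mean(energy[:n_floor]))
    peak = float(np.max(energy))
    if peak <= 0:
        raise TrialStructureError("silent input: no beeps found")
    threshold = max(floor * floor_ratio, 1e-6 * peak)
    runs = _runs(energy > threshold)
    if len(runs) < 2:
        raise TrialStructureError(
            f"expected two boundary beeps, found {len(runs)} energy run(s)"
        )
    if len(runs) == 2:
        raise EmptyTrialError("no word energy between the boundary beeps")
    start_beep, end_beep = runs[0], runs[-1]
    word_runs = [r for r in runs[1:-1]]
    word_start_frame = word_runs[0][0]
    word_end_frame = word_runs[-1][1]

    # onset measured relative to trial start; the trial clock is
    # anchored at the detected start-beep onset so absolute file offsets
    # do not matter
    beep_onset_ms = start_beep[0] * hop_ms
    onset_ms = word_start_frame * hop_ms - beep_onset_ms + profile.pre_delay

    slot_onsets = np.array([onset_for_col(c, profile) for c in range(profile.n_cols)])
    col = int(np.argmin(np.abs(slot_onsets - onset_ms)))  # argmin ties -> lower index

    a = word_start_frame * frame
    b = min(word_end_frame * frame, a + int(round(profile.word_dur * sr / 1000.0)))
    f0 = estimate_f0(Waveform(w.samples[a:b], sr))
    log_dist = np.abs(np.log2(np.asarray(pitchmap.frequencies)) - np.log2(f0))
    row = int(np.argmin(log_dist))

    onset_err = abs(slot_onsets[col] - onset_ms) / profile.word_dur
    f0_err = abs(np.log2(f0 / pitchmap.frequencies[row]))
    confidence = "clean" if (onset_err < 0.25 and f0_err < 0.05) else "marginal"
    return DecodedTrial(
        cell=Cell(row=row, col=col),
        measured_onset_ms=float(onset_ms),
        measured_f0_hz=float(f0),
        confidence=confidence,
    )


def add_noise(w: Waveform, snr_db: float, seed: int = 0) -> Waveform:
    """Additive white Gaussian noise at the given SNR.

    SNR is measured against the RMS of the active (non-silent) part of
    the signal, then the mixture is renormalized to peak 1 if needed so
    it remains a valid waveform.
    """
    rng = np.random.default_rng(seed)
    active = w.samples[np.abs(w.samples) > 1e-6]
    rms = np.sqrt(np.mean(active**2)) if active.size else np.sqrt(np.mean(w.samples**2))
    noise_std = rms / 10.0 ** (snr_db / 20.0)
    y = w.samples + rng.normal(0.0, noise_std, size=w.samples.size)
    peak = np.max(np.abs(y))
    if peak > 1.0:
        y /= peak
    return Waveform(y, w.sample_rate)
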