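"""Packaged fixtures, WAV I/O, and run configuration.

The fixtures are the per-subject success rates (and per-subject trial
SDs) of the two published participant groups, 14 subjects each after
outlier exclusion, transcribed digit-for-digit and guarded by a
checksum so the analysis pipeline can reproduce the printed group
statistics from them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .core import (
    DEFAULT_PRESET,
    PitchMap,
    TimingProfile,
    default_pitch_map,
    get_timing_preset,
)
from .encoder import DEFAULT_SAMPLE_RATE, BeepSpec, Waveform

__all__ = [
    "Fixture",
    "FixtureIntegrityError",
    "load_fixture",
    "write_wav",
    "read_wav",
    "RunConfig",
]


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


# Per-subject overall success rate (%) and per-subject SD (%) in the
# forward (front-of-body) and backward (behind-the-back) localization
# groups, subject order as published.
_FIXTURE_SOURCE: dict[str, dict[str, list[float]]] = {
    "forward": {
        "success": [83.33, 93.33, 74.44, 91.11, 74.44, 71.11, 77.78,
                    75.56, 86.67, 84.44, 84.44, 61.11, 74.44, 91.11],
        "sd": [37.48, 25.08, 43.86, 28.62, 43.86, 45.58, 41.81,
               43.22, 34.18, 36.45, 36.45, 49.02, 43.86, 28.62],
    },
    "backward": {
        "success": [75.56, 92.22, 74.44, 87.78, 83.33, 78.89, 91.11,
                    77.78, 80.00, 58.89, 72.22, 82.22, 74.44, 85.56],
        "sd": [43.22, 26.93, 43.86, 32.94, 37.48, 41.04, 28.62,
               41.81, 50.22, 49.48, 45.04, 38.45, 43.86, 35.35],
    },
}

_FIXTURE_SHA256 = "5c4d103c16e32ba5379deb705b733d50ed5006d787952505120a62c75e498b29"


def _fixture_digest() -> str:
    canonical = json.dumps(_FIXTURE_SOURCE, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("ascii")).hexdigest()


@dataclass(frozen=True)
class Fixture:
    condition: str
    success: tuple[float, ...]  # per-subject success rate, percent
    sd: tuple[float, ...]  # per-subject across-trial SD, percent

    def __post_init__(self) -> None:
        if len(self.success) != 14 or len(self.sd) != 14:
            raise ValueError("fixtures hold exactly 14 subjects per condition")
        if any(not 0.0 <= v <= 100.0 for v in self.success):
            raise ValueError("success rates must lie in [0, 100]")


def load_fixture(condition: str) -> Fixture:
    """The packaged per-subject success table for one condition."""
    if condition not in _FIXTURE_SOURCE:
        raise ValueError(
            f"unknown condition {condition!r}; expected 'forward' or 'backward'"
        )
    if _fixture_digest() != _FIXTURE_SHA256:
        raise FixtureIntegrityError("packaged fixture failed its checksum")
    src = _FIXTURE_SOURCE[condition]
    return Fixture(condition=condition,
                   success=tuple(src["success"]), sd=tuple(src["sd"]))


def write_wav(w: Waveform, path: str | Path) -> None:
    """Write a waveform as RIFF PCM 16-bit."""
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, pcm)


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF PCM WAV file back into a float waveform."""
    sr, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    return Waveform(np.clip(samples, -1.0, 1.0), int(sr))


@dataclass
class RunConfig:
    """Resolvable run configuration (timing preset + overrides, pitch
    map, sample rate, beeps, seeds, analysis knobs)."""

    preset: str = DEFAULT_PRESET
    overrides: dict | None = None
    pitch_map: list[str] | None = None
    sample_rate: int = DEFAULT_SAMPLE_RATE
    start_beep_hz: float = 1000.0
    end_beep_hz: float = 1500.0
    seed: int = 0
    bin_size: int = 10
    alpha: float = 0.05

    def timing_profile(self) -> TimingProfile:
        profile = get_timing_preset(self.preset)
        if self.overrides:
            fields = {
                k: self.overrides.get(k, getattr(profile, k))
                for k in ("pre_delay", "start_beep_dur", "post_start_gap",
                          "word_dur", "pre_end_gap", "end_beep_dur", "post_delay")
            }
            profile = TimingProfile(**fields, n_cols=profile.n_cols)
        return profile

    def pitchmap(self) -> PitchMap:
        if self.pitch_map is None:
            return default_pitch_map()
        return PitchMap.from_names(self.pitch_map)

    def beeps(self) -> tuple[BeepSpec, BeepSpec]:
        return BeepSpec(frequency=self.start_beep_hz), BeepSpec(frequency=self.end_beep_hz)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
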