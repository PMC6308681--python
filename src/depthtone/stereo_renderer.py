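"""Offline synthesis of the stereo audio cycle.

Each schedule event becomes a block of samples: the reference tone is a
centred sine at fixed volume, pauses are silence, and each column slot mixes
the three tones of its scan, every tone scaled by its cell's volume code and
the whole slot panned to the column's azimuth with a constant-power law over
the sensor's 57 degree horizontal field of view.  The result is written as
16-bit PCM stereo WAV.

Loudness follows a linear amplitude map ``(255 - code) / 255`` (code 0 =
nearest = full volume, 255 = silence).  Each slot gets a 5 ms raised-cosine
fade-in/out to avoid clicks at slot boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.io import wavfile

from .grid_mapper import SmallFieldGrid
from .sonification import SonificationSchedule, ToneBank

log = logging.getLogger(__name__)

FADE_MS = 5.0
"""Raised-cosine fade-in/out applied to each tone slot, in milliseconds."""


@dataclass(frozen=True)
class AudioConfig:
    """Output audio settings.

    The device target rate is 22050 Hz; 44100 Hz is the authoring default.
    ``hfov_deg`` is the sensor's horizontal field of view, over which the
    grid columns are panned.
    """

    sample_rate: int = 44100
    hfov_deg: float = 57.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if not 0 < self.hfov_deg < 180:
            raise ValueError("horizontal FOV must lie in (0, 180) degrees")


@dataclass(frozen=True)
class StereoBuffer:
    """Two equal-length channels of real samples in [-1, 1]."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=np.float64)
        right = np.asarray(self.right, dtype=np.float64)
        if left.shape != right.shape or left.ndim != 1:
            raise ValueError("channels must be equal-length 1-D arrays")
        if left.size and max(np.abs(left).max(), np.abs(right).max()) > 1.0 + 1e-12:
            raise ValueError("samples exceed unit magnitude")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def __len__(self) -> int:
        return len(self.left)

    @property
    def duration_s(self) -> float:
        return len(self.left) / self.sample_rate


def volume_gain(code: int) -> float:
    """Linear amplitude factor of an 8-bit volume code: (255 - code) / 255."""
    if not 0 <= code <= 255:
        raise ValueError(f"volume code {code} outside [0, 255]")
    return (255 - code) / 255.0


def column_azimuth(col: int, ncols: int, hfov_deg: float) -> float:
    """Centre azimuth in degrees of a grid column's angular sector.

    Negative is left of the optical axis; the middle column of an odd
    count sits exactly on axis.
    """
    if not 0 <= col < ncols:
        raise ValueError(f"column {col} outside [0, {ncols})")
    return -hfov_deg / 2.0 + (col + 0.5) * hfov_deg / ncols


def pan_gains(azimuth_deg: float) -> tuple[float, float]:
    """Constant-power stereo gains for an azimuth in [-90, 90] degrees.

    left = cos(theta), right = sin(theta) with theta mapping -90..+90 deg
    onto 0..pi/2, so left^2 + right^2 == 1 at every azimuth.
    """
    if not -90.0 <= azimuth_deg <= 90.0:
        raise ValueError(f"azimuth {azimuth_deg} outside [-90, 90]")
    theta = (azimuth_deg + 90.0) / 180.0 * math.pi / 2.0
    return math.cos(theta), math.sin(theta)


def event_sample_count(duration_ms: float, sample_rate: int) -> int:
    return int(round(duration_ms * sample_rate / 1000.0))


def _fade_envelope(n: int, sample_rate: int) -> np.ndarray:
    """Raised-cosine fade-in/out envelope of total length n."""
    nf = min(int(round(FADE_MS * sample_rate / 1000.0)), n // 2)
    env = np.ones(n)
    if nf > 0:
        ramp = 0.5 - 0.5 * np.cos(np.linspace(0.0, math.pi, nf))
        env[:nf] = ramp
        env[-nf:] = ramp[::-1]
    return env


def synthesize_tone(frequency: float, duration_ms: float, gain_db: float,
                    bank: ToneBank, audio: AudioConfig) -> np.ndarray:
    """A mono sine block at ``bank.base_amplitude`` scaled by ``gain_db``.

    Starts at phase 0; length is ``round(duration_ms * rate / 1000)``
    samples.  If the gained amplitude exceeds 1 it is rescaled to 1 with a
    warning.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n = event_sample_count(duration_ms, audio.sample_rate)
    amplitude = bank.base_amplitude * 10.0 ** (gain_db / 20.0)
    if amplitude > 1.0:
        log.warning("tone amplitude %.3f exceeds full scale; limiting to 1.0",
                    amplitude)
        amplitude = 1.0
    t = np.arange(n) / audio.sample_rate
    return amplitude * np.sin(2.0 * math.pi * frequency * t)


def _limit(slot_l: np.ndarray, slot_r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale a mixed slot only if its peak exceeds full scale."""
    peak = max(np.abs(slot_l).max(initial=0.0), np.abs(slot_r).max(initial=0.0))
    if peak > 1.0:
        log.warning("mixed slot peak %.3f > 1; rescaling", peak)
        slot_l = slot_l / peak
        slot_r = slot_r / peak
    return slot_l, slot_r


def render_cycle(grid: SmallFieldGrid, bank: ToneBank,
                 schedule: SonificationSchedule, audio: AudioConfig) -> StereoBuffer:
    """Synthesize one full transmission cycle of the given grid.

    Events are concatenated in schedule order; every scan-column slot mixes
    that scan's three tones, each scaled by its cell's volume and panned to
    the column azimuth.  Mixed slots are rescaled only if they would clip.
    """
    for event in schedule.events:
        if event.kind == "scan_column" and event.column >= grid.cols:
            raise ValueError(f"schedule column {event.column} outside grid "
                             f"with {grid.cols} columns")
    max_row = max((t.row for t in bank.tones), default=0)
    if max_row >= grid.rows:
        raise ValueError(f"tone bank addresses row {max_row} but grid has "
                         f"{grid.rows} rows")

    left_parts: list[np.ndarray] = []
    right_parts: list[np.ndarray] = []
    center_l, center_r = pan_gains(0.0)
    for event in schedule.events:
        n = event_sample_count(event.duration_ms, audio.sample_rate)
        if event.kind == "pause":
            left_parts.append(np.zeros(n))
            right_parts.append(np.zeros(n))
            continue
        if event.kind == "reference":
            mono = synthesize_tone(bank.reference_frequency, event.duration_ms,
                                   bank.reference_gain_db, bank, audio)
            mono *= _fade_envelope(n, audio.sample_rate)
            l, r = _limit(center_l * mono, center_r * mono)
        else:  # scan_column
            mono = np.zeros(n)
            for tone in bank.scan_tones(event.scan):
                gain = volume_gain(int(grid.codes[tone.row, event.column]))
                if gain > 0.0:
                    mono += gain * synthesize_tone(tone.frequency,
                                                   event.duration_ms,
                                                   tone.gain_db, bank, audio)
            mono *= _fade_envelope(n, audio.sample_rate)
            az = column_azimuth(event.column, grid.cols, audio.hfov_deg)
            gl, gr = pan_gains(az)
            l, r = _limit(gl * mono, gr * mono)
        left_parts.append(l)
        right_parts.append(r)
    return StereoBuffer(left=np.concatenate(left_parts),
                        right=np.concatenate(right_parts),
                        sample_rate=audio.sample_rate)


def write_wav(buffer: StereoBuffer, path: Union[str, Path]) -> None:
    """Write the buffer as RIFF/WAVE, PCM 16-bit little-endian stereo."""
    samples = np.stack([buffer.left, buffer.right], axis=1)
    pcm = np.clip(np.round(samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), buffer.sample_rate, pcm)


def read_wav(path: Union[str, Path]) -> StereoBuffer:
    """Read a 16-bit stereo WAV back into a float StereoBuffer."""
    rate, pcm = wavfile.read(str(path))
    if pcm.ndim != 2 or pcm.shape[1] != 2:
        raise ValueError(f"{path}: expected 2-channel WAV")
    samples = pcm.astype(np.float64) / 32767.0
    samples = np.clip(samples, -1.0, 1.0)
    return StereoBuffer(left=samples[:, 0], right=samples[:, 1], sample_rate=int(rate))
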