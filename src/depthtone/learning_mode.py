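"""Tilt-driven obstacle-indicator ("learning") mode.

This mode trains the association between pitch and elevation.  The device
watches only the central small field of the frame and signals the minimum
distance found there with a single tone whose pitch is chosen from the head
tilt: looking up selects higher tones, looking down lower ones, in bins of
about 7.17 degrees (the 43 degree vertical field of view split over the six
grid rows).  Beyond +/-21.5 degrees no sound is played.  Distance is
refreshed at 20 Hz (one 50 ms tone segment per reading) and every 80th
reading — every 4 s — is replaced by the reference pattern (200 ms pause,
300 ms reference tone, 200 ms pause), exactly as in normal mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .depth_transform import RAW_MAX, VOLUME_SILENCE, RawDepthFrame, VolumeLookupTable
from .sonification import ToneBank, default_tone_bank
from .stereo_renderer import (AudioConfig, StereoBuffer, _fade_envelope, _limit,
                              event_sample_count, pan_gains, synthesize_tone,
                              volume_gain)

log = logging.getLogger(__name__)

TILT_RESOLUTION_DEG = 0.5
"""Accelerometer tilt resolution in degrees."""


@dataclass(frozen=True)
class TiltReading:
    """One accelerometer inclination sample, positive = up, in 0.5 deg steps."""

    angle_deg: float

    def __post_init__(self) -> None:
        q = self.angle_deg / TILT_RESOLUTION_DEG
        if abs(q - round(q)) > 1e-9:
            raise ValueError(
                f"tilt {self.angle_deg} not a multiple of {TILT_RESOLUTION_DEG} deg")


@dataclass(frozen=True)
class LearningConfig:
    """Timing and geometry of the learning mode."""

    refresh_ms: float = 50.0
    reference_every: int = 80
    reference_ms: float = 300.0
    reference_pause_ms: float = 200.0
    vfov_deg: float = 43.0
    rows: int = 6
    cols: int = 5

    def __post_init__(self) -> None:
        if self.refresh_ms <= 0:
            raise ValueError("refresh period must be positive")
        if self.reference_every < 1:
            raise ValueError("reference_every must be >= 1")

    @property
    def row_bin_deg(self) -> float:
        """Angular width of one tilt bin (~7.17 deg at the defaults)."""
        return self.vfov_deg / self.rows

    @property
    def refresh_hz(self) -> float:
        return 1000.0 / self.refresh_ms


def tilt_to_row(tilt: TiltReading, config: LearningConfig = LearningConfig()
                ) -> Optional[int]:
    """Map a tilt angle to the grid row (and hence tone) it selects.

    Returns ``None`` outside +/- vfov/2 (no sound).  Bins are half-open
    with the upper edge inclusive: row r covers
    ``(vfov/2 - (r+1)*bin, vfov/2 - r*bin]`` with row 0 at the top (looking
    up), except that the lowest boundary -vfov/2 itself is still audible
    (row rows-1).
    """
    half = config.vfov_deg / 2.0
    angle = tilt.angle_deg
    if angle > half or angle < -half:
        return None
    # exact at representable edges: (half - angle) * rows / vfov
    t = (half - angle) * config.rows / config.vfov_deg
    row = int(math.floor(t + 1e-9))
    return min(row, config.rows - 1)


def central_region(frame: RawDepthFrame,
                   config: LearningConfig = LearningConfig()) -> np.ndarray:
    """The central small-field-sized pixel block of the frame.

    One grid cell wide and high (width/cols x height/rows), centred on the
    frame centre; 128x80 at x in [256, 384), y in [200, 280) for a 640x480
    frame with the default grid.
    """
    if frame.height % config.rows or frame.width % config.cols:
        raise ValueError("frame dimensions must be divisible by the grid")
    bw = frame.width // config.cols
    bh = frame.height // config.rows
    x0 = (frame.width - bw) // 2
    y0 = (frame.height - bh) // 2
    return frame.values[y0:y0 + bh, x0:x0 + bw]


@dataclass(frozen=True)
class ToneEvent:
    """One learning-mode output event: a frequency (or silence) and volume."""

    frequency: Optional[float]  # None = silence (tilt out of range)
    volume_code: int
    gain_db: float = 0.0


def learning_step(frame: RawDepthFrame, tilt: TiltReading,
                  lut: VolumeLookupTable,
                  config: LearningConfig = LearningConfig(),
                  bank: ToneBank | None = None) -> ToneEvent:
    """Compute one reading's tone event.

    The volume code is the normal-mode transform of the minimum valid raw
    reading in the central region (255 if none are valid); the frequency is
    the row tone selected by the tilt, or silence when the tilt exceeds the
    field of view.
    """
    bank = bank or default_tone_bank()
    row = tilt_to_row(tilt, config)
    region = central_region(frame, config)
    valid = region[region != RAW_MAX]
    code = int(lut[int(valid.min())]) if valid.size else VOLUME_SILENCE
    if row is None:
        return ToneEvent(frequency=None, volume_code=code)
    tone = bank.tone_for_row(row)
    return ToneEvent(frequency=tone.frequency, volume_code=code,
                     gain_db=tone.gain_db)


def render_learning_session(frames: Sequence[RawDepthFrame],
                            tilts: Sequence[TiltReading],
                            lut: VolumeLookupTable,
                            config: LearningConfig = LearningConfig(),
                            audio: AudioConfig = AudioConfig(),
                            bank: ToneBank | None = None) -> StereoBuffer:
    """Synthesize a learning session: one 50 ms centred tone per reading.

    ``frames`` and ``tilts`` must have equal length.  Every Nth reading
    (N = ``config.reference_every``) is replaced by the reference pattern:
    a pause, the 300 ms 100 Hz reference tone, and another pause.
    """
    if len(frames) != len(tilts):
        raise ValueError("frames and tilts must have equal length")
    bank = bank or default_tone_bank()
    center_l, center_r = pan_gains(0.0)
    left_parts: list[np.ndarray] = []
    right_parts: list[np.ndarray] = []
    n_refs = 0
    for i, (frame, tilt) in enumerate(zip(frames, tilts)):
        if (i + 1) % config.reference_every == 0:
            n_pause = event_sample_count(config.reference_pause_ms, audio.sample_rate)
            ref = synthesize_tone(bank.reference_frequency, config.reference_ms,
                                  bank.reference_gain_db, bank, audio)
            ref *= _fade_envelope(len(ref), audio.sample_rate)
            mono = np.concatenate([np.zeros(n_pause), ref, np.zeros(n_pause)])
            n_refs += 1
        else:
            event = learning_step(frame, tilt, lut, config, bank)
            n = event_sample_count(config.refresh_ms, audio.sample_rate)
            if event.frequency is None:
                mono = np.zeros(n)
            else:
                gain = volume_gain(event.volume_code)
                mono = gain * synthesize_tone(event.frequency, config.refresh_ms,
                                              event.gain_db, bank, audio)
                mono *= _fade_envelope(n, audio.sample_rate)
        l, r = _limit(center_l * mono, center_r * mono)
        left_parts.append(l)
        right_parts.append(r)
    log.info("learning session: %d readings, %d reference insertions",
             len(frames), n_refs)
    return StereoBuffer(left=np.concatenate(left_parts),
                        right=np.concatenate(right_parts),
                        sample_rate=audio.sample_rate)
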