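"""Distance-to-volume transfer functions for 11-bit structured-light depth readings.

A Kinect-v1-class sensor reports depth per pixel as an 11-bit integer in
``[0, 2047]``.  The code 2047 is a sentinel meaning "no valid reading"
(object too close, too far, or the IR pattern was washed out); the nearest
physically readable distance, about 0.57 m, comes back as raw code 488.

The sonification mixer downstream takes an 8-bit volume parameter where
0 is loudest (nearest obstacle) and 255 is silence.  This module implements
the four transfer functions that compress the raw 11-bit scale into that
8-bit volume scale, plus a 2048-entry lookup table so whole frames can be
converted with a single vectorized indexing operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

RAW_MAX = 2047
"""Largest 11-bit code; reserved as the invalid-reading sentinel."""

RAW_MIN_VALID = 488
"""Raw code the sensor returns at its shortest readable distance (~0.57 m)."""

VOLUME_SILENCE = 255
"""8-bit volume code meaning silence (farthest / unreadable)."""

#: Default parameter sets of the four built-in transfer functions.
#: ``linear`` rescales the raw code band directly (suited to tight rooms),
#: ``gamma_adapted`` is a cubic curve adapted from the freenect demo code,
#: ``own1`` (exponential) and ``own2`` (shifted cubic) are empirical curves
#: better suited to open spaces.
BUILTIN_PARAMS: dict[str, dict[str, float]] = {
    "linear": {"divisor": 2.215, "offset": 488.0},
    "gamma_adapted": {
        "scale": 36.0 * 256.0,
        "offset": 1244.44,
        "normalizer": 2048.0,
        "exponent": 3.0,
    },
    "own1": {"base": 2.0, "raw_divisor": 80.0, "outer_divisor": 36.0, "offset": 1.0},
    "own2": {
        "scale": 36.0 * 256.0,
        "offset": 3004.1,
        "normalizer": 2048.0,
        "exponent": 3.0,
    },
}

TRANSFORM_IDS = ("linear", "gamma_adapted", "own1", "own2", "custom")


@dataclass(frozen=True)
class TransformSpec:
    """A named distance-to-volume transfer function with its constants.

    Parameters
    ----------
    id
        One of ``linear``, ``gamma_adapted``, ``own1``, ``own2`` or
        ``custom``.  Built-in ids come with their published constants;
        ``custom`` requires explicit params and a callable is not supported
        (customisation happens through the same parameter names as the
        built-in family it mimics via ``family``).
    params
        Named real constants.  For built-in ids, omitted entries default to
        the published constants; provided entries override them.
    family
        For ``id="custom"``, which built-in formula shape to evaluate.
    """

    id: str = "linear"
    params: dict[str, float] = field(default_factory=dict)
    family: str | None = None

    def __post_init__(self) -> None:
        if self.id not in TRANSFORM_IDS:
            raise ValueError(f"unknown transform id {self.id!r}")
        if self.id == "custom":
            fam = self.family
            if fam not in BUILTIN_PARAMS:
                raise ValueError("custom transform requires family in "
                                 f"{sorted(BUILTIN_PARAMS)}")
        else:
            fam = self.id
        merged = dict(BUILTIN_PARAMS[fam])
        merged.update(self.params)
        for name, value in merged.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite")
        for name in ("divisor", "normalizer", "raw_divisor", "outer_divisor"):
            if name in merged and merged[name] <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        object.__setattr__(self, "params", merged)
        object.__setattr__(self, "family", fam)

    def evaluate_real(self, raw: float) -> float:
        """Evaluate the formula in real arithmetic, without rounding or clamping."""
        p = self.params
        if self.family == "linear":
            return (raw - p["offset"]) / p["divisor"]
        if self.family in ("gamma_adapted", "own2"):
            return (raw / p["normalizer"]) ** p["exponent"] * p["scale"] - p["offset"]
        # own1: exponential in the raw code
        return p["base"] ** (raw / p["raw_divisor"]) / p["outer_divisor"] - p["offset"]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def eval_transform(spec: TransformSpec, raw: int) -> int:
    """Convert one raw 11-bit reading to an 8-bit volume code.

    The formula is evaluated in real arithmetic, rounded to the nearest
    integer (ties away from zero) and clamped into ``[0, 255]``.  The
    sentinel ``raw == 2047`` short-circuits to 255 (silence) before any
    formula is evaluated.

    Raises
    ------
    ValueError
        If ``raw`` is not an integer in ``[0, 2047]``.
    """
    raw = int(raw)
    if not 0 <= raw <= RAW_MAX:
        raise ValueError(f"raw reading {raw} outside [0, {RAW_MAX}]")
    if raw == RAW_MAX:
        return VOLUME_SILENCE
    code = _round_half_away(spec.evaluate_real(raw))
    return min(max(code, 0), VOLUME_SILENCE)


@dataclass(frozen=True)
class VolumeLookupTable:
    """Precomputed volume code for every possible raw reading.

    ``entries[i]`` equals ``eval_transform(source, i)`` for all
    ``i in [0, 2047]``; index 2047 is always 255.
    """

    entries: np.ndarray
    source: TransformSpec

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        if entries.shape != (RAW_MAX + 1,):
            raise ValueError(f"lookup table must have {RAW_MAX + 1} entries")
        if entries.min() < 0 or entries.max() > VOLUME_SILENCE:
            raise ValueError("lookup entries must lie in [0, 255]")
        if entries[RAW_MAX] != VOLUME_SILENCE:
            raise ValueError("entry 2047 must be 255 (sentinel)")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, raw):
        return self.entries[raw]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def real_entries(self) -> np.ndarray:
        """Un-rounded transfer-function values clamped to [0, 255].

        Used by averaging aggregation to avoid double rounding; the
        sentinel entry 2047 is 255.  Computed lazily and cached.
        """
        cached = getattr(self, "_real_entries", None)
        if cached is None:
            vals = np.array([self.source.evaluate_real(i) for i in range(RAW_MAX)])
            cached = np.clip(np.append(vals, float(VOLUME_SILENCE)),
                             0.0, float(VOLUME_SILENCE))
            object.__setattr__(self, "_real_entries", cached)
        return cached


def build_lookup_table(spec: TransformSpec) -> VolumeLookupTable:
    """Tabulate ``eval_transform(spec, raw)`` over all 2048 raw codes."""
    entries = np.array([eval_transform(spec, raw) for raw in range(RAW_MAX + 1)],
                       dtype=np.int64)
    return VolumeLookupTable(entries=entries, source=spec)


@dataclass(frozen=True)
class RawDepthFrame:
    """A 2-D grid of raw 11-bit depth readings.

    ``values`` is an integer array of shape ``(height, width)``; row 0 is
    the top of the image.  Every value lies in ``[0, 2047]`` and 2047 never
    denotes a measured distance.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("depth frame must be a 2-D array")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("depth frame values must be integers")
        if values.size == 0:
            raise ValueError("depth frame must be non-empty")
        if values.min() < 0 or values.max() > RAW_MAX:
            raise ValueError(f"depth values must lie in [0, {RAW_MAX}]")
        object.__setattr__(self, "values", values.astype(np.int64))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying a measured distance (raw != 2047)."""
        return self.values != RAW_MAX


def read_pgm(path: Union[str, Path]) -> RawDepthFrame:
    """Load a raw depth frame from a binary 16-bit PGM (P5, maxval 65535).

    Rejects files whose pixel values exceed the 11-bit range.
    """
    values = np.asarray(iio.imread(Path(path)))
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel PGM image")
    if values.max() > RAW_MAX:
        raise ValueError(
            f"{path}: pixel value {int(values.max())} exceeds 11-bit maximum {RAW_MAX}")
    if values.min() < 0:
        raise ValueError(f"{path}: negative pixel values")
    return RawDepthFrame(values=values.astype(np.int64))


def write_pgm(frame: RawDepthFrame, path: Union[str, Path]) -> None:
    """Write a depth frame as a binary 16-bit PGM (P5, maxval 65535)."""
    iio.imwrite(Path(path), frame.values.astype(np.uint16))
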