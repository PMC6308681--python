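"""Downsampling of a depth frame to the small-field grid of volume codes.

The 640x480 frame carries far more detail than a listener can absorb, so it
is partitioned into a coarse grid of "small fields" (default 6 rows x 5
columns, i.e. 30 blocks of 128x80 pixels), each summarised by one 8-bit
volume code.  Two aggregation methods are provided:

``averaged`` (the default)
    Each pixel is converted through the volume lookup table; invalid pixels
    (sentinel 2047) are discarded.  If the nearest valid pixel in the block
    is farther than a safety limit (default 1.2 m), the field gets the mean
    of the converted codes.  If anything in the block is at or inside the
    limit — a near obstacle — the field instead gets the code of that
    minimum reading, so close hazards are never averaged away.

``min_only``
    The field is always the code of the minimum valid raw reading.

A field with no valid pixels is silent (code 255) in both methods.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Union

import numpy as np

from .depth_transform import RAW_MAX, VOLUME_SILENCE, RawDepthFrame, VolumeLookupTable

#: Raw code corresponding to the 1.2 m near-obstacle limit under the default
#: sensor calibration (see :mod:`depthtone.synthetic_scenes`).
DEFAULT_NEAR_LIMIT_RAW = 801


@dataclass(frozen=True)
class GridConfig:
    """Geometry and aggregation settings for the small-field grid.

    ``near_limit`` is the metric near-obstacle distance in metres;
    ``near_limit_raw`` is the same limit expressed in raw sensor units
    (derived once from the sensor calibration and stored here so that the
    per-block comparison happens in raw units, which is valid because every
    transfer function is monotone).  A block whose minimum raw reading is
    <= ``near_limit_raw`` is treated as containing a near obstacle.
    """

    rows: int = 6
    cols: int = 5
    near_limit: float = 1.2
    near_limit_raw: int = DEFAULT_NEAR_LIMIT_RAW
    method: str = "averaged"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 488 < self.near_limit_raw < RAW_MAX:
            raise ValueError("near_limit_raw must lie in (488, 2047)")
        if self.method not in ("averaged", "min_only"):
            raise ValueError(f"unknown aggregation method {self.method!r}")


@dataclass(frozen=True)
class SmallFieldGrid:
    """The downsampled depth map: one volume code per small field.

    ``codes[r, c]`` is the 8-bit volume code of row ``r`` (0 = top of the
    frame), column ``c`` (0 = left).  ``valid_counts`` records how many
    pixels in each block carried a measured distance.
    """

    codes: np.ndarray
    valid_counts: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2:
            raise ValueError("grid codes must be 2-D")
        if codes.min() < 0 or codes.max() > VOLUME_SILENCE:
            raise ValueError("grid codes must lie in [0, 255]")
        counts = self.valid_counts
        if counts is None:
            counts = np.zeros_like(codes)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != codes.shape:
            raise ValueError("valid_counts shape must match codes")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "valid_counts", counts)

    @property
    def rows(self) -> int:
        return self.codes.shape[0]

    @property
    def cols(self) -> int:
        return self.codes.shape[1]


def partition(frame: RawDepthFrame, config: GridConfig) -> list[list[np.ndarray]]:
    """Split the frame into rows x cols contiguous rectangular pixel blocks.

    The blocks tile the frame exactly; the frame dimensions must be
    divisible by the grid dimensions (640x480 with the default 6x5 grid
    gives 30 blocks of 128x80 pixels).

    Returns a nested list ``blocks[r][c]`` of 2-D raw-value arrays.
    """
    if frame.height % config.rows or frame.width % config.cols:
        raise ValueError(
            f"frame {frame.width}x{frame.height} not divisible by "
            f"{config.cols} cols x {config.rows} rows")
    bh = frame.height // config.rows
    bw = frame.width // config.cols
    return [
        [frame.values[r * bh:(r + 1) * bh, c * bw:(c + 1) * bw]
         for c in range(config.cols)]
        for r in range(config.rows)
    ]


def aggregate_field(block: np.ndarray, lut: VolumeLookupTable,
                    config: GridConfig) -> tuple[int, int]:
    """Reduce one pixel block to a single volume code.

    Returns ``(code, valid_count)``.  Per-pixel codes are kept as reals
    (the un-rounded transfer-function values, clamped to [0, 255]) when
    averaging, so the field code is rounded only once.

    Zero valid pixels always yields silence (255).
    """
    block = np.asarray(block)
    valid = block != RAW_MAX
    n_valid = int(valid.sum())
    if n_valid == 0:
        return VOLUME_SILENCE, 0
    raw_valid = block[valid]
    min_raw = int(raw_valid.min())
    if config.method == "min_only":
        return int(lut[min_raw]), n_valid
    if min_raw <= config.near_limit_raw:
        # near obstacle: report the closest reading, never an average
        return int(lut[min_raw]), n_valid
    mean = float(np.mean(lut.real_entries[raw_valid]))
    # round half away from zero (mean is non-negative here)
    return min(int(np.floor(mean + 0.5)), VOLUME_SILENCE), n_valid


def map_frame(frame: RawDepthFrame, lut: VolumeLookupTable,
              config: GridConfig) -> SmallFieldGrid:
    """Convert a full depth frame into the small-field grid of volume codes."""
    blocks = partition(frame, config)
    codes = np.empty((config.rows, config.cols), dtype=np.int64)
    counts = np.empty_like(codes)
    for r in range(config.rows):
        for c in range(config.cols):
            codes[r, c], counts[r, c] = aggregate_field(blocks[r][c], lut, config)
    return SmallFieldGrid(codes=codes, valid_counts=counts)


def write_grid_csv(grid: SmallFieldGrid, path: Union[str, Path]) -> None:
    """Write the grid as CSV, rows top-to-bottom, comma-separated codes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in grid.codes:
            writer.writerow(int(v) for v in row)


def read_grid_csv(path: Union[str, Path]) -> SmallFieldGrid:
    """Read a grid written by :func:`write_grid_csv` (renderer-only workflows)."""
    with open(path, newline="") as fh:
        rows = [[int(v) for v in row] for row in csv.reader(fh) if row]
    if not rows:
        raise ValueError(f"{path}: empty grid CSV")
    return SmallFieldGrid(codes=np.array(rows, dtype=np.int64))
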