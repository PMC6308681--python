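"""Small-field grid partitioning and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from depthtone import (GridConfig, RawDepthFrame, SmallFieldGrid,
                       TransformSpec, aggregate_field, build_lookup_table,
                       map_frame, partition, read_grid_csv, write_grid_csv)


def oracle_aggregate(block, spec, near_limit_raw, method="averaged"):
    """Brute-force re-statement of the aggregation pipeline in plain Python."""
    def real_code(raw):
        v = spec.evaluate_real(raw)
        return min(max(v, 0.0), 255.0)

    def int_code(raw):
        if raw == 2047:
            return 255
        v = spec.evaluate_real(raw)
        r = int(np.floor(v + 0.5)) if v >= 0 else int(np.ceil(v - 0.5))
        return min(max(r, 0), 255)

    valid = [int(p) for row in block for p in row if p != 2047]
    if not valid:
        return 255
    min_raw = min(valid)
    if method == "min_only" or min_raw <= near_limit_raw:
        return int_code(min_raw)
    mean = sum(real_code(r) for r in valid) / len(valid)
    return min(int(np.floor(mean + 0.5)), 255)


def test_default_partition_geometry(grid_config):
    frame = RawDepthFrame(values=np.full((480, 640), 1000))
    blocks = partition(frame, grid_config)
    assert len(blocks) == 6 and all(len(row) == 5 for row in blocks)
    assert all(b.shape == (80, 128) for row in blocks for b in row)


def test_partition_is_an_exact_disjoint_tiling():
    frame = RawDepthFrame(values=np.arange(120).reshape(12, 10))
    blocks = partition(frame, GridConfig(rows=6, cols=5))
    seen = np.concatenate([b.ravel() for row in blocks for b in row])
    assert sorted(seen.tolist()) == list(range(120))  # union = frame, disjoint


def test_identity_partition():
    frame = RawDepthFrame(values=np.full((480, 640), 700))
    blocks = partition(frame, GridConfig(rows=1, cols=1))
    assert blocks[0][0].shape == (480, 640)


def test_non_divisible_dimensions_rejected(grid_config):
    frame = RawDepthFrame(values=np.full((100, 101), 700))
    with pytest.raises(ValueError, match="divisible"):
        partition(frame, grid_config)


@pytest.mark.parametrize("block, expected", [
    (np.full((4, 4), 488), 0),      # near pixel (< 1.2 m): minimum wins
    (np.full((4, 4), 1000), 231),   # far, uniform: mean of identical codes
    (np.full((4, 4), 2047), 255),   # no valid pixel: silence
    (np.repeat([[900], [1000]], 2, axis=1), 209),  # mean of real codes 208.58
])
def test_aggregate_examples(block, expected, linear_lut, grid_config):
    code, _ = aggregate_field(block, linear_lut, grid_config)
    assert code == expected


def test_near_override_fires_at_limit_inclusive(linear_lut):
    cfg = GridConfig(near_limit_raw=801)
    # min raw exactly at the limit counts as near: code of the minimum, not a mean
    block = np.array([[801, 1500], [1500, 1500]])
    code, _ = aggregate_field(block, linear_lut, cfg)
    assert code == int(linear_lut[801])
    block = np.array([[802, 1000], [1000, 1000]])
    code, _ = aggregate_field(block, linear_lut, cfg)
    assert code != int(linear_lut[802])  # averaged instead


def test_map_frame_uniform_and_single_block(linear_lut, grid_config):
    uniform = RawDepthFrame(values=np.full((480, 640), 1000))
    grid = map_frame(uniform, linear_lut, grid_config)
    assert grid.codes.shape == (6, 5)
    assert np.all(grid.codes == grid.codes[0, 0])

    values = np.full((480, 640), 1500)
    values[80:160, 128:256] = 500  # exactly block (row 1, col 1)
    grid = map_frame(RawDepthFrame(values=values), linear_lut, grid_config)
    expected = np.full((6, 5), 255)  # (1500-488)/2.215 = 457 clamps to 255
    expected[1, 1] = int(linear_lut[500])
    assert np.array_equal(grid.codes, expected)
    assert int(linear_lut[500]) == 5


def test_all_invalid_frame_is_silent(linear_lut, grid_config):
    frame = RawDepthFrame(values=np.full((480, 640), 2047))
    grid = map_frame(frame, linear_lut, grid_config)
    assert np.all(grid.codes == 255)
    assert np.all(grid.valid_counts == 0)


frames_10x12 = arrays(np.int64, (12, 10),
                      elements=st.integers(0, 2047).map(
                          lambda v: 2047 if v > 1900 else v))


@given(values=frames_10x12)
@settings(deadline=None, derandomize=True)
def test_map_frame_matches_brute_force_oracle(values):
    """Both methods agree with a plain-Python re-statement on small frames."""
    frame = RawDepthFrame(values=values)
    spec = TransformSpec("linear")
    lut = build_lookup_table(spec)
    for method in ("averaged", "min_only"):
        cfg = GridConfig(rows=6, cols=5, method=method)
        grid = map_frame(frame, lut, cfg)
        blocks = partition(frame, cfg)
        for r in range(6):
            for c in range(5):
                assert grid.codes[r, c] == oracle_aggregate(
                    blocks[r][c], spec, cfg.near_limit_raw, method)


@given(values=frames_10x12)
@settings(deadline=None, derandomize=True)
def test_min_only_never_louder_than_averaged_and_counts_conserve(values):
    frame = RawDepthFrame(values=values)
    lut = build_lookup_table(TransformSpec("linear"))
    avg = map_frame(frame, lut, GridConfig(rows=6, cols=5, method="averaged"))
    mn = map_frame(frame, lut, GridConfig(rows=6, cols=5, method="min_only"))
    # the transform is monotone, so the minimum's code <= mean of codes
    assert np.all(mn.codes <= avg.codes)
    assert avg.valid_counts.sum() == np.count_nonzero(values != 2047)


def test_grid_csv_round_trip(tmp_path, rng):
    codes = rng.integers(0, 256, size=(6, 5))
    grid = SmallFieldGrid(codes=codes)
    path = tmp_path / "grid.csv"
    write_grid_csv(grid, path)
    assert read_grid_csv(path).codes.tolist() == codes.tolist()
    assert len(path.read_text().strip().splitlines()) == 6


def test_grid_config_validation():
    with pytest.raises(ValueError):
        GridConfig(rows=0)
    with pytest.raises(ValueError):
        GridConfig(near_limit_raw=488)
    with pytest.raises(ValueError):
        GridConfig(method="median")
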