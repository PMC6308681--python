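"""Audio synthesis: amplitude mapping, panning, slot mixing, WAV output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthtone import (AudioConfig, SmallFieldGrid, StereoBuffer,
                       column_azimuth, pan_gains, read_wav, render_cycle,
                       synthesize_tone, volume_gain, write_wav)


def slot_bounds(schedule, rate):
    """Sample ranges of each event, mirroring the renderer's timing rule."""
    bounds, start = [], 0
    for event in schedule.events:
        n = int(round(event.duration_ms * rate / 1000.0))
        bounds.append((event, start, start + n))
        start += n
    return bounds


@pytest.mark.parametrize("code, expected", [
    (255, 0.0), (0, 1.0), (127, 128 / 255)])
def test_volume_gain(code, expected):
    assert volume_gain(code) == pytest.approx(expected, abs=5e-4)


def test_volume_gain_domain():
    with pytest.raises(ValueError):
        volume_gain(256)
    with pytest.raises(ValueError):
        volume_gain(-1)


def test_column_azimuths_cover_the_fov_symmetrically():
    az = [column_azimuth(c, 5, 57.0) for c in range(5)]
    assert az == pytest.approx([-22.8, -11.4, 0.0, 11.4, 22.8])


def test_pan_gain_examples():
    assert pan_gains(0.0) == pytest.approx((2 ** -0.5, 2 ** -0.5))
    assert pan_gains(-90.0) == pytest.approx((1.0, 0.0), abs=1e-12)
    assert pan_gains(90.0) == pytest.approx((0.0, 1.0), abs=1e-12)
    # closed form at the edge column of the default grid
    left, right = pan_gains(22.8)
    assert (left, right) == pytest.approx((0.5534, 0.8329), abs=5e-4)


@given(azimuth=st.floats(-90, 90, allow_nan=False))
@settings(deadline=None, derandomize=True)
def test_pan_law_conserves_power(azimuth):
    left, right = pan_gains(azimuth)
    assert left * left + right * right == pytest.approx(1.0, abs=1e-9)
    # leftward azimuths favour the left channel
    if azimuth < 0:
        assert left > right


def test_synthesize_tone_length_and_amplitude(bank):
    audio = AudioConfig(sample_rate=44100)
    block = synthesize_tone(100.0, 300.0, 0.0, bank, audio)
    assert len(block) == 13230
    assert np.abs(block).max() == pytest.approx(0.2, rel=1e-3)
    boosted = synthesize_tone(67.32, 300.0, +8.0, bank, audio)
    assert np.abs(boosted).max() == pytest.approx(0.2 * 10 ** 0.4, rel=1e-3)
    silent = synthesize_tone(440.0, 100.0, -np.inf, bank, audio)
    assert np.all(silent == 0.0)


def test_overdriven_tone_is_limited(bank, caplog):
    audio = AudioConfig(sample_rate=22050)
    with caplog.at_level("WARNING"):
        block = synthesize_tone(440.0, 100.0, +40.0, bank, audio)
    assert np.abs(block).max() <= 1.0
    assert any("limiting" in r.message for r in caplog.records)


def test_cycle_length_and_event_timing(bank, schedule):
    grid = SmallFieldGrid(codes=np.full((6, 5), 128))
    buf = render_cycle(grid, bank, schedule, AudioConfig(sample_rate=44100))
    assert len(buf) == 127890  # 2.9 s at 44100 Hz
    assert buf.duration_s == pytest.approx(2.9)
    total = sum(int(round(e.duration_ms * 44100 / 1000)) for e in schedule.events)
    assert len(buf) == total


def test_all_silent_grid_only_reference_audible(bank, schedule, audio22):
    grid = SmallFieldGrid(codes=np.full((6, 5), 255))
    buf = render_cycle(grid, bank, schedule, audio22)
    for event, lo, hi in slot_bounds(schedule, audio22.sample_rate):
        seg = np.abs(buf.left[lo:hi]).max()
        if event.kind == "reference":
            assert seg > 0.01
        else:
            assert seg == 0.0


def test_loudness_monotone_in_volume_code(bank, schedule, audio22):
    """Bringing a cell closer (smaller code) never makes its slot quieter."""
    rms_by_code = []
    for code in (240, 160, 80, 0):
        codes = np.full((6, 5), 255)
        codes[0, 2] = code
        buf = render_cycle(SmallFieldGrid(codes=codes), bank, schedule, audio22)
        for event, lo, hi in slot_bounds(schedule, audio22.sample_rate):
            if event.kind == "scan_column" and event.scan == "upper" \
                    and event.column == 2:
                rms_by_code.append(np.sqrt(np.mean(buf.left[lo:hi] ** 2)))
    assert all(a < b for a, b in zip(rms_by_code, rms_by_code[1:]))


def test_single_cell_spectral_peak_and_lateralization(bank, schedule, audio22):
    """A lone near cell at (row 0, col 4) sounds as f1 panned to the right."""
    codes = np.full((6, 5), 255)
    codes[0, 4] = 0
    buf = render_cycle(SmallFieldGrid(codes=codes), bank, schedule, audio22)
    for event, lo, hi in slot_bounds(schedule, audio22.sample_rate):
        if event.kind == "scan_column" and event.scan == "upper" \
                and event.column == 4:
            left, right = buf.left[lo:hi], buf.right[lo:hi]
            spectrum = np.abs(np.fft.rfft(left + right))
            freqs = np.fft.rfftfreq(hi - lo, 1 / audio22.sample_rate)
            peak = freqs[np.argmax(spectrum)]
            assert peak == pytest.approx(2154.33, abs=10)
            assert np.sqrt(np.mean(right ** 2)) > np.sqrt(np.mean(left ** 2))


def test_mismatched_grid_rejected(bank, schedule, audio22):
    small = SmallFieldGrid(codes=np.full((6, 3), 200))  # fewer columns than scheduled
    with pytest.raises(ValueError, match="column"):
        render_cycle(small, bank, schedule, audio22)
    short = SmallFieldGrid(codes=np.full((4, 5), 200))  # fewer rows than the bank
    with pytest.raises(ValueError, match="row"):
        render_cycle(short, bank, schedule, audio22)


def test_wav_round_trip(tmp_path, rng):
    samples = rng.uniform(-1, 1, size=1000)
    buf = StereoBuffer(left=samples, right=-samples, sample_rate=44100)
    path = tmp_path / "out.wav"
    write_wav(buf, path)
    again = read_wav(path)
    assert again.sample_rate == 44100
    assert len(again) == 1000
    assert np.abs(again.left - buf.left).max() <= 1 / 32768 + 1e-9
    assert np.abs(again.right - buf.right).max() <= 1 / 32768 + 1e-9
    header = path.read_bytes()[:44]
    assert header[:4] == b"RIFF" and header[8:12] == b"WAVE"
    assert int.from_bytes(header[24:28], "little") == 44100
    assert int.from_bytes(header[22:24], "little") == 2  # stereo


def test_buffer_invariants():
    with pytest.raises(ValueError):
        StereoBuffer(left=np.zeros(5), right=np.zeros(4), sample_rate=44100)
    with pytest.raises(ValueError):
        StereoBuffer(left=np.array([1.5]), right=np.array([0.0]), sample_rate=44100)
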