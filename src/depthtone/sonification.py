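"""Tone bank and phase schedule for the acoustic depth-map transmission.

The grid is transmitted as a fixed cycle of tone events.  Six sine tones —
the notes of a C7 chord spread over several octaves, each raised 50 cents
(a quarter tone) so the result is deliberately un-musical — encode the six
grid rows: the higher the tone, the higher the row.  Tones are played three
at a time: a left-to-right "upper scan" carries the top three rows with the
three highest tones, then a right-to-left "lower scan" carries the bottom
three rows with the three lowest tones.  Each column slot lasts 200 ms.

Every cycle opens with a 300 ms, 100 Hz reference tone at constant volume,
giving the listener a loudness anchor independent of ambient noise, and
200 ms pauses separate the phases.  The default cycle therefore lasts
300 + 200 + 5x200 + 200 + 5x200 + 200 = 2900 ms, a full-map transmission
rate of about 0.345 Hz (with a per-column partial refresh of 5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Equal-temperament semitone offsets of the C7 chord tones from C.
_CHORD_SEMITONES = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "Ais": 10, "B": 11}

UPPER, LOWER = "upper", "lower"


def make_tone_frequency(chord_tone: str, octave: int, cents_shift: float = 0.0) -> float:
    """Equal-temperament frequency (A4 = 440 Hz) of a named tone, in Hz.

    The named chord tone in the given octave is shifted by ``cents_shift``
    cents (1200 cents per octave); the result is rounded to 2 decimals.

    >>> make_tone_frequency("A", 4)
    440.0
    >>> make_tone_frequency("C", 7, +50)
    2154.33
    """
    if chord_tone not in _CHORD_SEMITONES:
        raise ValueError(f"unknown tone name {chord_tone!r}")
    if not 0 <= octave <= 9:
        raise ValueError("octave must be in [0, 9]")
    # A4 = 440 Hz; C4 is 9 semitones below A4
    semitones_from_a4 = _CHORD_SEMITONES[chord_tone] - 9 + 12 * (octave - 4)
    freq = 440.0 * 2.0 ** (semitones_from_a4 / 12.0 + cents_shift / 1200.0)
    return round(freq, 2)


@dataclass(frozen=True)
class Tone:
    """One fixed-frequency tone of the bank.

    ``row`` is the grid row the tone encodes (0 = top); within one scan the
    three frequencies are distinct, and a higher row position always means
    a higher frequency.
    """

    label: str
    frequency: float
    gain_db: float
    scan: str
    row: int

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("tone frequency must be positive")
        if self.scan not in (UPPER, LOWER):
            raise ValueError(f"scan must be 'upper' or 'lower', got {self.scan!r}")


@dataclass(frozen=True)
class ToneBank:
    """The six row tones plus the reference tone and synthesis defaults.

    The per-tone gains equalise perceived loudness across the very wide
    frequency span (67 Hz - 2.15 kHz); they are dB offsets applied to the
    common base amplitude of 0.2.
    """

    tones: tuple[Tone, ...]
    reference_frequency: float = 100.0
    reference_gain_db: float = -6.0
    base_amplitude: float = 0.2
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if self.reference_frequency <= 0 or self.base_amplitude <= 0:
            raise ValueError("reference frequency and base amplitude must be positive")
        for scan in (UPPER, LOWER):
            freqs = [t.frequency for t in self.tones if t.scan == scan]
            if len(set(freqs)) != len(freqs):
                raise ValueError(f"duplicate frequencies within the {scan} scan")
        by_row = sorted(self.tones, key=lambda t: t.row)
        for hi, lo in zip(by_row, by_row[1:]):
            if hi.frequency <= lo.frequency:
                raise ValueError("tone frequency must strictly decrease top to bottom")

    def tone_for_row(self, row: int) -> Tone:
        for tone in self.tones:
            if tone.row == row:
                return tone
        raise KeyError(f"no tone assigned to row {row}")

    def scan_tones(self, scan: str) -> tuple[Tone, ...]:
        return tuple(t for t in self.tones if t.scan == scan)


def default_tone_bank() -> ToneBank:
    """The device's published six-tone bank.

    Frequencies are the published table values verbatim (C7-chord tones
    raised 50 cents); the three highest go to the upper scan (rows 0-2),
    the three lowest to the lower scan (rows 3-5).
    """
    tones = (
        Tone("C7+50", 2154.33, -9.0, UPPER, 0),
        Tone("G5+50", 806.97, -2.0, UPPER, 1),
        Tone("Ais4+50", 479.86, -4.0, UPPER, 2),
        Tone("G4+50", 403.49, -4.0, LOWER, 3),
        Tone("E3+50", 169.63, +5.0, LOWER, 4),
        Tone("C2+50", 67.32, +8.0, LOWER, 5),
    )
    return ToneBank(tones=tones)


@dataclass(frozen=True)
class ScheduleEvent:
    """One timed phase of the transmission cycle."""

    kind: str  # "reference", "pause", or "scan_column"
    duration_ms: float
    scan: str | None = None
    column: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("reference", "pause", "scan_column"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == "scan_column" and (self.scan is None or self.column is None):
            raise ValueError("scan_column events need a scan id and column index")


@dataclass(frozen=True)
class Timings:
    """Phase durations in milliseconds; shorten them as the user trains."""

    reference_ms: float = 300.0
    pause_ms: float = 200.0
    column_ms: float = 200.0

    def __post_init__(self) -> None:
        for name in ("reference_ms", "pause_ms", "column_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SonificationSchedule:
    """The ordered phase events of one transmission cycle."""

    events: tuple[ScheduleEvent, ...]

    @property
    def total_duration_ms(self) -> float:
        return sum(e.duration_ms for e in self.events)


def build_schedule(timings: Timings = Timings(), cols: int = 5) -> SonificationSchedule:
    """Assemble the cycle: reference, pause, upper scan left-to-right,
    pause, lower scan right-to-left, pause (14 events at the default 5
    columns)."""
    events = [ScheduleEvent("reference", timings.reference_ms),
              ScheduleEvent("pause", timings.pause_ms)]
    events += [ScheduleEvent("scan_column", timings.column_ms, scan=UPPER, column=c)
               for c in range(cols)]
    events.append(ScheduleEvent("pause", timings.pause_ms))
    events += [ScheduleEvent("scan_column", timings.column_ms, scan=LOWER, column=c)
               for c in reversed(range(cols))]
    events.append(ScheduleEvent("pause", timings.pause_ms))
    return SonificationSchedule(events=tuple(events))


def transmission_frequency(schedule: SonificationSchedule) -> float:
    """Full-map transmission rate: the reciprocal of the cycle duration,
    in Hz, rounded to 3 decimals (0.345 Hz at the defaults)."""
    total_s = schedule.total_duration_ms / 1000.0
    if total_s <= 0:
        raise ValueError("schedule has no duration")
    return round(1.0 / total_s, 3)


def column_refresh_frequency(schedule: SonificationSchedule) -> float:
    """Partial (per-column) refresh rate in Hz: the reciprocal of one
    column slot, excluding the gaps between scans (5 Hz at the defaults)."""
    columns = [e for e in schedule.events if e.kind == "scan_column"]
    if not columns:
        raise ValueError("schedule has no column events")
    return round(1000.0 / columns[0].duration_ms, 3)


def cell_assignments(schedule: SonificationSchedule, bank: ToneBank,
                     rows: int = 6) -> dict[tuple[int, int], tuple[int, Tone]]:
    """Map every grid cell (row, col) to its (event index, tone) pair.

    Each cell is covered exactly once per cycle: the upper scan's three
    tones carry rows 0-2 during its five column slots, the lower scan's
    tones carry rows 3-5.
    """
    mapping: dict[tuple[int, int], tuple[int, Tone]] = {}
    for idx, event in enumerate(schedule.events):
        if event.kind != "scan_column":
            continue
        for tone in bank.scan_tones(event.scan):
            key = (tone.row, event.column)
            if key in mapping:
                raise ValueError(f"cell {key} scheduled twice")
            mapping[key] = (idx, tone)
    return mapping
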