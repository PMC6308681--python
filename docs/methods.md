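# Methods

This note records the model implemented by `depthtone`, the defaults and
why they hold, and the choices made where the device description left the
design open.

## Sensor semantics

Raw depth is an 11-bit integer per pixel.  Code 2047 is a hard sentinel for
"no reading" and is checked before any formula; it never denotes a distance.
The nearest readable distance (~0.57 m) maps to code 488.  Codes in
[0, 487] cannot be produced by the physical sensor but are still accepted,
evaluated and clamped rather than rejected, because synthetic noise models
may generate them.  Frames are exchanged as binary 16-bit PGM (P5, maxval
65535) and the loader rejects pixels above 2047.

## Transfer functions

Four built-ins map raw code `d` to volume code `v` (0 loudest, 255 silence):

| id            | formula                                  | character |
|---------------|------------------------------------------|-----------|
| linear        | `(d − 488) / 2.215`                      | direct rescale; tight rooms |
| gamma_adapted | `(d/2048)³·36·256 − 1244.44`             | cubic, freenect-demo lineage |
| own1          | `2^(d/80)/36 − 1`                        | exponential; open air |
| own2          | `(d/2048)³·36·256 − 3004.1`              | cubic; skips the nearest band, never fully silent at range |

All constants are exposed in `TransformSpec.params` and overridable.  The
result is computed in real arithmetic, rounded to the nearest integer with
ties away from zero (no rounding rule is published; half-away is the common
C idiom for non-negative audio levels), then clamped to [0, 255].  A
2048-entry lookup table caches the integer codes; a parallel real-valued
table (clamped but un-rounded) serves the averaging step below so that no
value is rounded twice.

The `own1` formula as published is typographically ambiguous; it is read as
`2^(d/80)/36 − 1`, which is ≈0 at the minimum readable code 488 and reaches
255 near code 1054 — the same saturation point as the linear map and, under
the calibration below, ≈9 m, the sensor's plotted maximum.  The
`gamma_adapted` and `own2` constants are implemented exactly as published
even though their useful output bands are narrow or offset; they remain
configurable, and the monotonicity tests cover all four.

## Grid aggregation

The 640×480 frame is tiled exactly by rows×cols blocks (default 6×5, blocks
of 128×80; non-divisible geometry is a configuration error).  Aggregation
per block, `averaged` method:

1. convert pixels through the (real-valued) table;
2. discard invalid pixels (exactly the sentinel 2047 — no other ceiling),
   accumulate sum and count, and track the minimum raw reading;
3. if the minimum is farther than the near limit (default 1.2 m) and at
   least one pixel is valid, the field code is the rounded mean;
4. otherwise the field takes the code of the minimum reading — a near
   obstacle must dominate its field, not be diluted by background.

The `min_only` alternative always takes the minimum's code.  Decisions the
published algorithm leaves open, resolved here: the mean is taken over
transformed codes (the conversion step precedes the summation step), kept
real until a single final rounding; the near-limit comparison runs in raw
units (valid since every transfer function is monotone), with the limit
pre-converted once to raw units (1.2 m → 801) and stored in the config; a
tie at the limit counts as near; an all-invalid field is silent (255).
Because the transform is monotone, `min_only` codes never exceed `averaged`
codes — a tested invariant.

## Tone bank and schedule

The six tones are C7-chord tones (C, E, G, A♯) in various octaves raised
50 cents, taken verbatim from the device's published table: 2154.33 Hz
(−9 dB), 806.97 (−2), 479.86 (−4) for rows 0–2 (upper scan), 403.49 (−4),
169.63 (+5), 67.32 (+8) for rows 3–5 (lower scan).  Verbatim, because a few
published cells disagree with exact octave doubling by a few hundredths of
a Hz; `make_tone_frequency` regenerates any equal-temperament value
(A4 = 440 Hz) for testing and for custom banks.  The scan split is not
legible in the published table's colour coding; the three highest
frequencies are assigned to the upper scan, consistent with "higher rows ↔
higher tones", and the assignment is config-overridable.  Per-tone dB gains
equalise perceived loudness over the five-octave span; base amplitude is
0.2 at 44100 Hz (22050 Hz supported).

The default cycle is reference (300 ms, 100 Hz) · pause (200) · five upper
column slots left→right (5×200) · pause · five lower slots right→left ·
pause = 2900 ms; all durations are configurable to support the training
progression of gradually shortened phases.  The reference tone's loudness
is published only as "constant"; the default here is the maximum volume
code scaled by a −6 dB reference gain, configurable.

## Rendering

Choices the device delegated to its mixer library, made explicit here:

- **Amplitude map**: linear, `(255 − code)/255`.
- **Panning**: constant-power, `L = cos θ`, `R = sin θ` with θ mapping
  [−90°, +90°] onto [0, π/2]; each column is panned to the centre of its
  angular sector of the 57° horizontal field of view (±22.8° for the edge
  columns).  `L² + R² = 1` is a tested invariant.
- **Synthesis**: sines start at phase 0 each slot; a 5 ms raised-cosine
  fade-in/out per slot suppresses boundary clicks.  Event length is
  `round(duration·rate/1000)` samples, so a 50 ms segment at 22050 Hz is
  1102 samples — durations are exact to ±one sample.
- **Clipping**: a mixed slot is rescaled only if its peak exceeds full
  scale (logged); relative levels within the slot are preserved.
- Output is 16-bit PCM stereo WAV; rendering is offline only.

The offline renderer takes one frame per cycle (a live device would refresh
the grid before each column slot; with a static frame the two are
identical).

## Learning mode

Tilt bins are half-open with the upper edge inclusive: row r covers
`(21.5° − (r+1)·43°/6, 21.5° − r·43°/6]`, ≈7.17° per row, row 0 on top;
beyond ±21.5° no sound is played, except that −21.5° itself (the lowest
boundary) still sounds row 5.  Tilt readings are quantized to 0.5°.  The
"middle area" watched for obstacles is one small field (128×80) centred on
the frame; its minimum valid reading goes through the *same* lookup table
as normal mode.  The row tone comes from the normal-mode bank (row 0 = top
= highest).  At the default 20 Hz refresh, every 80th reading is *replaced*
(not overlaid) by the reference pattern — 200 ms pause, 300 ms reference,
200 ms pause — since the device description does not say whether distance
tones continue underneath; replacement keeps the anchor unambiguous.

## Synthetic scenes

The generator emulates the sensor, not the world: a pinhole camera (57°×43°,
640×480) ray-casts axis-aligned boxes, fronto-parallel walls and oblique
planes, recording the **z-coordinate** of the nearest hit — the
perpendicular-plane depth convention, so a fronto-parallel wall reads one
constant depth across the frame.  Metric depth converts to raw codes with
the classical tangent disparity model `z = a·tan(d/b + c)`,
(a, b, c) = (0.1236, 2842.5, 1.1863): the sensor's true response curve is
not published numerically, and any monotone model anchored at the published
point (code 488 ↔ 0.57 m) is admissible; this one reproduces that anchor
within 5 mm (it gives 0.572 m) and is invertible in closed form.  The
near-limit code 801 and the ≈9 m ceiling at code ≈1054 follow from it.
Depths outside [0.57, 9] m, missed rays, and an i.i.d. per-pixel dropout
fraction (seeded RNG, deterministic per seed) all produce the sentinel.

What the generator does **not** model: IR-pattern physics, sunlight
interference, correlated dropout along object edges, depth quantization
noise beyond the tangent model, motion, or RGB.  Passing tests therefore
demonstrate the correctness of the *processing* pipeline under the sensor's
published geometry and value semantics — not performance on real sensor
noise, and certainly not the human navigation performance the physical
device was built for, which software cannot reproduce.

## Problem sizes in the tests

The exhaustive transform checks cover all 2048 raw codes for all four
functions.  Aggregation is verified against a plain-Python oracle on 1000
random 10×12 frames (hypothesis, derandomised).  The end-to-end
localization property renders 100 random single-obstacle scenes at full
sensor resolution and 22050 Hz — the device's own output rate — and
requires the loudest column slot and dominant spectral tone to identify
the obstacle's grid cell in at least 99 of 100; obstacles are placed
inside cell interiors (70 % angular fill) because cell-boundary objects
legitimately excite two cells.
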