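"""Real-time acquisition of fluoroscopic conditions.

Two channels, mirroring how a closed fluoroscopy console is read out
without a data interface:

* a template-matching digit recognizer that reads the numeric fields a
  console screen displays (kV, mA, field of view, SID, gantry angles,
  frame rate, irradiation time, beam-on lamp).  A synthetic seven-segment
  renderer generates test frames; the recognizer itself only sees pixels
  and a layout, so real camera crops could be substituted.
* an ultrasonic time-of-flight chain for the patient-table position in
  three axes, with the speed of sound corrected for air temperature
  (v = 331.3 + 0.606·T m/s).

Numeric display conventions: fixed digit slots per field, leading blanks
for short values, an implicit decimal point recorded in the layout
(``decimals`` digits belong to the fractional part), and a reserved sign
slot for signed fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .conditions import FluoroConditions

__all__ = [
    "FieldROI",
    "ScreenLayout",
    "UltrasonicReading",
    "RenderError",
    "UnreadableFrameError",
    "render_screen_frame",
    "digit_templates",
    "recognize_frame",
    "stream_conditions",
    "sound_speed",
    "tof_to_distance",
    "distance_to_tof",
    "table_position",
    "sweep_validation",
]

# seven-segment geometry (cell pixels)
CELL_W, CELL_H = 12, 20
SLOT_GAP = 3

# segment -> (x0, y0, x1, y1) in cell coordinates; thickness 2
_SEGMENTS = {
    "A": (2, 0, 10, 2), "B": (9, 1, 11, 10), "C": (9, 10, 11, 19),
    "D": (2, 18, 10, 20), "E": (1, 10, 3, 19), "F": (1, 1, 3, 10),
    "G": (2, 9, 10, 11),
}
_DIGIT_SEGMENTS = {
    "0": "ABCDEF", "1": "BC", "2": "ABGED", "3": "ABGCD", "4": "FGBC",
    "5": "AFGCD", "6": "AFGEDC", "7": "ABC", "8": "ABCDEFG", "9": "ABCFGD",
    "-": "G", " ": "",
}


class RenderError(ValueError):
    """Value cannot be displayed in the field's digit slots."""


class UnreadableFrameError(RuntimeError):
    """A field could not be recognized; carries the failing field name."""

    def __init__(self, field_name: str, message: str = ""):
        self.field_name = field_name
        super().__init__(message or f"field '{field_name}' unreadable")


def _draw_glyph(char: str) -> np.ndarray:
    cell = np.zeros((CELL_H, CELL_W))
    for seg in _DIGIT_SEGMENTS[char]:
        x0, y0, x1, y1 = _SEGMENTS[seg]
        cell[y0:y1, x0:x1] = 1.0
    return cell


def digit_templates() -> dict[str, np.ndarray]:
    """Template set {0-9, minus, blank} matching the renderer's glyphs."""
    return {c: _draw_glyph(c) for c in _DIGIT_SEGMENTS}


@dataclass(frozen=True)
class FieldROI:
    """One numeric field on the console screen."""

    x: int
    y: int
    slots: int              # digit slots, including the sign slot if signed
    decimals: int = 0
    signed: bool = False

    @property
    def width(self) -> int:
        return self.slots * CELL_W + (self.slots - 1) * SLOT_GAP

    @property
    def height(self) -> int:
        return CELL_H

    def slot_box(self, i: int) -> tuple[int, int, int, int]:
        x = self.x + i * (CELL_W + SLOT_GAP)
        return x, self.y, x + CELL_W, self.y + CELL_H

    def format_value(self, value: float) -> str:
        """Fixed-slot display string; raises :class:`RenderError` on overflow."""
        scaled = value * 10 ** self.decimals
        ival = int(round(scaled))
        if abs(scaled - ival) > 1e-6:
            ival = int(round(scaled))  # displays round to their precision
        neg = ival < 0
        if neg and not self.signed:
            raise RenderError(f"negative value {value} in unsigned field")
        digits = str(abs(ival)).rjust(max(self.decimals + 1, 1), "0")
        avail = self.slots - (1 if self.signed else 0)
        if len(digits) > avail:
            raise RenderError(f"value {value} needs {len(digits)} digit slots, "
                              f"field has {avail}")
        s = digits.rjust(avail)
        if self.signed:
            sign = "-" if neg else " "
            # sign sits immediately left of the first digit
            pad = len(s) - len(s.lstrip())
            s = (" " * pad + sign + s.lstrip()) if pad else sign + s
            s = s[-self.slots:] if len(s) > self.slots else s.rjust(self.slots)
        return s

    def parse(self, chars: str, name: str) -> float:
        body = chars
        neg = False
        stripped = body.lstrip()
        if not stripped:
            raise UnreadableFrameError(name, f"field '{name}' is blank")
        if stripped.startswith("-"):
            neg = True
            stripped = stripped[1:]
        if not stripped or not stripped.isdigit():
            raise UnreadableFrameError(
                name, f"field '{name}' reads {chars!r}, not a number")
        val = int(stripped) / 10 ** self.decimals
        return -val if neg else val


@dataclass(frozen=True)
class ScreenLayout:
    """Pixel layout of the rendered console screen.

    ``fields`` maps condition names to ROIs; ``indicator`` is the beam-on
    lamp box (x, y, w, h); ``fixed`` carries conditions that the screen does
    not display (e.g. added filtration) and are merged verbatim.
    """

    frame_shape: tuple[int, int] = (180, 360)   # (rows, cols)
    fields: dict = field(default_factory=lambda: {
        "kvp": FieldROI(20, 15, 3),
        "ma": FieldROI(90, 15, 3, decimals=1),
        "fov_cm": FieldROI(160, 15, 2),
        "sid_cm": FieldROI(220, 15, 3),
        "lateral_deg": FieldROI(20, 60, 3, signed=True),
        "caudcran_deg": FieldROI(90, 60, 3, signed=True),
        "fps": FieldROI(160, 60, 2),
        "irradiation_time_s": FieldROI(220, 60, 5, decimals=1),
    })
    indicator: tuple[int, int, int, int] = (20, 110, 30, 14)
    fixed: dict = field(default_factory=lambda: {"filter_cu_mm": 0.3})

    def __post_init__(self) -> None:
        boxes = []
        h, w = self.frame_shape
        for name, roi in self.fields.items():
            box = (roi.x, roi.y, roi.x + roi.width, roi.y + roi.height)
            if box[0] < 0 or box[1] < 0 or box[2] > w or box[3] > h:
                raise ValueError(f"ROI '{name}' outside frame bounds")
            boxes.append(box)
        ix, iy, iw, ih = self.indicator
        boxes.append((ix, iy, ix + iw, iy + ih))
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError("overlapping ROIs in layout")


def render_screen_frame(conditions: FluoroConditions,
                        layout: ScreenLayout = ScreenLayout(),
                        noise_level: float = 0.0, seed: int = 0) -> np.ndarray:
    """Synthetic grayscale console frame showing ``conditions``.

    Seven-segment glyphs in each field ROI, a beam-on indicator lamp, then
    additive Gaussian noise (σ = ``noise_level``) and a brightness jitter
    uniform in ±``noise_level``/2; deterministic for a given seed.
    """
    img = np.zeros(layout.frame_shape)
    for name, roi in layout.fields.items():
        text = roi.format_value(getattr(conditions, name))
        for i, ch in enumerate(text):
            x0, y0, x1, y1 = roi.slot_box(i)
            img[y0:y1, x0:x1] = _draw_glyph(ch)
    ix, iy, iw, ih = layout.indicator
    img[iy:iy + ih, ix:ix + iw] = 0.9 if conditions.beam_on else 0.05
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level, img.shape)
        img = img + rng.uniform(-noise_level / 2, noise_level / 2)
        img = np.clip(img, 0.0, 1.0)
    return img


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom < 1e-12:
        return 0.0
    return float((ac * bc).sum() / denom)


NCC_THRESHOLD = 0.6
NCC_MARGIN = 0.05


def recognize_frame(image: np.ndarray, layout: ScreenLayout = ScreenLayout(),
                    template_set: dict[str, np.ndarray] | None = None,
                    ) -> FluoroConditions:
    """Recover :class:`FluoroConditions` from a console frame.

    Each digit slot is scored against every template by normalized
    cross-correlation (the zero-variance blank template instead scores
    ``1 − 2·RMS`` of the crop); the winner must score ≥ 0.6 with ≥ 0.05
    margin over the runner-up, otherwise :class:`UnreadableFrameError`
    names the failing field and the caller keeps its previous record.
    """
    if image.shape != layout.frame_shape:
        raise ValueError(f"frame shape {image.shape} != layout {layout.frame_shape}")
    templates = template_set if template_set is not None else digit_templates()
    values: dict[str, float] = {}
    for name, roi in layout.fields.items():
        chars = []
        for i in range(roi.slots):
            x0, y0, x1, y1 = roi.slot_box(i)
            crop = image[y0:y1, x0:x1]
            scores = {}
            for ch, tmpl in templates.items():
                if ch == " ":
                    scores[ch] = 1.0 - 2.0 * float(np.sqrt((crop ** 2).mean()))
                else:
                    scores[ch] = _ncc(crop, tmpl)
            ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
            best, second = ranked[0], ranked[1]
            if best[1] < NCC_THRESHOLD or best[1] - second[1] < NCC_MARGIN:
                raise UnreadableFrameError(
                    name, f"slot {i} of '{name}': best {best[0]!r} score "
                          f"{best[1]:.3f} (runner-up {second[1]:.3f})")
            chars.append(best[0])
        values[name] = roi.parse("".join(chars), name)
    ix, iy, iw, ih = layout.indicator
    lamp = image[iy:iy + ih, ix:ix + iw].mean()
    values["beam_on"] = bool(lamp > 0.5)
    values.update(layout.fixed)
    return FluoroConditions(**values)


def stream_conditions(frame_source: Iterable[tuple[float, np.ndarray]],
                      layout: ScreenLayout = ScreenLayout(),
                      period_s: float = 0.2,
                      ultrasonic: list | None = None,
                      ) -> Iterator[dict]:
    """Condition records (JSONL-ready dicts) from a timestamped frame source.

    One record per frame (the source is expected to tick every
    ``period_s``); unreadable frames re-emit the last good record flagged
    ``stale`` (or a ``{"gap": True}`` marker if none exists yet).  Table
    offsets are merged from ``ultrasonic`` — ``(timestamp_s,
    offset_mm_3vector)`` pairs — by nearest timestamp.
    """
    templates = digit_templates()
    us_t = np.array([t for t, _ in ultrasonic]) if ultrasonic else None
    last: FluoroConditions | None = None
    for t, frame in frame_source:
        try:
            cond = recognize_frame(frame, layout, templates)
            stale = False
            last = cond
        except UnreadableFrameError as exc:
            if last is None:
                yield {"timestamp_s": float(t), "gap": True,
                       "reason": exc.field_name}
                continue
            cond = last
            stale = True
        offset = (0.0, 0.0, 0.0)
        if us_t is not None and us_t.size:
            k = int(np.argmin(np.abs(us_t - t)))
            offset = tuple(float(v) for v in ultrasonic[k][1])
        rec = replace(cond, timestamp_s=float(t), table_offset_mm=offset).to_dict()
        rec["stale"] = stale
        yield rec


# ---------------------------------------------------------------------------
# ultrasonic table positioning


@dataclass(frozen=True)
class UltrasonicReading:
    """Round-trip echo times from the three axis sensors plus temperature."""

    tof_s: tuple[float, float, float]
    temperature_c: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if any(t is not None and t <= 0 for t in self.tof_s):
            raise ValueError("time of flight must be positive")
        if not -10.0 <= self.temperature_c <= 50.0:
            raise ValueError("temperature outside the sensor range −10..50 °C")


def sound_speed(temperature_c: float) -> float:
    """Speed of sound in air, m/s: v = 331.3 + 0.606·T(°C)."""
    if not -10.0 <= temperature_c <= 50.0:
        raise ValueError("temperature outside the sensor range −10..50 °C")
    return 331.3 + 0.606 * temperature_c


def tof_to_distance(reading: UltrasonicReading) -> np.ndarray:
    """Per-axis sensor-to-table distances in cm (round-trip time halved)."""
    v = sound_speed(reading.temperature_c)
    out = np.empty(3)
    for k, tof in enumerate(reading.tof_s):
        if tof is None:
            out[k] = np.nan
        else:
            out[k] = v * tof / 2.0 * 100.0
    return out


def distance_to_tof(distance_cm, temperature_c: float) -> np.ndarray:
    """Inverse of :func:`tof_to_distance` at the same temperature."""
    v = sound_speed(temperature_c)
    return np.asarray(distance_cm, dtype=float) / 100.0 * 2.0 / v


class IncompletePositionError(RuntimeError):
    """A table-position fix needs all three axes."""


def table_position(reading: UltrasonicReading, calibration_reference_cm,
                   axis_signs=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Table offset (mm, 3-vector) from the calibrated reference pose.

    Per axis: (measured distance − reference distance) × sensor facing sign.
    Raises :class:`IncompletePositionError` when any axis reading is missing.
    """
    d = tof_to_distance(reading)
    if np.any(np.isnan(d)):
        raise IncompletePositionError("missing axis in ultrasonic reading")
    ref = np.asarray(calibration_reference_cm, dtype=float)
    return (d - ref) * np.asarray(axis_signs, dtype=float) * 10.0


def sweep_validation(reference_cm=(30.0, 30.0, 30.0), temperature_c: float = 23.0,
                     span_cm: float = 10.0, step_cm: float = 2.0,
                     tof_noise_s: float = 0.0, seed: int = 0) -> dict:
    """Per-axis accuracy sweep of the ToF chain over ±``span_cm``.

    Simulates the validation protocol — true offsets at ``step_cm``
    intervals in ±``span_cm`` per axis — synthesizing echo times (optionally
    with Gaussian noise of σ ``tof_noise_s``) and reporting the recovered
    offset and its error at every point.
    """
    rng = np.random.default_rng(seed)
    ref = np.asarray(reference_cm, dtype=float)
    offsets = np.arange(-span_cm, span_cm + step_cm / 2, step_cm)
    result = {"offsets_cm": offsets, "per_axis_error_mm": np.empty((3, offsets.size))}
    for axis in range(3):
        for k, off in enumerate(offsets):
            true = ref.copy()
            true[axis] += off
            tof = distance_to_tof(true, temperature_c)
            if tof_noise_s > 0:
                tof = tof + rng.normal(0.0, tof_noise_s, 3)
            reading = UltrasonicReading(tof_s=tuple(tof),
                                        temperature_c=temperature_c)
            rec = table_position(reading, ref)
            result["per_axis_error_mm"][axis, k] = rec[axis] - off * 10.0
    return result
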