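"""File formats and domain types for the plate-behavior pipeline.

The acquisition system emits five kinds of files: an *events* file of
stimulus command strings, an *ROI* file mapping wells to pixel rectangles,
per-well *motion* (delta-pixel) and *centroid* traces, and a *sections*
file segmenting the run into named analysis windows.  This module defines
canonical plain-text (CSV + ``#``-comment header) dialects for all of them
and the in-memory types the rest of the package operates on.

Conventions used throughout the package:

* pixels are 0-based with origin at the top-left; ROI rectangles are
  half-open in both axes (``x0 <= x < x0 + width``);
* frame indices are 0-based; times are seconds from run start;
* centroid coordinates are ROI-relative ``(x, y)`` floats with ``NaN``
  marking frames where no fish was found.

Command-string grammar
----------------------
A command string is an optional leading integer (the command id) followed
by letter-prefixed decimal fields, e.g. ``"2a0.01f625d20D100b250"``:

======  =========================================================
letter  meaning
======  =========================================================
``a``   transducer drive amplitude (unitless, log-scale usable)
``f``   tone frequency, Hz
``d``   stimulus duration, ms
``D``   delay, ms (repeatable; delays accumulate in order)
``b``   LED panel drive level (``b250`` is baseline illumination)
======  =========================================================

Letters are case-sensitive; each is immediately followed by a decimal
number.  Absent fields take neutral defaults (``a=0``, ``d=0``, no delays,
light unchanged).
"""

from __future__ import annotations

import csv
import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ParseError",
    "EventCommand",
    "Roi",
    "RoiSet",
    "MotionTrace",
    "CentroidTrace",
    "Section",
    "SectionsSpec",
    "parse_event_string",
    "read_events_file",
    "write_events_file",
    "read_motion_trace",
    "write_motion_trace",
    "read_centroid_trace",
    "write_centroid_trace",
    "read_rois",
    "write_rois",
    "read_sections",
    "write_sections",
]


class FormatError(ValueError):
    """Raised when a file violates its documented dialect or an invariant."""


class ParseError(FormatError):
    """Raised when a command string does not match the grammar.

    Carries ``position``, the 0-based index of the offending character.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# Event commands
# ---------------------------------------------------------------------------

_FIELD_RE = re.compile(r"([A-Za-z])(-?\d+(?:\.\d+)?(?:[eE]-?\d+)?)")
_KNOWN_LETTERS = frozenset("afdDb")


@dataclass
class EventCommand:
    """One parsed stimulus command.

    ``light_b`` is ``None`` when the command leaves illumination unchanged;
    ``command_id`` is ``None`` when the string has no leading integer.
    """

    command_id: int | None = None
    amplitude_a: float = 0.0
    frequency_f: float | None = None
    duration_d: float = 0.0
    delays_D: tuple[float, ...] = ()
    light_b: int | None = None
    scheduled_time: float = 0.0
    raw: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_a < 0:
            raise FormatError(f"amplitude must be >= 0, got {self.amplitude_a}")
        if self.duration_d < 0:
            raise FormatError(f"duration must be >= 0, got {self.duration_d}")

    @property
    def is_stimulus_free(self) -> bool:
        """True when the command drives neither transducer nor light change."""
        return self.amplitude_a == 0 and self.light_b is None

    @property
    def modality(self) -> str:
        """``"acoustic"``, ``"visual"``, ``"mixed"`` or ``"none"``."""
        acoustic = self.amplitude_a > 0
        visual = self.light_b is not None
        if acoustic and visual:
            return "mixed"
        if acoustic:
            return "acoustic"
        if visual:
            return "visual"
        return "none"

    def to_string(self) -> str:
        """Serialize to the canonical field order ``id a f d D... b``.

        Parsing then re-serializing is the identity on canonical strings.
        Fields at their neutral default are omitted, except that an ``a`` or
        ``d`` field explicitly present in ``raw`` is preserved by parsing
        (see :func:`parse_event_string`).
        """
        parts: list[str] = []
        if self.command_id is not None:
            parts.append(str(self.command_id))
        if self.amplitude_a != 0 or "a" in self._explicit:
            parts.append(f"a{_fmt_num(self.amplitude_a)}")
        if self.frequency_f is not None:
            parts.append(f"f{_fmt_num(self.frequency_f)}")
        if self.duration_d != 0 or "d" in self._explicit:
            parts.append(f"d{_fmt_num(self.duration_d)}")
        for delay in self.delays_D:
            parts.append(f"D{_fmt_num(delay)}")
        if self.light_b is not None:
            parts.append(f"b{_fmt_num(self.light_b)}")
        return "".join(parts)

    # letters that appeared explicitly in the parsed string, so that
    # zero-valued fields (e.g. "a0f625d0") survive a round trip
    _explicit: frozenset = field(default_factory=frozenset, repr=False, compare=False)


def _fmt_num(x: float) -> str:
    if isinstance(x, int) or float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def parse_event_string(s: str, scheduled_time: float = 0.0) -> EventCommand:
    """Parse one command string into an :class:`EventCommand`.

    Raises :class:`ParseError` (naming the character position) for anything
    outside the grammar, and :class:`FormatError` for negative numeric
    values in fields that must be non-negative.
    """
    text = s.strip()
    if not text:
        raise ParseError("empty command string", position=0)
    pos = 0
    command_id: int | None = None
    m = re.match(r"\d+", text)
    if m:
        command_id = int(m.group(0))
        pos = m.end()

    fields: dict[str, float] = {}
    delays: list[float] = []
    explicit: set[str] = set()
    while pos < len(text):
        m = _FIELD_RE.match(text, pos)
        if not m:
            raise ParseError(
                f"malformed token at position {pos} in {text!r}: "
                f"expected <letter><number>, found {text[pos]!r}",
                position=pos,
            )
        letter, num_s = m.group(1), m.group(2)
        if letter not in _KNOWN_LETTERS:
            raise ParseError(
                f"unknown field letter {letter!r} at position {pos} in {text!r}",
                position=pos,
            )
        value = float(num_s)
        if value < 0:
            raise FormatError(
                f"field {letter!r} must be non-negative, got {num_s} in {text!r}"
            )
        if letter == "D":
            delays.append(value)
        else:
            if letter in fields:
                raise ParseError(
                    f"duplicate field {letter!r} at position {pos} in {text!r}",
                    position=pos,
                )
            fields[letter] = value
        explicit.add(letter)
        pos = m.end()

    cmd = EventCommand(
        command_id=command_id,
        amplitude_a=fields.get("a", 0.0),
        frequency_f=fields.get("f"),
        duration_d=fields.get("d", 0.0),
        delays_D=tuple(delays),
        light_b=int(fields["b"]) if "b" in fields else None,
        scheduled_time=scheduled_time,
        raw=text,
    )
    cmd._explicit = frozenset(explicit)
    return cmd


def read_events_file(path: str | Path) -> list[EventCommand]:
    """Read an events CSV (``time_s,command_string``) into a sorted list.

    Rows are returned sorted by scheduled time; ties preserve file order.
    Out-of-order input is sorted with a warning.  Duplicate times are
    allowed.
    """
    path = Path(path)
    events: list[EventCommand] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not row or not any(row) or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("time_s", "time"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected time_s,command_string")
            try:
                t = float(row[0])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad time {row[0]!r}") from e
            try:
                events.append(parse_event_string(row[1], scheduled_time=t))
            except ParseError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    times = [e.scheduled_time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        warnings.warn(f"{path}: events not sorted by time; sorting", stacklevel=2)
    events.sort(key=lambda e: e.scheduled_time)  # stable: ties keep file order
    return events


def write_events_file(path: str | Path, events: Iterable[EventCommand]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "command_string"])
        for e in events:
            w.writerow([_fmt_num(e.scheduled_time), e.raw or e.to_string()])


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Roi:
    """One well rectangle: half-open, 0-based pixels, origin top-left."""

    well_id: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise FormatError(f"ROI {self.well_id}: non-positive size")
        if self.x0 < 0 or self.y0 < 0:
            raise FormatError(f"ROI {self.well_id}: negative origin")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def overlaps(self, other: "Roi") -> bool:
        return (
            self.x0 < other.x1 and other.x0 < self.x1
            and self.y0 < other.y1 and other.y0 < self.y1
        )

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing a frame array."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def contains(self, x: float, y: float) -> bool:
        """ROI-relative containment check for a centroid."""
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass
class RoiSet:
    """An ordered, non-overlapping set of well ROIs for one plate."""

    rois: list[Roi]
    plate_format: str = "96-well"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.rois:
            if r.well_id in seen:
                raise FormatError(f"duplicate well id {r.well_id!r}")
            seen.add(r.well_id)
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1:]:
                if a.overlaps(b):
                    raise FormatError(f"ROIs {a.well_id} and {b.well_id} overlap")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, well_id: str) -> Roi:
        for r in self.rois:
            if r.well_id == well_id:
                return r
        raise KeyError(well_id)

    @property
    def well_ids(self) -> list[str]:
        return [r.well_id for r in self.rois]

    def validate_against_frame(self, shape: tuple[int, int]) -> None:
        """Check every ROI lies within an (height, width) frame."""
        h, w = shape
        for r in self.rois:
            if r.x1 > w or r.y1 > h:
                raise FormatError(
                    f"ROI {r.well_id} exceeds frame bounds {w}x{h}"
                )

    @classmethod
    def grid(
        cls,
        rows: int = 8,
        cols: int = 12,
        well_width: int = 48,
        well_height: int = 48,
        x_offset: int = 0,
        y_offset: int = 0,
        gap: int = 0,
        plate_format: str | None = None,
    ) -> "RoiSet":
        """Build a row-major grid of wells labelled A1..; A1 is top-left.

        The default 8x12 layout reproduces a 96-well plate with wells read
        A1, A2, ... H12.
        """
        rois = []
        for i in range(rows):
            for j in range(cols):
                well = f"{chr(ord('A') + i)}{j + 1}"
                rois.append(Roi(
                    well,
                    x_offset + j * (well_width + gap),
                    y_offset + i * (well_height + gap),
                    well_width,
                    well_height,
                ))
        fmt = plate_format or f"{rows * cols}-well"
        return cls(rois, plate_format=fmt)


def read_rois(path: str | Path) -> RoiSet:
    """Read an ROI CSV: ``# plate_format:`` header then well_id,x0,y0,w,h."""
    path = Path(path)
    plate_format = "unknown"
    rois: list[Roi] = []
    with path.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    if key.strip() == "plate_format":
                        plate_format = val.strip()
                continue
            row = [c.strip() for c in line.split(",")]
            if row[0] == "well_id":
                continue
            if len(row) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                rois.append(Roi(row[0], int(row[1]), int(row[2]),
                                int(row[3]), int(row[4])))
            except (ValueError, FormatError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    try:
        return RoiSet(rois, plate_format=plate_format)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from e


def write_rois(path: str | Path, rois: RoiSet) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write(f"# plate_format: {rois.plate_format}\n")
        fh.write("well_id,x0,y0,w,h\n")
        for r in rois:
            fh.write(f"{r.well_id},{r.x0},{r.y0},{r.width},{r.height}\n")


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

@dataclass
class MotionTrace:
    """Per-frame delta-pixel counts at a stated frame rate.

    ``values[i]`` is the number of ROI pixels that changed (beyond the
    tracker's noise floor) between frames ``i`` and ``i + 1``.
    """

    values: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise FormatError("motion trace must be a non-empty 1-D array")
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if np.any(np.isnan(self.values.astype(float))):
            raise FormatError("motion trace contains NaN")
        if np.any(self.values < 0):
            raise FormatError("motion trace contains negative values")
        self.values = self.values.astype(np.int64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fps

    def slice_time(self, start_s: float, end_s: float) -> "MotionTrace":
        """Sub-trace covering run-times ``[start_s, end_s)``."""
        i0 = max(0, int(math.ceil((start_s - self.t0) * self.fps - 1e-9)))
        i1 = min(len(self.values), int(math.ceil((end_s - self.t0) * self.fps - 1e-9)))
        i1 = max(i1, i0 + 1) if i0 < len(self.values) else i0
        return MotionTrace(self.values[i0:i1], self.fps, self.t0 + i0 / self.fps)


@dataclass
class CentroidTrace:
    """Per-frame (x, y) fish positions, ROI-relative, NaN when missing."""

    points: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) == 0:
            raise FormatError("centroid trace must be a non-empty (n, 2) array")
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.points).any(axis=1)

    def validate_within(self, roi: Roi) -> None:
        ok = self.missing.copy()
        x, y = self.points[:, 0], self.points[:, 1]
        with np.errstate(invalid="ignore"):
            ok |= (x >= 0) & (x < roi.width) & (y >= 0) & (y < roi.height)
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise FormatError(
                f"centroid at frame {bad} lies outside ROI {roi.well_id}"
            )

    def interpolated(self) -> np.ndarray:
        """Points with interior NaN runs linearly interpolated.

        Leading/trailing missing frames are filled by the nearest valid
        point; an all-missing trace is returned unchanged.
        """
        pts = self.points.copy()
        good = ~self.missing
        if not good.any() or good.all():
            return pts
        idx = np.arange(len(pts))
        for k in range(2):
            pts[:, k] = np.interp(idx, idx[good], pts[good, k])
        return pts

    def slice_time(self, start_s: float, end_s: float) -> "CentroidTrace":
        i0 = max(0, int(math.ceil((start_s - self.t0) * self.fps - 1e-9)))
        i1 = min(len(self.points), int(math.ceil((end_s - self.t0) * self.fps - 1e-9)))
        i1 = max(i1, i0 + 1) if i0 < len(self.points) else i0
        return CentroidTrace(self.points[i0:i1], self.fps, self.t0 + i0 / self.fps)


def _read_trace_header(path: Path) -> tuple[float, float, int]:
    """Parse ``# fps:`` / ``# t0:`` comments; return (fps, t0, body offset)."""
    fps = t0 = None
    offset = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key == "fps":
                    fps = float(val)
                elif key == "t0":
                    t0 = float(val)
                offset += 1
            else:
                break
    if fps is None:
        raise FormatError(f"{path}: missing '# fps:' header")
    if fps <= 0:
        raise FormatError(f"{path}: fps must be positive, got {fps}")
    return fps, (0.0 if t0 is None else t0), offset


def read_motion_trace(path: str | Path) -> MotionTrace:
    path = Path(path)
    fps, t0, offset = _read_trace_header(path)
    values: list[int] = []
    with path.open(newline="") as fh:
        for _ in range(offset):
            next(fh)
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=offset + 1):
            if not row or row[0] == "frame":
                continue
            try:
                v = float(row[1])
            except (IndexError, ValueError) as e:
                raise FormatError(f"{path}:{lineno}: bad motion row {row!r}") from e
            if math.isnan(v):
                raise FormatError(f"{path}:{lineno}: NaN motion value")
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative delta-pixel value {v}")
            values.append(int(round(v)))
    return MotionTrace(np.array(values, dtype=np.int64), fps=fps, t0=t0)


def write_motion_trace(path: str | Path, trace: MotionTrace) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write(f"# fps: {trace.fps!r}\n# t0: {trace.t0!r}\n")
        fh.write("frame,delta_pixels\n")
        for i, v in enumerate(trace.values):
            fh.write(f"{i},{int(v)}\n")


def read_centroid_trace(path: str | Path) -> CentroidTrace:
    path = Path(path)
    fps, t0, offset = _read_trace_header(path)
    pts: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        for _ in range(offset):
            next(fh)
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=offset + 1):
            if not row or row[0] == "frame":
                continue
            try:
                x = float("nan") if row[1].strip() in ("", "nan", "NA") else float(row[1])
                y = float("nan") if row[2].strip() in ("", "nan", "NA") else float(row[2])
            except (IndexError, ValueError) as e:
                raise FormatError(f"{path}:{lineno}: bad centroid row {row!r}") from e
            pts.append((x, y))
    return CentroidTrace(np.array(pts, dtype=float), fps=fps, t0=t0)


def write_centroid_trace(path: str | Path, trace: CentroidTrace) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write(f"# fps: {trace.fps!r}\n# t0: {trace.t0!r}\n")
        fh.write("frame,x,y\n")
        for i, (x, y) in enumerate(trace.points):
            xs = "nan" if math.isnan(x) else repr(float(x))
            ys = "nan" if math.isnan(y) else repr(float(y))
            fh.write(f"{i},{xs},{ys}\n")


# ---------------------------------------------------------------------------
# Sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Section:
    """A named analysis window.

    ``kind`` is ``"time"`` for baseline windows without high-speed events
    and ``"event"`` for windows analysed through their stimulus responses.
    ``event_selector`` optionally restricts an event section to commands
    whose raw string contains the selector substring (empty = all events).
    """

    name: str
    start_s: float
    end_s: float
    kind: str = "time"
    event_selector: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise FormatError(
                f"section {self.name!r}: start must precede end "
                f"({self.start_s} >= {self.end_s})"
            )
        if self.kind not in ("time", "event"):
            raise FormatError(f"section {self.name!r}: kind must be time|event")

    def contains_time(self, t: float) -> bool:
        return self.start_s <= t < self.end_s

    def select_events(self, events: Sequence[EventCommand]) -> list[EventCommand]:
        out = []
        for e in events:
            if not self.contains_time(e.scheduled_time):
                continue
            if self.event_selector and self.event_selector not in (e.raw or ""):
                continue
            out.append(e)
        return out


@dataclass
class SectionsSpec:
    """Ordered list of sections; overlap between sections is permitted."""

    sections: list[Section]

    def __iter__(self):
        return iter(self.sections)

    def __len__(self) -> int:
        return len(self.sections)

    def __getitem__(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)


def read_sections(path: str | Path) -> SectionsSpec:
    """Read a sections CSV: ``name,start_s,end_s,kind,selector``."""
    path = Path(path)
    sections: list[Section] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row]
            if not row or not any(row) or row[0].startswith("#"):
                continue
            if row[0] == "name":
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            selector = row[4] if len(row) > 4 else ""
            try:
                sections.append(Section(row[0], float(row[1]), float(row[2]),
                                        row[3], selector))
            except (ValueError, FormatError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return SectionsSpec(sections)


def write_sections(path: str | Path, spec: SectionsSpec) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("name,start_s,end_s,kind,selector\n")
        w = csv.writer(fh)
        for s in spec:
            w.writerow([s.name, _fmt_num(s.start_s), _fmt_num(s.end_s),
                        s.kind, s.event_selector])
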