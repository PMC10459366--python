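"""Time-lapse sequence, annotation and detection I/O.

Field recordings are long runs of still RGB images captured at a fixed
nominal interval (30 s by default) with a nightly recording stop.  This
module models those sequences, reads/writes YOLO-format bounding-box
labels (one text file per image, lines ``class cx cy w h`` normalised to
[0, 1]) and a simple CSV interchange format for detector outputs.

Bounding boxes use 0-based, half-open pixel coordinates
``[xmin, xmax) x [ymin, ymax)`` throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, time as dtime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: filename-stem timestamp pattern used when none is given
DEFAULT_TIMESTAMP_PATTERN = "%Y%m%d-%H%M%S"

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}

DETECTION_CSV_COLUMNS = [
    "frame_id", "xmin", "ymin", "xmax", "ymax", "confidence", "class_id",
]


def _round_half_up(x):
    """Round half away from zero (non-negative inputs: half up)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def within(self, width: int, height: int) -> bool:
        return self.xmin >= 0 and self.ymin >= 0 and self.xmax <= width and self.ymax <= height


@dataclass
class Frame:
    """One time-lapse image: H x W x 3 uint8 RGB plus capture metadata."""

    image: np.ndarray
    timestamp: datetime
    frame_id: str

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"frame {self.frame_id!r}: expected HxWx3 image, got {img.shape}")
        if img.dtype != np.uint8:
            raise ValueError(f"frame {self.frame_id!r}: expected uint8 image, got {img.dtype}")
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class Annotation:
    """Ground-truth box for one frame (single insect class by default)."""

    frame_id: str
    box: BoundingBox
    class_id: int = 0


@dataclass
class Detection:
    """Predicted box with a confidence score in [0, 1].

    ``timestamp`` and ``camera_id`` are optional metadata used by the
    abundance filtering stage; plain detector output need not carry them.
    """

    frame_id: str
    box: BoundingBox
    confidence: float
    class_id: int = 0
    timestamp: datetime | None = None
    camera_id: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class TimeLapseSequence:
    """Ordered, same-shape frames from one camera."""

    frames: list[Frame]
    camera_id: str = ""
    nominal_interval_s: float = 30.0
    skipped_files: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.nominal_interval_s <= 0:
            raise ValueError("nominal_interval_s must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        ts = [f.timestamp for f in self.frames]
        for a, b in zip(ts, ts[1:]):
            if not a < b:
                raise ValueError(f"timestamps not strictly increasing at {a} -> {b}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.frames:
            raise ValueError("empty sequence has no shape")
        return self.frames[0].shape

    @property
    def frame_ids(self) -> list[str]:
        return [f.frame_id for f in self.frames]


def parse_frame_timestamp(frame_id: str, pattern: str = DEFAULT_TIMESTAMP_PATTERN) -> datetime:
    """Parse a capture timestamp from a filename stem."""
    return datetime.strptime(frame_id, pattern)


def load_sequence(
    directory: str | Path,
    timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN,
    nominal_interval_s: float = 30.0,
    camera_id: str | None = None,
) -> TimeLapseSequence:
    """Load every decodable JPG/PNG under ``directory`` sorted by timestamp.

    Timestamps are parsed from filename stems with a strptime-style
    pattern.  Undecodable files are skipped with a logged warning and
    listed on ``TimeLapseSequence.skipped_files``; duplicate timestamps
    are an error (they would make triple formation ambiguous).
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not paths:
        raise FileNotFoundError(f"no image files in {directory}")

    frames: list[Frame] = []
    skipped: list[str] = []
    seen: dict[datetime, str] = {}
    for p in paths:
        ts = datetime.strptime(p.stem, timestamp_pattern)
        if ts in seen:
            raise ValueError(f"duplicate timestamp {ts}: {seen[ts]} and {p.name}")
        seen[ts] = p.name
        try:
            with Image.open(p) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
        except (OSError, UnidentifiedImageError, SyntaxError) as exc:
            logger.warning("skipping undecodable image %s: %s", p.name, exc)
            skipped.append(p.name)
            continue
        frames.append(Frame(image=arr, timestamp=ts, frame_id=p.stem))
    if not frames:
        raise FileNotFoundError(f"no decodable image files in {directory}")
    frames.sort(key=lambda f: f.timestamp)
    return TimeLapseSequence(
        frames=frames,
        camera_id=camera_id if camera_id is not None else directory.name,
        nominal_interval_s=nominal_interval_s,
        skipped_files=skipped,
    )


def save_sequence(seq: TimeLapseSequence, directory: str | Path, suffix: str = ".png") -> list[Path]:
    """Write every frame as ``<frame_id><suffix>`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in seq:
        path = directory / f"{f.frame_id}{suffix}"
        Image.fromarray(f.image).save(path)
        paths.append(path)
    return paths


def segment_runs(seq: TimeLapseSequence, max_gap_s: float) -> list[TimeLapseSequence]:
    """Split a sequence into maximal runs with inter-frame gaps <= max_gap_s.

    Recording stops overnight, so a day's frames form one run and the
    overnight gap starts a new one.  Concatenating the returned runs in
    order recovers the input frame order exactly.
    """
    if max_gap_s < seq.nominal_interval_s:
        raise ValueError("max_gap_s must be >= nominal_interval_s")
    runs: list[TimeLapseSequence] = []
    current: list[Frame] = []
    for f in seq:
        if current and (f.timestamp - current[-1].timestamp).total_seconds() > max_gap_s:
            runs.append(TimeLapseSequence(current, seq.camera_id, seq.nominal_interval_s))
            current = []
        current.append(f)
    if current:
        runs.append(TimeLapseSequence(current, seq.camera_id, seq.nominal_interval_s))
    return runs


def expected_frame_count(
    start: dtime | str, end: dtime | str, interval_s: float
) -> int:
    """Number of capture ticks in the half-open window [start, end).

    With the 04:30-22:30 daily schedule at a 30 s interval this is the
    per-camera daily maximum of 2160 images.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    start = _as_time(start)
    end = _as_time(end)
    seconds = (
        (end.hour - start.hour) * 3600
        + (end.minute - start.minute) * 60
        + (end.second - start.second)
    )
    if seconds < 0:
        raise ValueError("end must not precede start")
    # ticks fire at start, start+i, ... while strictly before end
    return int(math.ceil(seconds / interval_s))


def _as_time(t: dtime | str) -> dtime:
    if isinstance(t, dtime):
        return t
    parts = [int(p) for p in str(t).split(":")]
    while len(parts) < 3:
        parts.append(0)
    return dtime(*parts)


# ---------------------------------------------------------------------------
# YOLO label format


def yolo_to_box(cx: float, cy: float, w: float, h: float,
                image_width: int, image_height: int) -> BoundingBox:
    """Convert one normalised YOLO record to a pixel box.

    Corners are rounded symmetrically: xmin = round(cx*W - w*W/2),
    xmax = round(cx*W + w*W/2); a box that quantises to zero extent is
    widened to one pixel.
    """
    xmin = float(_round_half_up(cx * image_width - 0.5 * w * image_width))
    xmax = float(_round_half_up(cx * image_width + 0.5 * w * image_width))
    ymin = float(_round_half_up(cy * image_height - 0.5 * h * image_height))
    ymax = float(_round_half_up(cy * image_height + 0.5 * h * image_height))
    if xmax <= xmin:
        xmax = min(xmin + 1.0, float(image_width))
        xmin = xmax - 1.0
    if ymax <= ymin:
        ymax = min(ymin + 1.0, float(image_height))
        ymin = ymax - 1.0
    return BoundingBox(xmin, ymin, xmax, ymax)


def read_yolo_annotations(
    file: str | Path,
    image_width: int,
    image_height: int,
    frame_id: str | None = None,
) -> list[Annotation]:
    """Read one YOLO label file (``class cx cy w h`` per line, normalised)."""
    file = Path(file)
    if frame_id is None:
        frame_id = file.stem
    annotations: list[Annotation] = []
    for lineno, raw in enumerate(file.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"{file.name}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise ValueError(f"{file.name}:{lineno}: unparseable values: {raw!r}") from exc
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{file.name}:{lineno}: {name}={v} outside [0, 1]")
        box = yolo_to_box(cx, cy, w, h, image_width, image_height)
        annotations.append(Annotation(frame_id=frame_id, box=box, class_id=class_id))
    return annotations


def write_yolo_annotations(
    annotations: Iterable[Annotation],
    image_width: int,
    image_height: int,
    file: str | Path,
) -> None:
    """Write annotations in YOLO text format (normalised, 6 decimals)."""
    lines = []
    for ann in annotations:
        b = ann.box
        if not b.within(image_width, image_height):
            raise ValueError(f"box {b} outside {image_width}x{image_height} image")
        cx = 0.5 * (b.xmin + b.xmax) / image_width
        cy = 0.5 * (b.ymin + b.ymax) / image_height
        w = b.width / image_width
        h = b.height / image_height
        lines.append(f"{ann.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(file).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Detection CSV interchange


def read_detections_csv(file: str | Path) -> list[Detection]:
    """Read detections from CSV; rejects rows with confidence outside [0, 1].

    Required columns: frame_id,xmin,ymin,xmax,ymax,confidence,class_id.
    Optional ``timestamp`` (ISO 8601) and ``camera_id`` columns are
    carried through when present.
    """
    df = pd.read_csv(file, dtype={"frame_id": str}, float_precision="round_trip")
    missing = [c for c in DETECTION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{file}: missing column(s) {', '.join(missing)}")
    detections: list[Detection] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        conf = float(row.confidence)
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"{file}: row {i}: confidence {conf} outside [0, 1]")
        ts = getattr(row, "timestamp", None)
        timestamp = None if ts is None or (isinstance(ts, float) and math.isnan(ts)) \
            else pd.Timestamp(ts).to_pydatetime()
        cam = getattr(row, "camera_id", None)
        camera_id = None if cam is None or (isinstance(cam, float) and math.isnan(cam)) else str(cam)
        detections.append(
            Detection(
                frame_id=str(row.frame_id),
                box=BoundingBox(float(row.xmin), float(row.ymin),
                                float(row.xmax), float(row.ymax)),
                confidence=conf,
                class_id=int(row.class_id),
                timestamp=timestamp,
                camera_id=camera_id,
            )
        )
    return detections


def write_detections_csv(detections: Sequence[Detection], file: str | Path) -> None:
    """Write detections to CSV (lossless round-trip with read_detections_csv)."""
    records = []
    with_meta = any(d.timestamp is not None or d.camera_id is not None for d in detections)
    for d in detections:
        rec = {
            "frame_id": d.frame_id,
            "xmin": d.box.xmin,
            "ymin": d.box.ymin,
            "xmax": d.box.xmax,
            "ymax": d.box.ymax,
            "confidence": d.confidence,
            "class_id": d.class_id,
        }
        if with_meta:
            rec["timestamp"] = d.timestamp.isoformat() if d.timestamp else ""
            rec["camera_id"] = d.camera_id if d.camera_id is not None else ""
        records.append(rec)
    columns = DETECTION_CSV_COLUMNS + (["timestamp", "camera_id"] if with_meta else [])
    pd.DataFrame.from_records(records, columns=columns).to_csv(file, index=False)
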