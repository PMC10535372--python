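"""Pluggable epiglottis-detector interface.

The pipeline only needs a per-frame bounding box for the epiglottis; where
the box comes from (a trained object detector, manual annotation, or the
synthetic ground truth) is deliberately decoupled.  Detections travel as a
plain text file, one line per box::

    frame_index x y width height confidence

with 1-based frame indices and 0-based integer pixel coordinates
(``format="xywh"``).  The common normalized center-format dialect is also
accepted (``format="yolo"``): ``frame_index [class] cx cy w h [conf]`` with
coordinates in [0, 1], converted on load using the image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .rpa import BoundingBox

__all__ = [
    "DetectionRecord",
    "DetectionParseError",
    "load_detections",
    "write_detections",
    "select_box",
    "mock_detect",
]

DEFAULT_CONF_MIN = 0.25


class DetectionParseError(ValueError):
    """A detection file line could not be parsed."""

    def __init__(self, path, line_no: int, line: str, reason: str):
        super().__init__(f"{path}:{line_no}: {reason}: {line.strip()!r}")
        self.line_no = line_no


@dataclass
class DetectionRecord:
    """Zero or more candidate boxes for one frame."""

    frame: int
    boxes: list[BoundingBox] = field(default_factory=list)


def _parse_xywh(fields: list[str]) -> tuple[int, BoundingBox]:
    n = int(fields[0])
    x, y, w, h = (int(round(float(v))) for v in fields[1:5])
    conf = float(fields[5]) if len(fields) > 5 else 1.0
    return n, BoundingBox(x=x, y=y, width=w, height=h, confidence=conf)


def _parse_yolo(fields: list[str], image_size: tuple[int, int]) -> tuple[int, BoundingBox]:
    wi, hi = image_size
    n = int(fields[0])
    vals = [float(v) for v in fields[1:]]
    # optional leading class id: 5 or 6 trailing numbers
    if len(vals) == 5 and vals[0] == int(vals[0]) and not (0 < vals[0] < 1):
        vals = vals[1:] + [1.0]
    elif len(vals) == 6:
        vals = vals[1:]
    elif len(vals) == 4:
        vals = vals + [1.0]
    cx, cy, w, h, conf = vals
    bw = max(1, int(round(w * wi)))
    bh = max(1, int(round(h * hi)))
    x = int(round(cx * wi - bw / 2))
    y = int(round(cy * hi - bh / 2))
    return n, BoundingBox(x=x, y=y, width=bw, height=bh, confidence=conf)


def load_detections(
    path,
    format: Literal["xywh", "yolo"] = "xywh",
    image_size: tuple[int, int] | None = None,
) -> dict[int, DetectionRecord]:
    """Read a detection file into ``{frame_index: DetectionRecord}``.

    Frames not listed simply have no record — the epiglottis is treated as
    undetected there.  Malformed lines raise :class:`DetectionParseError`
    with the offending line number.
    """
    if format == "yolo" and image_size is None:
        raise ValueError("image_size is required for the normalized dialect")
    records: dict[int, DetectionRecord] = {}
    path = Path(path)
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            if format == "xywh":
                if len(fields) < 5:
                    raise ValueError("expected >= 5 fields")
                n, box = _parse_xywh(fields)
            else:
                if len(fields) < 5:
                    raise ValueError("expected >= 5 fields")
                n, box = _parse_yolo(fields, image_size)
        except DetectionParseError:
            raise
        except Exception as exc:
            raise DetectionParseError(path, line_no, line, str(exc)) from exc
        records.setdefault(n, DetectionRecord(frame=n)).boxes.append(box)
    return records


def write_detections(records: Mapping[int, DetectionRecord], path) -> None:
    """Write records in the plain pixel dialect (conf to 4 decimals)."""
    lines = []
    for n in sorted(records):
        for b in records[n].boxes:
            lines.append(f"{n} {b.x} {b.y} {b.width} {b.height} {b.confidence:.4f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def select_box(
    record: DetectionRecord | None, conf_min: float = DEFAULT_CONF_MIN
) -> BoundingBox | None:
    """Highest-confidence box with confidence >= conf_min; ties → larger area."""
    if record is None or not record.boxes:
        return None
    surviving = [b for b in record.boxes if b.confidence >= conf_min]
    if not surviving:
        return None
    return max(surviving, key=lambda b: (b.confidence, b.area))


def mock_detect(
    ground_truth, jitter: int = 0, seed: int | None = None
) -> dict[int, DetectionRecord]:
    """Detector test double driven by synthetic ground truth.

    Emits the true epiglottis box for every frame where the epiglottis is
    present, optionally perturbed by integer jitter uniform in
    [-jitter, jitter] on each coordinate; scope-slip frames emit no box.
    """
    rng = np.random.default_rng(seed)
    records: dict[int, DetectionRecord] = {}
    for fr in ground_truth.frames:
        if fr.box is None:
            continue
        x, y, w, h = fr.box
        if jitter:
            dx, dy, dw, dh = rng.integers(-jitter, jitter + 1, size=4)
            x, y = int(x + dx), int(y + dy)
            w, h = max(1, int(w + dw)), max(1, int(h + dh))
        records[fr.n] = DetectionRecord(
            frame=fr.n,
            boxes=[BoundingBox(x=int(x), y=int(y), width=int(w), height=int(h),
                               confidence=1.0)],
        )
    return records
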