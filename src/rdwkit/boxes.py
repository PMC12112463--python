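"""Axis-aligned bounding boxes in center/size form and YOLO label text I/O.

A box is ``(cx, cy, w, h)`` — center coordinates plus width and height — in
whatever unit the caller keeps consistent (pixels or [0,1]-normalized). On
disk the package uses the YOLO label convention: one text file per image,
one object per line, ``<class_id> <cx> <cy> <w> <h>`` with coordinates
normalized to [0,1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive width or height."""


@dataclass(frozen=True)
class BoxXYWH:
    """Axis-aligned box by center ``(cx, cy)`` and size ``(w, h)``, w,h > 0."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    def to_corners(self) -> Tuple[float, float, float, float]:
        """Return ``(x1, y1, x2, y2)`` corner form."""
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoxXYWH":
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.cx, self.cy, self.w, self.h)

    def area(self) -> float:
        return self.w * self.h


LabeledBox = Tuple[int, BoxXYWH]


def read_yolo_labels(path: str | os.PathLike) -> List[LabeledBox]:
    """Parse a YOLO label file into ``(class_id, BoxXYWH)`` pairs."""
    out: List[LabeledBox] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
            out.append((cls, BoxXYWH(cx, cy, w, h)))
    return out


def write_yolo_labels(path: str | os.PathLike, labels: Iterable[LabeledBox]) -> None:
    """Write ``(class_id, BoxXYWH)`` pairs in YOLO label format."""
    with open(path, "w", encoding="utf-8") as fh:
        for cls, box in labels:
            fh.write(f"{int(cls)} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f}\n")


def boxes_to_array(boxes: Sequence[BoxXYWH]):
    import numpy as np

    return np.array([b.as_tuple() for b in boxes], dtype=float).reshape(len(boxes), 4)
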