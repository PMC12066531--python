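"""Axis-aligned box primitives and the detection/track data model.

Coordinates are continuous pixels with the image origin at the top-left and
y increasing downward, matching detector output.  Boxes are stored in corner
form ``(x1, y1, x2, y2)``; areas are computed on real intervals, so there is
no 0-based / 1-based pixel convention to worry about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Detection classes: the seed scoop (the cup on the metering chain, the
#: "red" class) and the potato seed tuber riding in it (the "green" class).
CLASS_SCOOP = 0
CLASS_TUBER = 1
CLASS_NAMES = {CLASS_SCOOP: "scoop", CLASS_TUBER: "tuber"}


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in corner form; must have strictly positive area."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise ValueError(f"box coordinates must be finite, got {self!r}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box: need x1 < x2 and y1 < y2, got "
                f"({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Build from top-left corner plus width/height (MOT file convention)."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)


@dataclass(frozen=True)
class Detection:
    """One per-frame detector observation."""

    frame: int
    class_id: int
    score: float
    box: Box

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be non-negative, got {self.frame}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class TrackPoint:
    """One frame of a tracked identity: where track ``track_id`` was seen."""

    frame: int
    track_id: int
    class_id: int
    box: Box
    score: float

    def __post_init__(self) -> None:
        if self.track_id <= 0:
            raise ValueError(f"track_id must be positive, got {self.track_id}")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    The primary association similarity for tracking and the matching
    criterion for detection evaluation.  Symmetric, scale invariant, and 0
    for disjoint boxes.
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)
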