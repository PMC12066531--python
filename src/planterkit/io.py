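"""Readers and writers for detection streams, track results and labels.

File dialects
-------------
Detection / track files are CSV with columns

    frame, id, x, y, w, h, score, class

i.e. the MOTChallenge ``det``/result layout with one trailing ``class``
column appended (MOT det files carry no class).  ``id`` is ``-1`` for raw
detections and the assigned track id for tracker output.  Boxes are stored
as top-left ``(x, y)`` plus ``(w, h)`` and converted to corner form on read.

Ground-truth labels for metric evaluation use the YOLO dialect: one text
file per frame, rows ``class cx cy w h`` with coordinates normalized to
[0, 1].
"""

from __future__ import annotations

import csv
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

from .geometry import Box, Detection, TrackPoint

_COLUMNS = ("frame", "id", "x", "y", "w", "h", "score", "class")


class ParseError(ValueError):
    """A malformed row in a detection/track/label file."""


def _parse_row(row: Sequence[str], lineno: int) -> tuple[int, int, Box, float, int]:
    if len(row) != len(_COLUMNS):
        raise ParseError(
            f"line {lineno}: expected {len(_COLUMNS)} fields "
            f"{','.join(_COLUMNS)}, got {len(row)}"
        )
    try:
        frame = int(float(row[0]))
        obj_id = int(float(row[1]))
        x, y, w, h = (float(v) for v in row[2:6])
        score = float(row[6])
        class_id = int(float(row[7]))
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    if frame < 0:
        raise ParseError(f"line {lineno}: negative frame index {frame}")
    try:
        box = Box.from_xywh(x, y, w, h)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    return frame, obj_id, box, score, class_id


def _iter_rows(path: str | Path):
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "frame":
                continue  # optional header
            yield lineno, row


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detection CSV; rows are returned in file order."""
    out: list[Detection] = []
    for lineno, row in _iter_rows(path):
        frame, _obj_id, box, score, class_id = _parse_row(row, lineno)
        try:
            out.append(Detection(frame, class_id, score, box))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return out


def write_detections(path: str | Path, detections: Iterable[Detection]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for d in detections:
            x, y, w, h = d.box.to_xywh()
            writer.writerow(
                [d.frame, -1, repr(float(x)), repr(float(y)), repr(float(w)),
                 repr(float(h)), repr(float(d.score)), d.class_id]
            )


def group_by_frame(detections: Iterable[Detection]) -> "OrderedDict[int, list[Detection]]":
    """Group detections by frame index, frames in ascending order."""
    grouped: dict[int, list[Detection]] = {}
    for d in detections:
        grouped.setdefault(d.frame, []).append(d)
    return OrderedDict(sorted(grouped.items()))


def read_tracks(path: str | Path) -> list[TrackPoint]:
    """Read a track result CSV (same dialect, id = track id)."""
    out: list[TrackPoint] = []
    for lineno, row in _iter_rows(path):
        frame, obj_id, box, score, class_id = _parse_row(row, lineno)
        try:
            out.append(TrackPoint(frame, obj_id, class_id, box, score))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return out


def write_tracks(path: str | Path, points: Sequence[TrackPoint]) -> None:
    """Write track points; requires points sorted by (frame, track_id), no dupes."""
    keys = [(p.frame, p.track_id) for p in points]
    if keys != sorted(keys):
        raise ValueError("track points must be sorted by (frame, track_id)")
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (frame, track_id) pair in track points")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for p in points:
            x, y, w, h = p.box.to_xywh()
            writer.writerow(
                [p.frame, p.track_id, repr(float(x)), repr(float(y)), repr(float(w)),
                 repr(float(h)), repr(float(p.score)), p.class_id]
            )


def read_yolo_labels(
    path: str | Path, frame_width: float, frame_height: float
) -> list[tuple[int, Box]]:
    """Read one frame's YOLO-dialect label file into (class_id, Box) pairs."""
    out: list[tuple[int, Box]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 'class cx cy w h'")
            try:
                class_id = int(fields[0])
                cx, cy, w, h = (float(v) for v in fields[1:])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
            box = Box(
                (cx - w / 2) * frame_width,
                (cy - h / 2) * frame_height,
                (cx + w / 2) * frame_width,
                (cy + h / 2) * frame_height,
            )
            out.append((class_id, box))
    return out
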