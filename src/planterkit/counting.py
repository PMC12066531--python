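"""Dual-line crossing counter with independent left/right bookkeeping.

Raw tracker ids are unreliable for counting — the metering chain's motion
causes id switches — so a target is only counted when the *same* id is seen
to cross two horizontal virtual lines in order: first the entry line, then
the counting line, both moving downward.  An id that appears between the
lines (a mid-sequence id switch) never satisfies the entry-line membership
test and contributes nothing, and an id already counted (in ``list_sum``)
can never be counted again.  The left and right halves of the frame, split
at the chain's center, are tallied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .geometry import TrackPoint

LEFT = "left"
RIGHT = "right"
SIDES = (LEFT, RIGHT)


@dataclass(frozen=True)
class LineConfig:
    """Placement of the entry/counting lines and the left/right split."""

    entry_y: float
    count_y: float
    split_x: float
    frame_width: float = 640.0
    frame_height: float = 480.0

    def __post_init__(self) -> None:
        if not 0 < self.entry_y < self.count_y < self.frame_height:
            raise ValueError(
                "need 0 < entry_y < count_y < frame_height "
                f"(got {self.entry_y}, {self.count_y}, {self.frame_height})"
            )
        if not 0 < self.split_x < self.frame_width:
            raise ValueError(f"split_x {self.split_x} outside frame")

    @classmethod
    def default(cls, frame_width: float = 640.0, frame_height: float = 480.0) -> "LineConfig":
        """Lines mid-window: entry at 45 %, counting at 60 % of frame height."""
        return cls(
            entry_y=0.45 * frame_height,
            count_y=0.60 * frame_height,
            split_x=0.5 * frame_width,
            frame_width=frame_width,
            frame_height=frame_height,
        )


@dataclass(frozen=True)
class CountEvent:
    """One increment of a tally: track ``track_id`` was counted."""

    frame: int
    track_id: int
    side: str
    class_id: int


@dataclass
class CounterState:
    """Membership lists and tallies carried across frames."""

    list_left: set[int] = field(default_factory=set)
    list_right: set[int] = field(default_factory=set)
    list_sum: set[int] = field(default_factory=set)
    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    last_center: dict[int, tuple[float, float, int]] = field(default_factory=dict)

    def side_list(self, side: str) -> set[int]:
        return self.list_left if side == LEFT else self.list_right

    def tally(self, side: str, class_id: int) -> int:
        return self.counts.get((side, class_id), 0)


def crossing_test(prev_y: float, curr_y: float, line_y: float) -> bool:
    """True iff the center moved downward past the line: prev < line <= curr."""
    return prev_y < line_y <= curr_y


def _side_of(cx: float, lines: LineConfig) -> str:
    return LEFT if cx < lines.split_x else RIGHT


def update_counter(
    state: CounterState, frame_points: Sequence[TrackPoint], lines: LineConfig
) -> list[CountEvent]:
    """Advance the counter by one frame; mutates ``state`` in place.

    For each point the entry-line test runs before the counting-line test,
    so a target jumping past both lines in one frame step (dropped frames,
    fast chain) is still registered and counted in the same update.
    """
    events: list[CountEvent] = []
    for p in frame_points:
        cx, cy = p.box.center
        prev = state.last_center.get(p.track_id)
        if prev is not None:
            prev_y = prev[1]
            if crossing_test(prev_y, cy, lines.entry_y):
                side = _side_of(cx, lines)
                if p.track_id not in state.side_list(side) and p.track_id not in state.list_sum:
                    state.side_list(side).add(p.track_id)
            if crossing_test(prev_y, cy, lines.count_y):
                side = _side_of(cx, lines)
                if p.track_id in state.side_list(side) and p.track_id not in state.list_sum:
                    state.list_sum.add(p.track_id)
                    key = (side, p.class_id)
                    state.counts[key] = state.counts.get(key, 0) + 1
                    events.append(CountEvent(p.frame, p.track_id, side, p.class_id))
        state.last_center[p.track_id] = (cx, cy, p.frame)
    return events


@dataclass
class CountResult:
    """Final tallies and the full event log of one sequence."""

    counts: dict[tuple[str, int], int]
    events: list[CountEvent]

    def total(self, side: str | None = None, class_id: int | None = None) -> int:
        return sum(
            n
            for (s, c), n in self.counts.items()
            if (side is None or s == side) and (class_id is None or c == class_id)
        )


def count_sequence(points: Iterable[TrackPoint], lines: LineConfig) -> CountResult:
    """Fold the per-frame update over a whole (frame-sorted) track stream."""
    state = CounterState()
    events: list[CountEvent] = []
    current_frame: int | None = None
    buffer: list[TrackPoint] = []
    for p in points:
        if current_frame is not None and p.frame < current_frame:
            raise ValueError(
                f"track points not sorted by frame ({p.frame} after {current_frame})"
            )
        if p.frame != current_frame:
            if buffer:
                events.extend(update_counter(state, buffer, lines))
            buffer = []
            current_frame = p.frame
        buffer.append(p)
    if buffer:
        events.extend(update_counter(state, buffer, lines))
    return CountResult(dict(state.counts), events)
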