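"""Sowing-quality metering: pair tuber counts to scoop casts and classify.

Each seed scoop passing the counting line is one *cast*.  The tubers it
carried are identified by proximity in time on the same side: a tuber count
event is attributed to the nearest scoop count event within a frame window.
A cast with 0 tubers is a *miss*, 1 is *qualified*, and 2 or more is a
*replant* — the three quantities a planter operator watches.  The module
also provides the counting-accuracy arithmetic used to compare algorithmic
tallies against manual ground truth.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .counting import SIDES, CountEvent
from .geometry import CLASS_SCOOP, CLASS_TUBER


@dataclass(frozen=True)
class CastEvent:
    """One scoop cast with the number of tubers attributed to it."""

    scoop_count_frame: int
    side: str
    tuber_count: int

    def __post_init__(self) -> None:
        if self.tuber_count < 0:
            raise ValueError("tuber_count must be non-negative")


@dataclass
class MeteringReport:
    """Missed / qualified / replanted counts per side and overall."""

    per_side: dict[str, dict[str, int]] = field(
        default_factory=lambda: {s: {"missed": 0, "qualified": 0, "replanted": 0} for s in SIDES}
    )

    @property
    def missed(self) -> int:
        return sum(v["missed"] for v in self.per_side.values())

    @property
    def qualified(self) -> int:
        return sum(v["qualified"] for v in self.per_side.values())

    @property
    def replanted(self) -> int:
        return sum(v["replanted"] for v in self.per_side.values())

    @property
    def total(self) -> int:
        return self.missed + self.qualified + self.replanted

    @property
    def rates(self) -> dict[str, float]:
        n = self.total
        if n == 0:
            return {"missed": 0.0, "qualified": 0.0, "replanted": 0.0}
        return {
            "missed": self.missed / n,
            "qualified": self.qualified / n,
            "replanted": self.replanted / n,
        }

    def to_dict(self) -> dict:
        return {
            "per_side": self.per_side,
            "totals": {
                "missed": self.missed,
                "qualified": self.qualified,
                "replanted": self.replanted,
                "casts": self.total,
            },
            "rates": self.rates,
        }


def estimate_window(events: list[CountEvent]) -> int:
    """Default pairing window: half the median inter-scoop frame gap."""
    gaps: list[int] = []
    for side in SIDES:
        frames = sorted(e.frame for e in events if e.side == side and e.class_id == CLASS_SCOOP)
        gaps.extend(b - a for a, b in zip(frames, frames[1:]))
    if not gaps:
        return 0
    return max(1, int(statistics.median(gaps) // 2))


def pair_casts(events: list[CountEvent], window: int) -> list[CastEvent]:
    """Attribute tuber count events to scoop count events.

    Per side, each tuber event is absorbed by the nearest scoop event within
    ``window`` frames; ties between two equidistant scoops go to the earlier
    one.  Tuber events with no scoop in range are dropped (they cannot be
    attributed), and scoops with no tubers become zero-tuber casts.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    casts: list[CastEvent] = []
    for side in SIDES:
        scoops = sorted(
            (e.frame for e in events if e.side == side and e.class_id == CLASS_SCOOP)
        )
        tubers = [e.frame for e in events if e.side == side and e.class_id == CLASS_TUBER]
        loads = [0] * len(scoops)
        for tf in tubers:
            best: int | None = None
            best_dist: int | None = None
            for i, sf in enumerate(scoops):
                dist = abs(tf - sf)
                if dist <= window and (best_dist is None or dist < best_dist):
                    best, best_dist = i, dist
            if best is not None:
                loads[best] += 1
        casts.extend(
            CastEvent(scoop_count_frame=sf, side=side, tuber_count=n)
            for sf, n in zip(scoops, loads)
        )
    return casts


def classify_casts(casts: list[CastEvent]) -> MeteringReport:
    """0 tubers → missed, 1 → qualified, ≥2 → replanted."""
    report = MeteringReport()
    for cast in casts:
        bucket = (
            "missed"
            if cast.tuber_count == 0
            else "qualified" if cast.tuber_count == 1 else "replanted"
        )
        report.per_side[cast.side][bucket] += 1
    return report


def meter_events(events: list[CountEvent], window: int | None = None) -> MeteringReport:
    """Convenience: pair and classify in one call, auto-estimating the window."""
    if window is None:
        window = estimate_window(events)
    return classify_casts(pair_casts(events, window))


def counting_accuracy(manual: int, algorithmic: int) -> float:
    """Percent agreement with a manual count: 100·(1 − |alg − manual|/manual).

    Symmetric in over- and under-counting and 100.0 exactly when the counts
    agree.  Rounded to one decimal, the precision at which such accuracies
    are conventionally reported.
    """
    if manual <= 0:
        raise ValueError("manual count must be positive")
    return round(100.0 * (1.0 - abs(algorithmic - manual) / manual), 1)


def aggregate_accuracy(rows: list[tuple[int, int]]) -> float:
    """Accuracy of the pooled counts: sums over rows, then one accuracy."""
    manual = sum(m for m, _ in rows)
    algorithmic = sum(a for _, a in rows)
    return counting_accuracy(manual, algorithmic)
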