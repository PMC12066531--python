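"""Two-stage confidence-split multi-object tracker (ByteTrack scheme).

Detections of each frame are split by confidence score.  High-confidence
boxes are associated with existing tracks first (stage 1, Hungarian
assignment under IoU cost); tracks left unmatched then get a second chance
against the low-confidence boxes (stage 2), which recovers objects whose
score dipped — e.g. a talc-dusted tuber half-hidden by its scoop — instead
of discarding them.  Unmatched high-confidence boxes seed new tracks;
unmatched tracks are kept as *lost* for a grace period before removal.
Association never crosses classes: a scoop detection cannot extend a tuber
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import kalman
from .geometry import Box, Detection, TrackPoint, iou

_INVALID_COST = 1e6  # sentinel for class-mismatched / forbidden pairs


@dataclass(frozen=True)
class TrackerConfig:
    """Thresholds of the two-stage association.

    ``tau_high``/``tau_low`` split detections into high- and low-confidence
    sets; ``match_thresh_stage{1,2}`` are the maximum admissible IoU *cost*
    (1 − IoU) for a pair to be accepted in each stage; new tracks spawn only
    from unmatched detections scoring at least ``new_track_thresh``; a track
    unseen for more than ``max_lost_frames`` frames is removed.  Defaults
    are the published ByteTrack values.
    """

    tau_high: float = 0.5
    tau_low: float = 0.1
    match_thresh_stage1: float = 0.8
    match_thresh_stage2: float = 0.5
    new_track_thresh: float = 0.6
    max_lost_frames: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_low < self.tau_high <= 1.0:
            raise ValueError("need 0 <= tau_low < tau_high <= 1")
        for name in ("match_thresh_stage1", "match_thresh_stage2", "new_track_thresh"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.max_lost_frames < 0:
            raise ValueError("max_lost_frames must be >= 0")


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    LOST = "lost"
    REMOVED = "removed"


@dataclass
class Track:
    """One tracked identity with its motion belief and lifecycle status."""

    track_id: int
    class_id: int
    state: kalman.KalmanState
    status: TrackStatus
    last_frame: int
    history: list[TrackPoint] = field(default_factory=list)

    def predicted_box(self) -> Box:
        return self.state.box()


def two_stage_associate(
    tracks: list[Track], detections: list[Detection], cfg: TrackerConfig
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate one frame's detections with candidate tracks.

    Returns ``(matches, unmatched_tracks, unmatched_high_detections)`` as
    index lists into the inputs.  Stage 1 assigns detections with
    ``score >= tau_high``; stage 2 offers detections with
    ``tau_low <= score < tau_high`` to the tracks stage 1 left unmatched.
    Low-confidence detections never appear among the unmatched leftovers —
    they either extend a track or are dropped.
    """
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise ValueError(f"detections span multiple frames: {sorted(frames)}")

    high = [i for i, d in enumerate(detections) if d.score >= cfg.tau_high]
    low = [
        i for i, d in enumerate(detections) if cfg.tau_low <= d.score < cfg.tau_high
    ]

    matches, unmatched_tracks, unmatched_high = _match(
        tracks, list(range(len(tracks))), detections, high, cfg.match_thresh_stage1
    )
    stage2_matches, unmatched_tracks, _ = _match(
        tracks, unmatched_tracks, detections, low, cfg.match_thresh_stage2
    )
    return matches + stage2_matches, unmatched_tracks, unmatched_high


def _match(
    tracks: list[Track],
    track_idx: list[int],
    detections: list[Detection],
    det_idx: list[int],
    cost_thresh: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    if not track_idx or not det_idx:
        return [], list(track_idx), list(det_idx)
    cost = np.full((len(track_idx), len(det_idx)), _INVALID_COST)
    for r, ti in enumerate(track_idx):
        tbox = tracks[ti].predicted_box()
        for c, di in enumerate(det_idx):
            d = detections[di]
            if d.class_id != tracks[ti].class_id:
                continue
            cost[r, c] = 1.0 - iou(tbox, d.box)
    rows, cols = linear_sum_assignment(cost)
    matches = [
        (track_idx[r], det_idx[c])
        for r, c in zip(rows, cols)
        if cost[r, c] <= cost_thresh
    ]
    matched_t = {t for t, _ in matches}
    matched_d = {d for _, d in matches}
    return (
        matches,
        [t for t in track_idx if t not in matched_t],
        [d for d in det_idx if d not in matched_d],
    )


class ByteTracker:
    """Stateful frame-by-frame tracker; feed frames in increasing order."""

    def __init__(self, cfg: TrackerConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.tracks: list[Track] = []  # active + lost
        self._next_id = 1
        self._last_frame: int | None = None

    def step(self, frame: int, detections: list[Detection]) -> list[TrackPoint]:
        """Process one frame's detections; returns the points emitted now."""
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing (got {frame} after {self._last_frame})"
            )
        bad = [d.frame for d in detections if d.frame != frame]
        if bad:
            raise ValueError(f"detections carry frame {bad[0]}, expected {frame}")
        self._last_frame = frame

        for t in self.tracks:
            if t.status is TrackStatus.LOST:
                # freeze shape extrapolation while unobserved, as ByteTrack
                # does, so long-lost tracks cannot drift to negative height
                t.state.mean[6] = 0.0
                t.state.mean[7] = 0.0
            t.state = kalman.predict(t.state)

        matches, unmatched_t, unmatched_high = two_stage_associate(
            self.tracks, detections, self.cfg
        )

        emitted: list[TrackPoint] = []
        for ti, di in matches:
            track, det = self.tracks[ti], detections[di]
            track.state = kalman.update(track.state, det.box)
            track.status = TrackStatus.ACTIVE
            track.last_frame = frame
            point = TrackPoint(frame, track.track_id, track.class_id, det.box, det.score)
            track.history.append(point)
            emitted.append(point)

        for ti in unmatched_t:
            track = self.tracks[ti]
            if track.status is not TrackStatus.LOST:
                track.status = TrackStatus.LOST
            if frame - track.last_frame > self.cfg.max_lost_frames:
                track.status = TrackStatus.REMOVED

        for di in unmatched_high:
            det = detections[di]
            if det.score < self.cfg.new_track_thresh:
                continue
            track = Track(
                track_id=self._next_id,
                class_id=det.class_id,
                state=kalman.initiate(det.box),
                status=TrackStatus.ACTIVE,
                last_frame=frame,
            )
            self._next_id += 1
            point = TrackPoint(frame, track.track_id, track.class_id, det.box, det.score)
            track.history.append(point)
            emitted.append(point)
            self.tracks.append(track)

        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.REMOVED]
        emitted.sort(key=lambda p: p.track_id)
        return emitted


def track_sequence(
    detections: list[Detection], cfg: TrackerConfig | None = None
) -> list[TrackPoint]:
    """Run the tracker over a whole detection stream, sorted output."""
    from .io import group_by_frame

    tracker = ByteTracker(cfg)
    points: list[TrackPoint] = []
    for frame, dets in group_by_frame(detections).items():
        points.extend(tracker.step(frame, dets))
    points.sort(key=lambda p: (p.frame, p.track_id))
    return points
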