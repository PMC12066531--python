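"""Synthetic planter scenes: ground-truth trajectories and noisy detections.

The generator emulates a fixed top-down camera over the seed-clearing
position of a two-row potato planter: a 640×480 view of two vertical
columns of seed scoops riding the metering chain downward at constant
speed, each scoop carrying 0, 1 or 2 seed tubers nestled inside its box.
Ground truth is exact per-frame boxes plus each scoop's tuber load; the
detection stream degrades that truth with per-frame misses, multi-frame
gaps (which break tracker identities), Gaussian box jitter and a mixed
high/low confidence score distribution — the failure modes a real detector
exhibits on talc-dusted tubers.

Also houses the dataset utilities for the detector side of the system:
seeded image augmentation (rotate / brightness / noise / flip) and the
7:2:1 train/validation/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counting import LEFT, RIGHT, LineConfig
from .geometry import CLASS_SCOOP, CLASS_TUBER, Box, Detection, TrackPoint


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, kinematics and detector-noise parameters.

    Geometry defaults describe a 640×480 top-down view with scoop columns
    at 30 % and 70 % of the frame width; scoops are 64×48 px, tubers
    22×22 px, spaced 96 px along the chain and descending 4 px/frame
    (≈ 0.8 s between scoops at 30 fps).  ``load_probs`` is the distribution
    of tubers per scoop; noise parameters are per frame and per object.
    """

    frame_width: float = 640.0
    frame_height: float = 480.0
    n_scoops: int = 10  # per side
    scoop_spacing: float = 96.0
    speed: float = 4.0  # px/frame, downward
    scoop_size: tuple[float, float] = (64.0, 48.0)
    tuber_size: tuple[float, float] = (22.0, 22.0)
    column_x: tuple[float, float] = (192.0, 448.0)  # left/right scoop centers
    load_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.1, 1: 0.8, 2: 0.1}
    )
    miss_prob: float = 0.05
    jitter_sd: float = 1.0
    id_gap_prob: float = 0.01  # per frame: start a multi-frame detection gap
    gap_frames: tuple[int, int] = (3, 6)
    high_score_prob: float = 0.85
    high_score_range: tuple[float, float] = (0.6, 0.95)
    low_score_range: tuple[float, float] = (0.15, 0.45)
    drop_prob: float = 1.0  # tuber cast from its scoop after the counting line
    drop_speedup: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.scoop_spacing <= self.scoop_size[1]:
            raise ValueError("scoop_spacing must exceed scoop height")
        probs = np.array(list(self.load_probs.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("load_probs must be a probability distribution")
        for p in (self.miss_prob, self.id_gap_prob, self.high_score_prob, self.drop_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_scoops < 1:
            raise ValueError("need at least one scoop per side")

    def lines(self) -> LineConfig:
        return LineConfig.default(self.frame_width, self.frame_height)


@dataclass(frozen=True)
class ObjectTruth:
    """One simulated object's exact per-frame boxes."""

    object_id: int
    class_id: int
    side: str
    boxes: dict[int, Box]  # frame -> box (only frames fully inside the view)


@dataclass
class SceneTruth:
    """Everything the scene generator knows: trajectories, loads, totals."""

    objects: list[ObjectTruth]
    loads: dict[int, int]  # scoop object_id -> tuber load
    scoop_side: dict[int, str]
    config: SceneConfig

    def expected_counts(self) -> dict[tuple[str, int], int]:
        """Per-side per-class totals a perfect counter would report."""
        out: dict[tuple[str, int], int] = {}
        for obj in self.objects:
            key = (obj.side, obj.class_id)
            out[key] = out.get(key, 0) + 1
        return out

    def expected_metering(self) -> dict[str, dict[str, int]]:
        """Missed/qualified/replanted per side implied by the loads."""
        out = {s: {"missed": 0, "qualified": 0, "replanted": 0} for s in (LEFT, RIGHT)}
        for sid, load in self.loads.items():
            bucket = "missed" if load == 0 else "qualified" if load == 1 else "replanted"
            out[self.scoop_side[sid]][bucket] += 1
        return out

    def track_points(self) -> list[TrackPoint]:
        """Ground-truth trajectories as an oracle track stream."""
        points = [
            TrackPoint(frame, obj.object_id, obj.class_id, box, 1.0)
            for obj in self.objects
            for frame, box in obj.boxes.items()
        ]
        points.sort(key=lambda p: (p.frame, p.track_id))
        return points


def _box_at(cx: float, cy: float, size: tuple[float, float]) -> Box:
    w, h = size
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def _inside(box: Box, cfg: SceneConfig) -> bool:
    return 0 <= box.x1 and box.x2 <= cfg.frame_width and 0 <= box.y1 and box.y2 <= cfg.frame_height


def simulate_scene(cfg: SceneConfig) -> tuple[SceneTruth, list[Detection]]:
    """Generate one scene: exact truth plus the noisy detection stream.

    All randomness flows from ``cfg.seed`` through a single generator, so a
    fixed config reproduces byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    count_y = cfg.lines().count_y

    loads_values = sorted(cfg.load_probs)
    loads_p = np.array([cfg.load_probs[v] for v in loads_values], dtype=float)

    objects: list[ObjectTruth] = []
    loads: dict[int, int] = {}
    scoop_side: dict[int, str] = {}
    next_id = 1

    # Objects enter from above the frame; total span of one column's chain.
    chain_len = (cfg.n_scoops - 1) * cfg.scoop_spacing
    travel = chain_len + cfg.frame_height + cfg.scoop_size[1] + 2 * cfg.speed
    n_frames = int(np.ceil(travel / cfg.speed)) + 1

    for side, col_x in zip((LEFT, RIGHT), cfg.column_x):
        for i in range(cfg.n_scoops):
            scoop_id = next_id
            next_id += 1
            y0 = -cfg.scoop_size[1] / 2 - i * cfg.scoop_spacing - cfg.speed
            load = int(rng.choice(loads_values, p=loads_p))
            loads[scoop_id] = load
            scoop_side[scoop_id] = side

            scoop_boxes: dict[int, Box] = {}
            for t in range(n_frames):
                box = _box_at(col_x, y0 + cfg.speed * t, cfg.scoop_size)
                if _inside(box, cfg):
                    scoop_boxes[t] = box
            objects.append(ObjectTruth(scoop_id, CLASS_SCOOP, side, scoop_boxes))

            # Tubers ride inside the scoop; with two, they sit side by side.
            offsets = [(0.0, 2.0)] if load == 1 else [(-13.0, 2.0), (13.0, 2.0)]
            for dx, dy in offsets[:load] if load else []:
                tuber_id = next_id
                next_id += 1
                dropped = rng.random() < cfg.drop_prob
                tuber_boxes: dict[int, Box] = {}
                extra = 0.0
                for t in range(n_frames):
                    cy = y0 + dy + cfg.speed * t + extra
                    # Once cast past the counting line, the tuber falls free
                    # of the scoop, faster than the chain.
                    if dropped and cy > count_y + 40.0:
                        extra += cfg.speed * (cfg.drop_speedup - 1.0)
                    box = _box_at(col_x + dx, cy, cfg.tuber_size)
                    if _inside(box, cfg):
                        tuber_boxes[t] = box
                objects.append(ObjectTruth(tuber_id, CLASS_TUBER, side, tuber_boxes))

    truth = SceneTruth(objects, loads, scoop_side, cfg)

    detections: list[Detection] = []
    gap_until: dict[int, int] = {}
    for obj in objects:
        for frame in sorted(obj.boxes):
            if frame < gap_until.get(obj.object_id, -1):
                continue
            if rng.random() < cfg.id_gap_prob:
                gap_until[obj.object_id] = frame + int(rng.integers(*cfg.gap_frames, endpoint=True))
                continue
            if rng.random() < cfg.miss_prob:
                continue
            box = obj.boxes[frame]
            if cfg.jitter_sd > 0:
                j = rng.normal(0.0, cfg.jitter_sd, size=4)
                x1, y1 = box.x1 + j[0], box.y1 + j[1]
                x2, y2 = max(box.x2 + j[2], x1 + 1.0), max(box.y2 + j[3], y1 + 1.0)
                box = Box(x1, y1, x2, y2)
            if rng.random() < cfg.high_score_prob:
                score = float(rng.uniform(*cfg.high_score_range))
            else:
                score = float(rng.uniform(*cfg.low_score_range))
            detections.append(Detection(frame, obj.class_id, score, box))
    detections.sort(key=lambda d: d.frame)
    return truth, detections


# --------------------------------------------------------------------------
# dataset utilities: augmentation primitives and the 7:2:1 split
# --------------------------------------------------------------------------

AUGMENT_OPS = ("rotate", "brightness", "noise", "flip")


def rotate90(image: np.ndarray, k: int, boxes: list[Box] | None = None):
    """Rotate an (H, W[, C]) image by k·90° counter-clockwise, with boxes."""
    rotated = np.rot90(image, k=k % 4, axes=(0, 1))
    if boxes is None:
        return rotated
    h, w = image.shape[0], image.shape[1]
    out = boxes
    for _ in range(k % 4):
        # 90° CCW: (x, y) -> (y, w - x); box corners swap accordingly
        out = [Box(b.y1, w - b.x2, b.y2, w - b.x1) for b in out]
        h, w = w, h
    return rotated, out


def flip_horizontal(image: np.ndarray, boxes: list[Box] | None = None):
    flipped = image[:, ::-1].copy()
    if boxes is None:
        return flipped
    w = image.shape[1]
    return flipped, [Box(w - b.x2, b.y1, w - b.x1, b.y2) for b in boxes]


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    return np.clip(image.astype(float) * factor, 0.0, 255.0)


def add_noise(image: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(image.astype(float) + rng.normal(0.0, sd, image.shape), 0.0, 255.0)


def augment_image(image: np.ndarray, ops, seed: int = 0) -> np.ndarray:
    """Apply a subset of {rotate, brightness, noise, flip} with seeded params.

    Operators run in the fixed order above; an empty subset is the identity.
    """
    ops = list(ops)
    unknown = [o for o in ops if o not in AUGMENT_OPS]
    if unknown:
        raise ValueError(f"unknown augmentation op(s): {unknown}")
    rng = np.random.default_rng(seed)
    out = np.asarray(image)
    if "rotate" in ops:
        out = rotate90(out, k=int(rng.integers(1, 4)))
    if "brightness" in ops:
        out = adjust_brightness(out, factor=float(rng.uniform(0.6, 1.4)))
    if "noise" in ops:
        out = add_noise(out, sd=8.0, rng=rng)
    if "flip" in ops:
        out = flip_horizontal(out)
    return out


def split_dataset(
    n_items: int, seed: int = 0, ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled 7:2:1 train/validation/test index split.

    Sizes are round(r1·n) and round(r2·n) with the remainder as test; the
    three sets are disjoint and cover range(n).
    """
    if n_items < 10:
        raise ValueError("need at least 10 items to split 7:2:1")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    n_train = int(round(ratios[0] * n_items))
    n_val = int(round(ratios[1] * n_items))
    perm = np.random.default_rng(seed).permutation(n_items)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
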