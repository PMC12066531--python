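"""Detection metrics: precision, recall, AP, mAP@0.5 and mAP@0.5:0.95.

Detections are ranked by confidence and matched greedily to ground truth at
a given IoU threshold; the resulting ranked TP/FP flags define a
precision-recall curve whose area — integrated over the monotone precision
envelope, all recall points — is the class's average precision.  mAP is the
mean over classes, and the stricter variant additionally averages over IoU
thresholds 0.50, 0.55, …, 0.95.

A true-negative count is carried in :class:`MatchOutcome` for completeness
but plays no role in any of the computed metrics (there is no meaningful
"correctly detected background" event in box detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, Detection, iou

IOU_RANGE = tuple(np.arange(0.5, 0.96, 0.05).round(2))


@dataclass
class MatchOutcome:
    """Greedy matching result for one class at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    flags: list[bool] = field(default_factory=list)  # per ranked detection: TP?
    tn: int = 0  # carried for completeness; unused by every metric


def match_detections(
    detections: list[tuple[float, Box]], truths: list[Box], iou_thresh: float
) -> MatchOutcome:
    """Match score-ranked detections of one class against its truth boxes.

    Each detection, in descending score order, claims the unmatched truth
    box of highest IoU provided IoU >= ``iou_thresh`` (a TP); otherwise it
    is a FP.  Truth boxes left unclaimed are FNs.
    """
    scores = [s for s, _ in detections]
    if scores != sorted(scores, reverse=True):
        raise ValueError("detections must be sorted by descending score")
    matched = [False] * len(truths)
    flags: list[bool] = []
    for _score, dbox in detections:
        best, best_iou = -1, iou_thresh
        for ti, tbox in enumerate(truths):
            if matched[ti]:
                continue
            v = iou(dbox, tbox)
            if v >= best_iou:
                best, best_iou = ti, v
        if best >= 0:
            matched[best] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return MatchOutcome(tp=tp, fp=len(flags) - tp, fn=len(truths) - tp, flags=flags)


def precision_recall(outcome: MatchOutcome) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); vacuous denominators give 1.0."""
    p = outcome.tp / (outcome.tp + outcome.fp) if outcome.tp + outcome.fp else 1.0
    r = outcome.tp / (outcome.tp + outcome.fn) if outcome.tp + outcome.fn else 1.0
    return p, r


def average_precision(flags: list[bool], n_truth: int) -> float:
    """Area under the monotone P-R envelope of a ranked TP/FP flag list."""
    if n_truth < 0:
        raise ValueError("n_truth must be non-negative")
    if n_truth == 0:
        return 1.0 if not any(flags) else 0.0
    if not flags:
        return 0.0
    tp_cum = np.cumsum(flags)
    precisions = tp_cum / np.arange(1, len(flags) + 1)
    recalls = tp_cum / n_truth
    # monotone non-increasing precision envelope, right to left
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(envelope, recalls):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_ap(aps: dict[int, float] | list[float]) -> float:
    """Mean of per-class APs."""
    values = list(aps.values()) if isinstance(aps, dict) else list(aps)
    if not values:
        raise ValueError("no classes to average over")
    return float(np.mean(values))


def evaluate_detections(
    detections: list[Detection],
    truths: list[tuple[int, int, Box]],
    iou_thresholds: tuple[float, ...] = (0.5,),
) -> dict:
    """Full evaluation of a detection set against (frame, class, box) truths.

    Matching is per frame and per class; ranked flags are pooled across
    frames before the P-R integration, as the standard evaluators do.
    Classes absent from the ground truth are excluded from mAP.  Returns
    per-class precision/recall/AP at the first threshold plus mAP at every
    threshold and their mean.
    """
    classes = sorted({c for _f, c, _b in truths})
    if not classes:
        raise ValueError("ground truth contains no boxes")
    frames = sorted({d.frame for d in detections} | {f for f, _c, _b in truths})

    per_class: dict[int, dict] = {}
    maps: dict[float, float] = {}
    for thresh in iou_thresholds:
        aps: dict[int, float] = {}
        for cls in classes:
            ranked: list[tuple[float, bool]] = []
            tp = fp = fn = 0
            for frame in frames:
                dets = sorted(
                    ((d.score, d.box) for d in detections if d.frame == frame and d.class_id == cls),
                    key=lambda t: -t[0],
                )
                tboxes = [b for f, c, b in truths if f == frame and c == cls]
                outcome = match_detections(dets, tboxes, thresh)
                tp += outcome.tp
                fp += outcome.fp
                fn += outcome.fn
                ranked.extend(zip((s for s, _ in dets), outcome.flags))
            ranked.sort(key=lambda t: -t[0])
            flags = [f for _s, f in ranked]
            n_truth = tp + fn
            aps[cls] = average_precision(flags, n_truth)
            if thresh == iou_thresholds[0]:
                outcome_all = MatchOutcome(tp=tp, fp=fp, fn=fn)
                p, r = precision_recall(outcome_all)
                per_class[cls] = {"precision": p, "recall": r, "ap": aps[cls]}
        maps[thresh] = mean_ap(aps)
    result = {
        "per_class": per_class,
        "map_per_threshold": {f"{t:.2f}": v for t, v in maps.items()},
        "map_50": maps[iou_thresholds[0]],
    }
    if len(iou_thresholds) > 1:
        result["map_50_95"] = float(np.mean(list(maps.values())))
    return result
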