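# planterkit

Computational core of a metering system for potato precision planters.

A planter lifts seed tubers with a chain of seed scoops; a fixed top-down
camera over the seed-clearing position watches the two scoop columns move
through the frame. Given a per-frame detection stream (seed scoops and seed
tubers, the "red" and "green" classes), `planterkit` answers the questions an
operator cares about: *how many* scoops and tubers passed, and *how well* each
scoop was loaded — a cast with 0 tubers is a **miss**, 1 is **qualified**, and
≥ 2 is a **replant**.

The package implements, as pure library code over detection streams:

- **Two-stage confidence-split tracking** (the ByteTrack scheme). Per frame,
  detections are split at a confidence threshold; high-confidence boxes are
  matched to predicted track positions by Hungarian assignment under IoU cost,
  and the tracks left over get a second association pass against the
  low-confidence boxes. Motion is an 8-state constant-velocity Kalman filter
  over (center, aspect, height).
- **Dual-line crossing counting.** Because tracker ids can switch mid-scene, a
  target is counted only when the *same* id crosses an entry line and then a
  counting line moving downward, with left/right columns tallied independently
  and a global `list_sum` guard forbidding double counts.
- **Sowing metering.** Tuber count events are attributed to the nearest scoop
  count event in time (same side, bounded window) and each cast is classified
  missed / qualified / replanted. Counting accuracy against a manual count is
  `100·(1 − |alg − manual| / manual)`.
- **LAMP pruning scores.** For a layer's weights sorted ascending by
  magnitude, `score(u; W) = W[u]² / Σ_{v≥u} W[v]²`. Scores are layer-scale
  invariant, strictly monotone in |W|, and each layer's largest weight scores
  exactly 1 — so a single global sparsity target yields per-layer sparsities
  automatically and can never empty a layer.
- **RepConv / PConv / FasterBlock operators.** Reference numpy forward passes
  and the exact algebraic fusion of a multi-branch RepConv (3×3 + 1×1 +
  identity, each batch-normalized) into one 3×3 convolution with bias, plus
  parameter accounting.
- **Detection metrics.** Greedy IoU matching, precision/recall, all-point AP,
  mAP@0.5 and mAP@0.5:0.95.
- **A scene simulator** producing exact ground truth (trajectories, per-scoop
  tuber loads) and detection streams with realistic detector noise — misses,
  identity-breaking gaps, box jitter, mixed-confidence scores — so the whole
  pipeline is testable without a camera or a trained detector.

## Worked example

Simulate a scene (10 scoops per column, default detector noise), track, count
and meter it in one command:

```sh
planterkit run --seed 7 --out-dir out/
```

prints

```json
{
  "counts": {
    "left":  {"scoop": 10, "tuber": 9},
    "right": {"scoop": 10, "tuber": 9}
  },
  "metering": {"missed": 4, "qualified": 14, "replanted": 2, "casts": 20},
  "truth_counts": {
    "left":  {"scoop": 10, "tuber": 9},
    "right": {"scoop": 10, "tuber": 9}
  }
}
```

Reading this: all 20 simulated scoops and all 18 tubers were counted despite
the injected detection noise (`counts` equals `truth_counts`); of the 20
casts, 4 scoops came up empty, 14 carried exactly one tuber and 2 carried
two. Artifacts land in `out/`: `detections.csv` and `tracks.csv` (MOT-style
CSV with a trailing class column), `counts.json` (tallies + event log),
`metering.json`, `truth.json` and the combined `report.json`.

Each stage is also available separately — `simulate`, `track`, `count`,
`meter`, `accuracy`, `evaluate` (mAP against YOLO-dialect labels), `lamp`
(pruning masks for a `.npz` of weight tensors) and `fuse` (RepConv branch
fusion with a numerical equivalence report). For example, the counting
accuracy table for manually verified videos:

```sh
planterkit accuracy counts.csv   # columns: manual,algorithmic
```

prints per-row accuracies and the pooled aggregate.

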