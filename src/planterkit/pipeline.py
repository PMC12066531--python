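"""End-to-end pipeline: simulate/load detections → track → count → meter.

Each stage writes its artifact (detection CSV, track CSV, JSON reports) so
any stage can be re-run in isolation from the previous stage's file; the
whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io, metering, simulate, tracking
from .counting import LineConfig, count_sequence
from .geometry import CLASS_NAMES

log = logging.getLogger("planterkit")


@dataclass
class RunConfig:
    """Bundle of stage configs for one pipeline run."""

    tracker: tracking.TrackerConfig = field(default_factory=tracking.TrackerConfig)
    scene: simulate.SceneConfig = field(default_factory=simulate.SceneConfig)
    lines: LineConfig | None = None  # defaults to mid-window placement
    pairing_window: int | None = None  # None = auto-estimate
    detections_path: str | None = None  # if set, read instead of simulating
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        scene_kwargs = dict(raw.get("scene", {}))
        scene_kwargs.setdefault("seed", seed)
        for key in ("scoop_size", "tuber_size", "column_x", "gap_frames",
                    "high_score_range", "low_score_range"):
            if key in scene_kwargs:
                scene_kwargs[key] = tuple(scene_kwargs[key])
        if "load_probs" in scene_kwargs:
            scene_kwargs["load_probs"] = {
                int(k): float(v) for k, v in scene_kwargs["load_probs"].items()
            }
        cfg = cls(
            tracker=tracking.TrackerConfig(**raw.get("tracker", {})),
            scene=simulate.SceneConfig(**scene_kwargs),
            lines=LineConfig(**raw["lines"]) if "lines" in raw else None,
            pairing_window=raw.get("pairing_window"),
            detections_path=raw.get("detections_path"),
            seed=seed,
        )
        return cfg


def _counts_report(result, lines: LineConfig) -> dict:
    report = {
        side: {name: 0 for name in CLASS_NAMES.values()} for side in ("left", "right")
    }
    for (side, class_id), n in result.counts.items():
        report[side][CLASS_NAMES[class_id]] = n
    report["events"] = [asdict(e) for e in result.events]
    report["lines"] = {
        "entry_y": lines.entry_y, "count_y": lines.count_y, "split_x": lines.split_x
    }
    return report


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage, writing artifacts under ``out_dir``.

    Returns the combined report: counted totals, metering classification
    and, when the input was simulated, the ground truth for comparison.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if cfg.detections_path:
        log.info("reading detections from %s", cfg.detections_path)
        detections = io.read_detections(cfg.detections_path)
        io.write_detections(out / "detections.csv", detections)
    else:
        log.info("simulating scene (seed %d)", cfg.scene.seed)
        truth, detections = simulate.simulate_scene(cfg.scene)
        io.write_detections(out / "detections.csv", detections)
        (out / "truth.json").write_text(json.dumps(_truth_report(truth), indent=2))

    log.info("tracking %d detections", len(detections))
    points = tracking.track_sequence(detections, cfg.tracker)
    io.write_tracks(out / "tracks.csv", points)

    lines = cfg.lines or LineConfig.default(cfg.scene.frame_width, cfg.scene.frame_height)
    result = count_sequence(points, lines)
    counts_report = _counts_report(result, lines)
    (out / "counts.json").write_text(json.dumps(counts_report, indent=2))

    meter_report = metering.meter_events(result.events, cfg.pairing_window).to_dict()
    (out / "metering.json").write_text(json.dumps(meter_report, indent=2))

    report = {"counts": counts_report, "metering": meter_report}
    if truth is not None:
        report["truth"] = _truth_report(truth)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _truth_report(truth: simulate.SceneTruth) -> dict:
    counts = {
        side: {name: 0 for name in CLASS_NAMES.values()} for side in ("left", "right")
    }
    for (side, class_id), n in truth.expected_counts().items():
        counts[side][CLASS_NAMES[class_id]] = n
    return {
        "counts": counts,
        "metering": truth.expected_metering(),
        "loads": {str(k): v for k, v in truth.loads.items()},
    }
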