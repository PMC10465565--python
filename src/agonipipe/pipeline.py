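"""End-to-end orchestration: segmentation -> tracking -> classification ->
hierarchy analytics, with config handling and provenance metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, LightSchedule, classify_clip, \
    interactions_to_csv
from .detections import read_clip_detections
from .hierarchy import build_sociomatrix, david_scores, randomized_elo
from .motion import MagnitudeSeries, intervals_to_csv, segment_actions
from .tracker import TrackerConfig, anchor_fraction, track_clip, tracks_to_csv

log = logging.getLogger("agonipipe")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the light schedule and global seed.

    Defaults are the pipeline's operating constants: anchor confidence 0.98,
    proximity 50 px, speed threshold 5 px/frame, 10-frame rule windows,
    60-s merge gap, 1.2 retention magnitude, Elo init 1000 with K=100, and
    1000 randomization repetitions.
    """

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    elo_reps: int = 1000
    elo_variant: str = "paper"
    include_dark: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.elo_reps <= 0:
            raise ValueError("elo_reps must be positive")
        if self.elo_variant not in ("paper", "standard"):
            raise ValueError("elo_variant must be 'paper' or 'standard'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "tracker" in doc:
            kwargs["tracker"] = TrackerConfig(**doc["tracker"])
        if "classifier" in doc:
            kwargs["classifier"] = ClassifierConfig(**doc["classifier"])
        if "schedule" in doc:
            from datetime import time
            sched = {
                k: time.fromisoformat(v) if isinstance(v, str) else v
                for k, v in doc["schedule"].items()
            }
            kwargs["schedule"] = LightSchedule(**sched)
        for key in ("elo_reps", "elo_variant", "include_dark", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, input_dir, out_dir) -> Path:
    """Run every stage over an input directory and write all artifacts.

    Expects ``magnitude.csv`` (t_offset_s, magnitude) and one or more
    ``clip*.json`` clip-detection files in ``input_dir``; an optional
    ``clips.csv`` (clip, start_s[, start_iso]) maps clip files to absolute
    start times for timestamping and dark-period flagging.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mag_path = input_dir / "magnitude.csv"
    if mag_path.exists():
        series = MagnitudeSeries.from_csv(mag_path)
        intervals = segment_actions(series)
        intervals_to_csv(intervals, out_dir / "intervals.csv")
        log.info("segmentation: %d action intervals", len(intervals))

    clip_paths = sorted(input_dir.glob("clip*.json"))
    if not clip_paths:
        raise FileNotFoundError(
            f"tracking stage: no clip*.json detection files in {input_dir}")

    manifest = {}
    manifest_path = input_dir / "clips.csv"
    if manifest_path.exists():
        df = pd.read_csv(manifest_path)
        for r in df.itertuples():
            start_iso = getattr(r, "start_iso", None)
            manifest[str(r.clip)] = (
                float(r.start_s),
                datetime.fromisoformat(start_iso) if start_iso else None,
            )

    all_interactions = []
    for clip_path in clip_paths:
        frames = read_clip_detections(clip_path)
        tracks = track_clip(frames, config.tracker)
        tracks_to_csv(tracks, out_dir / f"tracks_{clip_path.stem}.csv")
        start_s, start_dt = manifest.get(clip_path.name, (0.0, None))
        interactions = classify_clip(
            tracks, config.classifier,
            clip_start=start_dt,
            schedule=config.schedule if start_dt else None,
        )
        interactions = [
            dataclasses.replace(ia, timestamp_s=ia.timestamp_s + start_s)
            for ia in interactions
        ]
        log.info("clip %s: anchors %.2f, %d interactions", clip_path.name,
                 anchor_fraction(frames, config.tracker), len(interactions))
        all_interactions.extend(interactions)
    all_interactions.sort(key=lambda i: i.timestamp_s)
    interactions_to_csv(all_interactions, out_dir / "interactions.csv")

    animals = sorted({i.initiator_id for i in all_interactions}
                     | {i.receiver_id for i in all_interactions})
    if animals:
        s = build_sociomatrix(all_interactions, animals,
                              include_dark=config.include_dark)
        s.to_csv(out_dir / "sociomatrix.csv")
        elo = randomized_elo(s, config.elo_reps, config.seed,
                             config.elo_variant)
        david = david_scores(s)
        pd.DataFrame({"animal": animals,
                      "elo": [elo[a] for a in animals],
                      "norm_david": [david[a] for a in animals]}
                     ).to_csv(out_dir / "ratings.csv", index=False)

    provenance = {
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "n_clips": len(clip_paths),
        "n_interactions": len(all_interactions),
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out_dir
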