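"""Data model and JSON I/O for per-frame animal detections.

Upstream of this package, a keypoint detector proposes bounding boxes plus
three keypoints per animal (nose tip, shoulder, tail base) and a re-id
classifier appends, for each box, a probability over the four paint markings
used to identify the animals (circle, line, tail, neck).  One JSON file per
action clip stores all of it; this module reads, validates and writes that
dialect and provides the IoU utility used throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

MARKINGS = ("circle", "line", "tail", "neck")
DEFAULT_FPS = 25

BBox = tuple[float, float, float, float]  # x_min, y_min, x_max, y_max


class SchemaError(ValueError):
    """A clip-detection file violates the expected schema."""


@dataclass(frozen=True)
class Detection:
    """One candidate animal in one frame."""

    bbox: BBox
    det_conf: float
    keypoints: tuple[tuple[float, float, float], ...]  # 3 x (x, y, conf)
    id_probs: Mapping[str, float]

    def __post_init__(self):
        x1, y1, x2, y2 = self.bbox
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not 0.0 <= self.det_conf <= 1.0:
            raise ValueError("det_conf outside [0, 1]")
        if len(self.keypoints) != 3:
            raise ValueError("expected 3 keypoints (nose, shoulder, tail)")
        if set(self.id_probs) != set(MARKINGS):
            raise ValueError(f"id_probs must cover {MARKINGS}")
        if abs(sum(self.id_probs.values()) - 1.0) > 1e-6:
            raise ValueError("id_probs must sum to 1")

    @property
    def centroid(self) -> tuple[float, float]:
        x1, y1, x2, y2 = self.bbox
        return (x1 + x2) / 2.0, (y1 + y2) / 2.0

    @property
    def best_id(self) -> str:
        return max(MARKINGS, key=lambda m: self.id_probs[m])


@dataclass(frozen=True)
class FrameDetections:
    frame_index: int
    detections: tuple[Detection, ...]

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def compute_iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes on real coordinates.

    Degenerate (zero-area) boxes yield 0 with a warning; disjoint boxes 0.
    """
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        warnings.warn("degenerate box in IoU computation")
        return 0.0
    ix = min(ax2, bx2) - max(ax1, bx1)
    iy = min(ay2, by2) - max(ay1, by1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (area_a + area_b - inter)


def _parse_detection(d: dict, where: str) -> Detection:
    try:
        return Detection(
            bbox=tuple(float(v) for v in d["bbox"]),
            det_conf=float(d["score"]),
            keypoints=tuple(tuple(float(v) for v in kp)
                            for kp in d["keypoints"]),
            id_probs={k: float(v) for k, v in d["id_probs"].items()},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def read_clip_detections(path) -> list[FrameDetections]:
    """Load a clip-detection JSON file, validating as it goes.

    Schema: {"clip_id", "fps", "frames": [{"frame": int, "detections":
    [{"bbox": [x1,y1,x2,y2], "score": f, "keypoints": [[x,y,c]x3],
    "id_probs": {marking: f}}]}]} with strictly increasing frame indices.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if "frames" not in doc:
        raise SchemaError(f"{path}: missing 'frames'")
    frames: list[FrameDetections] = []
    last = -1
    for entry in doc["frames"]:
        if "frame" not in entry:
            raise SchemaError(f"{path}: frame entry without 'frame' index")
        idx = int(entry["frame"])
        if idx <= last:
            raise SchemaError(f"{path}: frame {idx} not strictly increasing")
        last = idx
        dets = tuple(
            _parse_detection(d, f"{path} frame {idx}")
            for d in entry.get("detections", ())
        )
        frames.append(FrameDetections(idx, dets))
    return frames


def write_clip_detections(
    frames: Sequence[FrameDetections], path,
    clip_id: str = "clip", fps: int = DEFAULT_FPS,
) -> None:
    doc = {
        "clip_id": clip_id,
        "fps": fps,
        "frames": [
            {
                "frame": f.frame_index,
                "detections": [
                    {
                        "bbox": list(d.bbox),
                        "score": d.det_conf,
                        "keypoints": [list(kp) for kp in d.keypoints],
                        "id_probs": {m: d.id_probs[m] for m in MARKINGS},
                    }
                    for d in f.detections
                ],
            }
            for f in frames
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def centroids_to_csv(frames: Sequence[FrameDetections], path) -> None:
    rows = [
        (f.frame_index, d.best_id, *d.centroid, "detected")
        for f in frames for d in f.detections
    ]
    pd.DataFrame(rows, columns=["frame", "id", "x", "y", "flag"]).to_csv(
        path, index=False)
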