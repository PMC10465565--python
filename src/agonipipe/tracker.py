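"""Fixed-population multi-object tracking.

Exactly four marked animals are present in every frame of a clip; the
detector and re-identifier are imperfect (missed boxes, occluded markings,
spurious boxes around litters of kits).  Rather than a generic tracker built
for objects that enter and leave the scene, this module exploits the fixed
population through seven sequential steps:

1. anchor assignment — boxes identified with marking confidence >= 0.98 are
   committed to the matching identity track;
2. spatio-temporal filtering — anchors with no nearby anchor of the same
   track within +/-2 frames are discarded as likely misidentifications;
3. assignment by elimination — in frames where three identities are anchored
   and exactly one box is left, that box joins the missing track;
4. greedy tracklet gap filling — gaps are bridged by nearest-centroid chains
   of unassigned boxes, accepted only when the best chain's mean identity
   confidence clearly beats the runner-up;
5. deduplication — a box claimed by several tracks stays with the most
   confident one;
6. linear interpolation of remaining gaps (interpolated points are flagged
   as computer-generated);
7. outlier removal and rolling-mean smoothing of the centroid sequences.

All thresholds live in :class:`TrackerConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .detections import MARKINGS, Detection, FrameDetections

SourceFlag = str  # anchor | eliminated | tracklet | interpolated | smoothed


@dataclass(frozen=True)
class TrackerConfig:
    anchor_conf: float = 0.98            # inclusive marking-confidence bound
    neighbor_frames: int = 2             # temporal reach of the step-2 filter
    neighbor_dist_px: float = 60.0       # spatial reach of the step-2 filter
    tracklet_margin: float = 0.15        # step-4 mean-confidence margin
    smooth_window_frames: int = 13       # ~0.5 s at 25 fps
    outlier_speed_px_per_frame: float = 80.0

    def __post_init__(self):
        if not 0.5 < self.anchor_conf <= 1.0:
            raise ValueError("anchor_conf must lie in (0.5, 1]")
        for name in ("neighbor_frames", "neighbor_dist_px", "tracklet_margin",
                     "smooth_window_frames", "outlier_speed_px_per_frame"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    x: float
    y: float
    source: SourceFlag


@dataclass
class Track:
    animal_id: str
    points: list[TrackPoint] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.points])


class _Assignment:
    """Mutable tracker state: per identity, frame -> detection index."""

    def __init__(self, frames: Sequence[FrameDetections]):
        self.frames = list(frames)
        self.frame_index = [f.frame_index for f in self.frames]
        self.slots: dict[str, dict[int, tuple[int, SourceFlag]]] = {
            m: {} for m in MARKINGS}

    def det(self, fpos: int, dpos: int) -> Detection:
        return self.frames[fpos].detections[dpos]

    def centroid(self, identity: str, fpos: int):
        dpos, _ = self.slots[identity][fpos]
        return self.det(fpos, dpos).centroid

    def assigned_in_frame(self, fpos: int) -> set[int]:
        return {
            slot[fpos][0]
            for slot in self.slots.values() if fpos in slot
        }

    def unassigned_in_frame(self, fpos: int) -> list[int]:
        taken = self.assigned_in_frame(fpos)
        return [i for i in range(len(self.frames[fpos].detections))
                if i not in taken]

    @property
    def n_detections(self) -> int:
        return sum(len(f.detections) for f in self.frames)

    def n_assigned(self) -> int:
        return sum(len(slot) for slot in self.slots.values())


def _dist(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def assign_anchors(frames: Sequence[FrameDetections],
                   cfg: TrackerConfig) -> _Assignment:
    """Step 1: commit high-confidence identifications to their tracks.

    When two boxes in one frame claim the same identity at or above the
    anchor threshold, the higher probability wins and the other stays
    unassigned.
    """
    st = _Assignment(frames)
    for fpos, frame in enumerate(st.frames):
        best: dict[str, tuple[float, int]] = {}
        for dpos, det in enumerate(frame.detections):
            m = det.best_id
            p = det.id_probs[m]
            if p >= cfg.anchor_conf and (m not in best or p > best[m][0]):
                best[m] = (p, dpos)
        for m, (_, dpos) in best.items():
            st.slots[m][fpos] = (dpos, "anchor")
    return st


def spatiotemporal_filter(st: _Assignment, cfg: TrackerConfig) -> _Assignment:
    """Step 2: drop anchors that are temporally or spatially isolated.

    A correctly identified animal should be re-identifiable within the
    preceding/following ``neighbor_frames`` frames at a nearby position.
    """
    for m, slot in st.slots.items():
        keep = {}
        fposes = sorted(slot)
        for fpos in fposes:
            c = st.centroid(m, fpos)
            ok = any(
                g != fpos and abs(g - fpos) <= cfg.neighbor_frames
                and _dist(c, st.centroid(m, g)) <= cfg.neighbor_dist_px
                for g in fposes
                if abs(g - fpos) <= cfg.neighbor_frames
            )
            if ok:
                keep[fpos] = slot[fpos]
        st.slots[m] = keep
    return st


def eliminate_assign(st: _Assignment) -> _Assignment:
    """Step 3: in frames with three identified animals and a single leftover
    box, assign that box to the missing identity."""
    for fpos in range(len(st.frames)):
        present = [m for m in MARKINGS if fpos in st.slots[m]]
        if len(present) != 3:
            continue
        free = st.unassigned_in_frame(fpos)
        if len(free) != 1:
            continue
        missing = next(m for m in MARKINGS if m not in present)
        st.slots[missing][fpos] = (free[0], "eliminated")
    return st


def _gaps(slot: dict[int, tuple], n_frames: int) -> list[tuple[int, int]]:
    """Interior gaps as (entry_fpos, exit_fpos) pairs of assigned frames."""
    fposes = sorted(slot)
    return [
        (a, b)
        for a, b in zip(fposes, fposes[1:])
        if b - a > 1
    ]


def fill_gaps_greedy(st: _Assignment, cfg: TrackerConfig) -> _Assignment:
    """Step 4: bridge gaps with greedy nearest-centroid tracklets.

    Up to four candidate chains are seeded from the unassigned boxes of the
    first gap frame nearest the entry anchor; each chain then consumes the
    nearest unassigned box frame by frame (frames without any candidate box
    are skipped).  The chain whose mean identity confidence for the target
    animal exceeds the runner-up's by at least ``tracklet_margin`` is
    accepted; a lone candidate competes against 0.
    """
    for m in MARKINGS:
        slot = st.slots[m]
        for entry, exit_ in _gaps(slot, len(st.frames)):
            gap = range(entry + 1, exit_)
            first = next((f for f in gap if st.unassigned_in_frame(f)), None)
            if first is None:
                continue
            entry_c = st.centroid(m, entry)
            seeds = sorted(
                st.unassigned_in_frame(first),
                key=lambda d: _dist(entry_c, st.det(first, d).centroid),
            )[:4]
            candidates = []
            for seed in seeds:
                chain = [(first, seed)]
                pos = st.det(first, seed).centroid
                for f in range(first + 1, exit_):
                    free = st.unassigned_in_frame(f)
                    if not free:
                        continue
                    d = min(free, key=lambda i: _dist(
                        pos, st.det(f, i).centroid))
                    chain.append((f, d))
                    pos = st.det(f, d).centroid
                conf = float(np.mean(
                    [st.det(f, d).id_probs[m] for f, d in chain]))
                candidates.append((conf, chain))
            candidates.sort(key=lambda c: -c[0])
            best = candidates[0]
            second = candidates[1][0] if len(candidates) > 1 else 0.0
            if best[0] - second >= cfg.tracklet_margin:
                for f, d in best[1]:
                    slot[f] = (d, "tracklet")
    return st


def dedup_boxes(st: _Assignment) -> _Assignment:
    """Step 5: a detection owned by several tracks stays with the track of
    largest identity confidence; ties go to the track whose previous point is
    nearest, then to the alphabetically first identity."""
    for fpos in range(len(st.frames)):
        owners: dict[int, list[str]] = {}
        for m in MARKINGS:
            if fpos in st.slots[m]:
                owners.setdefault(st.slots[m][fpos][0], []).append(m)
        for dpos, ms in owners.items():
            if len(ms) < 2:
                continue
            det = st.det(fpos, dpos)

            def prev_dist(m: str) -> float:
                prior = [f for f in st.slots[m] if f < fpos]
                if not prior:
                    return float("inf")
                return _dist(det.centroid, st.centroid(m, max(prior)))

            winner = min(
                ms, key=lambda m: (-det.id_probs[m], prev_dist(m), m))
            for m in ms:
                if m != winner:
                    del st.slots[m][fpos]
    return st


def interpolate_gaps(st: _Assignment) -> dict[str, list[TrackPoint]]:
    """Step 6: produce one point per frame per identity.

    Interior gaps are linearly interpolated between the flanking centroids;
    leading/trailing gaps are filled by constant extension of the nearest
    known centroid.  All generated points are flagged ``interpolated``.
    """
    n = len(st.frames)
    tracks: dict[str, list[TrackPoint]] = {}
    for m in MARKINGS:
        slot = st.slots[m]
        pts: list[TrackPoint] = []
        fposes = sorted(slot)
        if not fposes:
            raise ValueError(
                f"track '{m}' has no assigned detections; cannot complete")
        for fpos in range(n):
            fi = st.frame_index[fpos]
            if fpos in slot:
                x, y = st.centroid(m, fpos)
                pts.append(TrackPoint(fi, x, y, slot[fpos][1]))
            elif fpos < fposes[0]:
                x, y = st.centroid(m, fposes[0])
                pts.append(TrackPoint(fi, x, y, "interpolated"))
            elif fpos > fposes[-1]:
                x, y = st.centroid(m, fposes[-1])
                pts.append(TrackPoint(fi, x, y, "interpolated"))
            else:
                lo = max(f for f in fposes if f < fpos)
                hi = min(f for f in fposes if f > fpos)
                w = (fpos - lo) / (hi - lo)
                x0, y0 = st.centroid(m, lo)
                x1, y1 = st.centroid(m, hi)
                pts.append(TrackPoint(
                    fi, x0 + w * (x1 - x0), y0 + w * (y1 - y0),
                    "interpolated"))
        tracks[m] = pts
    return tracks


def smooth_tracks(tracks: dict[str, list[TrackPoint]],
                  cfg: TrackerConfig) -> list[Track]:
    """Step 7: replace spatio-temporal outliers by interpolation, then apply
    a centered rolling mean to the coordinates.

    A point is an outlier when the implied speed both from the previous and
    to the next point exceeds ``outlier_speed_px_per_frame``.
    """
    out = []
    for m, pts in tracks.items():
        xy = np.array([(p.x, p.y) for p in pts])
        flags = [p.source for p in pts]
        if len(pts) > 2:
            speed = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            for i in range(1, len(pts) - 1):
                if (speed[i - 1] > cfg.outlier_speed_px_per_frame
                        and speed[i] > cfg.outlier_speed_px_per_frame):
                    xy[i] = (xy[i - 1] + xy[i + 1]) / 2.0
                    flags[i] = "smoothed"
        df = pd.DataFrame(xy)
        sm = df.rolling(cfg.smooth_window_frames, center=True,
                        min_periods=1).mean().to_numpy()
        out.append(Track(m, [
            TrackPoint(p.frame, sm[i, 0], sm[i, 1], flags[i])
            for i, p in enumerate(pts)
        ]))
    return out


def track_clip(frames: Sequence[FrameDetections],
               cfg: TrackerConfig | None = None,
               smooth: bool = True) -> list[Track]:
    """Run the seven tracking steps and return four complete tracks.

    ``smooth=False`` stops after step 6, leaving raw centroids (useful for
    validating the assignment logic against ground truth).
    """
    cfg = cfg or TrackerConfig()
    st = assign_anchors(frames, cfg)
    st = spatiotemporal_filter(st, cfg)
    st = eliminate_assign(st)
    st = fill_gaps_greedy(st, cfg)
    st = dedup_boxes(st)
    tracks = interpolate_gaps(st)
    if smooth:
        return smooth_tracks(tracks, cfg)
    return [Track(m, pts) for m, pts in tracks.items()]


def anchor_fraction(frames: Sequence[FrameDetections],
                    cfg: TrackerConfig | None = None) -> float:
    """Diagnostic: fraction of detections committed by steps 1-3 (the anchor
    boxes) relative to all detections in the clip."""
    cfg = cfg or TrackerConfig()
    st = assign_anchors(frames, cfg)
    st = spatiotemporal_filter(st, cfg)
    st = eliminate_assign(st)
    if st.n_detections == 0:
        return 0.0
    return st.n_assigned() / st.n_detections


def tracks_to_csv(tracks: Sequence[Track], path) -> None:
    rows = [
        (p.frame, t.animal_id, p.x, p.y, p.source)
        for t in tracks for p in t.points
    ]
    pd.DataFrame(rows, columns=["frame", "id", "x", "y", "source_flag"]
                 ).to_csv(path, index=False)


def tracks_from_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for m, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Track(str(m), [
            TrackPoint(int(r.frame), float(r.x), float(r.y),
                       str(r.source_flag))
            for r in grp.itertuples()
        ]))
    return tracks
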