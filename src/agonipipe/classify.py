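"""Rule-based detection of directed agonistic interactions from trajectories.

Within an action clip, the four per-animal centroid tracks are reduced to
speed series, the clip is cut into *event groups* (maximal runs of frames in
which at least one animal moves), and within each group three idealized
velocity/distance templates are evaluated for every pair of animals:

* contact_flee — the animals are in close proximity (Chebyshev distance
  <= 50 px), the initiator is stationary (<= 5 px/frame over the preceding
  10 frames) and the receiver accelerates away (>= 5 px/frame over the
  following 10 frames);
* approach_flee — the initiator approaches at speed until the distance drops
  below 50 px, then halts while the receiver flees;
* chase — both animals sustain >= 5 px/frame for >= 15 frames within 100 px
  Chebyshev; the chaser (initiator) is the animal trailing the other's path.

Each event group reports at most one interaction per pair of animals, and
the directed graph of interactions within a group is forced acyclic by
removing interactions chronologically backwards in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .tracker import Track

FPS = 25


@dataclass(frozen=True)
class ClassifierConfig:
    proximity_px: float = 50.0        # Chebyshev contact threshold
    speed_thresh: float = 5.0         # px/frame moving/stationary split
    rule_window_frames: int = 10      # pre/post decision windows
    move_thresh: float = 2.0          # event-group movement threshold
    merge_gap_frames: int = 12        # event groups closer than this merge
    chase_proximity_px: float = 100.0
    chase_min_frames: int = 15
    chase_lag_frames: int = 5
    velocity_median_window: int = 5
    interp_max_fraction: float = 0.5  # reject windows dominated by
    #                                   interpolated (computer-made) points
    detect_chaser: bool = True        # lag-error chaser identification


@dataclass(frozen=True)
class VelocitySeries:
    animal_id: str
    speeds: np.ndarray  # px/frame, length n_frames - 1


@dataclass(frozen=True)
class EventGroup:
    start_frame: int
    end_frame: int  # inclusive
    moving_ids: frozenset[str]


@dataclass(frozen=True)
class Interaction:
    timestamp_s: float   # onset, clip-relative unless shifted by the caller
    duration_s: float
    initiator_id: str
    receiver_id: str
    rule_tag: str        # contact_flee | approach_flee | chase
    dark: bool = False

    def __post_init__(self):
        if self.initiator_id == self.receiver_id:
            raise ValueError("initiator and receiver must differ")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class LightSchedule:
    """12L:12D light programme used to flag night-time (IR) interactions."""

    lights_off: time = time(20, 0)
    lights_on: time = time(8, 0)

    def is_dark(self, when: datetime) -> bool:
        t = when.time()
        if self.lights_off <= self.lights_on:
            return self.lights_off <= t < self.lights_on
        return t >= self.lights_off or t < self.lights_on


def compute_velocity(track: Track,
                     cfg: ClassifierConfig | None = None) -> VelocitySeries:
    """Frame-to-frame centroid speed, median-filtered to suppress jitter."""
    cfg = cfg or ClassifierConfig()
    xy = track.as_array()
    speed = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    filtered = pd.Series(speed).rolling(
        cfg.velocity_median_window, center=True, min_periods=1
    ).median().to_numpy()
    return VelocitySeries(track.animal_id, filtered)


def segment_event_groups(
    velocities: Sequence[VelocitySeries],
    cfg: ClassifierConfig | None = None,
) -> list[EventGroup]:
    """Maximal runs of frames in which at least one animal is moving.

    Runs separated by fewer than ``merge_gap_frames`` stationary frames are
    merged into one group (a behaviour bout rather than separate events).
    """
    cfg = cfg or ClassifierConfig()
    speeds = np.stack([v.speeds for v in velocities])
    moving = speeds.max(axis=0) >= cfg.move_thresh
    idx = np.flatnonzero(np.diff(np.r_[False, moving, False].astype(int)))
    runs = [(int(a), int(b) - 1) for a, b in zip(idx[::2], idx[1::2])]
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 < cfg.merge_gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    groups = []
    for a, b in merged:
        ids = frozenset(
            v.animal_id for v in velocities
            if np.any(v.speeds[a:b + 1] >= cfg.move_thresh)
        )
        groups.append(EventGroup(a, b, ids))
    return groups


def _cheb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.max(np.abs(a - b), axis=-1)


class _PairContext:
    """Precomputed per-pair views used by the rule templates."""

    def __init__(self, trajA: Track, trajB: Track, velA: VelocitySeries,
                 velB: VelocitySeries):
        self.ids = (trajA.animal_id, trajB.animal_id)
        self.xy = {trajA.animal_id: trajA.as_array(),
                   trajB.animal_id: trajB.as_array()}
        self.vel = {velA.animal_id: velA.speeds, velB.animal_id: velB.speeds}
        self.interp = {
            t.animal_id: np.array([p.source == "interpolated"
                                   for p in t.points])
            for t in (trajA, trajB)
        }
        self.dist = _cheb(self.xy[self.ids[0]], self.xy[self.ids[1]])
        self.n_vel = len(velA.speeds)


def _window_reliable(ctx: _PairContext, lo: int, hi: int,
                     cfg: ClassifierConfig) -> bool:
    lo, hi = max(lo, 0), min(hi, ctx.n_vel)
    if hi <= lo:
        return False
    for m in ctx.ids:
        if ctx.interp[m][lo:hi].mean() > cfg.interp_max_fraction:
            return False
    return True


def _contact_flee(ctx, init, recv, t0, cfg) -> bool:
    w = cfg.rule_window_frames
    if t0 - w < 0 or t0 + w >= ctx.n_vel:
        return False
    return (
        ctx.dist[t0] <= cfg.proximity_px
        and np.all(ctx.vel[init][t0 - w:t0 + 1] <= cfg.speed_thresh)
        and np.all(ctx.vel[recv][t0:t0 + w + 1] >= cfg.speed_thresh)
    )


def _approach_flee(ctx, init, recv, t0, cfg) -> bool:
    w = cfg.rule_window_frames
    if t0 - w < 0 or t0 + w >= ctx.n_vel:
        return False
    return (
        ctx.dist[t0] <= cfg.proximity_px
        and np.all(ctx.vel[init][t0 - w:t0] >= cfg.speed_thresh)
        and ctx.dist[t0] < ctx.dist[t0 - w]
        and np.all(ctx.vel[init][t0:t0 + w + 1] <= cfg.speed_thresh)
        and np.all(ctx.vel[recv][t0:t0 + w + 1] >= cfg.speed_thresh)
        and ctx.dist[t0 + w] > ctx.dist[t0]
    )


def _chase_window(ctx, t0, cfg) -> bool:
    hi = t0 + cfg.chase_min_frames
    if hi > ctx.n_vel:
        return False
    a, b = ctx.ids
    return bool(
        np.all(ctx.vel[a][t0:hi] >= cfg.speed_thresh)
        and np.all(ctx.vel[b][t0:hi] >= cfg.speed_thresh)
        and np.all(ctx.dist[t0:hi] <= cfg.chase_proximity_px)
    )


def _chaser(ctx, t0, cfg) -> tuple[str, str]:
    """The chaser trails: its position best matches the other animal's
    position ``chase_lag_frames`` earlier."""
    a, b = ctx.ids
    lag = cfg.chase_lag_frames
    lo, hi = t0 + lag, t0 + cfg.chase_min_frames
    xa, xb = ctx.xy[a], ctx.xy[b]
    err_a = np.linalg.norm(xa[lo:hi] - xb[lo - lag:hi - lag], axis=1).mean()
    err_b = np.linalg.norm(xb[lo:hi] - xa[lo - lag:hi - lag], axis=1).mean()
    if not cfg.detect_chaser or err_a == err_b:
        return (a, b) if a < b else (b, a)
    return (a, b) if err_a < err_b else (b, a)


def _duration_frames(ctx, t0, group: EventGroup, cfg) -> int:
    """Frames from onset until both animals stay below the speed threshold
    for 10 consecutive frames; capped at the group end."""
    quiet = 0
    end = min(group.end_frame, ctx.n_vel - 1)
    for t in range(t0, end + 1):
        both_slow = all(ctx.vel[m][t] < cfg.speed_thresh for m in ctx.ids)
        quiet = quiet + 1 if both_slow else 0
        if quiet >= cfg.rule_window_frames:
            return max(t - cfg.rule_window_frames + 1 - t0, 1)
    return max(end + 1 - t0, 1)


def detect_pair_interaction(
    trajA: Track, trajB: Track,
    velA: VelocitySeries, velB: VelocitySeries,
    group: EventGroup,
    cfg: ClassifierConfig | None = None,
    fps: int = FPS,
) -> Optional[Interaction]:
    """Evaluate the three rule templates for one pair within one group.

    Onsets are scanned frame by frame; at each onset the templates are tried
    in order (contact_flee, approach_flee, chase) and, for the first two,
    with either animal in the initiator role.  The first match wins.
    Windows dominated by interpolated track points are skipped as
    unreliable.
    """
    cfg = cfg or ClassifierConfig()
    ctx = _PairContext(trajA, trajB, velA, velB)
    a, b = ctx.ids
    w = cfg.rule_window_frames
    for t0 in range(group.start_frame, group.end_frame + 1):
        if not _window_reliable(ctx, t0 - w, t0 + w + 1, cfg):
            continue
        hit: tuple[str, str, str] | None = None
        for init, recv in ((a, b), (b, a)):
            if _contact_flee(ctx, init, recv, t0, cfg):
                hit = (init, recv, "contact_flee")
                break
        if hit is None:
            for init, recv in ((a, b), (b, a)):
                if _approach_flee(ctx, init, recv, t0, cfg):
                    hit = (init, recv, "approach_flee")
                    break
        if hit is None and _chase_window(ctx, t0, cfg):
            init, recv = _chaser(ctx, t0, cfg)
            hit = (init, recv, "chase")
        if hit is not None:
            init, recv, tag = hit
            dur = _duration_frames(ctx, t0, group, cfg)
            return Interaction(
                timestamp_s=t0 / fps,
                duration_s=dur / fps,
                initiator_id=init,
                receiver_id=recv,
                rule_tag=tag,
            )
    return None


def resolve_event_group(
    interactions: Sequence[Interaction],
) -> list[Interaction]:
    """Deduplicate and enforce acyclicity within one event group.

    Keeps only the earliest interaction per unordered pair, then, while the
    directed initiator->receiver graph contains a cycle, removes the
    latest-onset interaction participating in any cycle.
    """
    per_pair: dict[frozenset, Interaction] = {}
    for ia in sorted(interactions, key=lambda i: i.timestamp_s):
        key = frozenset((ia.initiator_id, ia.receiver_id))
        per_pair.setdefault(key, ia)
    kept = sorted(per_pair.values(), key=lambda i: i.timestamp_s)

    while True:
        g = nx.DiGraph()
        for ia in kept:
            g.add_edge(ia.initiator_id, ia.receiver_id, interaction=ia)
        cyclic_edges = set()
        for cycle in nx.simple_cycles(g):
            for u, v in zip(cycle, cycle[1:] + cycle[:1]):
                cyclic_edges.add((u, v))
        if not cyclic_edges:
            return kept
        victim = max(
            (ia for ia in kept
             if (ia.initiator_id, ia.receiver_id) in cyclic_edges),
            key=lambda i: i.timestamp_s,
        )
        kept = [ia for ia in kept if ia is not victim]


def classify_clip(
    tracks: Sequence[Track],
    cfg: ClassifierConfig | None = None,
    clip_start: datetime | None = None,
    schedule: LightSchedule | None = None,
    fps: int = FPS,
) -> list[Interaction]:
    """Full per-clip classification: velocities, event groups, pairwise rule
    evaluation, per-group resolution, and dark-period flagging.

    When ``clip_start`` and a light ``schedule`` are given, interactions
    whose onset falls inside the dark period are flagged ``dark=True``
    (night-vision footage does not allow identification of the animals, so
    downstream hierarchy analytics exclude them by default).
    """
    cfg = cfg or ClassifierConfig()
    vels = {t.animal_id: compute_velocity(t, cfg) for t in tracks}
    groups = segment_event_groups(list(vels.values()), cfg)
    by_id = {t.animal_id: t for t in tracks}
    ids = sorted(by_id)
    result: list[Interaction] = []
    for group in groups:
        found = []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ia = detect_pair_interaction(
                    by_id[a], by_id[b], vels[a], vels[b], group, cfg, fps)
                if ia is not None:
                    found.append(ia)
        result.extend(resolve_event_group(found))
    if clip_start is not None and schedule is not None:
        from datetime import timedelta
        result = [
            Interaction(
                ia.timestamp_s, ia.duration_s, ia.initiator_id,
                ia.receiver_id, ia.rule_tag,
                dark=schedule.is_dark(
                    clip_start + timedelta(seconds=ia.timestamp_s)),
            )
            for ia in result
        ]
    return sorted(result, key=lambda i: i.timestamp_s)


def interactions_to_csv(interactions: Sequence[Interaction], path) -> None:
    pd.DataFrame(
        [
            (i.timestamp_s, i.duration_s, i.initiator_id, i.receiver_id,
             i.rule_tag, i.dark)
            for i in interactions
        ],
        columns=["timestamp_s", "duration_s", "initiator", "receiver",
                 "rule_tag", "dark"],
    ).to_csv(path, index=False)


def interactions_from_csv(path) -> list[Interaction]:
    df = pd.read_csv(path)
    return [
        Interaction(float(r.timestamp_s), float(r.duration_s),
                    str(r.initiator), str(r.receiver), str(r.rule_tag),
                    bool(r.dark))
        for r in df.itertuples()
    ]
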