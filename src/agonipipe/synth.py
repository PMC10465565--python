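"""Synthetic pen scenes with scripted agonistic events.

Generates ground-truth trajectories for four marked animals in a
rectangular pen, plants idealized agonistic events (contact-flee,
approach-flee, chase) whose velocity/distance signatures satisfy the
classification rule templates by construction, and degrades the ground
truth into realistic detection files (dropout, centroid jitter, occlusion
windows with flattened identity confidence, spurious kit-cluster boxes).
Every pipeline stage is thereby testable without any recorded video.

Between events the animals rest at their current position with small
sub-pixel jitter; scripted movement uses speeds of 6-12 px/frame, matching
the scale of real chasing/fleeing bouts at 25 fps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify
from .classify import ClassifierConfig, EventGroup, Interaction
from .detections import MARKINGS, Detection, FrameDetections
from .motion import MagnitudeSeries
from .tracker import Track, TrackPoint

_WALK_SPEED = 1.8    # px/frame; below the 2 px/frame movement threshold
_FLEE_SPEED = 8.0
_CHASE_SPEED = 7.0
_HOLD_FRAMES = 15
_FLEE_FRAMES = 25
_CHASE_FRAMES = 45
_DECEL_FRAMES = 8
_CONTACT_CHEB = 20.0  # px; near-contact distance at event onset
_CHASE_GAP = 60.0     # px; spatial offset chaser-to-chased


@dataclass(frozen=True)
class SceneConfig:
    pen_size_px: tuple[int, int] = (640, 360)
    fps: int = 25
    duration_s: float = 120.0
    n_contact_flee: int = 1
    n_approach_flee: int = 1
    n_chase: int = 1
    dropout_rate: float = 0.1
    id_conf_high: float = 0.995
    id_conf_occluded: float = 0.4
    jitter_sd_px: float = 2.0
    kit_clutter_rate: float = 0.05
    n_occlusion_windows: int = 2
    occlusion_s: float = 2.0
    rest_jitter_px: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("dropout_rate", "kit_clutter_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class GroundTruthScene:
    cfg: SceneConfig
    trajectories: np.ndarray           # (n_frames, 4, 2), MARKINGS order
    planted_events: tuple[Interaction, ...]

    def tracks(self) -> list[Track]:
        """Ground-truth trajectories as Track objects (all points anchors)."""
        return [
            Track(m, [
                TrackPoint(f, float(self.trajectories[f, a, 0]),
                           float(self.trajectories[f, a, 1]), "anchor")
                for f in range(self.trajectories.shape[0])
            ])
            for a, m in enumerate(MARKINGS)
        ]

    def to_csv(self, path) -> None:
        rows = [
            (f, m, *self.trajectories[f, a])
            for f in range(self.trajectories.shape[0])
            for a, m in enumerate(MARKINGS)
        ]
        pd.DataFrame(rows, columns=["frame", "id", "x", "y"]).to_csv(
            path, index=False)


class _SceneBuilder:
    def __init__(self, cfg: SceneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        w, h = cfg.pen_size_px
        self.pos = np.zeros((cfg.n_frames, 4, 2))
        self.cur = np.array([
            (0.22 * w, 0.25 * h), (0.78 * w, 0.25 * h),
            (0.22 * w, 0.75 * h), (0.78 * w, 0.75 * h),
        ])
        self.frontier = 0  # frames < frontier are finalized

    def _fill_rest(self, until: int) -> None:
        until = max(until, self.frontier)
        self.pos[self.frontier:until] = self.cur
        self.frontier = until

    def hold(self, n: int) -> None:
        self._fill_rest(min(self.frontier + n, self.cfg.n_frames))

    def walk(self, a: int, target: np.ndarray, speed: float) -> None:
        """Move animal ``a`` to ``target`` in a straight line while the
        others rest; advances the frontier."""
        delta = np.asarray(target, dtype=float) - self.cur[a]
        dist = float(np.linalg.norm(delta))
        n = int(math.ceil(dist / speed)) if dist > 0 else 0
        if self.frontier + n > self.cfg.n_frames:
            raise ValueError("scene duration too short for scripted events")
        for k in range(n):
            self.pos[self.frontier + k] = self.cur
            frac = min((k + 1) * speed / dist, 1.0)
            self.pos[self.frontier + k, a] = self.cur[a] + frac * delta
        if n:
            self.cur[a] = target
            self.frontier += n

    def move_profile(self, moves: dict[int, np.ndarray],
                     speeds: np.ndarray) -> None:
        """Advance animals along unit directions with per-frame speeds.

        ``moves`` maps animal index -> unit direction; ``speeds`` is either
        a (n_steps,) profile shared by all movers or (n_steps, len(moves)).
        """
        speeds = np.atleast_2d(np.asarray(speeds, dtype=float).T).T
        if speeds.shape[1] == 1 and len(moves) > 1:
            speeds = np.repeat(speeds, len(moves), axis=1)
        n = speeds.shape[0]
        if self.frontier + n > self.cfg.n_frames:
            raise ValueError("scene duration too short for scripted events")
        for k in range(n):
            for col, (a, d) in enumerate(moves.items()):
                self.cur[a] = self.cur[a] + speeds[k, col] * d
            self.pos[self.frontier + k] = self.cur
        self.frontier += n


def _decel(speed: float) -> np.ndarray:
    return np.linspace(speed, 0.0, _DECEL_FRAMES + 1)[1:]


def _clear_lane_y(b: _SceneBuilder, involved: set[int]) -> float:
    """A horizontal lane keeping >55 px Chebyshev clearance from resting
    bystanders, so the proximity rules cannot implicate them."""
    h = b.cfg.pen_size_px[1]
    others = [b.cur[a][1] for a in range(4) if a not in involved]
    candidates = np.arange(60.0, h - 60.0 + 1e-9, 5.0)
    if not others:
        return float(candidates[len(candidates) // 2])
    clearance = np.min(
        np.abs(candidates[:, None] - np.array(others)[None, :]), axis=1)
    return float(candidates[int(np.argmax(clearance))])


def _plant_contact_flee(b: _SceneBuilder, init: int, recv: int) -> Interaction:
    cfg = b.cfg
    w, _ = cfg.pen_size_px
    run = _FLEE_SPEED * (_FLEE_FRAMES + _DECEL_FRAMES)
    y = _clear_lane_y(b, {init, recv})
    x0 = float(np.clip(b.cur[init][0], 40.0, w - run - 80.0))
    # Initiator settles on the lane; the receiver walks into near-contact.
    b.walk(init, np.array([x0, y]), _WALK_SPEED)
    b.walk(recv, np.array([x0 + _CONTACT_CHEB, y]), _WALK_SPEED)
    b.hold(_HOLD_FRAMES)
    t0 = b.frontier
    profile = np.r_[np.full(_FLEE_FRAMES, _FLEE_SPEED), _decel(_FLEE_SPEED)]
    b.move_profile({recv: np.array([1.0, 0.0])}, profile)
    b.hold(_HOLD_FRAMES)
    active = _FLEE_FRAMES + int(np.sum(_decel(_FLEE_SPEED) >= 5.0))
    return Interaction(t0 / cfg.fps, active / cfg.fps,
                       MARKINGS[init], MARKINGS[recv], "contact_flee")


def _plant_approach_flee(b: _SceneBuilder, init: int,
                         recv: int) -> Interaction:
    cfg = b.cfg
    w, _ = cfg.pen_size_px
    run = _FLEE_SPEED * (_FLEE_FRAMES + _DECEL_FRAMES)  # receiver's flight
    # Stage the pair on a horizontal lane with room for approach and flight.
    bx = float(np.clip(b.cur[recv][0], 230.0, w - run - 40.0))
    by = _clear_lane_y(b, {init, recv})
    b.walk(recv, np.array([bx, by]), _WALK_SPEED)
    b.walk(init, np.array([bx - 170.0, by]), _WALK_SPEED)
    b.hold(_HOLD_FRAMES)
    d0 = bx - b.cur[init][0]
    # The initiator keeps closing in for 6 frames after the receiver bolts,
    # reaching a minimum separation of ~12 px just before the bolt; the
    # distance at the halt frame then sits well inside the contact radius.
    n_approach = 6 + int(math.floor((d0 - 12.0) / _CHASE_SPEED))
    t0 = b.frontier + n_approach          # initiator halts here
    # Initiator closes in; the receiver bolts 6 frames before the halt.
    b.move_profile({init: np.array([1.0, 0.0])},
                   np.full(n_approach - 6, _CHASE_SPEED))
    b.move_profile(
        {init: np.array([1.0, 0.0]), recv: np.array([1.0, 0.0])},
        np.column_stack([np.full(6, _CHASE_SPEED), np.full(6, _FLEE_SPEED)]),
    )
    profile = np.r_[np.full(_FLEE_FRAMES - 6, _FLEE_SPEED),
                    _decel(_FLEE_SPEED)]
    b.move_profile({recv: np.array([1.0, 0.0])}, profile)
    b.hold(_HOLD_FRAMES)
    active = _FLEE_FRAMES + int(np.sum(_decel(_FLEE_SPEED) >= 5.0))
    return Interaction(t0 / cfg.fps, active / cfg.fps,
                       MARKINGS[init], MARKINGS[recv], "approach_flee")


def _plant_chase(b: _SceneBuilder, init: int, recv: int) -> Interaction:
    cfg = b.cfg
    w, _ = cfg.pen_size_px
    run = _CHASE_SPEED * (_CHASE_FRAMES + _DECEL_FRAMES)
    bx = float(np.clip(b.cur[recv][0], _CHASE_GAP + 40.0, w - run - 40.0))
    by = _clear_lane_y(b, {init, recv})
    b.walk(recv, np.array([bx, by]), _WALK_SPEED)
    b.walk(init, np.array([bx - _CHASE_GAP, by]), _WALK_SPEED)
    b.hold(_HOLD_FRAMES)
    t0 = b.frontier
    d = np.array([1.0, 0.0])
    profile = np.r_[np.full(_CHASE_FRAMES, _CHASE_SPEED),
                    _decel(_CHASE_SPEED)]
    b.move_profile({init: d, recv: d}, profile)
    b.hold(_HOLD_FRAMES)
    active = _CHASE_FRAMES + int(np.sum(_decel(_CHASE_SPEED) >= 5.0))
    return Interaction(t0 / cfg.fps, active / cfg.fps,
                       MARKINGS[init], MARKINGS[recv], "chase")


_PLANTERS = {
    "contact_flee": _plant_contact_flee,
    "approach_flee": _plant_approach_flee,
    "chase": _plant_chase,
}


def _verify_event(scene: GroundTruthScene, event: Interaction) -> None:
    """Assert the planted event's signature is recognized by the rule
    evaluator on the exact trajectories (construction self-check)."""
    cfg = ClassifierConfig()
    tracks = {t.animal_id: t for t in scene.tracks()}
    a, b = sorted((event.initiator_id, event.receiver_id))
    va = classify.compute_velocity(tracks[a], cfg)
    vb = classify.compute_velocity(tracks[b], cfg)
    t0 = int(round(event.timestamp_s * scene.cfg.fps))
    lo = max(t0 - 2 * cfg.rule_window_frames, 0)
    hi = min(t0 + int(event.duration_s * scene.cfg.fps)
             + 2 * cfg.rule_window_frames,
             scene.trajectories.shape[0] - 2)
    group = EventGroup(lo, hi, frozenset((a, b)))
    found = classify.detect_pair_interaction(
        tracks[a], tracks[b], va, vb, group, cfg, scene.cfg.fps)
    if (found is None
            or found.initiator_id != event.initiator_id
            or found.receiver_id != event.receiver_id
            or found.rule_tag != event.rule_tag):
        raise RuntimeError(
            f"planted {event.rule_tag} event failed rule verification: "
            f"{found}")


def generate_scene(cfg: SceneConfig | None = None) -> GroundTruthScene:
    """Script a deterministic scene with the configured planted events.

    Events are laid out sequentially, each preceded by slow (sub-threshold)
    staging walks and separated by stationary holds, so that every planted
    event forms its own movement segment.  Each planted event is verified
    against the rule evaluator before the scene is returned.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    b = _SceneBuilder(cfg, rng)
    b.hold(2 * _HOLD_FRAMES)

    specs = (["contact_flee"] * cfg.n_contact_flee
             + ["approach_flee"] * cfg.n_approach_flee
             + ["chase"] * cfg.n_chase)
    rng.shuffle(specs)
    events = []
    for tag in specs:
        init, recv = rng.choice(4, size=2, replace=False)
        events.append(_PLANTERS[tag](b, int(init), int(recv)))
    b.hold(cfg.n_frames - b.frontier)

    if cfg.rest_jitter_px > 0:
        # Mean-reverting sub-pixel wiggle so "resting" animals are not
        # bit-identical between frames.
        noise = np.zeros_like(b.pos)
        step = rng.normal(0.0, cfg.rest_jitter_px,
                          size=b.pos.shape)
        for f in range(1, cfg.n_frames):
            noise[f] = 0.9 * noise[f - 1] + step[f]
        b.pos = b.pos + noise

    scene = GroundTruthScene(cfg, b.pos, tuple(events))
    for ev in events:
        _verify_event(scene, ev)
    return scene


def _keypoints(centroid, heading, conf=0.9):
    nose = centroid + 25.0 * heading
    tail = centroid - 25.0 * heading
    return (
        (float(nose[0]), float(nose[1]), conf),
        (float(centroid[0]), float(centroid[1]), conf),
        (float(tail[0]), float(tail[1]), conf),
    )


def _id_probs(true_id: str, peak: float) -> dict[str, float]:
    rest = (1.0 - peak) / 3.0
    return {m: (peak if m == true_id else rest) for m in MARKINGS}


def degrade_to_detections(
    scene: GroundTruthScene, cfg: SceneConfig | None = None,
) -> list[FrameDetections]:
    """Corrupt ground truth into per-frame detection records.

    Per frame and animal: the detection is dropped with probability
    ``dropout_rate``; the centroid is jittered with Gaussian noise; during
    scripted occlusion windows the identity confidence collapses to
    ``id_conf_occluded`` (below the anchor threshold, forcing the tracker's
    gap logic).  Spurious kit-cluster boxes with uninformative identity
    probabilities are injected at ``kit_clutter_rate`` per frame.
    """
    cfg = cfg or scene.cfg
    rng = np.random.default_rng(cfg.seed + 1)
    n_frames = scene.trajectories.shape[0]
    w, h = cfg.pen_size_px

    occluded = np.zeros((n_frames, 4), dtype=bool)
    occ_len = int(cfg.occlusion_s * cfg.fps)
    for _ in range(cfg.n_occlusion_windows):
        if occ_len == 0 or n_frames <= occ_len:
            break
        a = int(rng.integers(4))
        start = int(rng.integers(n_frames - occ_len))
        occluded[start:start + occ_len, a] = True

    frames = []
    for f in range(n_frames):
        dets = []
        for a, m in enumerate(MARKINGS):
            if rng.random() < cfg.dropout_rate:
                continue
            c = scene.trajectories[f, a] + rng.normal(
                0.0, cfg.jitter_sd_px, size=2)
            vel = (scene.trajectories[min(f + 1, n_frames - 1), a]
                   - scene.trajectories[max(f - 1, 0), a])
            nv = np.linalg.norm(vel)
            heading = vel / nv if nv > 1e-6 else np.array([1.0, 0.0])
            peak = cfg.id_conf_occluded if occluded[f, a] else cfg.id_conf_high
            dets.append(Detection(
                bbox=(float(c[0] - 30), float(c[1] - 20),
                      float(c[0] + 30), float(c[1] + 20)),
                det_conf=0.9,
                keypoints=_keypoints(c, heading),
                id_probs=_id_probs(m, peak),
            ))
        if rng.random() < cfg.kit_clutter_rate:
            cx = rng.uniform(30, w - 30)
            cy = rng.uniform(30, h - 30)
            dets.append(Detection(
                bbox=(cx - 25, cy - 18, cx + 25, cy + 18),
                det_conf=0.5,
                keypoints=_keypoints(np.array([cx, cy]),
                                     np.array([1.0, 0.0]), conf=0.3),
                id_probs={m: 0.25 for m in MARKINGS},
            ))
        frames.append(FrameDetections(f, tuple(dets)))
    return frames


def magnitude_from_scene(scene: GroundTruthScene) -> MagnitudeSeries:
    """Per-second pen-level motion magnitude implied by the trajectories.

    The summed per-frame displacement of all animals within each second is
    scaled so that a single animal running at flee speed registers well
    above the action-retention threshold while resting jitter stays below
    the suppression floor, then clipped to the 0-5 range typical of
    mean-flow magnitudes.
    """
    fps = scene.cfg.fps
    n_sec = scene.trajectories.shape[0] // fps
    disp = np.linalg.norm(np.diff(scene.trajectories, axis=0), axis=2)
    mags = np.empty(n_sec)
    for s in range(n_sec):
        lo = s * fps
        hi = min(lo + fps, disp.shape[0])
        mags[s] = disp[lo:hi].sum() / 30.0
    return MagnitudeSeries(pen_id=f"synthetic-{scene.cfg.seed}",
                           values=np.clip(mags, 0.0, 5.0))
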