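import numpy as np
import pytest

from agonipipe import synth, tracker
from agonipipe.detections import MARKINGS, Detection, FrameDetections
from conftest import noise_free_config


def make_det(x, y, probs=None, best=None, peak=0.99):
    if probs is None:
        rest = (1.0 - peak) / 3.0
        probs = {m: (peak if m == best else rest) for m in MARKINGS}
    return Detection(
        bbox=(x - 30, y - 20, x + 30, y + 20), det_conf=0.9,
        keypoints=((x, y, 0.9),) * 3, id_probs=probs)


def make_frames(spec):
    """spec: list per frame of (x, y, best_id, peak) tuples."""
    return [
        FrameDetections(f, tuple(
            make_det(x, y, best=best, peak=peak)
            for x, y, best, peak in dets))
        for f, dets in enumerate(spec)
    ]


def static_frames(n=10, peak=0.99):
    pos = {"circle": (50, 50), "line": (200, 50),
           "tail": (50, 200), "neck": (200, 200)}
    return make_frames([
        [(x, y, m, peak) for m, (x, y) in pos.items()] for _ in range(n)
    ])


class TestAnchors:
    def test_uniform_probs_give_no_anchors(self):
        frames = make_frames([
            [(50, 50, None, 0.25)] for _ in range(5)
        ])
        # peak 0.25 == uniform
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        assert all(not slot for slot in st.slots.values())

    def test_perfect_clip_anchors_every_frame(self):
        frames = static_frames()
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        assert all(len(st.slots[m]) == len(frames) for m in MARKINGS)

    def test_threshold_is_inclusive_at_0_98(self):
        frames = make_frames([[(50, 50, "circle", 0.98)]])
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        assert 0 in st.slots["circle"]
        frames = make_frames([[(50, 50, "circle", 0.9799)]])
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        assert 0 not in st.slots["circle"]

    def test_conflicting_claims_keep_higher_probability(self):
        frame = FrameDetections(0, (
            make_det(50, 50, best="circle", peak=0.985),
            make_det(300, 300, best="circle", peak=0.995),
        ))
        st = tracker.assign_anchors([frame], tracker.TrackerConfig())
        assert st.slots["circle"][0][0] == 1


class TestSpatiotemporalFilter:
    def test_isolated_anchor_removed(self):
        frames = make_frames(
            [[(50, 50, "circle", 0.99)]] + [[] for _ in range(5)])
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        st = tracker.spatiotemporal_filter(st, tracker.TrackerConfig())
        assert not st.slots["circle"]

    def test_dense_contiguous_anchors_kept(self):
        frames = static_frames()
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        st = tracker.spatiotemporal_filter(st, tracker.TrackerConfig())
        assert all(len(st.slots[m]) == len(frames) for m in MARKINGS)

    @pytest.mark.parametrize("offset,kept", [(30, True), (300, False)])
    def test_neighbor_distance_rule(self, offset, kept):
        frames = make_frames([
            [(50, 50, "circle", 0.99)],
            [],
            [(50 + offset, 50, "circle", 0.99)],
        ])
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        st = tracker.spatiotemporal_filter(st, tracker.TrackerConfig())
        assert (0 in st.slots["circle"]) is kept


class TestEliminationAndDedup:
    def three_plus_unassigned(self, extra_unassigned=0):
        dets = [
            make_det(50, 50, best="circle"),
            make_det(200, 50, best="line"),
            make_det(50, 200, best="tail"),
            make_det(200, 200, probs={m: 0.25 for m in MARKINGS}),
        ]
        for k in range(extra_unassigned):
            dets.append(make_det(300 + 50 * k, 300,
                                 probs={m: 0.25 for m in MARKINGS}))
        frame = FrameDetections(0, tuple(dets))
        reps = [FrameDetections(i, frame.detections) for i in range(5)]
        return [FrameDetections(i, f.detections)
                for i, f in enumerate(reps)]

    def test_lone_unknown_box_assigned_by_elimination(self):
        frames = self.three_plus_unassigned()
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        st = tracker.spatiotemporal_filter(st, tracker.TrackerConfig())
        st = tracker.eliminate_assign(st)
        assert st.slots["neck"][0] == (3, "eliminated")

    def test_two_unknown_boxes_stay_unassigned(self):
        frames = self.three_plus_unassigned(extra_unassigned=1)
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        st = tracker.spatiotemporal_filter(st, tracker.TrackerConfig())
        st = tracker.eliminate_assign(st)
        assert not st.slots["neck"]

    def test_duplicate_box_stays_with_higher_confidence_track(self):
        frames = static_frames(5)
        st = tracker.assign_anchors(frames, tracker.TrackerConfig())
        # Force the circle detection into both circle and line tracks.
        st.slots["line"][2] = (0, "anchor")
        st = tracker.dedup_boxes(st)
        assert 2 in st.slots["circle"]
        assert st.slots["line"].get(2, (None,))[0] != 0


class TestGapFilling:
    def gap_clip(self, good_peak, bad_peak):
        """Anchors at frames 0-1 and 8-9; frames 2-7 contain two unassigned
        boxes: one continuing the circle path (peak prob ``good_peak``) and
        a decoy (``bad_peak``)."""
        rows = []
        for f in range(10):
            x = 50 + 10 * f
            if f in (0, 1, 8, 9):
                rows.append([(x, 50, "circle", 0.99)])
            else:
                rows.append([(x, 50, "circle", good_peak),
                             (400, 300, "circle", bad_peak)])
        return make_frames(rows)

    def test_clear_margin_accepts_tracklet(self):
        frames = self.gap_clip(good_peak=0.7, bad_peak=0.2)
        cfg = tracker.TrackerConfig()
        st = tracker.assign_anchors(frames, cfg)
        st = tracker.spatiotemporal_filter(st, cfg)
        st = tracker.fill_gaps_greedy(st, cfg)
        for f in range(2, 8):
            assert st.slots["circle"][f][1] == "tracklet"
            assert st.slots["circle"][f][0] == 0  # the path box, not decoy

    def test_ambiguous_margin_leaves_gap(self):
        frames = self.gap_clip(good_peak=0.5, bad_peak=0.45)
        cfg = tracker.TrackerConfig()
        st = tracker.assign_anchors(frames, cfg)
        st = tracker.spatiotemporal_filter(st, cfg)
        st = tracker.fill_gaps_greedy(st, cfg)
        assert all(f not in st.slots["circle"] for f in range(2, 8))


class TestInterpolationAndSmoothing:
    def test_linear_interpolation_of_interior_gap(self):
        frames = make_frames(
            [[(0, 0, "circle", 0.99)]] * 11
        )
        cfg = tracker.TrackerConfig()
        st = tracker.assign_anchors(frames, cfg)
        # carve a gap at frames 11..13 between anchors at (0,0) and (4,4)
        st.frames += [FrameDetections(i, ()) for i in range(11, 14)]
        st.frame_index += list(range(11, 14))
        st.frames.append(FrameDetections(
            14, (make_det(4, 4, best="circle"),)))
        st.frame_index.append(14)
        st.slots["circle"][14] = (0, "anchor")
        for m in ("line", "tail", "neck"):
            st.slots[m][0] = (0, "anchor")  # arbitrary, to complete tracks
        tracks = tracker.interpolate_gaps(st)
        pts = {p.frame: p for p in tracks["circle"]}
        for f, expect in [(11, 1.0), (12, 2.0), (13, 3.0)]:
            assert pts[f].x == pytest.approx(expect)
            assert pts[f].y == pytest.approx(expect)
            assert pts[f].source == "interpolated"

    def test_leading_gap_extends_first_anchor(self):
        frames = make_frames([[]] * 3 + [[(70, 80, "circle", 0.99)]] * 5)
        cfg = tracker.TrackerConfig()
        st = tracker.assign_anchors(frames, cfg)
        for m in ("line", "tail", "neck"):
            st.slots[m][3] = (0, "anchor")
        tracks = tracker.interpolate_gaps(st)
        for f in range(3):
            p = tracks["circle"][f]
            assert (p.x, p.y) == (70, 80)
            assert p.source == "interpolated"

    def test_stationary_track_unchanged_by_smoothing(self):
        pts = [tracker.TrackPoint(f, 50.0, 60.0, "anchor")
               for f in range(30)]
        out = tracker.smooth_tracks({"circle": pts},
                                    tracker.TrackerConfig())[0]
        assert all(p.x == 50.0 and p.y == 60.0 for p in out.points)

    def test_linear_trajectory_not_displaced_by_smoothing(self):
        pts = [tracker.TrackPoint(f, 3.0 * f, 100.0, "anchor")
               for f in range(50)]
        out = tracker.smooth_tracks({"circle": pts},
                                    tracker.TrackerConfig())[0]
        inner = out.points[10:-10]
        assert all(p.x == pytest.approx(3.0 * p.frame) for p in inner)

    def test_single_spike_removed(self):
        pts = [tracker.TrackPoint(f, 10.0, 10.0, "anchor")
               for f in range(20)]
        pts[10] = tracker.TrackPoint(10, 510.0, 10.0, "anchor")
        out = tracker.smooth_tracks({"circle": pts},
                                    tracker.TrackerConfig(
                                        smooth_window_frames=1))[0]
        assert out.points[10].x == pytest.approx(10.0)
        assert out.points[10].source == "smoothed"


class TestTrackClip:
    @pytest.mark.parametrize("seed", range(6))
    def test_noise_free_tracking_equals_ground_truth(self, seed):
        scene = synth.generate_scene(noise_free_config(seed=seed))
        frames = synth.degrade_to_detections(scene)
        tracks = tracker.track_clip(frames, smooth=False)
        by_id = {t.animal_id: t for t in tracks}
        for a, m in enumerate(MARKINGS):
            got = by_id[m].as_array()
            assert np.allclose(got, scene.trajectories[:, a], atol=1e-9)

    def test_population_constraint_holds(self, noisy_runs):
        scene, tracks, _ = noisy_runs[0]
        n_frames = scene.trajectories.shape[0]
        for t in tracks:
            assert len(t.points) == n_frames
            assert [p.frame for p in t.points] == list(range(n_frames))

    def test_dropout_and_occlusion_still_track_within_10px(self):
        cfg = synth.SceneConfig(seed=11, dropout_rate=0.2)
        scene = synth.generate_scene(cfg)
        frames = synth.degrade_to_detections(scene)
        tracks = tracker.track_clip(frames)
        by_id = {t.animal_id: t for t in tracks}
        frac_ok = np.mean([
            np.linalg.norm(
                by_id[m].as_array() - scene.trajectories[:, a], axis=1) <= 10
            for a, m in enumerate(MARKINGS)
        ])
        assert frac_ok >= 0.95

    def test_tracking_error_monotone_in_dropout(self):
        # Statistical monotone-degradation property over matched seeds.
        rates = (0.0, 0.25, 0.5)
        errors = {r: [] for r in rates}
        for seed in range(20):
            for r in rates:
                cfg = synth.SceneConfig(seed=seed, dropout_rate=r,
                                        duration_s=60.0, n_chase=0)
                scene = synth.generate_scene(cfg)
                frames = synth.degrade_to_detections(scene)
                tracks = tracker.track_clip(frames)
                by_id = {t.animal_id: t for t in tracks}
                err = np.mean([
                    np.linalg.norm(by_id[m].as_array()
                                   - scene.trajectories[:, a], axis=1).mean()
                    for a, m in enumerate(MARKINGS)
                ])
                errors[r].append(err)
        means = [np.mean(errors[r]) for r in rates]
        assert means[0] <= means[1] <= means[2]

    def test_anchor_fraction_diagnostic_on_default_noise(self, noisy_runs):
        fracs = []
        for seed in range(10):
            scene = synth.generate_scene(synth.SceneConfig(seed=seed))
            frames = synth.degrade_to_detections(scene)
            fracs.append(tracker.anchor_fraction(frames))
        assert np.mean(fracs) >= 0.4
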