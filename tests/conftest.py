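import numpy as np
import pytest

from agonipipe import classify, synth, tracker


def noise_free_config(seed: int, **kw) -> synth.SceneConfig:
    kw.setdefault("dropout_rate", 0.0)
    kw.setdefault("jitter_sd_px", 0.0)
    kw.setdefault("kit_clutter_rate", 0.0)
    kw.setdefault("n_occlusion_windows", 0)
    return synth.SceneConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free scene with all three event types planted."""
    return synth.generate_scene(noise_free_config(seed=42))


@pytest.fixture(scope="session")
def clean_detections(clean_scene):
    return synth.degrade_to_detections(clean_scene)


@pytest.fixture(scope="session")
def noisy_runs():
    """Scene -> degrade -> track -> classify under the default noise profile
    for a batch of seeds; shared across recovery and invariant tests."""
    runs = []
    for seed in range(50):
        scene = synth.generate_scene(synth.SceneConfig(seed=seed))
        frames = synth.degrade_to_detections(scene)
        tracks = tracker.track_clip(frames)
        found = classify.classify_clip(tracks)
        runs.append((scene, tracks, found))
    return runs


def match_planted(scene, found, tol_s: float = 3.0):
    """Pair each planted event with a detected interaction of the same dyad
    within ``tol_s`` seconds; returns (n_recovered, n_direction_correct)."""
    recovered = direction = 0
    for ev in scene.planted_events:
        hits = [
            f for f in found
            if abs(f.timestamp_s - ev.timestamp_s) <= tol_s
            and {f.initiator_id, f.receiver_id}
            == {ev.initiator_id, ev.receiver_id}
        ]
        if hits:
            recovered += 1
            direction += hits[0].initiator_id == ev.initiator_id
    return recovered, direction
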