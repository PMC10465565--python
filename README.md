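# agonipipe

Detection of agonistic interactions between group-housed animals from
overhead video, and dominance-hierarchy analytics built on top of them.

Studying dominance in captive groups — the motivating case is four
individually paint-marked rabbit does sharing a commercial group pen with
their litters — traditionally requires a human observer to score every
attack, flee and chase. `agonipipe` implements the computer-vision side
of that workflow for a *fixed* population watched by a fixed camera:

1. **Action segmentation** (`agonipipe.motion`) — a per-second
   motion-magnitude series (dense Farnebäck optical flow at 1 fps, or any
   precomputed series) is filtered and thresholded into *action clips*,
   the short episodes in which at least one animal moves fast.
2. **Tracking** (`agonipipe.tracker`) — per-frame detections (bounding
   boxes, keypoints, and a probability over the four identity markings)
   are assembled into exactly four identity tracks by a seven-step
   tracker that exploits the fixed population: high-confidence anchors,
   isolation filtering, assignment by elimination, greedy tracklet gap
   filling, deduplication, interpolation, smoothing.
3. **Classification** (`agonipipe.classify`) — trajectories are reduced
   to speed series and scanned with rule templates over Chebyshev
   distance and speed (contact-flee, approach-flee, chase), yielding
   time-stamped *directed* interactions: initiator dominates receiver.
   Per movement bout, at most one interaction per pair is kept and the
   interaction graph is forced acyclic.
4. **Hierarchy analytics** (`agonipipe.hierarchy`) — interactions feed a
   time-dependent sociomatrix S(t) whose entry s_ij(t) counts wins of i
   over j before time t. From it the package computes randomized Elo
   ratings (the interaction multiset replayed in 1000 random orders
   through E_i = 1/(1+10^((R_j−R_i)/400)), R_i ← R_i + 100(1−E_i),
   R_j ← R_j − 100·E_i, ratings initialized at 1000), normalized David's
   scores, the rank-indexed interaction-probability matrix P, and an
   Elo-convergence simulation answering: after how many observed
   interactions is the dominant animal identified with high certainty?

A validation module (`agonipipe.validate`) scores automated interaction
lists against human annotations with a time-window tolerance, and a
synthetic scene generator (`agonipipe.synth`) scripts ground-truth pens
with planted events, detection dropout, identity-confidence collapse and
kit-clutter boxes so that the whole pipeline is testable with no video.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

Generate a noisy synthetic scene, run tracking and classification, and
derive hierarchy metrics:

```python
from agonipipe import (SceneConfig, generate_scene, degrade_to_detections,
                       track_clip, classify_clip, build_sociomatrix,
                       randomized_elo, david_scores,
                       simulate_elo_convergence,
                       REFERENCE_INTERACTION_MATRIX)

scene = generate_scene(SceneConfig(seed=7))          # 120 s, 3 planted events
frames = degrade_to_detections(scene)                # noisy detections
tracks = track_clip(frames)                          # 7-step tracker
interactions = classify_clip(tracks)                 # rule-based classifier

for ia in interactions:
    print(f"{ia.timestamp_s:6.2f}s  {ia.initiator_id:>6} > "
          f"{ia.receiver_id:<6} {ia.rule_tag}  ({ia.duration_s:.2f}s)")

animals = ["circle", "line", "tail", "neck"]
s = build_sociomatrix(interactions, animals)
elo = randomized_elo(s, n_reps=1000, seed=7)
david = david_scores(s)
for a in animals:
    print(f"{a:>6}: elo {elo[a]:7.1f}   normDS {david[a]:.2f}")

res = simulate_elo_convergence(REFERENCE_INTERACTION_MATRIX, 64,
                               n_sims=1000, seed=7)
print(f"rank-1 certainty after 64 interactions: "
      f"{res.rank_certainty[64]:.1%}")
```

Output:

```
 10.12s    tail > neck   contact_flee  (1.12s)
 17.72s  circle > tail   chase  (1.96s)
 32.08s  circle > line   approach_flee  (1.12s)
circle: elo  1096.2   normDS 2.25
  line: elo   946.3   normDS 1.25
  tail: elo  1003.7   normDS 1.50
  neck: elo   953.8   normDS 1.00
rank-1 certainty after 64 interactions: 97.9%
```

All three planted events are recovered with the correct initiator;
circle, which initiated two of them, tops both the randomized Elo
ratings and the normalized David's scores (which always sum to
n(n−1)/2 = 6). The last line runs the convergence simulation on the
built-in reference interaction-probability matrix: sampling 64
interactions is enough to name the dominant animal in ~97% of runs.

The same stages are available from the shell:

```sh
agonipipe synth --seed 7 --out-dir pen7/
agonipipe run --in-dir pen7/ --out-dir pen7/out --seed 7
agonipipe simulate --n 64 --sims 1000 --seed 7 --out sim.csv
```

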