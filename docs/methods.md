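# Methods

`agonipipe` turns overhead video of a fixed group of four individually
marked animals (the motivating system is group-housed rabbit does in
commercial pens) into a time-stamped list of directed agonistic
interactions, and from that list derives time-dependent dominance
analytics. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic test bed does and does not show.

## Pipeline model

The pipeline assumes:

* a fixed population — exactly four animals are present in every frame;
* agonistic behaviour of the explosive kind (attack/flee, approach/flee,
  chase) is accompanied by sustained fast locomotion, so pen-level motion
  is a high-recall pre-filter and per-animal speed is the classification
  signal;
* an upstream detector/re-identifier supplies per-frame bounding boxes,
  three keypoints (nose, shoulder, tail base) and a probability over the
  four paint markings (circle, line, tail, neck). Training those networks
  is out of scope; the package consumes their JSON output.

Subtle agonistic signs (threatening, freezing, slow approaches) carry
little motion signal and are deliberately not detected.

### Stage 1 — group-level action segmentation (`motion`)

Dense optical flow between consecutive 1-fps grayscale frames yields the
mean displacement magnitude per second. Flow is computed with the
Farnebäck polynomial-expansion method (pyramid scale 0.5, 3 levels, window
15, 3 iterations, polynomial neighbourhood 5, polynomial sigma 1.2),
implemented in `_farneback.py` on top of numpy/scipy with the classic
parameter surface. On a smooth random texture translated by (3, 4) px the
implementation recovers a mean magnitude of 4.9 against the true 5.0, and
exactly 0 for identical frames.

The magnitude series is segmented by, in order: suppression of values
below 1 px; a centered rolling median (7 s); a centered rolling mean
(15 s); an edge-restoring dilation pass; merging of runs separated by
gaps under 60 s (gap filled with the median of the two neighbouring
runs); retention of runs with mean filtered magnitude above 1.2.

Numerical choices worth recording:

* **Run support vs magnitude.** Support of an action interval is taken
  from the median-filtered signal, which preserves block boundaries
  exactly; the mean-filtered signal (which smears support outward by half
  its window) supplies the magnitudes for the 1.2 retention test. This
  makes segmentation idempotent: constant-high blocks separated by
  ≥ 60 s are returned with their exact boundaries.
* **Dilation pass.** The onset/offset samples eaten by the median filter
  are restored by extending each run outward while the raw suppressed
  signal is nonzero, capped at 7 s (half the median window) per side.
  This recovers real onsets without inventing activity.
* **Boundaries.** Rolling windows shrink at the series edges (no
  padding), avoiding phantom activity at clip boundaries.
* **"Below 1"** is read strictly: a magnitude of exactly 1.0 survives
  suppression.

Hourly summaries count action seconds per clock hour and smooth them with
a Savitzky–Golay filter (window 11 h, order 3); negative fitted values
are ceiled to zero.

### Stage 2 — fixed-population tracking (`tracker`)

Seven sequential steps (anchor assignment at marking confidence ≥ 0.98,
spatio-temporal filtering, assignment by elimination, greedy
nearest-centroid tracklet gap filling, deduplication, linear
interpolation, outlier removal + rolling-mean smoothing) produce exactly
one centroid per animal per frame. Parameters, all in `TrackerConfig`:

| parameter | default | meaning |
|---|---|---|
| `anchor_conf` | 0.98 (inclusive) | marking confidence for anchor boxes |
| `neighbor_frames` / `neighbor_dist_px` | 2 / 60 | step-2 isolation test: an anchor needs a same-track anchor within ±2 frames and 60 px |
| `tracklet_margin` | 0.15 | step-4 acceptance: best chain's mean identity confidence must beat the runner-up by this margin (a lone candidate competes against 0) |
| `smooth_window_frames` | 13 (~0.5 s) | step-7 centered rolling mean |
| `outlier_speed_px_per_frame` | 80 | step-7: points implying this speed both from the previous and to the next point are replaced by interpolation |

The 60 px / 0.15 / 13 / 80 values are package choices where the
procedure itself fixes no number; each is configurable. Ties are broken
deterministically (higher confidence, then nearer previous centroid, then
alphabetical identity). Leading/trailing gaps, which the step list does
not address, are filled by constant extension of the nearest known
centroid and flagged `interpolated` like interior gap fills.

### Stage 3 — rule-based classification (`classify`)

Per-frame speeds (centroid displacement, 5-frame rolling median) cut the
clip into event groups: maximal runs of frames where some animal moves at
≥ 2 px/frame, merged across gaps shorter than 12 frames. Within a group,
three templates are scanned frame by frame (first match wins, in order):

* **contact_flee** — Chebyshev distance ≤ 50 px at onset; initiator speed
  ≤ 5 px/frame over the preceding 10 frames; receiver speed ≥ 5 px/frame
  over the following 10 frames;
* **approach_flee** — initiator ≥ 5 px/frame over the 10 frames before
  onset with the distance decreasing to ≤ 50 px, then initiator ≤ 5 and
  receiver ≥ 5 over the following 10 frames with the distance increasing;
* **chase** — both animals ≥ 5 px/frame for ≥ 15 consecutive frames
  within 100 px Chebyshev; the initiator is the trailing animal, i.e. the
  one whose positions best match the other's positions 5 frames earlier
  (smaller mean lag error).

The 50 px / 5 px-frame / 10-frame constants are the printed operating
thresholds of the underlying rule; the event-group threshold (2
px/frame), merge gap (12 frames) and the chase constants (100 px, 15
frames, lag 5) are package defaults chosen for scale-consistency with
them. The chaser-identification heuristic can be disabled
(`detect_chaser=False`), in which case the alphabetically first animal is
reported — only useful for sensitivity analysis.

Duration runs from onset until both animals stay below 5 px/frame for 10
consecutive frames (capped at the group end). Decision windows in which
more than half of either track is interpolated are skipped as
unreliable. Each group reports at most one interaction per unordered
pair (the earliest), and cycles in the directed initiator→receiver graph
are broken by removing the latest-onset interaction on any cycle until
the graph is acyclic. Circling behaviour is not separately detected; it
is absorbed by this per-group deduplication.

Night-time interactions (the light schedule defaults to 12L:12D with
lights off 20:00–08:00) are flagged `dark` and excluded from hierarchy
analytics by default, because identity cannot be established under
infrared illumination.

### Stage 4 — dominance analytics (`hierarchy`)

The interaction list defines a time-dependent sociomatrix S(t): s_ij(t)
counts interactions with timestamp strictly below t in which i dominated
j (ties at exactly t are excluded).

**Randomized Elo.** The multiset of interactions in S(t) is replayed in
1000 random orders; each replay starts all ratings at 1000 and applies,
per interaction with winner i and loser j,

    E_i = 1 / (1 + 10^((R_j − R_i)/400)),
    R_i ← R_i + 100 (1 − E_i),   R_j ← R_j − 100 E_i.

The loser update uses −100·E_i, which is *not* the conventional zero-sum
Elo (−100·(1 − E_i)); the two coincide only at E_i = ½. The asymmetric
form is implemented verbatim as the primary variant because it is the
update this pipeline is specified against; `elo_variant="standard"`
selects the zero-sum form for comparison. The per-animal mean of the
final ratings over the 1000 replays is the randomized Elo rating;
averaging removes the order dependence of classical Elo. With a fixed
seed the result is reproducible; under relabeling of animals the result
is equivariant in distribution (and exactly for a single interaction),
which is how the tests check it.

**Normalized David's scores.** For each dyad with at least one
interaction, P_ij = s_ij/(s_ij+s_ji); silent dyads contribute zero (the
common convention; `dij_corrected=True` applies the sampling-corrected
proportion instead). DS = w + w2 − l − l2 with w the row sums, w2 = Pw,
l the column sums, l2 = Pᵀl; normalization maps DS onto 0..(n−1) via
(DS + n(n−1)/2)/n. The scores always sum to n(n−1)/2, a property the
suite asserts on random matrices.

**Interaction-probability matrix and convergence.** Pooling interactions
across groups after reindexing each group's animals by final randomized-
Elo rank gives a rank-indexed probability matrix P. The package ships
the reference P estimated from a 20-group commercial study
(`REFERENCE_INTERACTION_MATRIX`, off-diagonal sum 0.9999 as printed).
`simulate_elo_convergence` draws i.i.d. dyad sequences from P and replays
them through the Elo update; each simulated sequence is itself one random
ordering, so no within-simulation re-randomization is performed (an
interpretation choice — the alternative would re-randomize each prefix at
every length). The rank-1 certainty curve — the fraction of simulations
in which the top-ranked animal holds the strictly highest rating after k
interactions — is the headline output: with the reference P, 1000
simulations and 64 interactions it sits near 97%. The first two or three
points of the curve are structurally non-monotone (one win makes rank 1
strictly highest; a second interaction among the others can undo it), so
isotonicity is only asserted past that burn-in.

### Validation (`validate`)

Windowed precision/recall treat an automated and a reference event as the
same when they share the ordered (initiator, receiver) pair and lie
within ±δt seconds (boundary inclusive, since annotator timing is
ambiguous). Matching is existence-based — one event may satisfy several
counterparts — matching the definition the metrics are specified against;
`matching="one2one"` provides the stricter Hungarian alternative for
sensitivity analysis. The finer ethogram categories of manual
annotations are collapsed to the ordered pair. Error-mode counts
(false positives, id swaps, missed events) are expressed as percentages
of the detected count, rounded to two decimals.

## The synthetic test bed (`synth`)

The generator scripts four animals in a 640×360 px pen at 25 fps. Planted
events realize the three rule templates with flee/chase speeds of 7–8
px/frame (within the 6–12 px/frame range of real bouts); staging walks
run at 1.8 px/frame, below the movement threshold, so only planted events
form event groups. Events are laid out on horizontal lanes chosen to keep
more than 55 px Chebyshev clearance from resting bystanders — without
that clearance the contact rule correctly (by its own logic) implicates a
bystander the flight passes, which is a real failure mode of rule-based
classification, not of the generator. Every planted event is verified
against the rule evaluator before the scene is emitted.

Degradation to detections models: detection dropout (default 10%),
centroid jitter (Gaussian, σ = 2 px), occlusion windows (2 windows of
2 s) in which identity confidence collapses to 0.4 — below the anchor
threshold, forcing the tracker's gap machinery — and spurious kit-cluster
boxes (rate 0.05/frame) with uniform identity probabilities. The
defaults are the package's standing noise profile for calibration
claims: under it, planted-event recall is ≥ 90% and direction accuracy
≥ 95% over 50 seeds, and the anchor fraction diagnostic stays ≥ 0.4.

What the generator does **not** emulate: rendered pixels (the flow stage
is tested on translated textures instead), curved or erratic flight
paths, simultaneous overlapping events, animals jumping onto platforms
(a known real-world failure source for the dominant/subordinate call),
kits as tracked agents, and night-vision imagery. Passing tests
therefore demonstrate the internal consistency of the pipeline and its
robustness to the modelled noise, not field performance; field
precision/recall can only be measured against human annotation of real
video.

## Problem sizes

Default test scenes last 120 s (3000 frames) with three planted events;
batch properties use 20–50 seeds. Hierarchy analytics use the specified
1000 randomization repetitions and 1000 simulations. These sizes were
chosen so the full suite exercises every stage end to end in a few
minutes on a single core.

## Known limitations

* The two non-contact rule templates and the chase-initiator heuristic
  are reconstructions of idealized signature plots, not published rule
  text; they are configurable and clearly separated in the code.
* The greedy gap filler only consumes unassigned boxes; it never revisits
  low-confidence boxes already claimed by another track.
* Whether interaction duration should be measured per pair or per event
  group is ambiguous; the package uses per-pair motion decay.
* The exact structuring element of the edge-restoring dilation is a
  package choice (raw-signal-gated, 7-s cap) and a known divergence risk
  against other implementations of the same filter chain.
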