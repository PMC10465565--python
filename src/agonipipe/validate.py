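"""Comparison of automated interaction lists against reference annotations.

Automated detections and human annotations of the same footage rarely align
frame-perfectly: onset times are ambiguous and annotators split or merge
bouts differently.  Agreement is therefore measured with a time-window
tolerance: an event counts as matched when the other list contains an event
of the same type — the same ordered (initiator, receiver) pair — within
±delta_t seconds (boundary inclusive).  Matching is existence-based: a
single event may satisfy several counterparts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class AnnotatedEvent:
    timestamp_s: float
    initiator_id: str
    receiver_id: str
    source: str = "auto"  # auto | manual


def _matched_fraction(events, pool, delta_t_s: float) -> float:
    hits = 0
    for e in events:
        if any(
            o.initiator_id == e.initiator_id
            and o.receiver_id == e.receiver_id
            and abs(o.timestamp_s - e.timestamp_s) <= delta_t_s
            for o in pool
        ):
            hits += 1
    return hits / len(events)


def _one2one_fraction(events, pool, delta_t_s: float) -> float:
    """Optimal one-to-one matching (assignment problem) variant."""
    cost = np.ones((len(events), len(pool)))
    for i, e in enumerate(events):
        for j, o in enumerate(pool):
            if (o.initiator_id == e.initiator_id
                    and o.receiver_id == e.receiver_id
                    and abs(o.timestamp_s - e.timestamp_s) <= delta_t_s):
                cost[i, j] = 0.0
    ri, cj = optimize.linear_sum_assignment(cost)
    return float(np.sum(cost[ri, cj] == 0.0)) / len(events)


def windowed_precision_recall(
    auto: Sequence[AnnotatedEvent],
    manual: Sequence[AnnotatedEvent],
    delta_t_s: float,
    matching: str = "existence",
) -> tuple[float, float]:
    """Precision and recall under a ±delta_t_s tolerance window.

    Recall is the fraction of manual events with a same-type automated event
    within the window; precision is the symmetric fraction over automated
    events.  Empty lists yield NaN for the affected metric with a warning.
    ``matching="one2one"`` switches to strict bipartite (Hungarian)
    matching.
    """
    frac = _one2one_fraction if matching == "one2one" else _matched_fraction
    if auto:
        precision = frac(auto, manual, delta_t_s)
    else:
        warnings.warn("no automated events; precision undefined")
        precision = float("nan")
    if manual:
        recall = frac(manual, auto, delta_t_s)
    else:
        warnings.warn("no manual events; recall undefined")
        recall = float("nan")
    return precision, recall


def error_mode_summary(
    n_detected: int, n_false_pos: int, n_id_swap: int, n_missed: int,
) -> tuple[float, float, float]:
    """Express error-mode counts as percentages of the detected count.

    Returns (false-positive %, id-swap %, missed %), rounded to 2 decimals.
    """
    if n_detected <= 0:
        raise ValueError("n_detected must be positive")
    pct = lambda k: round(100.0 * k / n_detected, 2)
    return pct(n_false_pos), pct(n_id_swap), pct(n_missed)


def elo_agreement(auto_ratings: Sequence[float],
                  manual_ratings: Sequence[float]) -> float:
    """Pearson correlation between paired per-animal ratings obtained from
    the automated pipeline and from reference annotations."""
    r, _ = stats.pearsonr(np.asarray(auto_ratings, dtype=float),
                          np.asarray(manual_ratings, dtype=float))
    return float(r)
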