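"""Matplotlib helpers for the standard hierarchy figures."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .hierarchy import ConvergenceResult  # noqa: E402


def plot_elo_trajectory(curves: pd.DataFrame, path) -> None:
    """Randomized-Elo rating curves over time, one line per animal.

    ``curves`` is the DataFrame produced by :func:`hierarchy.elo_trajectory`
    (index = grid time in seconds, columns = animals).
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    hours = np.asarray(curves.index, dtype=float) / 3600.0
    for animal in curves.columns:
        ax.plot(hours, curves[animal], label=animal)
    ax.axhline(1000.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("time since grouping (h)")
    ax.set_ylabel("randomized Elo rating")
    ax.legend(title="marking")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_convergence(res: ConvergenceResult, path,
                     labels: Sequence[str] | None = None) -> None:
    """Mean simulated rating per rank with its 95% envelope, plus the
    rank-1 certainty curve on a twin axis."""
    n = res.mean.shape[1]
    labels = labels or [f"rank {r + 1}" for r in range(n)]
    x = np.arange(res.mean.shape[0])
    fig, ax = plt.subplots(figsize=(7, 4))
    for r in range(n):
        ax.plot(x, res.mean[:, r], label=labels[r])
        ax.fill_between(x, res.ci_low[:, r], res.ci_high[:, r], alpha=0.15)
    ax.set_xlabel("number of observed interactions")
    ax.set_ylabel("randomized Elo rating")
    ax.legend(loc="upper left")
    ax2 = ax.twinx()
    ax2.plot(x, res.rank_certainty, color="black", lw=1.0, ls=":")
    ax2.set_ylabel("rank-1 certainty")
    ax2.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
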