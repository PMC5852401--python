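"""Box-whisker and cumulative-curve plots for distance distributions."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .distance_metrics import DistanceSet
from .similarity_analysis import distance_histogram


def plot_box_whisker(
    sets: Sequence[DistanceSet], out: str | Path | None = None, ax=None
):
    """Box-whisker plot of one or more distance sets; whiskers at Q3+1.5*IQR
    (and Q1-1.5*IQR below), fliers shown as points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(sets), 4))
    ax.boxplot(
        [ds.values for ds in sets],
        tick_labels=[ds.group_label or ds.metric.name for ds in sets],
        whis=1.5,
    )
    ax.set_ylabel(f"{sets[0].metric.name} distance")
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_cumulative(
    sets: Sequence[DistanceSet], n_bins: int = 100,
    out: str | Path | None = None, ax=None,
):
    """Cumulative distance-histogram curves, the visual companion of the
    two-sample Kolmogorov-Smirnov statistic."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for ds in sets:
        h = distance_histogram(ds, n_bins=n_bins)
        ax.step(h.edges[1:], h.cumulative, where="post",
                label=ds.group_label or ds.metric.name)
    ax.set_xlabel(f"{sets[0].metric.name} distance")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
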