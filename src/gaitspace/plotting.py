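"""Optional matplotlib figures: dendrograms, polar phase histograms, footfalls."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from .cluster import CircularHistogram, LinkageTree
from .simulate import FootfallPattern

__all__ = ["plot_dendrogram", "plot_circular_histogram", "plot_footfall"]


def plot_dendrogram(tree: LinkageTree, path: str, max_leaves: int = 50) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(tree.merges, ax=ax, truncate_mode="lastp", p=max_leaves, no_labels=True)
    ax.set_ylabel("dissimilarity (normalized gait distance)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_circular_histogram(
    hist: CircularHistogram, path: str, title: str = ""
) -> None:
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    centers = 2 * np.pi * (hist.edges[:-1] + hist.edges[1:]) / 2
    width = 2 * np.pi * np.diff(hist.edges)
    ax.bar(centers, hist.counts, width=width, fill=False, edgecolor="C0")
    theta = 2 * np.pi * hist.mean_direction
    ax.plot([theta, theta], [0, hist.resultant_length * max(hist.counts.max(), 1)],
            color="C0", lw=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_footfall(pattern: FootfallPattern, labels, path: str) -> None:
    n_legs = pattern.stance.shape[0]
    fig, ax = plt.subplots(figsize=(8, 0.5 * n_legs + 1))
    for k in range(n_legs):
        on = pattern.stance[k]
        edges = np.flatnonzero(np.diff(on.astype(int)) != 0) + 1
        bounds = np.concatenate([[0], edges, [on.size]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if on[lo]:
                ax.plot(
                    pattern.time_cycles[[lo, hi - 1]], [n_legs - k] * 2,
                    color="k", lw=6, solid_capstyle="butt",
                )
    ax.set_yticks(range(n_legs, 0, -1), list(labels))
    ax.set_xlabel("time (stride cycles)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
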