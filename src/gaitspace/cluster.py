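"""Unsupervised grouping of gait points.

Pairwise normalized gait distances feed Ward hierarchical agglomerative
clustering; the dendrogram is cut below its highest merges, cluster
centroids are per-coordinate circular means, and clusters are named after
the nearest model gait.  A per-point nearest-model classifier provides the
baseline against which clustering is validated, and circular histograms
summarize the phase-difference distributions per leg pair.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .space import (
    GaitMetricTensor,
    GaitPoint,
    ModelGait,
    distances_to,
    signed_circular_delta,
)

__all__ = [
    "LinkageTree",
    "ClusterResult",
    "CircularHistogram",
    "pairwise_distances",
    "ward_linkage",
    "cut_clusters",
    "cluster_centroid",
    "name_clusters",
    "nearest_model_assignment",
    "cluster_gait_points",
    "cluster_summaries",
    "circular_histogram",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LinkageTree:
    """Agglomerative merge history (scipy linkage matrix)."""

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclasses.dataclass
class ClusterResult:
    """Labels, centroids and model proximities for one clustering run."""

    labels: np.ndarray                       # 1..k per gait point
    k: int
    tree: LinkageTree
    centroids: dict[int, GaitPoint]
    names: dict[int, str]                    # cluster id -> e.g. "MT1"
    model_proximity: dict[tuple[int, str], tuple[float, tuple[float, float]]]
    # (cluster id, model name) -> (mean normalized distance, 95% CI)


@dataclasses.dataclass
class CircularHistogram:
    """Binned circular distribution of one phase-difference coordinate."""

    edges: np.ndarray      # n_bins + 1 edges on [0, 1]
    counts: np.ndarray
    mean_direction: float  # cycles in [0, 1)
    resultant_length: float  # R in [0, 1]


def pairwise_distances(points: np.ndarray, metric: GaitMetricTensor) -> np.ndarray:
    """Condensed matrix of normalized gait distances between all point pairs."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if d != metric.ndim:
        raise ValueError("dimension mismatch with metric")
    if n < 2:
        raise ValueError("need at least 2 points")
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    from .space import _form

    for i in range(n - 1):
        x = signed_circular_delta(pts[i + 1 :], pts[i])
        block = np.sqrt(np.einsum("ij,jk,ik->i", x, metric.g, x))
        for j in np.flatnonzero((np.abs(x) == 0.5).any(axis=1)):
            block[j] = _form(x[j], metric.g)
        out[pos : pos + block.size] = block
        pos += block.size
    return out / metric.d_max


def ward_linkage(condensed: np.ndarray) -> LinkageTree:
    """Ward's linkage on a precomputed condensed gait-distance matrix.

    The distances are non-Euclidean (hypertorus quotient metric), so Ward's
    variance interpretation is heuristic here; it is applied directly to the
    precomputed distances via the Lance-Williams update, matching common
    practice with gait distances.
    """
    condensed = np.asarray(condensed, dtype=float)
    if condensed.ndim != 1 or condensed.size < 1:
        raise ValueError("need a condensed distance matrix for >= 2 points")
    return LinkageTree(merges=linkage(condensed, method="ward"))


def cut_clusters(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels 1..k from cutting the dendrogram below its k-1 highest merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    return fcluster(tree.merges, t=k, criterion="maxclust")


def cluster_centroid(points: np.ndarray) -> GaitPoint:
    """Per-coordinate circular mean of a cluster's gait points, in [0, 1)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("empty cluster")
    ang = 2.0 * np.pi * pts
    mean = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return GaitPoint(tuple((mean / (2.0 * np.pi)) % 1.0))


def name_clusters(
    centroids: Mapping[int, GaitPoint],
    models: Sequence[ModelGait],
    metric: GaitMetricTensor,
) -> dict[int, str]:
    """Name each cluster after its nearest model gait.

    Clusters sharing a nearest model are numbered by increasing centroid
    distance, so "MT1" is closer to the modified tripod than "MT2".
    """
    nearest: dict[int, tuple[str, float]] = {}
    for cid, c in centroids.items():
        dists = [distances_to(c.as_array(), m, metric)[0] for m in models]
        j = int(np.argmin(dists))
        nearest[cid] = (models[j].name, float(dists[j]))
    names: dict[int, str] = {}
    for model_name in {v[0] for v in nearest.values()}:
        members = sorted(
            (cid for cid, v in nearest.items() if v[0] == model_name),
            key=lambda cid: nearest[cid][1],
        )
        for rank, cid in enumerate(members, start=1):
            names[cid] = f"{model_name}{rank}"
    return names


def nearest_model_assignment(
    points: np.ndarray,
    models: Sequence[ModelGait],
    metric: GaitMetricTensor,
) -> np.ndarray:
    """Label each gait point with the name of its nearest model gait.

    Exact ties break deterministically toward the earliest model in the given
    (canonical) order and are logged.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dists = np.column_stack([distances_to(pts, m, metric) for m in models])
    best = np.argmin(dists, axis=1)  # argmin takes the first index on ties
    ties = (dists == dists[np.arange(len(pts)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "%d point(s) equidistant to multiple models; broke ties toward "
            "the canonical order",
            int(ties.sum()),
        )
    names = np.array([m.name for m in models])
    return names[best]


def cluster_gait_points(
    points: np.ndarray,
    models: Sequence[ModelGait],
    metric: GaitMetricTensor,
    k: int = 3,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Full clustering pipeline: distances, Ward tree, cut, centroids, names.

    ``k`` defaults to 3, the choice used for empirical datasets; use k=2 for
    two-model simulation mixtures.
    """
    from .space import dataset_to_model

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tree = ward_linkage(pairwise_distances(pts, metric))
    labels = cut_clusters(tree, k)
    centroids = {
        int(cid): cluster_centroid(pts[labels == cid]) for cid in np.unique(labels)
    }
    names = name_clusters(centroids, models, metric)
    rng = np.random.default_rng(seed)
    proximity: dict[tuple[int, str], tuple[float, tuple[float, float]]] = {}
    for cid in centroids:
        member = pts[labels == cid]
        for m in models:
            proximity[(cid, m.name)] = dataset_to_model(
                member, m, metric, n_boot=n_boot, seed=rng
            )
    return ClusterResult(
        labels=labels,
        k=k,
        tree=tree,
        centroids=centroids,
        names=names,
        model_proximity=proximity,
    )


@dataclasses.dataclass
class ClusterSummary:
    """Kinematic and stability statistics for one cluster (per-frame pooling)."""

    n_frames: int
    speed_mean: float
    speed_sd: float
    ssm_median: float
    ssm_mad: float
    n_support_counts: dict[int, int]


def cluster_summaries(
    labels: np.ndarray,
    speed: np.ndarray,
    ssm: np.ndarray,
    n_support: np.ndarray,
) -> dict[int, ClusterSummary]:
    """Per-cluster speed mean +/- sd, SSM median +/- MAD and N_support histogram."""
    labels = np.asarray(labels)
    speed = np.asarray(speed, dtype=float)
    ssm = np.asarray(ssm, dtype=float)
    n_support = np.asarray(n_support)
    if not (labels.size == speed.size == ssm.size == n_support.size):
        raise ValueError("labels, speed, ssm and n_support must be frame-aligned")
    out: dict[int, ClusterSummary] = {}
    for cid in np.unique(labels):
        sel = labels == cid
        s, m, ns = speed[sel], ssm[sel], n_support[sel]
        m_fin = m[np.isfinite(m)]
        med = float(np.median(m_fin)) if m_fin.size else float("nan")
        mad = float(np.median(np.abs(m_fin - med))) if m_fin.size else float("nan")
        vals, counts = np.unique(ns, return_counts=True)
        out[int(cid)] = ClusterSummary(
            n_frames=int(sel.sum()),
            speed_mean=float(s.mean()),
            speed_sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
            ssm_median=med,
            ssm_mad=mad,
            n_support_counts={int(v): int(c) for v, c in zip(vals, counts)},
        )
    return out


def circular_histogram(samples: np.ndarray, n_bins: int = 24) -> CircularHistogram:
    """Histogram on the unit circle plus the circular mean vector.

    The mean direction is the angle of the resultant of the samples mapped to
    the circle; its length R is 1 for perfectly concentrated samples and
    tends to 0 for uniform ones.
    """
    x = np.asarray(samples, dtype=float) % 1.0
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise ValueError("need at least 1 sample")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    ang = 2.0 * np.pi * x
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    return CircularHistogram(
        edges=edges,
        counts=counts,
        mean_direction=float(np.arctan2(s, c) / (2.0 * np.pi) % 1.0),
        resultant_length=float(np.hypot(c, s)),
    )
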