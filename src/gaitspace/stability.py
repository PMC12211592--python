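"""Static-stability and posture measures.

Per-frame support polygons (convex hulls of the tarsi in stance), the static
stability margin (SSM) and its ideal value (ISSM), adjacent-leg spacing
angles, tarsal range of motion with robust outlier removal, and leg
extension in the body frame.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

from .trackio import BodyFrameTrial, TrackedTrial

__all__ = [
    "SupportPolygon",
    "StabilityTrace",
    "PostureSummary",
    "support_polygon",
    "stability_margins",
    "stability_trace",
    "leg_spacing",
    "range_of_motion",
    "leg_extension",
    "mean_leg_directions",
    "posture_summary",
]


@dataclasses.dataclass
class SupportPolygon:
    """Convex hull of the stance tarsi in one frame."""

    vertices: np.ndarray   # (m, 2), hull vertices in order; all points if degenerate
    n_support: int
    degenerate: bool       # fewer than 3 distinct non-collinear supports
    area: float


@dataclasses.dataclass
class StabilityTrace:
    """Per-frame stability measures for a trial."""

    stance_sets: list[tuple[str, ...]]
    polygons: list[SupportPolygon]
    n_support: np.ndarray
    ssm: np.ndarray    # mm, signed; negative outside the hull or when degenerate
    issm: np.ndarray   # mm, margin with the COM at the polygon centroid


@dataclasses.dataclass
class PostureSummary:
    """Per-leg posture measures in the body frame."""

    directions: dict[str, float]        # mean bearing about the COM, deg in [0, 360)
    spacing: dict[tuple[str, str], float]   # adjacent-leg angles, deg
    uniform_expectation: float          # 360 / n_legs, deg
    rom_area: dict[str, float]          # range-of-motion hull area, mm^2
    rom_flag: dict[str, bool]           # True if area undefined (<3 survivors)
    extension: dict[str, tuple[float, float]]  # (fore-aft, lateral) mm


def support_polygon(points: np.ndarray | Sequence) -> SupportPolygon:
    """Convex hull of the stance tarsus positions.

    Fewer than three distinct, non-collinear points give a degenerate
    (zero-area) polygon; the empty set gives an empty polygon.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return SupportPolygon(np.empty((0, 2)), 0, True, 0.0)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 3:
        return SupportPolygon(uniq, n, True, 0.0)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return SupportPolygon(uniq, n, True, 0.0)
    return SupportPolygon(pts[hull.vertices], n, False, float(hull.volume))


def stability_margins(polygon: SupportPolygon, com: np.ndarray) -> tuple[float, float]:
    """Static stability margin and its ideal value, in mm.

    SSM is the minimum distance from the COM's ground projection to the
    support polygon's edges: positive inside the polygon, zero on its
    boundary, and the negated distance to the hull when outside or when the
    support is degenerate (< 3 supports cannot enclose the COM).  ISSM is the
    same margin evaluated with the COM at the polygon's area centroid, the
    maximum attainable for that support.
    """
    com = np.asarray(com, dtype=float)
    if polygon.n_support == 0:
        return math.nan, math.nan
    if polygon.degenerate:
        geom = (
            Point(polygon.vertices[0])
            if polygon.vertices.shape[0] == 1
            else LineString(polygon.vertices)
        )
        ssm = -geom.distance(Point(com))
        return float(ssm), 0.0
    poly = Polygon(polygon.vertices)
    p = Point(com)
    d = poly.exterior.distance(p)
    ssm = d if poly.contains(p) or poly.touches(p) else -d
    issm = poly.exterior.distance(poly.centroid)
    return float(ssm), float(issm)


def stability_trace(
    trial: TrackedTrial, stance_masks: Mapping[str, np.ndarray]
) -> StabilityTrace:
    """Per-frame support polygon, N_support, SSM and ISSM for a trial.

    Uses lab-frame tarsus coordinates of the legs flagged in stance and the
    COM's ground projection in the same frame.
    """
    n = trial.n_frames
    stance_sets: list[tuple[str, ...]] = []
    polygons: list[SupportPolygon] = []
    n_support = np.zeros(n, dtype=int)
    ssm = np.full(n, np.nan)
    issm = np.full(n, np.nan)
    legs = [l for l in trial.present_legs if l in stance_masks]
    for i in range(n):
        in_stance = tuple(l for l in legs if stance_masks[l][i])
        pts = np.array([trial.tarsi[l][i] for l in in_stance]).reshape(-1, 2)
        poly = support_polygon(pts)
        stance_sets.append(in_stance)
        polygons.append(poly)
        n_support[i] = poly.n_support
        ssm[i], issm[i] = stability_margins(poly, trial.com[i])
    return StabilityTrace(stance_sets, polygons, n_support, ssm, issm)


def leg_spacing(
    directions: Mapping[str, float]
) -> tuple[dict[tuple[str, str], float], float]:
    """Angles between angularly adjacent legs about the COM.

    ``directions`` maps leg labels to mean bearings in degrees.  Returns the
    gap between each pair of neighbours in angular order (keyed by the pair,
    summing to 360 deg) and the uniform-spacing expectation 360 / n_legs.
    """
    if len(directions) < 2:
        raise ValueError("need at least 2 legs")
    labels = list(directions)
    angles = np.array([directions[l] % 360.0 for l in labels])
    if len(np.unique(np.round(angles, 9))) < len(labels):
        import warnings

        warnings.warn("coincident leg directions; spacing is degenerate")
    order = np.argsort(angles)
    gaps: dict[tuple[str, str], float] = {}
    for k in range(len(order)):
        a, b = order[k], order[(k + 1) % len(order)]
        gap = (angles[b] - angles[a]) % 360.0
        if k == len(order) - 1 and len(order) > 1:
            gap = (angles[b] - angles[a]) % 360.0
        gaps[(labels[a], labels[b])] = float(gap)
    return gaps, 360.0 / len(labels)


def range_of_motion(
    points: np.ndarray, mad_factor: float = 3.0
) -> tuple[float, bool]:
    """Convex-hull area of a tarsus's positions after robust outlier removal.

    Radial distances from the coordinate-wise 2-D median are screened with
    the median/MAD rule: points whose distance deviates from the median
    distance by more than ``mad_factor`` times the MAD are dropped.  Returns
    (area in mm^2, undefined flag); the flag is set when fewer than three
    points survive.  A degenerate (collinear/coincident) survivor set has
    area 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.shape[0] == 0:
        return math.nan, True
    center = np.median(pts, axis=0)
    r = np.linalg.norm(pts - center, axis=1)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    keep = np.abs(r - med) <= mad_factor * mad if mad > 0 else np.ones(r.size, bool)
    survivors = pts[keep]
    if survivors.shape[0] < 3:
        return math.nan, True
    try:
        hull = ConvexHull(survivors)
    except QhullError:
        return 0.0, False
    return float(hull.volume), False


def leg_extension(body_frame_xy: np.ndarray) -> tuple[float, float]:
    """Mean fore-aft and lateral tarsus-to-COM distances in the body frame (mm)."""
    xy = np.asarray(body_frame_xy, dtype=float).reshape(-1, 2)
    xy = xy[np.isfinite(xy).all(axis=1)]
    if xy.shape[0] == 0:
        return math.nan, math.nan
    lateral = float(np.abs(xy[:, 0]).mean())
    fore_aft = float(np.abs(xy[:, 1]).mean())
    return fore_aft, lateral


def mean_leg_directions(bf: BodyFrameTrial) -> dict[str, float]:
    """Circular-mean bearing of each tarsus about the COM, deg in [0, 360)."""
    out: dict[str, float] = {}
    for leg, xy in bf.tarsi_bf.items():
        good = np.isfinite(xy).all(axis=1) & bf.valid_mask
        theta = np.arctan2(xy[good, 1], xy[good, 0])
        mean = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
        out[leg] = math.degrees(mean) % 360.0
    return out


def posture_summary(bf: BodyFrameTrial, mad_factor: float = 3.0) -> PostureSummary:
    """Posture measures for one trial in the body frame."""
    directions = mean_leg_directions(bf)
    spacing, expectation = leg_spacing(directions)
    rom_area: dict[str, float] = {}
    rom_flag: dict[str, bool] = {}
    extension: dict[str, tuple[float, float]] = {}
    for leg, xy in bf.tarsi_bf.items():
        good = xy[np.isfinite(xy).all(axis=1)]
        rom_area[leg], rom_flag[leg] = range_of_motion(good, mad_factor)
        extension[leg] = leg_extension(good)
    return PostureSummary(
        directions=directions,
        spacing=spacing,
        uniform_expectation=expectation,
        rom_area=rom_area,
        rom_flag=rom_flag,
        extension=extension,
    )
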