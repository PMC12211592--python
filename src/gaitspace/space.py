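"""Hypertorus gait space: leg phases, phase differences, the gait metric and distances.

A gait of an animal with ``N`` legs is summarized by the ``N - 1`` phase
differences between adjacent legs (ordered counterclockwise in dorsal view
from the foremost left leg to the foremost right leg).  Each phase difference
is periodic on [0, 1) cycles, so a gait is a point on an (N-1)-dimensional
hypertorus.  Distances between gaits use the metric induced on these
successive-difference coordinates by quotienting the flat, unit-weight
leg-phase space by a common phase shift of all legs: two leg-coordination
patterns that differ only by *when* the cycle starts are the same gait.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CANONICAL_LEGS",
    "LegOrdering",
    "PhaseSeries",
    "GaitPoint",
    "ModelGait",
    "GaitMetricTensor",
    "ConstantSignalError",
    "standardize",
    "estimate_phase",
    "phase_differences",
    "model_gaits",
    "circular_delta",
    "signed_circular_delta",
    "metric_tensor",
    "gait_distance",
    "dataset_to_model",
]

#: Canonical dorsal-view circuit: foremost left leg, down the left side,
#: around the rear, back up the right side to the foremost right leg.
CANONICAL_LEGS: tuple[str, ...] = ("L1", "L2", "L3", "L4", "R4", "R3", "R2", "R1")


class ConstantSignalError(ValueError):
    """A constant series carries no oscillation phase (e.g. a dragged leg)."""


@dataclasses.dataclass(frozen=True)
class LegOrdering:
    """Present legs in the canonical counterclockwise circuit."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate leg labels")
        unknown = set(self.labels) - set(CANONICAL_LEGS)
        if unknown:
            raise ValueError(f"unknown leg labels: {sorted(unknown)}")
        canon = tuple(l for l in CANONICAL_LEGS if l in self.labels)
        if canon != tuple(self.labels):
            raise ValueError(
                f"labels must follow the canonical circuit; expected {canon}"
            )

    @classmethod
    def from_present(cls, present: Iterable[str]) -> "LegOrdering":
        present = set(present)
        return cls(tuple(l for l in CANONICAL_LEGS if l in present))

    @property
    def n_legs(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class PhaseSeries:
    """Per-leg oscillation phase in cycles, one row per leg in ordering."""

    ordering: LegOrdering
    phases: np.ndarray  # (n_legs, n_frames), values in [0, 1) or NaN

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.shape[0] != self.ordering.n_legs:
            raise ValueError("one phase row per ordered leg required")


@dataclasses.dataclass(frozen=True)
class GaitPoint:
    """A point on the gait hypertorus: N_legs - 1 phase differences in cycles."""

    dphi: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dphi", tuple(float(v) % 1.0 for v in self.dphi))

    @property
    def ndim(self) -> int:
        return len(self.dphi)

    def as_array(self) -> np.ndarray:
        return np.array(self.dphi, dtype=float)


@dataclasses.dataclass(frozen=True)
class ModelGait:
    """A named idealized coordination pattern."""

    name: str
    point: GaitPoint

    @property
    def n_legs(self) -> int:
        return self.point.ndim + 1


#: Canonical model order used for deterministic tie-breaking.
MODEL_ORDER = ("ALT", "ABT", "MT")


def model_gaits(n_legs: int, missing: Iterable[str] | None = None) -> list[ModelGait]:
    """Named model gaits valid for a leg count.

    Eight intact legs admit the alternating tetrapod (ALT, all adjacent pairs
    in antiphase).  Six legs after loss of the diagonal pair {L4, R1} admit the
    ablated tetrapod (ABT: the two legs flanking the gap move together, so the
    third phase difference is 0) and the modified tripod (MT, all 0.5).
    """
    if missing is not None:
        missing = set(missing)
    if n_legs == 8:
        if missing:
            raise LookupError("no named models for 8 legs with missing legs")
        return [ModelGait("ALT", GaitPoint((0.5,) * 7))]
    if n_legs == 6:
        if missing is not None and missing != {"L4", "R1"}:
            raise LookupError(
                f"named 6-leg models assume missing legs {{L4, R1}}, got {sorted(missing)}"
            )
        return [
            ModelGait("ABT", GaitPoint((0.5, 0.5, 0.0, 0.5, 0.5))),
            ModelGait("MT", GaitPoint((0.5,) * 5)),
        ]
    raise LookupError(f"no named model gaits for n_legs={n_legs}")


def standardize(series: np.ndarray) -> np.ndarray:
    """Scale a series to zero mean and unit (sample) variance.

    Raises
    ------
    ConstantSignalError
        If the series has zero variance; such a leg cannot be phased.
    """
    x = np.asarray(series, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ConstantSignalError("need at least 2 finite samples")
    mean = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ConstantSignalError("zero-variance series carries no phase")
    return (x - mean) / sd


def estimate_phase(y_std: np.ndarray, v_std: np.ndarray) -> np.ndarray:
    """Effective oscillation phase, in cycles, from standardized position/velocity.

    Treats the tarsus as a noisy harmonic oscillator: for y = A cos(wt) the
    pair (y, -v/w) traces the unit circle, so after standardizing both series
    the four-quadrant angle of (y_hat, -v_hat) recovers the phase:

        phi = atan2(-v_hat, y_hat) / 2 pi   (mod 1)

    Frames where both inputs are exactly zero (or non-finite) get NaN.
    """
    y = np.asarray(y_std, dtype=float)
    v = np.asarray(v_std, dtype=float)
    if y.shape != v.shape:
        raise ValueError("position and velocity series must share a shape")
    phi = np.arctan2(-v, y) / (2.0 * np.pi) % 1.0
    undefined = ((y == 0.0) & (v == 0.0)) | ~np.isfinite(y) | ~np.isfinite(v)
    phi = np.where(undefined, np.nan, phi)
    return phi


def phase_differences(phases: PhaseSeries) -> np.ndarray:
    """Adjacent-leg phase differences per frame.

    Returns an (n_frames, n_legs - 1) array with
    ``dphi_i = (phi_{i+1} - phi_i) mod 1`` along the leg ordering.  Frames
    with any undefined leg phase yield NaN rows.  Adding a common constant to
    every leg's phase leaves the result unchanged.
    """
    p = phases.phases
    if p.shape[0] < 2:
        raise ValueError("need at least 2 legs")
    d = (p[1:] - p[:-1]).T % 1.0
    d[d == 1.0] = 0.0  # float rounding at the wrap point
    return d


def circular_delta(a, b) -> np.ndarray | float:
    """Minimal circular distance between phases in cycles, in [0, 0.5]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 1.0
    out = np.minimum(d, 1.0 - d)
    if np.ndim(out) == 0:
        return float(out)
    return out


def signed_circular_delta(a, b) -> np.ndarray | float:
    """Wrapped signed difference a - b mapped to (-0.5, 0.5] cycles.

    Its absolute value is :func:`circular_delta`; the sign records which way
    around the circle the minimal separation runs, which the quadratic form
    needs for its cross terms to equal the common-phase-minimized leg-space
    distance.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 0.5) % 1.0 - 0.5
    # map -0.5 to +0.5 so the representative is unique
    d = np.where(d == -0.5, 0.5, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


@dataclasses.dataclass(frozen=True)
class GaitMetricTensor:
    """Quadratic form on phase-difference coordinates plus its maximum distance."""

    n_legs: int
    g: np.ndarray        # (n_legs-1, n_legs-1), symmetric positive definite
    d_max: float         # cycles, attained when every delta is 0.5

    @property
    def ndim(self) -> int:
        return self.n_legs - 1


def metric_tensor(n_legs: int) -> GaitMetricTensor:
    """The gait-space metric tensor for ``n_legs`` legs.

    Start from the flat metric on the N leg phases with unit weight per leg,
    and quotient by the common phase (a rigid rotation of every leg's cycle).
    In the successive-difference coordinates dphi_i this induces

        g_ij = min(N - i, N - j) - (N - i)(N - j) / N ,   i, j = 1..N-1,

    which weights every leg pair equally while removing the mean phase.  The
    maximum distance between two gaits is attained when every coordinate
    separation is 0.5 cycles: d_max = sqrt(0.25 * sum_ij g_ij).
    """
    if n_legs < 2:
        raise ValueError("need at least 2 legs")
    n = int(n_legs)
    a = n - np.arange(1, n)  # N - i for i = 1..N-1
    g = np.minimum.outer(a, a) - np.outer(a, a) / n
    d_max = float(np.sqrt(0.25 * g.sum()))
    return GaitMetricTensor(n_legs=n, g=g, d_max=d_max)


def _form(x: np.ndarray, g: np.ndarray) -> float:
    """sqrt(x g x), resolving the sign ambiguity of coordinates at exactly 0.5.

    A separation of half a cycle has two equally minimal wrapped
    representatives (+0.5 and -0.5).  The branch maximizing the form is taken:
    this is symmetric in the argument order (swapping the gaits negates every
    candidate vector) and preserves the convention that the maximum distance
    d_max is attained when every coordinate separation is half a cycle.
    """
    boundary = np.flatnonzero(np.abs(x) == 0.5)
    if boundary.size == 0:
        return float(np.sqrt(x @ g @ x))
    best = -np.inf
    for bits in range(1 << boundary.size):
        v = x.copy()
        for j, idx in enumerate(boundary):
            if bits >> j & 1:
                v[idx] = -v[idx]
        best = max(best, float(v @ g @ v))
    return float(np.sqrt(best))


def _as_coords(point) -> np.ndarray:
    if isinstance(point, ModelGait):
        return point.point.as_array()
    if isinstance(point, GaitPoint):
        return point.as_array()
    return np.asarray(point, dtype=float)


def gait_distance(a, b, metric: GaitMetricTensor) -> tuple[float, float]:
    """Gait distance in cycles and its normalized form in [0, 1].

    Per coordinate, the signed minimal circular separation x_i is taken
    (|x_i| is the minimum distance on a unit-circumference circle); then

        d_AB = sqrt( sum_ij g_ij x_i x_j ),    Delta_AB = d_AB / d_max.

    For nearby gaits this equals the distance between the two leg-phase
    configurations minimized over a common phase shift.
    """
    xa, xb = _as_coords(a), _as_coords(b)
    if xa.shape[-1] != metric.ndim or xb.shape[-1] != metric.ndim:
        raise ValueError(
            f"gait points must have {metric.ndim} coordinates for {metric.n_legs} legs"
        )
    x = np.atleast_1d(signed_circular_delta(xa, xb))
    d = _form(x, metric.g)
    return d, d / metric.d_max


def distances_to(points: np.ndarray, ref, metric: GaitMetricTensor) -> np.ndarray:
    """Normalized gait distance from each row of ``points`` to a reference gait."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != metric.ndim:
        raise ValueError("dimension mismatch with metric")
    x = signed_circular_delta(pts, _as_coords(ref))
    d = np.sqrt(np.einsum("ij,jk,ik->i", x, metric.g, x))
    fix = np.flatnonzero((np.abs(x) == 0.5).any(axis=1))
    for i in fix:
        d[i] = _form(x[i], metric.g)
    return d / metric.d_max


def dataset_to_model(
    points: np.ndarray,
    model: ModelGait,
    metric: GaitMetricTensor,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Mean normalized distance from a dataset to a model gait, with 95% CI.

    The confidence interval is a percentile bootstrap (resampling gait points
    with replacement) of the mean; reproducible for a given seed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts[~np.isnan(pts).any(axis=1)]
    if pts.shape[0] < 1:
        raise ValueError("empty dataset")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    delta = distances_to(pts, model, metric)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = delta.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = delta[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(delta.mean()), (float(lo), float(hi))
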