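"""Per-trial locomotor performance measures.

Speed, relative speed (body lengths per second), path tortuosity, yaw,
stride detection from tarsus velocity peaks, stance/swing segmentation from
caudal motion relative to the COM, duty factors, and the allometric helper
relating running speed to body length.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .trackio import (
    BodyFrameTrial,
    TrackedTrial,
    com_velocity,
    local_quadratic_derivative,
    local_quadratic_smooth,
)

__all__ = [
    "PathSummary",
    "StrideTable",
    "StanceMask",
    "path_summary",
    "detect_strides",
    "stride_table",
    "stance_swing",
    "duty_factors",
    "predicted_length_exponent",
]


@dataclasses.dataclass
class PathSummary:
    """Whole-trial performance scalars."""

    mean_speed: float        # mm/s
    relative_speed: float    # body lengths per second
    tortuosity: float        # displacement / path length, <= 1
    yaw: np.ndarray          # deg per frame, signed
    mean_abs_yaw: float      # deg


@dataclasses.dataclass
class StrideTable:
    """Stride boundaries and derived quantities for one leg.

    ``boundaries`` are the frame indices of successive tarsus-velocity peaks;
    the stride period is their mean spacing.  ``empty`` flags series in which
    fewer than two peaks were found.
    """

    boundaries: np.ndarray          # frame indices of velocity peaks
    boundary_times: np.ndarray      # s
    periods: np.ndarray             # s, per stride
    period: float                   # s, mean
    frequency: float                # Hz, 1 / period
    lengths: np.ndarray             # mm per stride (COM displacement)
    empty: bool = False


@dataclasses.dataclass
class StanceMask:
    """Per-leg stance masks and per-stride duty factors."""

    masks: dict[str, np.ndarray]            # leg -> bool per frame
    duty: dict[str, np.ndarray]             # leg -> duty factor per stride
    duty_mean: dict[str, float]             # leg -> mean duty factor


def path_summary(
    trial: TrackedTrial, velocity: np.ndarray | None = None,
    window_ms: float = 50.0,
) -> PathSummary:
    """Speed, tortuosity and yaw for one trial.

    Tortuosity is the straightness index tau = d / D: net COM displacement
    over the summed per-frame path length.  Both are measured on the
    running-quadratic-fit-smoothed COM trajectory, so high-rate tracking
    jitter does not inflate the path length (and tau <= 1 by the triangle
    inequality).  Yaw is the signed angle from the instantaneous COM velocity
    to the cranial-pointing body axis, positive when the body axis lies
    counterclockwise of the velocity in dorsal view.
    """
    if velocity is None:
        velocity = com_velocity(trial, window_ms)
    com = np.column_stack(
        [
            local_quadratic_smooth(trial.com[:, c], window_ms, trial.frame_rate)
            for c in range(2)
        ]
    )
    steps = np.linalg.norm(np.diff(com, axis=0), axis=1)
    path_length = float(steps.sum())
    if path_length == 0.0:
        raise ZeroDivisionError("zero path length: tortuosity undefined")
    displacement = float(np.linalg.norm(com[-1] - com[0]))
    tortuosity = displacement / path_length

    axis = trial.cranial - trial.caudal  # cranial-pointing body axis
    cross = velocity[:, 0] * axis[:, 1] - velocity[:, 1] * axis[:, 0]
    dot = (velocity * axis).sum(axis=1)
    yaw = np.degrees(np.arctan2(cross, dot))

    speed = np.linalg.norm(velocity, axis=1)
    mean_speed = float(speed.mean())
    return PathSummary(
        mean_speed=mean_speed,
        relative_speed=mean_speed / trial.body_length,
        tortuosity=tortuosity,
        yaw=yaw,
        mean_abs_yaw=float(np.abs(yaw).mean()),
    )


def _dominant_period_frames(x: np.ndarray) -> float | None:
    """Lag (frames) of the first autocorrelation peak, or None if aperiodic."""
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    ac /= ac[0]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        return None
    return float(peaks[0])


def detect_strides(
    velocity_along_motion: np.ndarray,
    frame_rate: float,
    com: np.ndarray | None = None,
    min_distance: float | None = None,
    min_prominence: float | None = None,
) -> StrideTable:
    """Stride boundaries from peaks in a tarsus's velocity along the COM motion.

    The stride period is the mean spacing of successive velocity peaks.  Peak
    selection defaults: minimum inter-peak distance of half the dominant
    period (from the autocorrelation) and minimum prominence of half the
    series' standard deviation.  If ``com`` positions are supplied, stride
    length is the COM displacement accumulated over each stride.
    """
    v = np.asarray(velocity_along_motion, dtype=float)
    # quantize at 1e-9 of the dynamic range so numerically flat plateaus become
    # exact ties and find_peaks returns their central sample
    v_range = float(v.max() - v.min()) if v.size else 0.0
    if v_range > 0:
        q = 1e-9 * v_range
        v = np.round(v / q) * q
    if min_distance is None:
        period = _dominant_period_frames(v)
        min_distance = max(1.0, 0.5 * period) if period else 1.0
    if min_prominence is None:
        min_prominence = 0.5 * float(v.std())
    peaks, _ = find_peaks(v, distance=min_distance, prominence=min_prominence or None)
    if peaks.size < 2:
        return StrideTable(
            boundaries=np.array([], dtype=int),
            boundary_times=np.array([]),
            periods=np.array([]),
            period=math.nan,
            frequency=math.nan,
            lengths=np.array([]),
            empty=True,
        )
    times = peaks / frame_rate
    periods = np.diff(times)
    period = float(periods.mean())
    if com is not None:
        com = np.asarray(com, dtype=float)
        lengths = np.linalg.norm(com[peaks[1:]] - com[peaks[:-1]], axis=1)
    else:
        lengths = np.full(periods.shape, np.nan)
    return StrideTable(
        boundaries=peaks,
        boundary_times=times,
        periods=periods,
        period=period,
        frequency=1.0 / period,
        lengths=lengths,
        empty=False,
    )


def stride_table(
    trial: TrackedTrial,
    velocity: np.ndarray | None = None,
    window_ms: float = 40.0,
) -> dict[str, StrideTable]:
    """Per-leg stride tables from lab-frame tarsus velocity projected on the motion."""
    if velocity is None:
        velocity = com_velocity(trial)
    speed = np.linalg.norm(velocity, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = velocity / np.where(speed > 0, speed, np.nan)[:, None]
    out: dict[str, StrideTable] = {}
    for leg, xy in trial.tarsi.items():
        v_leg = np.column_stack(
            [
                local_quadratic_derivative(xy[:, c], window_ms, trial.frame_rate)
                for c in range(2)
            ]
        )
        along = (v_leg * u).sum(axis=1)
        along = np.nan_to_num(along)
        out[leg] = detect_strides(along, trial.frame_rate, com=trial.com)
    return out


def _debounce(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Remove state runs shorter than ``min_run`` frames (morphological)."""
    if min_run <= 1 or mask.size == 0:
        return mask
    out = mask.copy()
    for target in (True, False):  # first prune stance blips, then swing blips
        edges = np.flatnonzero(np.diff(out.astype(int)) != 0) + 1
        bounds = np.concatenate([[0], edges, [out.size]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if out[lo] == target and hi - lo < min_run:
                out[lo:hi] = not target
    return out


def stance_swing(
    bf: BodyFrameTrial,
    threshold: float = 2.0,
    debounce: int = 3,
    strides: Mapping[str, StrideTable] | None = None,
    window_ms: float = 40.0,
) -> StanceMask:
    """Stance/swing segmentation and duty factors.

    A tarsus is in stance when it moves caudally relative to the COM: its
    fore-aft body-frame velocity is below ``-threshold`` mm/s.  Runs shorter
    than ``debounce`` frames are removed.  A dragged leg, fixed relative to
    the body, never satisfies the criterion and gets duty factor 0.  Duty
    factors are the in-stance fraction of each stride's frames, using the
    stride boundaries in ``strides`` (computed if not supplied).
    """
    trial = bf.source
    if strides is None:
        strides = stride_table(trial, bf.com_velocity)
    masks: dict[str, np.ndarray] = {}
    duty: dict[str, np.ndarray] = {}
    duty_mean: dict[str, float] = {}
    for leg, xy in bf.tarsi_bf.items():
        y = xy[:, 1]
        y_filled = np.where(np.isfinite(y), y, 0.0)
        vy = local_quadratic_derivative(y_filled, window_ms, trial.frame_rate)
        mask = (vy < -threshold) & bf.valid_mask & np.isfinite(y)
        mask = _debounce(mask, debounce)
        masks[leg] = mask
        tab = strides.get(leg)
        if tab is None or tab.empty:
            duty[leg] = np.array([])
            duty_mean[leg] = float(mask.mean())  # cycle-free fallback
            continue
        b = tab.boundaries
        d = np.array(
            [mask[lo:hi].mean() for lo, hi in zip(b[:-1], b[1:])], dtype=float
        )
        duty[leg] = d
        duty_mean[leg] = float(d.mean()) if d.size else float(mask.mean())
    return StanceMask(masks=masks, duty=duty, duty_mean=duty_mean)


def duty_factors(stance: StanceMask) -> dict[str, float]:
    """Mean duty factor per leg."""
    return dict(stance.duty_mean)


def predicted_length_exponent(
    a: float, sigma_a: float, b: float, sigma_b: float
) -> tuple[float, float]:
    """Exponent (and first-order error) of speed vs body length.

    Combines a speed-mass scaling ``v ~ M^a`` with a mass-length scaling
    ``M ~ L^b`` into ``v ~ L^(a b)``; the uncertainty propagates as
    ``sigma = sqrt(b^2 sigma_a^2 + a^2 sigma_b^2)``.
    """
    exponent = a * b
    sigma = math.sqrt((b * sigma_a) ** 2 + (a * sigma_b) ** 2)
    return exponent, sigma
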