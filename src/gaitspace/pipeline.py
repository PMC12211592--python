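"""High-level pipeline: tracked trial -> leg phases -> gait points.

Chains the body-frame transform, the running-quadratic-fit derivatives, the
oscillation-phase estimator and the adjacent-leg phase differences, the
sequence every downstream analysis (distances, clustering, footfalls)
starts from.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .space import (
    LegOrdering,
    PhaseSeries,
    estimate_phase,
    phase_differences,
    standardize,
)
from .trackio import (
    BodyFrameTrial,
    TrackedTrial,
    com_velocity,
    local_quadratic_derivative,
    to_body_frame,
)

__all__ = ["TrialPhases", "leg_phases", "gait_points"]


@dataclasses.dataclass
class TrialPhases:
    """Per-leg phases plus the body-frame context they came from."""

    ordering: LegOrdering
    phases: PhaseSeries
    body_frame: BodyFrameTrial
    valid: np.ndarray  # frames with a defined heading and untruncated windows


def leg_phases(
    trial: TrackedTrial,
    com_window_ms: float = 50.0,
    tarsus_window_ms: float = 40.0,
    min_speed: float = 1.0,
) -> TrialPhases:
    """Estimate each leg's oscillation phase from fore-aft body-frame motion.

    Each present tarsus's fore-aft body-frame coordinate and its
    running-quadratic-fit derivative are standardized over the trial and
    combined into a phase by the harmonic-oscillator estimator.  Frames near
    the trial ends, where the derivative windows are truncated, are excluded
    from the validity mask along with low-speed frames.
    """
    vel = com_velocity(trial, com_window_ms)
    bf = to_body_frame(trial, vel, min_speed=min_speed)
    ordering = LegOrdering.from_present(trial.present_legs)
    rows = []
    for leg in ordering.labels:
        y = bf.tarsi_bf[leg][:, 1]
        y_filled = np.where(np.isfinite(y), y, 0.0)
        v = local_quadratic_derivative(y_filled, tarsus_window_ms, trial.frame_rate)
        rows.append(estimate_phase(standardize(y_filled), standardize(v)))
    phases = PhaseSeries(ordering=ordering, phases=np.array(rows))

    half = int(
        round(max(com_window_ms, tarsus_window_ms) / 1000.0 * trial.frame_rate / 2.0)
    )
    valid = bf.valid_mask.copy()
    valid[:half] = False
    if half > 0:
        valid[-half:] = False
    valid &= np.isfinite(phases.phases).all(axis=0)
    return TrialPhases(ordering=ordering, phases=phases, body_frame=bf, valid=valid)


def gait_points(
    trial: TrackedTrial,
    com_window_ms: float = 50.0,
    tarsus_window_ms: float = 40.0,
    min_speed: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, TrialPhases]:
    """Per-frame gait points for a trial.

    Returns ``(points, valid, phases)`` where ``points`` is an
    (n_frames, n_legs - 1) array of adjacent-leg phase differences in cycles
    and ``valid`` masks the frames with well-defined phases.
    """
    tp = leg_phases(trial, com_window_ms, tarsus_window_ms, min_speed)
    points = phase_differences(tp.phases)
    return points, tp.valid, tp
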