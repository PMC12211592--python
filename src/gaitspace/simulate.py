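"""Synthetic gait and trial generation.

Everything downstream of tracking is testable without recordings: von
Mises-perturbed gait points around model gaits, maximum-likelihood recovery
of the concentration parameter, ideal footfall patterns, and full synthetic
tracked trials in which each tarsus oscillates fore-aft with the model
gait's phase offsets and a duty-factor-asymmetric waveform.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy.special import ive
from scipy.stats import vonmises

from .space import CANONICAL_LEGS, GaitPoint, LegOrdering, ModelGait, model_gaits
from .trackio import TrackedTrial

__all__ = [
    "NoiseModel",
    "SyntheticTrialConfig",
    "FootfallPattern",
    "sample_gait_points",
    "fit_kappa",
    "footfall_pattern",
    "synth_trial",
]


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Independent per-coordinate von Mises noise around a model gait.

    kappa is the concentration on the radian scale: large kappa means tight
    clustering around the model's phase differences, kappa = 0 is uniform.
    """

    mu: GaitPoint
    kappa: float
    independent: bool = True

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def sample_gait_points(
    model: ModelGait | GaitPoint,
    kappa: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n gait points with von Mises noise about a model gait.

    Each coordinate is sampled independently from a von Mises distribution
    with mean 2*pi*mu_i and concentration kappa, then mapped back to cycles
    in [0, 1).  kappa = 0 gives uniform coordinates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    point = model.point if isinstance(model, ModelGait) else model
    mu = point.as_array()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kappa == 0:
        return rng.uniform(0.0, 1.0, size=(n, mu.size))
    ang = vonmises.rvs(
        kappa, loc=2.0 * np.pi * mu, size=(n, mu.size), random_state=rng
    )
    return (ang / (2.0 * np.pi)) % 1.0


def _resultant_length(cycles: np.ndarray) -> float:
    ang = 2.0 * np.pi * np.asarray(cycles, dtype=float)
    return float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))


def _A(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution: I1(k)/I0(k)."""
    return ive(1, kappa) / ive(0, kappa)


def _kappa_from_R(R: float) -> float:
    """Invert A(kappa) = R: Banerjee et al. approximation plus Newton polish."""
    if R >= 1.0 - 1e-12:
        return math.inf
    if R < 1e-8:
        return 0.0
    if R < 0.53:
        k = 2 * R + R**3 + 5 * R**5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        k = 1.0 / (R**3 - 4 * R**2 + 3 * R)
    for _ in range(25):
        a = _A(k)
        da = 1.0 - a * a - a / k
        if da <= 0:
            break
        step = (a - R) / da
        k = max(k - step, 1e-12)
        if abs(step) < 1e-12 * max(k, 1.0):
            break
    return float(k)


def fit_kappa(samples: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration from circular samples (cycles).

    Solves A(kappa) = R_bar, where R_bar is the mean resultant length.  For
    multi-dimensional gait points each coordinate is fitted separately (R is
    invariant to the circular mean, so no explicit centering is needed) and
    the mean kappa over coordinates is returned.  Identical samples give
    ``inf`` (infinite concentration); near-uniform samples give ~0.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    kappas = [_kappa_from_R(_resultant_length(x[:, j])) for j in range(x.shape[1])]
    if any(math.isinf(k) for k in kappas):
        return math.inf
    return float(np.mean(kappas))


@dataclasses.dataclass
class FootfallPattern:
    """Ideal stance pattern of a model gait sampled over whole strides."""

    stance: np.ndarray       # (n_legs, n_samples) bool
    n_support: np.ndarray    # per sample
    time_cycles: np.ndarray  # sample times in stride cycles
    duty: float

    def stance_fractions(self) -> np.ndarray:
        """Fraction of time each leg spends in stance."""
        return self.stance.mean(axis=1)


def cumulative_leg_phases(gait: ModelGait | GaitPoint) -> np.ndarray:
    """Per-leg phase offsets implied by a gait's adjacent phase differences."""
    point = gait.point if isinstance(gait, ModelGait) else gait
    return np.concatenate([[0.0], np.cumsum(point.as_array())]) % 1.0


def footfall_pattern(
    gait: ModelGait | GaitPoint,
    duty: float,
    n_strides: int = 10,
    samples_per_stride: int = 1000,
) -> FootfallPattern:
    """Ideal footfall diagram for a model gait.

    Leg k is in stance when ``(t f + phi_k) mod 1 < duty`` with phi_k the
    cumulative leg phase implied by the gait's phase differences.  At duty
    0.5 the alternating tetrapod keeps four of eight legs planted at every
    instant, the modified tripod three of six, and the ablated tetrapod
    alternates between a tetrapod and a statically precarious bipod.
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie in (0, 1)")
    phi = cumulative_leg_phases(gait)
    t = np.arange(n_strides * samples_per_stride) / samples_per_stride
    stance = ((t[None, :] + phi[:, None]) % 1.0) < duty
    return FootfallPattern(
        stance=stance,
        n_support=stance.sum(axis=0),
        time_cycles=t,
        duty=duty,
    )


_MODEL_MISSING = {"ALT": (), "ABT": ("L4", "R1"), "MT": ("L4", "R1")}


@dataclasses.dataclass
class SyntheticTrialConfig:
    """Conditions for one synthetic running trial.

    Defaults emulate the study conditions these tools target: a ~16 mm
    dorsal-view runner filmed at 500 frames/s, completing about six strides
    per bout at ~6 Hz with duty factors just above one half, and landmark
    tracking noise with a +/-0.8 mm (2 sigma) uncertainty band.
    """

    gait: str = "ALT"                  # ALT, ABT or MT (sets missing legs)
    n_strides: int = 6
    stride_frequency: float = 6.0      # Hz
    duty_factor: float = 0.55
    body_length: float = 16.0          # mm
    speed: float | None = None         # mm/s; default 8 BL/s
    amplitude: float | None = None     # mm fore-aft; default speed*duty/f (no slip)
    frame_rate: float = 500.0          # Hz
    tracking_noise_sd: float = 0.4     # mm, Gaussian per coordinate
    phase_kappa: float | None = None   # per-stride von Mises jitter; None = none
    missing: tuple[str, ...] | None = None  # override the gait's default
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1)")
        for name in ("stride_frequency", "body_length", "frame_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.tracking_noise_sd < 0:
            raise ValueError("tracking_noise_sd must be non-negative")
        if self.phase_kappa is not None and self.phase_kappa < 0:
            raise ValueError("phase_kappa must be non-negative")


def _leg_anchors(legs: tuple[str, ...], body_length: float) -> dict[str, np.ndarray]:
    """Resting tarsus anchors: uniform angular spread about the COM.

    Legs are placed at radius 0.75 BL, uniformly spaced in bearing and
    symmetric about the direction of travel (+y), mirroring the observed
    tendency to keep legs evenly spread, intact or not.
    """
    n = len(legs)
    spacing = 360.0 / n
    anchors: dict[str, np.ndarray] = {}
    for k, leg in enumerate(legs):
        # counterclockwise circuit starting just left of straight ahead
        theta = math.radians(90.0 + (k + 0.5) * spacing)
        anchors[leg] = 0.75 * body_length * np.array(
            [math.cos(theta), math.sin(theta)]
        )
    return anchors


def _fore_aft_waveform(phase: np.ndarray, duty: float, amplitude: float) -> np.ndarray:
    """Piecewise-linear stride waveform of the body-frame fore-aft offset.

    Touchdown at phase 0 with the tarsus ahead of its anchor (+A/2); linear
    retraction to -A/2 over the stance fraction ``duty`` (so a matched
    amplitude makes the foot exactly ground-fixed), then linear protraction
    back over the swing.  The piecewise form makes stance/swing ground truth
    exact.
    """
    p = phase % 1.0
    w = np.where(
        p < duty,
        0.5 - p / duty,
        -0.5 + (p - duty) / (1.0 - duty),
    )
    return amplitude * w


def synth_trial(config: SyntheticTrialConfig) -> TrackedTrial:
    """Generate a full synthetic tracked trial for a model gait.

    The COM advances at constant speed along +y in the lab frame; each
    present leg's tarsus oscillates fore-aft about its anchor with the
    gait's cumulative phase offsets, optional per-stride von Mises phase
    jitter, and Gaussian tracking noise on every landmark.  The output is a
    standard :class:`TrackedTrial` that passes validation unmodified.
    """
    rng = np.random.default_rng(config.seed)
    missing = (
        set(config.missing)
        if config.missing is not None
        else set(_MODEL_MISSING.get(config.gait, ()))
    )
    legs = tuple(l for l in CANONICAL_LEGS if l not in missing)
    models = {m.name: m for m in model_gaits(len(legs), missing or None)}
    if config.gait not in models:
        raise ValueError(
            f"gait {config.gait!r} is not defined for {len(legs)} legs"
        )
    gait = models[config.gait]
    phi = cumulative_leg_phases(gait)

    f = config.stride_frequency
    fs = config.frame_rate
    speed = config.speed if config.speed is not None else 8.0 * config.body_length
    amplitude = (
        config.amplitude
        if config.amplitude is not None
        else speed * config.duty_factor / f
    )
    n = int(round(config.n_strides / f * fs)) + 1
    t = np.arange(n) / fs

    com = np.column_stack([np.zeros(n), speed * t])
    half_axis = np.array([0.0, config.body_length / 2.0])
    cranial = com + half_axis
    caudal = com - half_axis

    anchors = _leg_anchors(legs, config.body_length)
    tarsi: dict[str, np.ndarray] = {}
    for k, leg in enumerate(legs):
        phase = f * t + phi[k]
        if config.phase_kappa is not None and np.isfinite(config.phase_kappa):
            n_str = int(np.ceil(phase.max())) + 1
            jitter = (
                vonmises.rvs(
                    config.phase_kappa, loc=0.0, size=n_str, random_state=rng
                )
                / (2.0 * np.pi)
            )
            phase = phase + jitter[np.floor(phase).astype(int)]
        w = _fore_aft_waveform(phase, config.duty_factor, amplitude)
        tarsi[leg] = com + anchors[leg] + np.column_stack([np.zeros(n), w])

    if config.tracking_noise_sd > 0:
        def noisy(arr: np.ndarray) -> np.ndarray:
            return arr + rng.normal(0.0, config.tracking_noise_sd, size=arr.shape)

        com, cranial, caudal = noisy(com), noisy(cranial), noisy(caudal)
        tarsi = {leg: noisy(xy) for leg, xy in tarsi.items()}

    return TrackedTrial(
        specimen_id="synthetic",
        treatment="C1" if not missing else "1AUT0",
        frame_rate=fs,
        body_length=config.body_length,
        time=t,
        com=com,
        cranial=cranial,
        caudal=caudal,
        tarsi=tarsi,
    )
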