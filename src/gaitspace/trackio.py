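"""Reading, writing and validating tracked-landmark trials.

A trial is a fixed-rate dorsal-view time series of 2-D landmarks in mm: the
body center of mass (COM), the cranial and caudal ends of the body, and the
tarsus tip of each present leg.  The on-disk form is a plain CSV with header

    frame,time,com_x,com_y,cranial_x,cranial_y,caudal_x,caudal_y,<LEG>_x,<LEG>_y,...

with LEG in {L1,L2,L3,L4,R4,R3,R2,R1}; empty cells are missing samples and
wholly absent leg columns mean the leg is autotomized.  Trial metadata
(specimen id, treatment, frame rate, body length) travels in a YAML/JSON
sidecar next to the CSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .space import CANONICAL_LEGS

__all__ = [
    "TrackedTrial",
    "BodyFrameTrial",
    "TrackSchemaError",
    "TrackFormatError",
    "TrackValidationError",
    "DegenerateTrialError",
    "read_tracks",
    "write_tracks",
    "local_quadratic_derivative",
    "com_velocity",
    "to_body_frame",
    "to_lab_frame",
]

TREATMENTS = ("C1", "CC", "1AUT0", "1AUT1", "C2", "2AUT0", "2AUT1", "OTHER")

_MANDATORY = ("com_x", "com_y", "cranial_x", "cranial_y", "caudal_x", "caudal_y")


class TrackSchemaError(ValueError):
    """Missing or unmappable mandatory columns."""


class TrackFormatError(ValueError):
    """Malformed file contents (e.g. non-monotonic time)."""


class TrackValidationError(ValueError):
    """Contents violate trial invariants (e.g. long tracking gaps)."""


class DegenerateTrialError(ValueError):
    """A trial for which the requested quantity is undefined."""


@dataclasses.dataclass
class TrackedTrial:
    """One tracked locomotion bout.

    All per-frame arrays share a common length; coordinates are in mm, time in
    seconds, sampled at ``frame_rate`` Hz.  ``tarsi`` maps present leg labels
    to (n, 2) arrays; autotomized legs are simply absent from the mapping.
    """

    specimen_id: str
    treatment: str
    frame_rate: float
    body_length: float
    time: np.ndarray
    com: np.ndarray
    cranial: np.ndarray
    caudal: np.ndarray
    tarsi: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("com", "cranial", "caudal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.tarsi = {k: np.asarray(v, dtype=float) for k, v in self.tarsi.items()}
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def present_legs(self) -> tuple[str, ...]:
        return tuple(l for l in CANONICAL_LEGS if l in self.tarsi)

    def validate(self) -> None:
        if self.treatment not in TREATMENTS:
            raise TrackValidationError(f"unknown treatment {self.treatment!r}")
        if not self.frame_rate > 0:
            raise TrackValidationError("frame_rate must be positive")
        if not self.body_length > 0:
            raise TrackValidationError("body_length must be positive")
        n = self.n_frames
        if n < 2:
            raise TrackValidationError("need at least 2 frames")
        for name in ("com", "cranial", "caudal"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise TrackValidationError(f"{name} must be an ({n}, 2) array")
            if not np.isfinite(arr).all():
                raise TrackValidationError(f"non-finite coordinates in {name}")
        unknown = set(self.tarsi) - set(CANONICAL_LEGS)
        if unknown:
            raise TrackValidationError(f"unknown leg labels {sorted(unknown)}")
        for leg, arr in self.tarsi.items():
            if arr.shape != (n, 2):
                raise TrackValidationError(f"tarsus {leg} must be an ({n}, 2) array")
            if not np.isfinite(arr).all():
                raise TrackValidationError(f"non-finite coordinates in leg {leg}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise TrackFormatError("time must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-3, atol=1e-6):
            raise TrackFormatError("time spacing inconsistent with frame_rate")


@dataclasses.dataclass
class BodyFrameTrial:
    """A trial expressed in the comoving body frame.

    Per frame, landmarks are translated so the COM sits at the origin and
    rotated so the instantaneous COM velocity points along +y.  Frames whose
    COM speed falls below the validity threshold have no defined orientation
    and carry NaN coordinates.
    """

    source: TrackedTrial
    tarsi_bf: dict[str, np.ndarray]
    com_velocity: np.ndarray
    valid_mask: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.com_velocity, axis=1)


def _default_columns(legs: Iterable[str]) -> dict[str, str]:
    cols = {"frame": "frame", "time": "time"}
    for base in ("com", "cranial", "caudal"):
        cols[f"{base}_x"] = f"{base}_x"
        cols[f"{base}_y"] = f"{base}_y"
    for leg in legs:
        cols[f"{leg}_x"] = f"{leg}_x"
        cols[f"{leg}_y"] = f"{leg}_y"
    return cols


def _sidecar_path(path: Path) -> Path:
    for ext in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    raise TrackSchemaError(f"no metadata sidecar (.yaml/.json) found next to {path}")


def _interpolate_gaps(xy: np.ndarray, leg: str, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap; longer runs fail."""
    out = xy.copy()
    for c in range(2):
        col = out[:, c]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        if isnan.all():
            raise TrackValidationError(f"leg {leg}: all samples missing")
        # locate NaN runs
        idx = np.flatnonzero(isnan)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) > max_gap:
                raise TrackValidationError(
                    f"leg {leg}: tracking gap of {len(run)} frames exceeds "
                    f"the {max_gap}-frame limit"
                )
            if run[0] == 0 or run[-1] == len(col) - 1:
                raise TrackValidationError(
                    f"leg {leg}: missing samples at the trial boundary"
                )
        warnings.warn(
            f"leg {leg}: interpolating {isnan.sum()} missing samples "
            f"(gaps <= {max_gap} frames)",
            stacklevel=3,
        )
        good = ~isnan
        col[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), col[good])
    return out


def read_tracks(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    max_gap: int = 3,
    px_per_mm: float | None = None,
) -> TrackedTrial:
    """Read a tracked trial from CSV plus its metadata sidecar.

    Parameters
    ----------
    path
        The tracks CSV.  A sidecar ``<stem>.yaml`` (or ``.json``) with
        ``specimen_id``, ``treatment``, ``frame_rate`` and ``body_length``
        must sit next to it.
    schema
        Optional column map (canonical name -> file column), given directly
        or as a YAML file, to absorb tracker-export dialects.
    max_gap
        Longest interior run of missing samples, in frames, repaired by
        linear interpolation; longer gaps raise ``TrackValidationError``.
    px_per_mm
        If given, coordinates in the file are pixels and are divided by this
        calibration factor on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = _default_columns(CANONICAL_LEGS)
    if schema is not None:
        if isinstance(schema, (str, Path)):
            with open(schema) as fh:
                schema = yaml.safe_load(fh)
        colmap.update(schema)

    df = pd.read_csv(path)
    for canon in _MANDATORY + ("time",):
        if colmap[canon] not in df.columns:
            raise TrackSchemaError(f"missing mandatory column {colmap[canon]!r}")

    scale = 1.0 / px_per_mm if px_per_mm else 1.0

    def col(name: str) -> np.ndarray:
        return df[colmap[name]].to_numpy(dtype=float)

    time = col("time")
    if np.any(np.diff(time) <= 0):
        raise TrackFormatError("time column is not strictly increasing")

    def pair(base: str) -> np.ndarray:
        return np.column_stack([col(f"{base}_x"), col(f"{base}_y")]) * scale

    tarsi: dict[str, np.ndarray] = {}
    for leg in CANONICAL_LEGS:
        cx, cy = colmap[f"{leg}_x"], colmap[f"{leg}_y"]
        if cx not in df.columns or cy not in df.columns:
            continue  # absent column pair: autotomized leg
        xy = np.column_stack(
            [df[cx].to_numpy(dtype=float), df[cy].to_numpy(dtype=float)]
        )
        if np.isnan(xy).all():
            continue  # all-empty columns also mean an absent leg
        xy = _interpolate_gaps(xy, leg, max_gap) * scale
        tarsi[leg] = xy
    if not tarsi:
        raise TrackSchemaError("no tarsus columns present")

    meta_path = _sidecar_path(path)
    with open(meta_path) as fh:
        if meta_path.suffix == ".json":
            meta = json.load(fh)
        else:
            meta = yaml.safe_load(fh)
    try:
        trial = TrackedTrial(
            specimen_id=str(meta["specimen_id"]),
            treatment=str(meta["treatment"]),
            frame_rate=float(meta["frame_rate"]),
            body_length=float(meta["body_length"]),
            time=time,
            com=pair("com"),
            cranial=pair("cranial"),
            caudal=pair("caudal"),
            tarsi=tarsi,
        )
    except KeyError as exc:
        raise TrackSchemaError(f"sidecar {meta_path} lacks field {exc}") from exc
    return trial


def write_tracks(trial: TrackedTrial, path: str | Path, decimals: int = 6) -> Path:
    """Write a trial as CSV + YAML sidecar; inverse of :func:`read_tracks`."""
    path = Path(path)
    cols: dict[str, object] = {
        "frame": np.arange(trial.n_frames),
        "time": trial.time,
    }
    for base in ("com", "cranial", "caudal"):
        arr = getattr(trial, base)
        cols[f"{base}_x"], cols[f"{base}_y"] = arr[:, 0], arr[:, 1]
    for leg in trial.present_legs:
        arr = trial.tarsi[leg]
        cols[f"{leg}_x"], cols[f"{leg}_y"] = arr[:, 0], arr[:, 1]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")
    meta = {
        "specimen_id": trial.specimen_id,
        "treatment": trial.treatment,
        "frame_rate": float(trial.frame_rate),
        "body_length": float(trial.body_length),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def local_quadratic_derivative(
    series: np.ndarray, window_ms: float, frame_rate: float
) -> np.ndarray:
    """Per-frame slope of a running least-squares quadratic fit.

    A quadratic is fitted over a centered window of the requested duration and
    its slope evaluated at the center frame; this is exact for polynomials of
    degree <= 2 and attenuates high frequencies smoothly.  Edge frames use
    truncated one-sided windows (dropping to a linear fit if fewer than three
    samples remain) so the output stays aligned with the input.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    half = int(round(window_ms / 1000.0 * frame_rate / 2.0))
    if 2 * half + 1 < 3:
        raise ValueError("window must span at least 3 frames")
    deriv = np.empty(n)
    weights: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        key = (i - lo, hi - i)
        w = weights.get(key)
        if w is None:
            t = (np.arange(lo, hi) - i) / frame_rate
            order = 2 if t.size >= 3 else 1
            design = np.vander(t, order + 1)  # columns: ..., t, 1
            w = np.linalg.pinv(design)[order - 1]
            weights[key] = w
        deriv[i] = w @ x[lo:hi]
    return deriv


def local_quadratic_smooth(
    series: np.ndarray, window_ms: float, frame_rate: float
) -> np.ndarray:
    """Running quadratic-fit value at the center frame (position smoothing).

    The companion of :func:`local_quadratic_derivative`: the same windowed
    least-squares quadratic, evaluated instead of differentiated.  Exact for
    polynomials of degree <= 2; truncated one-sided windows at the edges.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    half = int(round(window_ms / 1000.0 * frame_rate / 2.0))
    if 2 * half + 1 < 3:
        raise ValueError("window must span at least 3 frames")
    out = np.empty(n)
    weights: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        key = (i - lo, hi - i)
        w = weights.get(key)
        if w is None:
            t = (np.arange(lo, hi) - i) / frame_rate
            order = 2 if t.size >= 3 else 1
            design = np.vander(t, order + 1)
            w = np.linalg.pinv(design)[order]  # constant-term row = value at center
            weights[key] = w
        out[i] = w @ x[lo:hi]
    return out


def com_velocity(trial: TrackedTrial, window_ms: float = 50.0) -> np.ndarray:
    """COM velocity (mm/s) via the running quadratic fit, 50 ms window default."""
    return np.column_stack(
        [
            local_quadratic_derivative(trial.com[:, c], window_ms, trial.frame_rate)
            for c in range(2)
        ]
    )


def _rotations(vel: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit velocity components (ux, uy) per frame; NaN where invalid."""
    speed = np.linalg.norm(vel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = vel / speed[:, None]
    u[~valid] = np.nan
    return u[:, 0], u[:, 1]


def to_body_frame(
    trial: TrackedTrial,
    velocity: np.ndarray | None = None,
    min_speed: float = 1.0,
) -> BodyFrameTrial:
    """Transform tarsi to the comoving body frame (COM at origin, velocity +y).

    Frames with COM speed below ``min_speed`` (mm/s) have an undefined
    heading and are flagged invalid.  The per-frame map is a rigid rotation
    plus translation, so pairwise landmark distances are preserved.
    """
    if velocity is None:
        velocity = com_velocity(trial)
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != (trial.n_frames, 2):
        raise ValueError("velocity must be an (n_frames, 2) array")
    speed = np.linalg.norm(velocity, axis=1)
    valid = speed >= min_speed
    if not valid.any():
        raise DegenerateTrialError(
            "COM speed below min_speed in every frame; body frame undefined"
        )
    ux, uy = _rotations(velocity, valid)
    tarsi_bf: dict[str, np.ndarray] = {}
    for leg, xy in trial.tarsi.items():
        r = xy - trial.com
        # rotation sending the unit velocity (ux, uy) to (0, 1)
        bx = uy * r[:, 0] - ux * r[:, 1]
        by = ux * r[:, 0] + uy * r[:, 1]
        tarsi_bf[leg] = np.column_stack([bx, by])
    return BodyFrameTrial(
        source=trial, tarsi_bf=tarsi_bf, com_velocity=velocity, valid_mask=valid
    )


def to_lab_frame(bf: BodyFrameTrial, leg: str) -> np.ndarray:
    """Invert the body-frame transform for one leg (valid frames only)."""
    ux, uy = _rotations(bf.com_velocity, bf.valid_mask)
    b = bf.tarsi_bf[leg]
    rx = uy * b[:, 0] + ux * b[:, 1]
    ry = -ux * b[:, 0] + uy * b[:, 1]
    return np.column_stack([rx, ry]) + bf.source.com
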