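"""Two-static-pose sensor-to-body calibration.

The participant first stands still (gravity defines the superior-inferior
axis in the sensor frame), then sits leaning back with legs extended so that
gravity tilts within the sagittal plane.  Cross products between the two
normalised gravity directions yield the medial-lateral and
anterior-posterior axes; a final cross product re-orthogonalises ML.  The
three unit vectors form the rows of a direction-cosine matrix that projects
sensor-frame vectors onto anatomical (SI, ML, AP) components.

The matrix is applied in projection form (axis vectors as rows): for a
sensor-frame sample ``v``, the anatomical components are
``(v . a, v . b, v . c)``.  Polarity of the anatomical axes is not fixed by
gravity alone; handedness is enforced (det = +1) and signal polarity is
normalised downstream by the detectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .signal_model import (
    ANATOMICAL_CHANNELS,
    DataError,
    Frame,
    GaitWarning,
    InertialRecording,
    UsageError,
)

__all__ = [
    "StaticPoseSample",
    "BodyFrameTransform",
    "DegeneratePoseError",
    "mean_gravity",
    "build_transform",
    "apply_transform",
]

GRAVITY = 9.81  # m/s^2

#: default minimum still-window length, s
MIN_WINDOW_S = 0.5
#: gyro RMS above which a "static" pose is suspect, deg/s
STILLNESS_RMS_THRESH = 10.0
#: minimum angle between the two pose gravity vectors, deg
MIN_POSE_ANGLE_DEG = 5.0


class DegeneratePoseError(DataError):
    """The two calibration poses are too close to define the sagittal plane."""


@dataclass(frozen=True)
class StaticPoseSample:
    """Normalised mean gravity direction plus a stillness figure of merit."""

    g_unit: np.ndarray  # unit 3-vector in the sensor frame
    motion_rms: float  # deg/s, RMS gyro magnitude over the window

    def __post_init__(self) -> None:
        g = np.asarray(self.g_unit, dtype=float).reshape(3)
        n = np.linalg.norm(g)
        if abs(n - 1.0) > 1e-9:
            raise DataError(f"g_unit must be a unit vector, |g| = {n:.6g}")
        object.__setattr__(self, "g_unit", g)


@dataclass(frozen=True)
class BodyFrameTransform:
    """Orthonormal sensor-to-anatomical mapping (rows a=SI, b=ML, c=AP)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        M = self.matrix
        if np.max(np.abs(M @ M.T - np.eye(3))) > 1e-8:
            raise DataError("transform axes are not orthonormal")
        if np.linalg.det(M) < 0:
            raise DataError("transform is left-handed (det < 0)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 projection matrix with rows (SI, ML, AP)."""
        return np.vstack([self.a, self.b, self.c])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "SI": self.a.tolist(),
            "ML": self.b.tolist(),
            "AP": self.c.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "BodyFrameTransform":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        return cls(np.array(payload["SI"]), np.array(payload["ML"]), np.array(payload["AP"]))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def mean_gravity(
    rec: InertialRecording, window: tuple[float, float] | None = None
) -> StaticPoseSample:
    """Average the accelerometer over a still window and normalise.

    ``window`` is a (start, end) interval on the recording's clock; by
    default the whole recording is used.  Errors if the window is shorter
    than 0.5 s or the mean acceleration is not gravity-dominated (norm below
    half of g); warns if the gyro RMS exceeds 10 deg/s.
    """
    if window is None:
        window = (float(rec.time[0]), float(rec.time[-1]))
    t0, t1 = window
    if t0 < rec.time[0] - 1e-9 or t1 > rec.time[-1] + 1e-9:
        raise UsageError("window extends beyond the recording span")
    if t1 - t0 < MIN_WINDOW_S:
        raise UsageError(f"still window must be at least {MIN_WINDOW_S} s")
    mask = (rec.time >= t0) & (rec.time <= t1)
    mean_acc = rec.acc[mask].mean(axis=0)
    norm = np.linalg.norm(mean_acc)
    if norm < 0.5 * GRAVITY:
        raise DataError(
            f"not static / not gravity-dominated: |mean acc| = {norm:.3g} m/s^2"
        )
    motion_rms = float(np.sqrt(np.mean(np.sum(rec.gyr[mask] ** 2, axis=1))))
    if motion_rms > STILLNESS_RMS_THRESH:
        warnings.warn(
            f"pose not still: gyro RMS {motion_rms:.1f} deg/s", GaitWarning, stacklevel=2
        )
    return StaticPoseSample(g_unit=mean_acc / norm, motion_rms=motion_rms)


def build_transform(
    pose_stand: StaticPoseSample, pose_sit: StaticPoseSample
) -> BodyFrameTransform:
    """Construct the anatomical axes from standing and seated gravity.

    SI is the standing gravity direction; ML is the cross product of the
    seated gravity direction with SI; AP = SI x ML; ML is then redefined as
    AP x SI to enforce mutual orthogonality.  If the resulting triad is
    left-handed, ML is flipped so det = +1 (gravity alone does not fix the
    left/right polarity).
    """
    a = pose_stand.g_unit
    angle = float(
        np.degrees(np.arccos(np.clip(np.dot(a, pose_sit.g_unit), -1.0, 1.0)))
    )
    if angle < MIN_POSE_ANGLE_DEG or angle > 180.0 - MIN_POSE_ANGLE_DEG:
        raise DegeneratePoseError(
            f"calibration poses are near-parallel ({angle:.2f} deg apart); "
            "the sagittal plane is undefined"
        )
    b = _unit(np.cross(pose_sit.g_unit, a))
    c = _unit(np.cross(a, b))
    b = np.cross(c, a)  # exact re-orthogonalisation
    if np.linalg.det(np.vstack([a, b, c])) < 0:
        b = -b
    return BodyFrameTransform(a=a, b=b, c=c)


def apply_transform(
    rec: InertialRecording, transform: BodyFrameTransform
) -> InertialRecording:
    """Project a sensor-frame recording onto anatomical (SI, ML, AP) axes."""
    if rec.frame is not Frame.SENSOR:
        raise UsageError("recording is already in the anatomical frame")
    M = transform.matrix
    return replace(
        rec,
        acc=rec.acc @ M.T,
        gyr=rec.gyr @ M.T,
        frame=Frame.ANATOMICAL,
        channel_names=ANATOMICAL_CHANNELS,
    )
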