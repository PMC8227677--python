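"""Domain types for inertial time series and gait events, plus CSV I/O.

The package works with uniformly sampled 3-axis accelerometer (m/s^2) and
3-axis rotational-velocity (deg/s) recordings.  A recording lives either in
the raw *sensor* frame (channels x, y, z) or, after sensor-to-body
calibration, in the *anatomical* frame with channels SI (superior-inferior),
ML (medial-lateral) and AP (anterior-posterior).

Two plain CSV dialects are defined here and used throughout:

* time-series dialect: header ``time_s,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z``
* event dialect: header ``t_s,kind`` with ``kind`` in {HS, TO}

All files are UTF-8 with "." as decimal separator; event times are seconds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANATOMICAL_CHANNELS",
    "SENSOR_CHANNELS",
    "IMU_CSV_COLUMNS",
    "EVENT_CSV_COLUMNS",
    "Frame",
    "EventKind",
    "GaitError",
    "FormatError",
    "DataError",
    "UsageError",
    "GaitWarning",
    "InertialRecording",
    "GaitEvent",
    "EventSeries",
    "read_imu_csv",
    "write_imu_csv",
    "read_event_csv",
    "write_event_csv",
]

ANATOMICAL_CHANNELS: tuple[str, str, str] = ("SI", "ML", "AP")
SENSOR_CHANNELS: tuple[str, str, str] = ("x", "y", "z")

IMU_CSV_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
EVENT_CSV_COLUMNS = ["t_s", "kind"]

#: tolerance on |dt - 1/fs| for the uniform-sampling invariant, seconds
_UNIFORM_TOL_S = 1e-6


class GaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitError):
    """A file does not follow one of the CSV dialects."""


class DataError(GaitError):
    """Data content violates an invariant (timing, units, signal content)."""


class UsageError(GaitError):
    """An operation was applied to an input it is not defined for."""


class GaitWarning(UserWarning):
    """Non-fatal data-quality notice (dropped events, unsorted input, ...)."""


class Frame(str, enum.Enum):
    SENSOR = "sensor"
    ANATOMICAL = "anatomical"


class EventKind(str, enum.Enum):
    HS = "HS"  # heel strike / initial contact
    TO = "TO"  # toe off / final contact


@dataclass(frozen=True)
class InertialRecording:
    """Uniformly sampled 3-axis acceleration + rotational velocity.

    Parameters
    ----------
    time:
        Sample instants in seconds, strictly increasing with uniform step
        ``1/fs`` (to 1e-6 s).
    acc:
        ``(n, 3)`` acceleration in m/s^2.
    gyr:
        ``(n, 3)`` rotational velocity in deg/s.
    fs:
        Sampling rate in Hz.
    frame:
        ``Frame.SENSOR`` or ``Frame.ANATOMICAL``.
    channel_names:
        Axis labels; must be exactly ``("SI", "ML", "AP")`` when anatomical.
    location_label:
        Free-text mounting site (e.g. "DFoot", "Heel", "LLS", "MLS", "Shin").
    meta:
        Free-form provenance (e.g. polarity normalisation applied).
    """

    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    frame: Frame = Frame.SENSOR
    channel_names: tuple[str, str, str] = SENSOR_CHANNELS
    location_label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        acc = np.asarray(self.acc, dtype=float)
        gyr = np.asarray(self.gyr, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyr", gyr)
        object.__setattr__(self, "frame", Frame(self.frame))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if time.ndim != 1 or len(time) < 2:
            raise DataError("recording needs at least two samples")
        if acc.shape != (len(time), 3) or gyr.shape != (len(time), 3):
            raise DataError(
                "acc and gyr must be (n, 3) arrays matching the time vector; "
                f"got acc {acc.shape}, gyr {gyr.shape}, n={len(time)}"
            )
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise DataError("time vector must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) >= _UNIFORM_TOL_S:
            raise DataError(
                f"non-uniform sampling: max |dt - 1/fs| = "
                f"{np.max(np.abs(dt - 1.0 / self.fs)):.3g} s"
            )
        if self.frame is Frame.ANATOMICAL and self.channel_names != ANATOMICAL_CHANNELS:
            raise DataError(
                "anatomical recordings must use channels "
                f"{ANATOMICAL_CHANNELS}, got {self.channel_names}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel(self, which: str, name: str) -> np.ndarray:
        """Return one named axis of ``acc`` or ``gyr``."""
        if which not in ("acc", "gyr"):
            raise UsageError(f"which must be 'acc' or 'gyr', got {which!r}")
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise UsageError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return (self.acc if which == "acc" else self.gyr)[:, idx]

    def shifted(self, dt: float) -> "InertialRecording":
        """Return a copy with the clock shifted by ``dt`` seconds."""
        return replace(self, time=self.time + dt)


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single timed gait event (heel strike or toe off)."""

    t: float
    kind: EventKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))
        object.__setattr__(self, "t", float(self.t))


@dataclass(frozen=True)
class EventSeries:
    """Time-ordered heel-strike / toe-off events with a provenance tag."""

    events: tuple[GaitEvent, ...]
    source: str = ""

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        ts = [e.t for e in events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise DataError("events must be nondecreasing in time")

    @classmethod
    def from_events(cls, events: Iterable[GaitEvent], source: str = "") -> "EventSeries":
        """Build a series, sorting if needed (stable in time, HS before TO at ties)."""
        evs = sorted(events, key=lambda e: (e.t, e.kind.value))
        return cls(tuple(evs), source=source)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GaitEvent]:
        return iter(self.events)

    def times(self, kind: EventKind | str | None = None) -> np.ndarray:
        if kind is None:
            return np.array([e.t for e in self.events], dtype=float)
        kind = EventKind(kind)
        return np.array([e.t for e in self.events if e.kind is kind], dtype=float)

    def shifted(self, dt: float) -> "EventSeries":
        return EventSeries(
            tuple(GaitEvent(e.t + dt, e.kind) for e in self.events), source=self.source
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_imu_csv(path: str | Path, fs_expected: float) -> InertialRecording:
    """Read a time-series CSV (dialect header ``time_s,acc_x,...,gyr_z``).

    The time column is re-based to start at 0 and the recording is tagged as
    sensor-frame.  Raises :class:`FormatError` on header mismatch,
    :class:`DataError` on non-monotonic time or a sampling-rate mismatch
    (median dt off by more than 1% from ``1/fs_expected``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    missing = [c for c in IMU_CSV_COLUMNS if c not in cols]
    extra = [c for c in cols if c not in IMU_CSV_COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise FormatError(f"{path.name}: {'; '.join(parts)}")
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise DataError(f"{path.name}: time column is not strictly increasing")
    med_dt = float(np.median(np.diff(time)))
    if abs(med_dt - 1.0 / fs_expected) > 0.01 / fs_expected:
        raise DataError(
            f"{path.name}: sampling-rate mismatch — median dt {med_dt:.6g} s "
            f"vs expected {1.0 / fs_expected:.6g} s"
        )
    return InertialRecording(
        time=time - time[0],
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        gyr=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float),
        fs=fs_expected,
        frame=Frame.SENSOR,
    )


def write_imu_csv(rec: InertialRecording, path: str | Path) -> Path:
    """Write a recording in the time-series dialect (axes in stored order)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "acc_x": rec.acc[:, 0],
            "acc_y": rec.acc[:, 1],
            "acc_z": rec.acc[:, 2],
            "gyr_x": rec.gyr[:, 0],
            "gyr_y": rec.gyr[:, 1],
            "gyr_z": rec.gyr[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
    return path


def read_event_csv(path: str | Path) -> EventSeries:
    """Read an event CSV (``t_s,kind``); unsorted rows are sorted with a warning."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_CSV_COLUMNS:
        raise FormatError(
            f"{path.name}: expected columns {EVENT_CSV_COLUMNS}, got {list(df.columns)}"
        )
    events = []
    for t, kind in zip(df["t_s"], df["kind"]):
        try:
            k = EventKind(str(kind).strip())
        except ValueError:
            raise FormatError(
                f"{path.name}: unknown event kind {kind!r} (expected HS or TO)"
            ) from None
        events.append(GaitEvent(float(t), k))
    ts = [e.t for e in events]
    if any(b < a for a, b in zip(ts, ts[1:])):
        warnings.warn(
            f"{path.name}: events out of order; sorting", GaitWarning, stacklevel=2
        )
    return EventSeries.from_events(events, source=path.stem)


def write_event_csv(series: EventSeries, path: str | Path) -> Path:
    """Write events in the event dialect; inverse of :func:`read_event_csv`."""
    path = Path(path)
    df = pd.DataFrame(
        {"t_s": [e.t for e in series], "kind": [e.kind.value for e in series]}
    )
    df.to_csv(path, index=False, float_format="%.9f")
    return path
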