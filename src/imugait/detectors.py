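"""Five IMU gait-event detection algorithms sharing one interface.

All five algorithms segment strides with the same primitive: the large
positive peak in medial-lateral (ML) rotational velocity at mid-swing.
Around each mid-swing peak they locate heel strike (HS) and toe off (TO)
from different signal features:

1. ``rv_minima``       — ML rotational-velocity minima flanking the peak.
2. ``rv_zero``         — ML rotational-velocity zero crossings flanking the
                         peak (sub-frame interpolated).
3. ``siacc_apacc``     — drift-corrected sagittal angle (ZUPT on the foot, a
                         modified mid-stance anchor on the shank) gives peak
                         plantar/dorsiflexion; TO is an anterior-posterior
                         (AP) acceleration minimum near peak plantarflexion,
                         HS a superior-inferior (SI) acceleration minimum
                         near peak dorsiflexion.
4. ``mlvel_apacc``     — a per-stride "trusted swing" region (ML rotational
                         velocity above 20% of the local mid-swing maximum)
                         excludes events; TO is the AP acceleration minimum
                         before trusted swing, HS the ML rotational-velocity
                         minimum after it.
5. ``apacc_mlvel``     — TO is the ML rotational-velocity zero crossing
                         before the peak; HS is the AP acceleration maximum
                         in a 50 ms-before / 20 ms-after window around the
                         post-peak ML rotational-velocity minimum.

Every detector maps ``(InertialRecording, DetectorParams) -> EventSeries``
and first normalises ML polarity so the mid-swing excursion is positive,
making results independent of mounting side and axis sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .signal_model import (
    DataError,
    EventKind,
    EventSeries,
    Frame,
    GaitEvent,
    GaitWarning,
    InertialRecording,
    UsageError,
)

__all__ = [
    "DetectorParams",
    "SagittalAngleTrace",
    "DETECTOR_NAMES",
    "orient_midswing_positive",
    "find_midswing_peaks",
    "detect_rv_minima",
    "detect_rv_zero_crossing",
    "estimate_sagittal_angle",
    "detect_siacc_apacc",
    "detect_mlvel_apacc",
    "detect_apacc_mlvel",
    "detect",
]

#: ML rotational-velocity magnitude below which a trial has no gait content, deg/s
_MIN_GAIT_AMPLITUDE = 10.0
#: minimum stationary-interval length for ZUPT anchoring, s
_ZUPT_MIN_DWELL_S = 0.1

FOOT_LOCATIONS = {"heel", "dfoot", "foot"}


@dataclass(frozen=True)
class DetectorParams:
    """Shared tunables for all detectors.

    ``trusted_swing_frac`` (0.20) and the HS search window
    (``hs_window_before`` 50 ms / ``hs_window_after`` 20 ms) are fixed by the
    algorithm definitions; the remaining fields fill gaps those definitions
    leave open (peak prominence, minimum stride period, ZUPT stillness
    threshold, flexion search half-width).
    """

    trusted_swing_frac: float = 0.20
    hs_window_before: float = 0.050  # s
    hs_window_after: float = 0.020  # s
    peak_min_prominence_frac: float = 0.5
    min_stride_period: float = 0.6  # s
    zupt_gyro_thresh: float = 15.0  # deg/s
    flexion_search_halfwidth: float = 0.15  # s

    def __post_init__(self) -> None:
        for name in (
            "hs_window_before",
            "hs_window_after",
            "peak_min_prominence_frac",
            "min_stride_period",
            "zupt_gyro_thresh",
            "flexion_search_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        if not 0.0 < self.trusted_swing_frac < 1.0:
            raise UsageError("trusted_swing_frac must lie in (0, 1)")


@dataclass(frozen=True)
class SagittalAngleTrace:
    """Drift-corrected integral of ML rotational velocity (degrees)."""

    time: np.ndarray
    angle: np.ndarray
    anchors: np.ndarray  # times forced to zero angle


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def orient_midswing_positive(rec: InertialRecording) -> InertialRecording:
    """Flip the ML gyro channel if the dominant excursion is negative.

    Idempotent; records the flip in ``rec.meta['ml_flipped']``.  Errors if
    the ML rotational velocity never exceeds 10 deg/s in magnitude (no gait
    content to orient by).
    """
    if rec.frame is not Frame.ANATOMICAL:
        raise UsageError("detectors require an anatomical-frame recording")
    ml = rec.channel("gyr", "ML")
    if np.max(np.abs(ml)) < _MIN_GAIT_AMPLITUDE:
        raise DataError(
            "no gait content: |ML rotational velocity| stays below "
            f"{_MIN_GAIT_AMPLITUDE} deg/s"
        )
    if abs(ml.min()) <= abs(ml.max()):
        if "ml_flipped" in rec.meta:
            return rec
        return replace(rec, meta={**rec.meta, "ml_flipped": False})
    idx = rec.channel_names.index("ML")
    gyr = rec.gyr.copy()
    gyr[:, idx] = -gyr[:, idx]
    return replace(rec, gyr=gyr, meta={**rec.meta, "ml_flipped": True})


def find_midswing_peaks(
    rec: InertialRecording, params: DetectorParams | None = None
) -> np.ndarray:
    """Times of mid-swing ML rotational-velocity peaks, in order.

    A recording with no gait content (near-flat ML gyro) yields an empty
    array rather than an error.
    """
    params = params or DetectorParams()
    try:
        rec = orient_midswing_positive(rec)
    except DataError:
        return np.array([], dtype=float)
    return rec.time[_peak_indices(rec.channel("gyr", "ML"), rec.fs, params)]


def _peak_indices(ml: np.ndarray, fs: float, params: DetectorParams) -> np.ndarray:
    peak_ref = float(ml.max())
    if peak_ref <= 0:
        return np.array([], dtype=int)
    idx, _ = find_peaks(
        ml,
        prominence=params.peak_min_prominence_frac * peak_ref,
        distance=max(1, int(round(params.min_stride_period * fs))),
    )
    return idx


def _strict_local_min(sig: np.ndarray, lo: int, hi: int) -> int | None:
    """Index of the minimum of ``sig[lo:hi]`` if it is a strict local minimum."""
    lo, hi = max(lo, 0), min(hi, len(sig))
    if hi - lo < 1:
        return None
    i = lo + int(np.argmin(sig[lo:hi]))
    if 0 < i < len(sig) - 1 and sig[i] < sig[i - 1] and sig[i] < sig[i + 1]:
        return i
    return None


def _strict_local_max(sig: np.ndarray, lo: int, hi: int) -> int | None:
    i = _strict_local_min(-sig, lo, hi)
    return i


def _last_upward_crossing(
    sig: np.ndarray, time: np.ndarray, lo: int, hi: int
) -> float | None:
    """Interpolated time of the last - to + zero crossing in ``[lo, hi)``."""
    lo, hi = max(lo, 0), min(hi, len(sig) - 1)
    seg = np.flatnonzero((sig[lo:hi] <= 0) & (sig[lo + 1 : hi + 1] > 0))
    if len(seg) == 0:
        return None
    i = lo + int(seg[-1])
    return _interp_zero(sig, time, i)


def _first_downward_crossing(
    sig: np.ndarray, time: np.ndarray, lo: int, hi: int
) -> float | None:
    lo, hi = max(lo, 0), min(hi, len(sig) - 1)
    seg = np.flatnonzero((sig[lo:hi] >= 0) & (sig[lo + 1 : hi + 1] < 0))
    if len(seg) == 0:
        return None
    i = lo + int(seg[0])
    return _interp_zero(sig, time, i)


def _interp_zero(sig: np.ndarray, time: np.ndarray, i: int) -> float:
    s0, s1 = sig[i], sig[i + 1]
    if s0 == 0.0:
        return float(time[i])
    return float(time[i] + (time[i + 1] - time[i]) * (-s0) / (s1 - s0))


def _stride_estimate(peak_times: np.ndarray, params: DetectorParams) -> float:
    if len(peak_times) >= 2:
        return float(np.median(np.diff(peak_times)))
    return max(2.0 * params.min_stride_period, 1.0)


class _Segmented:
    """Oriented recording with mid-swing peaks and per-peak search bounds."""

    def __init__(self, rec: InertialRecording, params: DetectorParams):
        self.rec = orient_midswing_positive(rec)
        self.params = params
        self.ml = self.rec.channel("gyr", "ML")
        self.time = self.rec.time
        self.fs = self.rec.fs
        self.ip = _peak_indices(self.ml, self.fs, params)
        if len(self.ip) == 0:
            raise DataError("no mid-swing peaks found; cannot segment strides")
        self.tp = self.time[self.ip]
        self.stride_est = _stride_estimate(self.tp, params)

    @property
    def n(self) -> int:
        return len(self.ip)

    def left_mid_idx(self, k: int) -> int:
        """Sample bound at the midpoint toward the previous peak (fallback: half stride)."""
        if k > 0:
            t = 0.5 * (self.tp[k - 1] + self.tp[k])
        else:
            t = self.tp[k] - 0.5 * self.stride_est
        return int(np.searchsorted(self.time, t, side="right"))

    def right_mid_idx(self, k: int) -> int:
        if k + 1 < self.n:
            t = 0.5 * (self.tp[k] + self.tp[k + 1])
        else:
            t = self.tp[k] + 0.5 * self.stride_est
        return int(np.searchsorted(self.time, t, side="left"))


def _omit(what: str, k: int, why: str) -> None:
    warnings.warn(
        f"{what} omitted for mid-swing peak {k}: {why}", GaitWarning, stacklevel=3
    )


def _series(events: list[GaitEvent], rec: InertialRecording, name: str) -> EventSeries:
    src = f"{name}/{rec.location_label}" if rec.location_label else name
    return EventSeries.from_events(events, source=src)


# ---------------------------------------------------------------------------
# type 1 — rotational-velocity minima
# ---------------------------------------------------------------------------

def detect_rv_minima(
    rec: InertialRecording, params: DetectorParams | None = None
) -> EventSeries:
    """TO and HS as ML rotational-velocity minima flanking each mid-swing peak."""
    params = params or DetectorParams()
    seg = _Segmented(rec, params)
    events: list[GaitEvent] = []
    for k in range(seg.n):
        i_to = _strict_local_min(seg.ml, seg.left_mid_idx(k), seg.ip[k])
        if i_to is None:
            _omit("TO", k, "no local ML rotational-velocity minimum before the peak")
        else:
            events.append(GaitEvent(seg.time[i_to], EventKind.TO))
        i_hs = _strict_local_min(seg.ml, seg.ip[k] + 1, seg.right_mid_idx(k))
        if i_hs is None:
            _omit("HS", k, "no local ML rotational-velocity minimum after the peak")
        else:
            events.append(GaitEvent(seg.time[i_hs], EventKind.HS))
    return _series(events, seg.rec, "rv_minima")


# ---------------------------------------------------------------------------
# type 2 — rotational-velocity zero crossings
# ---------------------------------------------------------------------------

def detect_rv_zero_crossing(
    rec: InertialRecording, params: DetectorParams | None = None
) -> EventSeries:
    """TO/HS as interpolated ML rotational-velocity zero crossings around each peak."""
    params = params or DetectorParams()
    seg = _Segmented(rec, params)
    events: list[GaitEvent] = []
    for k in range(seg.n):
        lo = seg.ip[k - 1] if k > 0 else 0
        t_to = _last_upward_crossing(seg.ml, seg.time, lo, seg.ip[k])
        if t_to is None:
            _omit("TO", k, "no upward zero crossing before the peak")
        else:
            events.append(GaitEvent(t_to, EventKind.TO))
        hi = seg.ip[k + 1] if k + 1 < seg.n else len(seg.ml) - 1
        t_hs = _first_downward_crossing(seg.ml, seg.time, seg.ip[k], hi)
        if t_hs is None:
            _omit("HS", k, "no downward zero crossing after the peak")
        else:
            events.append(GaitEvent(t_hs, EventKind.HS))
    return _series(events, seg.rec, "rv_zero")


# ---------------------------------------------------------------------------
# type 3 — sagittal angle + SI/AP acceleration minima
# ---------------------------------------------------------------------------

def estimate_sagittal_angle(
    rec: InertialRecording,
    params: DetectorParams | None = None,
    mode: str = "foot",
) -> SagittalAngleTrace:
    """Drift-corrected sagittal angle from integrated ML rotational velocity.

    The raw angle is the cumulative trapezoidal integral of the ML gyro.
    Drift is removed by a piecewise-linear correction forced to zero at
    anchor instants: in ``foot`` mode these are the centres of stationary
    intervals (gyro magnitude below ``zupt_gyro_thresh`` for at least 0.1 s,
    the classical zero-velocity update); in ``shank`` mode — where the shank
    never stops during stance — the midpoints between successive mid-swing
    peaks.  Beyond the first/last anchor the adjacent correction segment is
    extended.  Foot mode falls back to shank anchors (with a warning) when
    no stationary interval exists.
    """
    params = params or DetectorParams()
    if mode not in ("foot", "shank"):
        raise UsageError(f"mode must be 'foot' or 'shank', got {mode!r}")
    try:
        rec = orient_midswing_positive(rec)
    except DataError:
        pass  # a near-still recording integrates to a (near-)zero angle
    ml = rec.channel("gyr", "ML")
    raw = cumulative_trapezoid(ml, rec.time, initial=0.0)

    anchor_idx: np.ndarray | None = None
    if mode == "foot":
        anchor_idx = _zupt_anchor_indices(rec, params)
        if anchor_idx is None:
            warnings.warn(
                "no stationary interval for ZUPT anchoring; "
                "falling back to mid-stance anchors",
                GaitWarning,
                stacklevel=2,
            )
    if anchor_idx is None:
        ip = _peak_indices(ml, rec.fs, params)
        if len(ip) < 2:
            raise DataError("mid-stance anchoring requires at least two mid-swing peaks")
        anchor_idx = ((ip[:-1] + ip[1:]) // 2).astype(int)

    correction = _piecewise_linear_through(rec.time, raw, anchor_idx)
    angle = raw - correction
    return SagittalAngleTrace(
        time=rec.time, angle=angle, anchors=rec.time[anchor_idx]
    )


def _zupt_anchor_indices(
    rec: InertialRecording, params: DetectorParams
) -> np.ndarray | None:
    mag = np.linalg.norm(rec.gyr, axis=1)
    below = mag < params.zupt_gyro_thresh
    min_len = max(1, int(round(_ZUPT_MIN_DWELL_S * rec.fs)))
    anchors = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_len:
            anchors.append((start + stop - 1) // 2)
    if not anchors:
        return None
    return np.asarray(anchors, dtype=int)


def _piecewise_linear_through(
    t: np.ndarray, y: np.ndarray, anchor_idx: np.ndarray
) -> np.ndarray:
    ta, ya = t[anchor_idx], y[anchor_idx]
    if len(anchor_idx) == 1:
        return np.full_like(y, ya[0])
    line = np.interp(t, ta, ya)
    before = t < ta[0]
    if np.any(before):
        s0 = (ya[1] - ya[0]) / (ta[1] - ta[0])
        line[before] = ya[0] + s0 * (t[before] - ta[0])
    after = t > ta[-1]
    if np.any(after):
        s1 = (ya[-1] - ya[-2]) / (ta[-1] - ta[-2])
        line[after] = ya[-1] + s1 * (t[after] - ta[-1])
    return line


def detect_siacc_apacc(
    rec: InertialRecording,
    params: DetectorParams | None = None,
    mode: str = "auto",
) -> EventSeries:
    """TO/HS from acceleration minima near peak plantar-/dorsiflexion.

    ``mode='auto'`` picks foot-style ZUPT anchoring for foot-mounted sensors
    (location label Heel/DFoot) and the mid-stance anchor otherwise.
    """
    params = params or DetectorParams()
    if mode == "auto":
        mode = "foot" if rec.location_label.lower() in FOOT_LOCATIONS else "shank"
    seg = _Segmented(rec, params)
    trace = estimate_sagittal_angle(seg.rec, params, mode=mode)
    ap = seg.rec.channel("acc", "AP")
    si = seg.rec.channel("acc", "SI")
    hw = max(1, int(round(params.flexion_search_halfwidth * seg.fs)))
    events: list[GaitEvent] = []
    for k in range(seg.n):
        lo = seg.ip[k - 1] if k > 0 else 0
        i_pf = _strict_local_min(trace.angle, lo, seg.ip[k])
        if i_pf is None:
            _omit("TO", k, "no peak plantarflexion before the peak")
        else:
            i_to = _windowed_strict_min(ap, i_pf - hw, i_pf + hw + 1)
            if i_to is None:
                _omit("TO", k, "no interior AP acceleration minimum near plantarflexion")
            else:
                events.append(GaitEvent(seg.time[i_to], EventKind.TO))
        hi = seg.ip[k + 1] if k + 1 < seg.n else len(seg.ml)
        i_df = _strict_local_max(trace.angle, seg.ip[k] + 1, hi)
        if i_df is None:
            _omit("HS", k, "no peak dorsiflexion after the peak")
        else:
            i_hs = _windowed_strict_min(si, i_df - hw, i_df + hw + 1)
            if i_hs is None:
                _omit("HS", k, "no interior SI acceleration minimum near dorsiflexion")
            else:
                events.append(GaitEvent(seg.time[i_hs], EventKind.HS))
    return _series(events, seg.rec, "siacc_apacc")


def _windowed_strict_min(sig: np.ndarray, lo: int, hi: int) -> int | None:
    """Strict local minimum that is also interior to the search window."""
    lo, hi = max(lo, 0), min(hi, len(sig))
    i = _strict_local_min(sig, lo, hi)
    if i is None or i == lo or i == hi - 1:
        return None
    return i


# ---------------------------------------------------------------------------
# type 4 — trusted swing: ML velocity minimum (HS) / AP acceleration minimum (TO)
# ---------------------------------------------------------------------------

def detect_mlvel_apacc(
    rec: InertialRecording, params: DetectorParams | None = None
) -> EventSeries:
    """Trusted-swing-gated detection: AP acceleration minimum (TO) and ML
    rotational-velocity minimum (HS) outside each per-stride trusted swing.

    Trusted swing is the maximal contiguous interval around a mid-swing peak
    where ML rotational velocity exceeds ``trusted_swing_frac`` of that
    peak's (local) value; no event may fall inside it.
    """
    params = params or DetectorParams()
    seg = _Segmented(rec, params)
    ap = seg.rec.channel("acc", "AP")
    spans = [_trusted_swing(seg.ml, p, params.trusted_swing_frac) for p in seg.ip]
    events: list[GaitEvent] = []
    n = len(seg.ml)
    for k, (s, e) in enumerate(spans):
        lo = spans[k - 1][1] + 1 if k > 0 else 0
        if lo >= s:
            _omit("TO", k, "no samples between previous trusted swing and this one")
        else:
            i_to = lo + int(np.argmin(ap[lo:s]))
            events.append(GaitEvent(seg.time[i_to], EventKind.TO))
        hi = spans[k + 1][0] if k + 1 < seg.n else n
        if e + 1 >= hi:
            _omit("HS", k, "no samples between this trusted swing and the next")
        else:
            i_hs = e + 1 + int(np.argmin(seg.ml[e + 1 : hi]))
            events.append(GaitEvent(seg.time[i_hs], EventKind.HS))
    return _series(events, seg.rec, "mlvel_apacc")


def _trusted_swing(ml: np.ndarray, peak_idx: int, frac: float) -> tuple[int, int]:
    """[start, end] sample span of the contiguous region above the local threshold."""
    thresh = frac * ml[peak_idx]
    s = peak_idx
    while s > 0 and ml[s - 1] > thresh:
        s -= 1
    e = peak_idx
    while e < len(ml) - 1 and ml[e + 1] > thresh:
        e += 1
    return s, e


# ---------------------------------------------------------------------------
# type 5 — AP acceleration maximum in a window around the ML velocity minimum
# ---------------------------------------------------------------------------

def detect_apacc_mlvel(
    rec: InertialRecording, params: DetectorParams | None = None
) -> EventSeries:
    """TO at the pre-peak ML zero crossing; HS as the AP acceleration maximum
    within [-50 ms, +20 ms] of the post-peak ML rotational-velocity minimum.

    The millisecond window is converted to frames by rounding outward so the
    boundary instants are always included; an HS landing exactly on a window
    edge is kept but flagged with a warning.
    """
    params = params or DetectorParams()
    seg = _Segmented(rec, params)
    ap = seg.rec.channel("acc", "AP")
    back = math.ceil(params.hs_window_before * seg.fs - 1e-9)
    fwd = math.ceil(params.hs_window_after * seg.fs - 1e-9)
    events: list[GaitEvent] = []
    for k in range(seg.n):
        lo = seg.ip[k - 1] if k > 0 else 0
        t_to = _last_upward_crossing(seg.ml, seg.time, lo, seg.ip[k])
        if t_to is None:
            _omit("TO", k, "no upward zero crossing before the peak")
        else:
            events.append(GaitEvent(t_to, EventKind.TO))
        i_ref = _strict_local_min(seg.ml, seg.ip[k] + 1, seg.right_mid_idx(k))
        if i_ref is None:
            _omit("HS", k, "no post-peak ML rotational-velocity minimum")
            continue
        w_lo = max(0, i_ref - back)
        w_hi = min(len(ap) - 1, i_ref + fwd)
        i_hs = w_lo + int(np.argmax(ap[w_lo : w_hi + 1]))
        if i_hs in (w_lo, w_hi):
            warnings.warn(
                f"HS search-window edge hit for mid-swing peak {k}",
                GaitWarning,
                stacklevel=2,
            )
        events.append(GaitEvent(seg.time[i_hs], EventKind.HS))
    return _series(events, seg.rec, "apacc_mlvel")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

DETECTOR_NAMES = ("rv_minima", "rv_zero", "siacc_apacc", "mlvel_apacc", "apacc_mlvel")

_REGISTRY = {
    "rv_minima": detect_rv_minima,
    "rv_zero": detect_rv_zero_crossing,
    "siacc_apacc": detect_siacc_apacc,
    "mlvel_apacc": detect_mlvel_apacc,
    "apacc_mlvel": detect_apacc_mlvel,
}


def detect(
    name: str, rec: InertialRecording, params: DetectorParams | None = None
) -> EventSeries:
    """Run a detector by registry name."""
    try:
        fn = _REGISTRY[name]
    except KeyError:
        raise UsageError(
            f"unknown detector {name!r}; choose from {DETECTOR_NAMES}"
        ) from None
    return fn(rec, params)
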