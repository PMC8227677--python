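"""Synthetic gait-signal generator with exact ground-truth events.

The generator is not a biomechanical model: it plants, stride by stride,
exactly the signal features the detectors consume, so every detected event
has an auditable ground truth.

Per stride with drawn period ``T_i`` (heel strike at ``HS_i``, toe off at
``HS_i + stance_frac * T_i``):

* ML rotational velocity: a baseline near zero through stance, sharp
  negative notches with vertices exactly at TO and the next HS, a steep rise
  crossing zero within a few milliseconds of each event, a positive swing
  plateau, and a large Gaussian mid-swing bump centred between TO and the
  next HS.  This yields co-located minima, zero crossings and a
  trusted-swing region for the rotational-velocity detectors.
* AP acceleration: a negative spike at TO and a positive spike at HS.
* SI acceleration: a negative spike at HS (gravity-free channel).

An optional heel-sensor artifact adds a positive drift/oscillation to the AP
acceleration in the quarter second before each TO, displacing the AP minimum
in that region well before the event — the known failure mode of
trusted-swing AP-minimum detection on heel-mounted sensors.

White Gaussian noise is added per channel; stride periods are drawn before
any noise, so trials with the same seed share identical event timing across
noise and artifact settings (paired comparisons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_model import (
    ANATOMICAL_CHANNELS,
    EventKind,
    EventSeries,
    Frame,
    GaitError,
    GaitEvent,
    InertialRecording,
    write_event_csv,
    write_imu_csv,
)

__all__ = [
    "GaitSimParams",
    "SyntheticTrial",
    "BatteryConfig",
    "LabeledTrial",
    "LOCATION_PROFILES",
    "TASK_JITTER_SD",
    "simulate_trial",
    "simulate_calibration",
    "make_benchmark_battery",
    "export_battery",
]

# fixed waveform geometry (seconds) — narrow enough for 60 Hz grids and the
# shortest plausible stance/swing phases
_NOTCH_LEAD = 0.07  # descent into the TO notch
_NOTCH_RISE = 0.012  # steep recovery after a notch vertex (zero cross < 1 frame)
_NOTCH_SETTLE = 0.05  # relaxation back to baseline after an HS notch
_BUMP_SIGMA = 0.05  # mid-swing Gaussian width
_ACC_SPIKE_HALFWIDTH = 0.04  # AP spike half-width
_SI_SPIKE_HALFWIDTH = 0.035
_ARTIFACT_SPAN = 0.25  # heel AP drift window before TO
_BASELINE_ML = -8.0  # deg/s, slight negative stance baseline
_TO_NOTCH_FRAC = 0.7  # TO minima are shallower than HS minima, as on real shanks
_MIN_STANCE = 0.35  # s, shortest stance the waveform geometry supports
_MIN_SWING = 0.20


@dataclass(frozen=True)
class GaitSimParams:
    """Generator settings; defaults emulate healthy self-paced walking at 60 Hz."""

    n_strides: int = 20
    fs: float = 60.0
    stride_period_mean: float = 1.05  # s
    stride_period_sd: float = 0.02  # s, stride-to-stride timing jitter
    stance_frac: float = 0.62
    midswing_amp: float = 250.0  # deg/s
    minima_amp: float = 120.0  # deg/s, depth of the TO/HS notches
    swing_level: float = 60.0  # deg/s, plateau between notches and the bump
    ap_spike_amp: float = 5.0  # m/s^2
    si_spike_amp: float = 4.0  # m/s^2
    noise_sd_gyr: float = 2.0  # deg/s
    noise_sd_acc: float = 0.1  # m/s^2
    heel_artifact: bool = False
    heel_drift_amp: float = 8.0  # m/s^2, AP drift amplitude before TO
    polarity: int = 1
    seed: int = 0
    lead_in: float = 0.4  # s of quiet signal before the first HS
    tail: float = 0.4  # s after the terminal HS

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise GaitError("n_strides must be at least 1")
        if not 0.0 < self.stance_frac < 1.0:
            raise GaitError("stance_frac must lie in (0, 1)")
        if self.fs <= 0:
            raise GaitError("fs must be positive")
        if self.polarity not in (1, -1):
            raise GaitError("polarity must be +1 or -1")


@dataclass(frozen=True)
class SyntheticTrial:
    """Generated recording, its ground-truth events, and the settings used."""

    recording: InertialRecording
    truth: EventSeries
    params: GaitSimParams
    true_misalignment: np.ndarray | None = None


def simulate_trial(
    params: GaitSimParams, misalignment: np.ndarray | None = None
) -> SyntheticTrial:
    """Generate one trial; optionally rotate it into a misaligned sensor frame.

    ``misalignment`` is a 3x3 rotation mapping anatomical (SI, ML, AP)
    vectors to sensor coordinates; when given, the recording is emitted in
    the sensor frame and the rotation stored for calibration tests.
    """
    rng = np.random.default_rng(params.seed)
    periods = np.full(params.n_strides, params.stride_period_mean)
    if params.stride_period_sd > 0:
        periods = periods + rng.normal(0.0, params.stride_period_sd, params.n_strides)

    hs = params.lead_in + np.concatenate(([0.0], np.cumsum(periods)))  # n+1 HS
    to = hs[:-1] + params.stance_frac * periods
    stance = to - hs[:-1]
    swing = hs[1:] - to
    if np.any(stance < _MIN_STANCE) or np.any(swing < _MIN_SWING):
        raise GaitError(
            "inconsistent parameters: planted waveform features would overlap "
            f"(min stance {stance.min():.3f} s, min swing {swing.min():.3f} s)"
        )
    midswing = 0.5 * (to + hs[1:])

    t_end = hs[-1] + params.tail
    n = int(round(t_end * params.fs)) + 1
    time = np.arange(n) / params.fs

    ml = _ml_waveform(time, hs, to, midswing, params)
    ap = _spike_train(time, to, -params.ap_spike_amp, _ACC_SPIKE_HALFWIDTH)
    ap += _spike_train(time, hs, +params.ap_spike_amp, _ACC_SPIKE_HALFWIDTH)
    si = _spike_train(time, hs, -params.si_spike_amp, _SI_SPIKE_HALFWIDTH)
    if params.heel_artifact:
        ap += _heel_artifact(time, to, params.heel_drift_amp)

    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    acc[:, ANATOMICAL_CHANNELS.index("SI")] = si
    acc[:, ANATOMICAL_CHANNELS.index("AP")] = ap
    gyr[:, ANATOMICAL_CHANNELS.index("ML")] = params.polarity * ml

    if params.noise_sd_gyr > 0:
        gyr = gyr + rng.normal(0.0, params.noise_sd_gyr, (n, 3))
    if params.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, params.noise_sd_acc, (n, 3))

    truth = EventSeries.from_events(
        [GaitEvent(t, EventKind.HS) for t in hs[:-1]]
        + [GaitEvent(t, EventKind.TO) for t in to],
        source="truth",
    )

    if misalignment is not None:
        R = np.asarray(misalignment, dtype=float)
        _check_rotation(R)
        rec = InertialRecording(
            time=time,
            acc=acc @ R.T,
            gyr=gyr @ R.T,
            fs=params.fs,
            frame=Frame.SENSOR,
        )
        return SyntheticTrial(rec, truth, params, true_misalignment=R)

    rec = InertialRecording(
        time=time,
        acc=acc,
        gyr=gyr,
        fs=params.fs,
        frame=Frame.ANATOMICAL,
        channel_names=ANATOMICAL_CHANNELS,
    )
    return SyntheticTrial(rec, truth, params)


def _ml_waveform(
    time: np.ndarray,
    hs: np.ndarray,
    to: np.ndarray,
    midswing: np.ndarray,
    p: GaitSimParams,
) -> np.ndarray:
    b0, S, A = _BASELINE_ML, p.swing_level, p.minima_amp
    pts: list[tuple[float, float]] = [(0.0, b0)]
    # first HS: a notch rising back to the stance baseline
    pts += [(hs[0] - _NOTCH_SETTLE, b0), (hs[0], -A), (hs[0] + _NOTCH_SETTLE, b0)]
    for i in range(len(to)):
        pts += [
            (to[i] - _NOTCH_LEAD, b0),
            (to[i], -_TO_NOTCH_FRAC * A),
            (to[i] + _NOTCH_RISE, S),
        ]
        h = hs[i + 1]
        pts += [(h - _NOTCH_RISE, S), (h, -A), (h + _NOTCH_SETTLE, b0)]
    xp = np.array([x for x, _ in pts])
    fp = np.array([y for _, y in pts])
    if np.any(np.diff(xp) <= 0):
        raise GaitError("inconsistent parameters: waveform keypoints overlap")
    ml = np.interp(time, xp, fp)
    for m in midswing:
        ml = ml + (p.midswing_amp - S) * np.exp(-0.5 * ((time - m) / _BUMP_SIGMA) ** 2)
    return ml


def _spike_train(
    time: np.ndarray, centers: np.ndarray, amp: float, halfwidth: float
) -> np.ndarray:
    """Sum of triangular spikes with vertices exactly at ``centers``."""
    out = np.zeros_like(time)
    for c in centers:
        out += amp * np.clip(1.0 - np.abs(time - c) / halfwidth, 0.0, None)
    return out


def _heel_artifact(time: np.ndarray, to: np.ndarray, amp: float) -> np.ndarray:
    """Positive AP drift with superimposed oscillation before each TO."""
    out = np.zeros_like(time)
    for c in to:
        mask = (time >= c - _ARTIFACT_SPAN) & (time <= c)
        u = (time[mask] - (c - _ARTIFACT_SPAN)) / _ARTIFACT_SPAN
        out[mask] += amp * (u + 0.15 * np.sin(6.0 * np.pi * u))
    return out


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3) or np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8:
        raise GaitError("misalignment must be a 3x3 rotation matrix")
    if np.linalg.det(R) < 0:
        raise GaitError("misalignment must be a proper rotation (det = +1)")


GRAVITY = 9.81  # m/s^2


def simulate_calibration(
    true_R: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fs: float = 60.0,
    duration: float = 2.0,
    tilt_deg: float = 40.0,
) -> tuple[InertialRecording, InertialRecording, np.ndarray]:
    """Standing and seated still recordings under a known misalignment.

    Standing gravity reaction lies along anatomical SI; the seated pose
    tilts it by ``tilt_deg`` toward AP within the sagittal plane.  Both are
    mapped into the sensor frame by ``true_R`` and emitted as still 2 s
    recordings with optional accelerometer noise.
    """
    R = np.asarray(true_R, dtype=float)
    _check_rotation(R)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    time = np.arange(n) / fs
    g_stand = GRAVITY * np.array([1.0, 0.0, 0.0])  # (SI, ML, AP)
    tilt = np.radians(tilt_deg)
    g_sit = GRAVITY * np.array([np.cos(tilt), 0.0, np.sin(tilt)])
    recs = []
    for g in (g_stand, g_sit):
        acc = np.tile(R @ g, (n, 1))
        if noise_sd > 0:
            acc = acc + rng.normal(0.0, noise_sd, (n, 3))
        recs.append(
            InertialRecording(
                time=time,
                acc=acc,
                gyr=np.zeros((n, 3)),
                fs=fs,
                frame=Frame.SENSOR,
                location_label="calibration",
            )
        )
    return recs[0], recs[1], R


# ---------------------------------------------------------------------------
# benchmark battery: 5 location profiles x 2 tasks x n trials
# ---------------------------------------------------------------------------

#: per-location amplitude/artifact profiles; the heel profile carries the
#: pre-TO AP drift artifact
LOCATION_PROFILES: dict[str, dict] = {
    "DFoot": {"midswing_amp": 250.0},
    "Heel": {"midswing_amp": 240.0, "heel_artifact": True},
    "LLS": {"midswing_amp": 300.0},
    "MLS": {"midswing_amp": 320.0},
    "Shin": {"midswing_amp": 200.0},
}

#: stride-period jitter per walking task (obstacle navigation is less regular)
TASK_JITTER_SD: dict[str, float] = {"straight": 0.02, "obstacle": 0.05}


@dataclass(frozen=True)
class BatteryConfig:
    seed: int = 0
    n_trials: int = 3
    n_strides: int = 12
    tasks: tuple[str, ...] = ("straight", "obstacle")
    locations: tuple[str, ...] = tuple(LOCATION_PROFILES)
    base: GaitSimParams = field(default_factory=GaitSimParams)


@dataclass(frozen=True)
class LabeledTrial:
    trial: SyntheticTrial
    task: str
    location: str
    index: int


def make_benchmark_battery(config: BatteryConfig | None = None) -> list[LabeledTrial]:
    """Deterministic labeled trial set over the location x task factorial."""
    config = config or BatteryConfig()
    out: list[LabeledTrial] = []
    counter = 0
    for task in config.tasks:
        for location in config.locations:
            profile = LOCATION_PROFILES.get(location, {})
            for idx in range(config.n_trials):
                seed = (config.seed * 1_000_003 + counter) % 2**31
                counter += 1
                params = replace(
                    config.base,
                    n_strides=config.n_strides,
                    stride_period_sd=TASK_JITTER_SD.get(
                        task, config.base.stride_period_sd
                    ),
                    seed=seed,
                    **profile,
                )
                trial = simulate_trial(params)
                trial = SyntheticTrial(
                    recording=replace(trial.recording, location_label=location),
                    truth=trial.truth,
                    params=trial.params,
                )
                out.append(LabeledTrial(trial, task=task, location=location, index=idx))
    return out


def export_battery(trials: list[LabeledTrial], outdir: str | Path) -> Path:
    """Write battery trials and truth events as CSV plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for lt in trials:
        stem = f"{lt.task}_{lt.location}_{lt.index:02d}"
        imu_path = outdir / f"{stem}_imu.csv"
        ref_path = outdir / f"{stem}_ref_events.csv"
        write_imu_csv(lt.trial.recording, imu_path)
        write_event_csv(lt.trial.truth, ref_path)
        entries.append(
            {
                "trial_id": f"{lt.task}_{lt.index:02d}",
                "task": lt.task,
                "location": lt.location,
                "imu_csv": imu_path.name,
                "ref_events_csv": ref_path.name,
                "frame": lt.trial.recording.frame.value,
                "seed": lt.trial.params.seed,
            }
        )
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"fs": trials[0].trial.recording.fs if trials else 60.0,
                                    "trials": entries}, indent=2))
    return manifest
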