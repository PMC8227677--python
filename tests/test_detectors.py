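import numpy as np
import pytest
from dataclasses import replace

from imugait.detectors import (
    DETECTOR_NAMES,
    DetectorParams,
    _piecewise_linear_through,
    _trusted_swing,
    detect,
    detect_apacc_mlvel,
    detect_rv_minima,
    detect_rv_zero_crossing,
    detect_siacc_apacc,
    estimate_sagittal_angle,
    find_midswing_peaks,
    orient_midswing_positive,
)
from imugait.signal_model import (
    ANATOMICAL_CHANNELS,
    DataError,
    EventKind,
    Frame,
    GaitWarning,
    InertialRecording,
)
from imugait.synthetic_data import GaitSimParams, simulate_trial

from conftest import event_errors

FRAME_S = 1.0 / 60.0


def _anatomical(ml, ap=None, si=None, fs=60.0):
    n = len(ml)
    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    gyr[:, 1] = ml
    if ap is not None:
        acc[:, 2] = ap
    if si is not None:
        acc[:, 0] = si
    return InertialRecording(
        time=np.arange(n) / fs,
        acc=acc,
        gyr=gyr,
        fs=fs,
        frame=Frame.ANATOMICAL,
        channel_names=ANATOMICAL_CHANNELS,
    )


class TestOrientation:
    def test_positive_trial_unchanged(self, clean_trial):
        rec = orient_midswing_positive(clean_trial.recording)
        assert rec.meta["ml_flipped"] is False
        np.testing.assert_array_equal(
            rec.channel("gyr", "ML"), clean_trial.recording.channel("gyr", "ML")
        )

    def test_negated_trial_flipped(self, clean_trial):
        neg = simulate_trial(
            replace(clean_trial.params, polarity=-1)
        ).recording
        rec = orient_midswing_positive(neg)
        assert rec.meta["ml_flipped"] is True
        np.testing.assert_allclose(
            rec.channel("gyr", "ML"), clean_trial.recording.channel("gyr", "ML")
        )

    def test_near_zero_signal_is_no_gait(self):
        with pytest.raises(DataError, match="no gait"):
            orient_midswing_positive(_anatomical(np.full(100, 2.0)))

    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_sign_symmetry_of_every_detector(self, name, clean_trial):
        neg = simulate_trial(replace(clean_trial.params, polarity=-1))
        a = detect(name, clean_trial.recording).times()
        b = detect(name, neg.recording).times()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestMidswingPeaks:
    def test_single_bump(self):
        t = np.arange(180) / 60.0
        ml = 200.0 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        peaks = find_midswing_peaks(_anatomical(ml))
        assert len(peaks) == 1
        assert abs(peaks[0] - 1.0) <= FRAME_S

    def test_flat_signal_gives_no_peaks(self):
        assert len(find_midswing_peaks(_anatomical(np.zeros(100)))) == 0

    def test_generator_midswing_times_recovered(self, clean_trial):
        peaks = find_midswing_peaks(clean_trial.recording)
        assert len(peaks) == 20
        hs = clean_trial.truth.times("HS")
        to = clean_trial.truth.times("TO")
        expected = 0.5 * (to[:-1] + hs[1:])  # mid-swing between TO_i and HS_{i+1}
        np.testing.assert_allclose(peaks[:-1], expected, atol=FRAME_S)


class TestZeroCrossingDetector:
    def test_sine_closed_form(self):
        t = np.arange(61) / 60.0
        ml = 100.0 * np.sin(2 * np.pi * t)
        ev = detect_rv_zero_crossing(_anatomical(ml))
        assert abs(ev.times("TO")[0] - 0.0) < 1e-9
        assert abs(ev.times("HS")[0] - 0.5) < 1e-6

    def test_all_positive_signal_has_no_crossings(self):
        t = np.arange(180) / 60.0
        ml = 200.0 * np.exp(-0.5 * ((t - 1.5) / 0.05) ** 2) + 5.0
        with pytest.warns(GaitWarning):
            ev = detect_rv_zero_crossing(_anatomical(ml))
        assert len(ev) == 0


class TestMinimaDetector:
    def test_monotone_flanks_give_no_events(self):
        t = np.arange(180) / 60.0
        ml = 200.0 * np.exp(-0.5 * ((t - 1.5) / 0.3) ** 2)
        with pytest.warns(GaitWarning):
            ev = detect_rv_minima(_anatomical(ml))
        assert len(ev) == 0


class TestSagittalAngle:
    def test_zero_gyro_zero_angle(self):
        trace = estimate_sagittal_angle(_anatomical(np.zeros(200)), mode="foot")
        np.testing.assert_allclose(trace.angle, 0.0, atol=1e-12)

    def test_constant_bias_cancelled_by_end_anchors(self):
        # closed form: a constant-rate drift is a line through the anchor
        # points, so piecewise-linear correction removes it exactly
        t = np.arange(300) / 60.0
        raw = np.cumsum(np.full(300, 5.0)) / 60.0
        corrected = raw - _piecewise_linear_through(t, raw, np.array([0, 299]))
        assert np.max(np.abs(corrected)) < 1e-6

    def test_zupt_end_windows_cancel_bias_end_to_end(self):
        # ML gyro holds a constant 5 deg/s bias; another axis moves except in
        # the first and last 0.3 s, so ZUPT anchors sit at both ends
        n = 300
        ml = np.full(n, 5.0)
        rec = _anatomical(ml)
        gyr = rec.gyr.copy()
        gyr[:, 0] = 100.0
        gyr[:18, 0] = 0.0
        gyr[-18:, 0] = 0.0
        rec = replace(rec, gyr=gyr)
        trace = estimate_sagittal_angle(rec, mode="foot")
        assert len(trace.anchors) == 2
        np.testing.assert_allclose(
            trace.angle[np.searchsorted(trace.time, trace.anchors)], 0.0, atol=1e-9
        )
        assert np.max(np.abs(trace.angle)) < 1e-6

    def test_noise_robust_angle_correlates_with_clean(self, clean_trial):
        noisy = simulate_trial(
            replace(clean_trial.params, noise_sd_gyr=10.0, noise_sd_acc=0.3)
        )
        a = estimate_sagittal_angle(clean_trial.recording, mode="shank").angle
        b = estimate_sagittal_angle(noisy.recording, mode="shank").angle
        assert np.corrcoef(a, b)[0, 1] > 0.95

    def test_foot_and_shank_modes_agree_on_clean_foot_trial(self, clean_trial):
        ev_foot = detect_siacc_apacc(clean_trial.recording, mode="foot")
        ev_shank = detect_siacc_apacc(clean_trial.recording, mode="shank")
        np.testing.assert_allclose(ev_foot.times(), ev_shank.times(), atol=1e-12)


class TestTrustedSwing:
    def test_twenty_percent_of_local_peak(self):
        sig = np.array([0.0, 60.0, 100.0, 250.0, 100.0, 60.0, 0.0])
        assert _trusted_swing(sig, 3, 0.20) == (1, 5)  # threshold 50 deg/s

    def test_threshold_is_per_stride(self):
        # two strides with different peak heights: each threshold tracks its
        # own peak, so the smaller stride keeps a non-empty trusted swing
        t = np.arange(240) / 60.0
        ml = 300.0 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        ml += 150.0 * np.exp(-0.5 * ((t - 3.0) / 0.05) ** 2)
        ml -= 80.0 * np.exp(-0.5 * ((t - 0.5) / 0.02) ** 2)
        ml -= 80.0 * np.exp(-0.5 * ((t - 1.5) / 0.02) ** 2)
        ml -= 80.0 * np.exp(-0.5 * ((t - 2.5) / 0.02) ** 2)
        ml -= 80.0 * np.exp(-0.5 * ((t - 3.5) / 0.02) ** 2)
        rec = _anatomical(ml)
        from imugait.detectors import _Segmented

        seg = _Segmented(rec, DetectorParams(min_stride_period=1.0))
        spans = [
            _trusted_swing(seg.ml, p, 0.20) for p in seg.ip
        ]
        assert len(spans) == 2
        for (s, e), p in zip(spans, seg.ip):
            assert s < p < e


class TestApaccMlvelWindow:
    def _craft(self, ap_spike_frame):
        n = 200
        i = np.arange(n)
        ml = 200.0 * np.exp(-0.5 * ((i - 70) / 5.0) ** 2)
        ml -= 50.0 * np.exp(-0.5 * ((i - 100) / 1.5) ** 2)
        ap = np.zeros(n)
        ap[ap_spike_frame] = 1.0
        return _anatomical(ml, ap=ap)

    @pytest.mark.parametrize("frame", [97, 100, 102])
    def test_window_frames_included(self, frame):
        # reference ML minimum at frame 100; 50 ms -> 3 frames back,
        # 20 ms -> 2 frames forward (outward rounding): frames 97..102
        ev = detect_apacc_mlvel(self._craft(frame))
        assert int(round(ev.times("HS")[0] * 60)) == frame

    def test_spike_outside_window_clips_to_edge(self):
        with pytest.warns(GaitWarning, match="edge"):
            ev = detect_apacc_mlvel(self._craft(105))
        assert int(round(ev.times("HS")[0] * 60)) == 97  # argmax ties -> window start


class TestDetectorProperties:
    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_noise_free_recovery_within_one_frame(self, name, clean_trial):
        ev = detect(name, clean_trial.recording)
        for kind in (EventKind.HS, EventKind.TO):
            n, errs = event_errors(ev, clean_trial.truth, kind)
            assert n >= 19
            assert np.median(errs) <= FRAME_S + 1e-9

    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_events_alternate_to_then_hs(self, name, clean_trial):
        ev = detect(name, clean_trial.recording)
        kinds = [e.kind for e in ev]
        assert kinds == [EventKind.TO, EventKind.HS] * (len(kinds) // 2)
        assert np.all(np.diff(ev.times()) > 0)

    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_time_shift_equivariance(self, name, clean_trial):
        delta = 5.0
        shifted = clean_trial.recording.shifted(delta)
        a = detect(name, clean_trial.recording).times()
        b = detect(name, shifted).times()
        np.testing.assert_allclose(b - a, delta, atol=1e-9)
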