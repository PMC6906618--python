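import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from gaitmon.detect import (
    AnalysisWindow,
    PlausibilityConfig,
    RejectionReason,
    analyze_recording,
    bandpass,
    classify_window,
    dominant_frequency,
    window_indices,
)
from gaitmon.io import AccelRecording
from gaitmon.simulate import (
    SimulationConfig,
    simulate_nonwalk_activity,
    simulate_still,
    simulate_walk,
)

T0 = pd.Timestamp("2018-03-01 09:00:00", tz="UTC")
RATE = 100.0


def _filtfilt_gain(freq_hz, low=0.7, high=3.0, rate=RATE, order=4):
    """Independent oracle: squared Butterworth magnitude response (the
    forward-backward pass applies the filter twice)."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=rate)
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(np.ones(3000), 0.7, 3.0, RATE)
        assert np.max(np.abs(out)) < 1e-6

    @pytest.mark.parametrize("freq", [1.5, 0.1, 2.8])
    def test_tone_amplitude_matches_response_oracle(self, freq):
        t = np.arange(6000) / RATE
        out = bandpass(np.sin(2 * np.pi * freq * t), 0.7, 3.0, RATE)
        interior = out[1500:4500]
        measured = np.max(np.abs(interior))
        assert measured == pytest.approx(_filtfilt_gain(freq), rel=0.05, abs=0.01)

    def test_in_band_tone_passes_near_unity(self):
        t = np.arange(6000) / RATE
        out = bandpass(np.sin(2 * np.pi * 1.5 * t), 0.7, 3.0, RATE)
        assert np.max(np.abs(out[1500:4500])) == pytest.approx(1.0, rel=0.05)

    def test_low_tone_strongly_attenuated(self):
        t = np.arange(12000) / RATE
        out = bandpass(np.sin(2 * np.pi * 0.1 * t), 0.7, 3.0, RATE)
        assert np.max(np.abs(out[3000:9000])) < 0.1

    def test_short_signal_advises_minimum_length(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.ones(10), 0.7, 3.0, RATE)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(1000), 3.0, 0.7, RATE)


class TestWindows:
    def test_ten_seconds_fifty_percent_overlap(self):
        idx = window_indices(1000, RATE, 2.5, 0.5)
        assert len(idx) == 7
        assert [s for s, _ in idx] == [0, 125, 250, 375, 500, 625, 750]
        assert all(e - s == 250 for s, e in idx)

    def test_recording_shorter_than_one_window(self):
        assert window_indices(200, RATE, 2.5, 0.5) == []

    def test_zero_overlap(self):
        assert len(window_indices(1000, RATE, 2.5, 0.0)) == 4

    def test_overlap_out_of_range(self):
        with pytest.raises(ValueError, match="overlap"):
            window_indices(1000, RATE, 2.5, 0.95)


class TestDominantFrequency:
    def test_pure_tone_recovered_within_bin_width(self):
        t = np.arange(250) / RATE
        win = np.column_stack([np.sin(2 * np.pi * 2.0 * t)] * 3)
        freq, mag = dominant_frequency(win, RATE)
        bin_width = RATE / (4 * 250)
        assert freq[0] == pytest.approx(2.0, abs=2 * bin_width)
        assert mag[0] > 0

    def test_larger_peak_wins(self):
        t = np.arange(250) / RATE
        x = 0.2 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 2.0 * t)
        freq, _ = dominant_frequency(np.column_stack([x, x, x]), RATE)
        assert freq[0] == pytest.approx(2.0, abs=0.15)

    def test_white_noise_mostly_absent(self):
        rng = np.random.default_rng(42)
        n_absent = 0
        for _ in range(200):
            win = rng.standard_normal((250, 3))
            freq, _ = dominant_frequency(win, RATE)
            n_absent += int(np.isnan(freq[0]))
        assert n_absent >= 180  # >= 90% of windows


class TestClassify:
    def _window(self, mean, activity, fx=2.0):
        return AnalysisWindow(
            start_index=0,
            end_index=250,
            dom_freq_hz=np.array([fx, np.nan, np.nan]),
            dom_mag=np.array([1.0, 0.0, 0.0]),
            mean_accel_g=np.asarray(mean, dtype=float),
            activity_g=activity,
        )

    def test_static_lying_rejected_for_gravity(self):
        w = classify_window(self._window([0, 0, 1.0], 0.0), PlausibilityConfig())
        assert not w.is_walking
        assert w.rejection_reason == RejectionReason.GRAVITY_ANGLE

    def test_upright_motionless_rejected_for_activity(self):
        w = classify_window(self._window([1.0, 0, 0], 0.005), PlausibilityConfig())
        assert not w.is_walking
        assert w.rejection_reason == RejectionReason.ACTIVITY

    def test_no_dominant_frequency_rejected_last(self):
        w = classify_window(
            self._window([1.0, 0, 0], 0.2, fx=np.nan), PlausibilityConfig()
        )
        assert w.rejection_reason == RejectionReason.NO_DOMINANT_FREQUENCY

    def test_simulated_walk_detected(self):
        cfg = SimulationConfig(seed=11)
        samples, seg = simulate_walk(0.8, 30.0, cfg, np.random.default_rng(11))
        assert seg.cadence_hz == pytest.approx(1.76)
        rec = AccelRecording("S", "D", T0, RATE, samples)
        windows, _ = analyze_recording(rec)
        frac = np.mean([w.is_walking for w in windows])
        assert frac >= 0.9

    def test_loosening_thresholds_is_monotone(self):
        rng = np.random.default_rng(7)
        tight = PlausibilityConfig(angle_max_deg=30, act_min_g=0.05, act_max_g=1.0)
        loose = PlausibilityConfig(angle_max_deg=60, act_min_g=0.01, act_max_g=3.0)
        for _ in range(300):
            vec = rng.normal(size=3)
            w = self._window(
                vec,
                float(rng.uniform(0, 2.5)),
                fx=2.0 if rng.random() < 0.8 else np.nan,
            )
            walking_tight = classify_window(w, tight).is_walking
            walking_loose = classify_window(w, loose).is_walking
            assert not (walking_tight and not walking_loose)


class TestLabeledSegments:
    def test_sensitivity_and_false_positive_rate(self):
        """Window-level detection on a labeled walking/activity/still tape."""
        cfg = SimulationConfig(seed=21)
        rng = np.random.default_rng(21)
        pieces, labels = [], []
        for kind, dur in [
            ("still", 120), ("walking", 120), ("activity", 120),
            ("walking", 90), ("still", 90), ("activity", 90), ("walking", 150),
        ]:
            if kind == "walking":
                s, _ = simulate_walk(float(rng.uniform(0.4, 1.1)), dur, cfg, rng)
            elif kind == "activity":
                s, _ = simulate_nonwalk_activity(dur, cfg, rng)
            else:
                s, _ = simulate_still(dur, cfg, rng)
            pieces.append(s)
            labels.extend([kind] * s.shape[0])
        rec = AccelRecording("S", "D", T0, RATE, np.vstack(pieces))
        labels = np.array(labels)
        windows, _ = analyze_recording(rec)

        walk_windows = [
            w for w in windows
            if (labels[w.start_index : w.end_index] == "walking").all()
        ]
        nonwalk_windows = [
            w for w in windows
            if not (labels[w.start_index : w.end_index] == "walking").any()
        ]
        sens = np.mean([w.is_walking for w in walk_windows])
        fpr = np.mean([w.is_walking for w in nonwalk_windows])
        assert sens >= 0.9
        assert fpr <= 0.1
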