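"""Spindle detector thresholds, boundaries, metrics and the ISAs statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from somnotype.hypnogram_metrics import EpochSelection
from somnotype.spindles import (DetectionParams, SpindleEvent, detect_events_1d,
                                detect_spindles, filter_by_frequency,
                                sigma_envelope, spindle_metrics)

from conftest import make_recording

FS = 128.0


def oracle_scan(env, lower, upper, fs, min_dur=0.25):
    """Independent sample-by-sample scan of the fluctuation-threshold rules.

    Local maxima of the rectified envelope are the amplitude fluctuations;
    events run between the nearest sub-lower fluctuations around any
    supra-upper one.  Written as plain loops, independent of the package's
    vectorised implementation.
    """
    peaks = [i for i in range(1, len(env) - 1)
             if env[i] > env[i - 1] and env[i] >= env[i + 1]]
    spans = []
    for k, p in enumerate(peaks):
        if env[p] > upper:
            pre = [q for q in peaks[:k] if env[q] < lower]
            post = [q for q in peaks[k + 1:] if env[q] < lower]
            if pre and post:
                spans.append((pre[-1], post[0] + 1))
    spans.sort()
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_dur * fs]


def full_selection(rec):
    return EpochSelection(np.ones((rec.n_channels, rec.n_epochs), bool))


def burst_recording(peak_factor=8.5, freq=13.0, dur=1.0, base=1.0,
                    minutes=5.0, seed=0):
    """Carrier background plus one Hann-enveloped burst of known strength.

    The background is a small-amplitude 13 Hz carrier so the channel mean
    rectified amplitude is the analytic 2a/π; the burst peak is set to
    ``peak_factor`` times that mean.
    """
    t = np.arange(int(FS * minutes * 60)) / FS
    x = base * np.sin(2 * np.pi * freq * t)
    mean_amp = 2 * base / np.pi
    t0 = minutes * 30.0
    rel = (t - t0) / dur
    env = np.where((rel >= 0) & (rel <= 1),
                   0.5 * (1 - np.cos(2 * np.pi * rel)), 0.0)
    x = x * (1.0 + (peak_factor * mean_amp / base - 1.0) * env)
    return make_recording(x[None, :]), t0, dur


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        rec = make_recording(np.zeros((1, int(FS * 60))))
        assert sigma_envelope(rec).max() == 0

    def test_rectified_sine_mean_is_2a_over_pi(self):
        a = 5.0
        t = np.arange(int(FS * 120)) / FS
        rec = make_recording((a * np.sin(2 * np.pi * 13 * t))[None, :])
        env = sigma_envelope(rec)
        assert env[0].mean() == pytest.approx(2 * a / np.pi, rel=0.01)

    def test_stopband_attenuation(self):
        t = np.arange(int(FS * 60)) / FS
        rec = make_recording(np.sin(2 * np.pi * 3 * t)[None, :])
        env = sigma_envelope(rec)
        rms_out = np.sqrt((env[0] ** 2).mean())
        assert rms_out < 0.05 * np.sqrt(0.5)

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            sigma_envelope(rec, band=(11.0, 70.0))


class TestDetection:
    def test_constant_sinusoid_yields_no_events(self):
        # max/mean of |sin| is π/2, far below the 8x upper threshold
        t = np.arange(int(FS * 300)) / FS
        rec = make_recording(np.sin(2 * np.pi * 13 * t)[None, :])
        events = detect_spindles(rec, full_selection(rec))
        assert events == []

    def test_single_burst_detected_with_correct_shape(self):
        rec, t0, dur = burst_recording(peak_factor=8.5)
        events = detect_spindles(rec, full_selection(rec))
        assert len(events) == 1
        ev = events[0]
        assert ev.start < t0 + dur and ev.end > t0
        assert abs(ev.duration - dur) <= 0.15
        assert ev.mean_frequency == pytest.approx(13.0, abs=0.5)

    def test_burst_below_upper_threshold_ignored(self):
        rec, _, _ = burst_recording(peak_factor=5.0)
        assert detect_spindles(rec, full_selection(rec)) == []

    def test_matches_brute_force_oracle_on_random_envelopes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            env = np.abs(rng.normal(0, 1, 4000))
            # sprinkle a few large fluctuations
            for i in rng.integers(100, 3900, size=3):
                env[i:i + 40] += rng.uniform(5, 12) * np.abs(
                    np.sin(np.linspace(0, np.pi, 40)))
            lower, upper = 2 * env.mean(), 8 * env.mean()
            ours = detect_events_1d(env, lower, upper, FS)
            oracle = oracle_scan(env, lower, upper, FS)
            assert ours == oracle

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 2 ** 31 - 1),
           n_bursts=hst.integers(0, 5),
           lower_f=hst.floats(1.5, 3.0),
           upper_f=hst.floats(5.0, 10.0))
    def test_oracle_equivalence_property(self, seed, n_bursts, lower_f, upper_f):
        rng = np.random.default_rng(seed)
        env = np.abs(rng.normal(0, 1, 2000))
        for i in rng.integers(50, 1900, size=n_bursts):
            env[i:i + 30] += rng.uniform(3, 15) * np.abs(
                np.sin(np.linspace(0, np.pi, 30)))
        lower, upper = lower_f * env.mean(), upper_f * env.mean()
        assert detect_events_1d(env, lower, upper, FS) == \
            oracle_scan(env, lower, upper, FS)

    def test_scale_equivariance(self):
        rec, _, _ = burst_recording(peak_factor=9.0)
        sel = full_selection(rec)
        ev1 = detect_spindles(rec, sel)
        rec.data *= 3.0
        ev2 = detect_spindles(rec, sel)
        assert len(ev1) == len(ev2) == 1
        assert ev2[0].start == ev1[0].start and ev2[0].end == ev1[0].end
        assert ev2[0].mean_amplitude == pytest.approx(3 * ev1[0].mean_amplitude)

    def test_empty_selection_raises(self):
        rec = make_recording(np.zeros((1, int(FS * 60))))
        with pytest.raises(ValueError):
            detect_spindles(rec, EpochSelection(np.zeros((1, 2), bool)))


def ev(channel="E1", start=0.0, end=1.0, mean_amp=5.0, freq=13.0):
    return SpindleEvent(channel=channel, start=start, end=end,
                        peak_amplitude=mean_amp * 1.5, mean_amplitude=mean_amp,
                        mean_frequency=freq)


class TestMetrics:
    @staticmethod
    def _selection(minutes, n_channels=1):
        return EpochSelection(np.ones((n_channels, int(minutes * 2)), bool))

    def test_no_events(self):
        m = spindle_metrics([], self._selection(10), ["E1"])
        assert m.density[0] == 0
        assert m.isas[0] == 0
        assert np.isnan(m.mean_duration[0])

    def test_density_arithmetic(self):
        events = [ev(start=i, end=i + 1.0) for i in range(0, 40, 2)]
        m = spindle_metrics(events, self._selection(10), ["E1"])
        assert m.density[0] == pytest.approx(2.0)

    def test_isas_closed_form(self):
        # one event with constant rectified amplitude 10 µV in 10 min:
        # integral/duration = 10, divided by 10 min -> 1 µV/min exactly
        m = spindle_metrics([ev(mean_amp=10.0, end=0.7)],
                            self._selection(10), ["E1"])
        assert m.isas[0] == pytest.approx(1.0, abs=1e-12)

    def test_subband_partition_at_14hz(self):
        events = [ev(freq=f) for f in (12.0, 13.9, 14.0, 15.5, 16.0, 11.5)]
        whole = filter_by_frequency(events, (12.0, 16.0))
        slow = filter_by_frequency(events, (12.0, 14.0))
        fast = filter_by_frequency(events, (14.0, 16.0))
        assert len(whole) == 5          # 11.5 Hz falls outside
        assert len(slow) == 2           # 12.0, 13.9
        assert len(fast) == 3           # 14.0, 15.5, 16.0
        assert {id(e) for e in slow} | {id(e) for e in fast} == {id(e) for e in whole}

    def test_zero_retained_time_raises(self):
        with pytest.raises(ValueError):
            spindle_metrics([], EpochSelection(np.zeros((1, 4), bool)), ["E1"])
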