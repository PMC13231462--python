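"""Filtering and event detection: analytic filter gains, exact pulse
trains, the missed-beat interpolation rule, and generator-oracle counts."""

import numpy as np
import pytest

import dyadaffect as da
from dyadaffect.errors import InvalidArgumentError, QualityError
from dyadaffect.simulate import _ricker_template, _scr_kernel
from dyadaffect.preprocess import _interpolate_gaps


def make_pulse_train(beat_times, fs=600.0, duration=None):
    """Clean synthetic ECG: Ricker pulses at the given beat times."""
    duration = duration or (max(beat_times) + 1.0)
    x = np.zeros(int(duration * fs))
    tmpl = _ricker_template(fs)
    half = len(tmpl) // 2
    for t in beat_times:
        i = int(round(t * fs))
        lo, hi = i - half, i + half + 1
        x[max(lo, 0):hi] += tmpl[max(lo, 0) - lo:]
    return x


class TestLowpassFilter:
    fs = 600.0

    def test_dc_gain_unity(self):
        x = np.full(4000, 3.7)
        assert np.allclose(da.lowpass_filter(x, self.fs), 3.7, atol=1e-9)

    def test_stopband_attenuation_matches_analytic_response(self):
        # two filtfilt passes square the magnitude: |H(20 Hz)|^2 = 1/(1+(20/5)^8)
        t = np.arange(0, 20, 1 / self.fs)
        x = np.sin(2 * np.pi * 20.0 * t)
        y = da.lowpass_filter(x, self.fs)
        residual = np.abs(y[2000:-2000]).max()
        analytic = 1.0 / (1.0 + (20.0 / 5.0) ** 8)
        assert residual < 0.01
        assert residual == pytest.approx(analytic, rel=0.5)

    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 60, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = da.lowpass_filter(x, self.fs)
        assert np.abs(y[3000:-3000]).max() == pytest.approx(1.0, rel=0.01)

    def test_zero_phase(self):
        t = np.arange(0, 30, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.5 * t)
        y = da.lowpass_filter(x, self.fs)
        lags = np.arange(-50, 51)
        xc = [np.dot(x[500:-500], np.roll(y, k)[500:-500]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            da.lowpass_filter(np.zeros(100), fs=8.0, cutoff=5.0)


class TestRPeakDetection:
    def test_exact_metronome_train(self):
        beats = np.arange(1.0, 59.0, 1.0)
        ev = da.detect_r_peaks(make_pulse_train(beats), 600.0)
        assert np.allclose(np.diff(ev.times), 1.0, atol=0.005)

    def test_missed_beat_interpolated_at_midpoint(self):
        beats = [t for t in np.arange(1.0, 21.0, 1.0) if t != 11.0]
        ev = da.detect_r_peaks(make_pulse_train(beats), 600.0)
        interp_times = ev.times[ev.interpolated]
        assert len(interp_times) == 1
        assert interp_times[0] == pytest.approx(11.0, abs=0.01)

    def test_long_gap_gets_multiple_evenly_spaced_events(self):
        times = np.array([*np.arange(0, 10.0, 1.0), 13.0, 14.0, 15.0, 16.0])
        out, flags = _interpolate_gaps(times)
        ins = out[flags]
        assert len(ins) == 3  # 4 s gap at 1 s median -> 3 substitutes
        assert np.allclose(ins, [10.0, 11.0, 12.0])

    def test_interpolation_respects_refractory(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.uniform(0.7, 1.3, 100))
        times = np.delete(times, [20, 40, 41, 70])
        out, _ = _interpolate_gaps(times)
        assert np.diff(out).min() > 0.25

    def test_count_matches_generator_ground_truth(self, dyad_recording):
        seg = dyad_recording.segments[1]
        span = (seg.start_sample / dyad_recording.fs, seg.end_sample / dyad_recording.fs)
        ecg = dyad_recording.slice("p1", "ecg", seg)
        ev = da.detect_r_peaks(ecg, dyad_recording.fs)
        truth = dyad_recording.truth["p1"]["beat_times"]
        n_true = np.sum((truth >= span[0]) & (truth < span[1]))
        assert abs(len(ev) - n_true) <= 1

    def test_translation_equivariance(self):
        beats = np.arange(1.0, 30.0, 1.0)
        fs = 600.0
        x = make_pulse_train(beats, fs, duration=32.0)
        shift = 300  # 0.5 s
        ev0 = da.detect_r_peaks(x, fs)
        ev1 = da.detect_r_peaks(np.roll(x, shift), fs)
        assert np.allclose(ev1.times[:25], ev0.times[:25] + shift / fs, atol=0.002)

    def test_too_few_peaks_raises(self):
        with pytest.raises(QualityError):
            da.detect_r_peaks(np.zeros(12000), 600.0)


class TestBreathDetection:
    def test_sinusoid_peak_count(self):
        fs = 600.0
        t = np.arange(0, 240, 1 / fs)
        ev = da.detect_breath_peaks(np.sin(2 * np.pi * 0.25 * t), fs)
        assert abs(len(ev) - 60) <= 1

    def test_two_cycles_two_crests(self):
        fs = 600.0
        t = np.arange(0, 10, 1 / fs)  # two 5-s cycles at 0.2 Hz
        ev = da.detect_breath_peaks(np.sin(2 * np.pi * 0.2 * t), fs)
        assert len(ev) == 2
        assert np.allclose(ev.times, [1.25, 6.25], atol=0.01)

    def test_count_matches_generator(self, dyad_recording):
        seg = dyad_recording.segments[2]
        fs = dyad_recording.fs
        resp = da.lowpass_filter(dyad_recording.slice("p2", "resp", seg), fs)
        ev = da.detect_breath_peaks(resp, fs)
        span = (seg.start_sample / fs, seg.end_sample / fs)
        truth = dyad_recording.truth["p2"]["breath_times"]
        n_true = np.sum((truth >= span[0]) & (truth < span[1]))
        assert abs(len(ev) - n_true) <= 1


class TestScrDetection:
    fs = 600.0

    def _tonic(self, duration=60.0, level=2.0):
        return np.full(int(duration * self.fs), level)

    def _inject(self, x, t0, amp):
        k = _scr_kernel(self.fs)
        i = int(t0 * self.fs)
        seg = k[: len(x) - i]
        x[i : i + len(seg)] += amp * seg
        return x

    def test_constant_eda_no_scrs(self):
        ev = da.detect_scrs(self._tonic(), self.fs)
        assert len(ev) == 0

    def test_single_kernel_amplitude_recovered(self):
        x = self._inject(self._tonic(), 20.0, 0.3)
        ev = da.detect_scrs(x, self.fs)
        assert len(ev) == 1
        assert ev.amplitudes[0] == pytest.approx(0.3, abs=0.02)

    def test_subthreshold_kernel_ignored(self):
        x = self._inject(self._tonic(), 20.0, 0.01)
        assert len(da.detect_scrs(x, self.fs)) == 0

    def test_two_kernels_two_events(self):
        x = self._inject(self._inject(self._tonic(120.0), 20.0, 0.2), 80.0, 0.4)
        ev = da.detect_scrs(x, self.fs)
        assert len(ev) == 2
        assert np.allclose(sorted(ev.amplitudes), [0.2, 0.4], atol=0.02)


class TestInstantaneousRate:
    def _events(self, times):
        return da.EventSeries("r_peak", np.asarray(times, float),
                              np.zeros(len(times)), np.zeros(len(times), bool))

    def test_metronome_constant_60(self):
        ev = self._events(np.arange(0, 60.0, 1.0))
        rs = da.instantaneous_rate(ev, 0.0, 59.0)
        assert np.allclose(rs.values, 60.0)
        assert rs.fs == 4.0

    def test_alternating_intervals_bounded(self):
        times = np.cumsum([0] + [0.5, 1.0] * 30)
        rs = da.instantaneous_rate(self._events(times), 0.0, times[-1])
        assert rs.values.min() >= 60.0 - 1e-9
        assert rs.values.max() <= 120.0 + 1e-9

    def test_mean_rate_matches_interval_average(self, dyad_recording):
        seg = dyad_recording.segments[1]
        fs = dyad_recording.fs
        ev = da.detect_r_peaks(dyad_recording.slice("p1", "ecg", seg), fs)
        span_s = seg.n_samples / fs
        rs = da.instantaneous_rate(ev, 0.0, span_s)
        direct = 60.0 * (len(ev) - 1) / (ev.times[-1] - ev.times[0])
        assert rs.values.mean() == pytest.approx(direct, rel=0.02)

    def test_too_few_events_raises(self):
        with pytest.raises(QualityError):
            da.instantaneous_rate(self._events([1.0]), 0.0, 10.0)


class TestSplitSegments:
    def test_six_240s_views_roundtrip(self, dyad_recording):
        segs = da.split_segments(dyad_recording)
        assert [s.name for s in segs] == [
            "baseline1", "conversation1", "conversation2",
            "conversation3", "conversation4", "baseline2",
        ]
        total = sum(s.n_samples for s in segs)
        assert total <= dyad_recording.n_samples
        for s in segs:
            assert s.n_samples == int(240 * dyad_recording.fs)
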