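"""Raw-trace preprocessing: R peaks, RR correction, respiration, EDA,
windowing."""

import numpy as np
import pytest

from autonomics import preprocess as pp
from autonomics import synthetic as syn
from autonomics.exceptions import EmptyResultError, SignalQualityError, WindowError


class TestDetectRPeaks:
    def test_round_trip_on_clean_ecg(self):
        tr = syn.make_truth("s", "CONTROL", seed=7)
        rr, _ = syn.generate_rr_with_respiration(tr, "REST", seed=3)
        ecg, peaks = syn.synthesize_ecg(rr)
        det = pp.detect_r_peaks(ecg, syn.ECG_FS)
        inner = peaks[1:-1]  # boundary beats have a truncated template
        errs = [np.min(np.abs(det - p)) for p in inner]
        assert max(errs) <= 0.005
        assert abs(len(det) - len(peaks)) <= 2

    def test_sensitivity_under_noise(self):
        tr = syn.make_truth("s", "CONTROL", seed=8)
        rr, _ = syn.generate_rr_with_respiration(tr, "REST", seed=4)
        ecg, peaks = syn.synthesize_ecg(rr, noise_sd=0.10, seed=5)
        det = pp.detect_r_peaks(ecg, syn.ECG_FS)
        hits = sum(1 for p in peaks[1:-1] if np.min(np.abs(det - p)) < 0.05)
        assert hits / (len(peaks) - 2) >= 0.99

    def test_flat_trace_raises_empty_result(self):
        with pytest.raises(EmptyResultError):
            pp.detect_r_peaks(np.zeros(int(30 * 300)), 300)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            pp.detect_r_peaks(np.zeros(10000), 100)

    def test_refractory_period(self):
        tr = syn.make_truth("s", "CONTROL", seed=9)
        rr, _ = syn.generate_rr_with_respiration(tr, "REST", seed=6)
        det = pp.detect_r_peaks(syn.synthesize_ecg(rr)[0], syn.ECG_FS)
        assert np.min(np.diff(det)) >= 0.2


class TestCorrectRR:
    def _series(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        rr = 800 + 30 * rng.standard_normal(n)
        bt = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
        return pp.RRSeries(bt, rr)

    def test_clean_series_untouched(self):
        s = self._series()
        out = pp.correct_rr(s)
        assert out.n_corrected == 0
        assert np.array_equal(out.rr, s.rr)

    def test_missed_beat_interpolated(self):
        s = self._series(1)
        truth_mean = s.rr.mean()
        s.rr[150] *= 2  # a missed beat doubles one interval
        out = pp.correct_rr(s)
        assert out.flags[150] == 1
        assert out.rr.mean() == pytest.approx(truth_mean, rel=0.01)

    def test_heavily_corrupted_segment_rejected(self):
        s = self._series(2)
        idx = np.arange(0, s.rr.size, 3)  # ~33% corrupted
        s.rr[idx] *= 2
        with pytest.raises(SignalQualityError):
            pp.correct_rr(s)

    def test_idempotent(self):
        s = self._series(3)
        s.rr[50] *= 1.8
        once = pp.correct_rr(s)
        twice = pp.correct_rr(once)
        assert np.allclose(once.rr, twice.rr)
        assert twice.n_corrected == 0


class TestRespirationChain:
    fs = 2048.0

    def _sine(self, f, duration=240.0, dc=0.0):
        t = np.arange(0, duration, 1 / self.fs)
        return np.sin(2 * np.pi * f * t) + dc

    def test_passband_amplitude_preserved(self):
        filt = pp.preprocess_respiration(self._sine(0.25), self.fs)
        core = filt[int(30 * 64): int(210 * 64)]
        amp = (core.max() - core.min()) / 2
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuation(self):
        filt = pp.preprocess_respiration(self._sine(5.0), self.fs)
        core = np.abs(filt[int(30 * 64): int(210 * 64)])
        assert 20 * np.log10(max(core.max(), 1e-300)) <= -40

    def test_dc_removed(self):
        filt = pp.preprocess_respiration(self._sine(0.25, dc=3.0), self.fs)
        assert abs(np.mean(filt)) < 0.01

    def test_output_rate_and_duration(self):
        filt = pp.preprocess_respiration(self._sine(0.25, 120.0), self.fs)
        assert abs(filt.size / 64.0 - 120.0) < 1 / 64.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pp.preprocess_respiration(self._sine(0.25, 30.0), self.fs)


class TestDetectBreaths:
    def test_regular_breathing_count_and_intervals(self):
        filt = pp.preprocess_respiration(
            np.sin(2 * np.pi * 0.25 * np.arange(0, 240, 1 / 2048.0)), 2048.0)
        br = pp.detect_breaths(filt)
        assert br.peak_times.size == 60
        assert np.all(np.abs(br.bb - 4.0) <= 0.02)

    def test_min_distance_keeps_higher_peak(self):
        # two candidate peaks 1 s apart: the higher one survives
        fs = 64.0
        t = np.arange(0, 120, 1 / fs)
        x = np.zeros(t.size)
        for c, a in ((60.0, 1.0), (61.0, 0.6)):
            x += a * np.exp(-((t - c) ** 2) / (2 * 0.15**2))
        br = pp.detect_breaths(x, fs)
        assert br.peak_times.size == 1
        assert abs(br.peak_times[0] - 60.0) < 0.1

    def test_breath_times_match_generator_truth(self):
        trace, onsets = syn.synthesize_respiration(3.5, 0.4, 300.0, fs=2048.0, seed=2)
        filt = pp.preprocess_respiration(trace, 2048.0)
        br = pp.detect_breaths(filt)
        true_peaks = onsets[:-1] + 0.25 * np.diff(onsets)
        true_peaks = true_peaks[(true_peaks > 5) & (true_peaks < 295)]
        errs = [np.min(np.abs(br.peak_times - p)) for p in true_peaks]
        assert np.sqrt(np.mean(np.square(errs))) < 0.05

    def test_flat_trace_gives_empty_series(self):
        br = pp.detect_breaths(np.zeros(64 * 100))
        assert br.peak_times.size == 0 and br.bb.size == 0


class TestRespirogram:
    def test_constant_trace(self):
        rg = pp.build_respirogram(np.full(64 * 100, 2.5), np.array([1.0, 2.0, 3.0]))
        assert np.all(rg.values == 2.5)

    def test_beat_outside_span_rejected(self):
        with pytest.raises(ValueError):
            pp.build_respirogram(np.zeros(64 * 10), np.array([5.0, 11.0]))

    def test_sinusoid_sampled_at_beats(self):
        fs = 64.0
        t = np.arange(0, 100, 1 / fs)
        trace = np.sin(2 * np.pi * 0.2 * t)
        beats = np.array([10.3, 20.71, 33.33])
        rg = pp.build_respirogram(trace, beats, fs)
        expected = np.sin(2 * np.pi * 0.2 * np.round(beats * fs) / fs)
        assert np.allclose(rg.values, expected, atol=1e-12)


class TestPreprocessEDA:
    def test_z_score_invariant(self):
        rng = np.random.default_rng(0)
        x = 5 + np.cumsum(rng.normal(0, 0.01, 256 * 120))
        clean = pp.preprocess_eda(x, 256.0)
        assert abs(np.mean(clean.samples)) < 1e-9
        assert np.std(clean.samples) == pytest.approx(1.0, abs=1e-9)

    def test_slow_waveform_preserved(self):
        t = np.arange(0, 300, 1 / 256.0)
        x = np.sin(2 * np.pi * 0.1 * t)
        clean = pp.preprocess_eda(x, 256.0)
        ideal = np.sin(2 * np.pi * 0.1 * np.arange(clean.samples.size) / 16.0)
        ideal = (ideal - ideal.mean()) / ideal.std()
        r = np.corrcoef(clean.samples, ideal)[0, 1]
        assert r > 0.999

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            pp.preprocess_eda(np.full(256 * 120, 3.0), 256.0)


class TestCentralWindow:
    def _rr(self, duration=400.0):
        bt = np.arange(0.0, duration, 0.8)
        return pp.RRSeries.from_beat_times(bt)

    def test_six_minute_phase_centered(self):
        rr = self._rr()
        w = pp.extract_central_window(rr, (0.0, 360.0), 240.0)
        assert w.beat_times[0] >= 60.0 and w.beat_times[-1] <= 300.0
        assert w.beat_times[0] - 60.0 < 1.0 and 300.0 - w.beat_times[-1] < 1.0

    def test_exact_width_phase_kept_whole(self):
        rr = self._rr(240.0)
        w = pp.extract_central_window(rr, (0.0, 240.0), 240.0)
        assert w.beat_times.size == rr.beat_times.size

    def test_short_phase_rejected(self):
        with pytest.raises(WindowError):
            pp.extract_central_window(self._rr(), (0.0, 180.0), 240.0)

    def test_eda_slice_length(self):
        clean = pp.CleanEDA(np.zeros(16 * 400), 16.0)
        w = pp.extract_central_window(clean, (0.0, 400.0), 240.0)
        assert abs(w.samples.size / 16.0 - 240.0) <= 2 / 16.0

    def test_breath_intervals_inside_window(self):
        br = pp.BreathSeries(np.arange(0.0, 400.0, 3.7), None)
        br = pp.BreathSeries(br.peak_times, np.diff(br.peak_times))
        w = pp.extract_central_window(br, (0.0, 400.0), 240.0)
        assert w.peak_times[0] >= 80.0 and w.peak_times[-1] <= 320.0
        assert w.bb.size == w.peak_times.size - 1
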