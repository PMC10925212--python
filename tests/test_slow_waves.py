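"""Slow-wave filtering, detection, and amplitude matching."""

import numpy as np
import pytest

import oscipipe as op
from oscipipe.slow_waves import SlowWave

FS = 250.0


def wave(amplitude, slope=None, channel=0, hour="first", t0=0.0):
    slope = slope if slope is not None else amplitude / 0.25
    return SlowWave(
        channel=channel,
        t_zero_down=t0,
        t_trough=t0 + amplitude / slope,
        t_zero_up=t0 + 0.5,
        amplitude=amplitude,
        descending_slope=slope,
        hour_label=hour,
    )


class TestFilterSleepEEG:
    def test_passband_tone_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        sig = np.vstack([np.sin(2 * np.pi * 1.0 * t), -np.sin(2 * np.pi * 1.0 * t)])
        out = op.filter_sleep_eeg(sig, FS)
        mid = slice(int(10 * FS), int(50 * FS))
        assert np.abs(out[0, mid]).max() > 0.95

    def test_stopband_tone_attenuated(self):
        t = np.arange(int(60 * FS)) / FS
        sig = np.vstack([np.sin(2 * np.pi * 20.0 * t), -np.sin(2 * np.pi * 20.0 * t)])
        out = op.filter_sleep_eeg(sig, FS)
        mid = slice(int(10 * FS), int(50 * FS))  # skip filtfilt edge transients
        assert np.abs(out[0, mid]).max() < 0.1  # > 20 dB down

    def test_average_reference_zero_mean(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 10, (4, int(30 * FS)))
        out = op.filter_sleep_eeg(sig, FS)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-8)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            op.filter_sleep_eeg(np.zeros((2, 500)), 50.0)


class TestDetectSlowWaves:
    quiet = op.AperiodicSpec(offset=-6.0, exponent=0.5, duration=30, n_channels=4, seed=1)

    def test_closed_form_amplitude_and_slope(self):
        """A 75 uV generator wave with 0.25 s falling time is detected
        with amplitude 75 +- 2 uV and slope 300 +- 10 uV/s."""
        w = op.SlowWaveSpecSim(amplitude=75.0, falling_time=0.25, wave_duration=0.5,
                               onset=10.0, channel=1)
        sig, _ = op.generate_sleep_signal([w], self.quiet)
        filtered = op.filter_sleep_eeg(sig, self.quiet.sample_rate)
        det = [x for x in op.detect_slow_waves(filtered, self.quiet.sample_rate, [(0, 30)])
               if x.channel == 1 and x.amplitude > 20]
        assert len(det) == 1
        assert det[0].amplitude == pytest.approx(75.0, abs=2.0)
        assert det[0].descending_slope == pytest.approx(300.0, abs=10.0)
        assert 0.25 <= det[0].duration <= 1.0

    def test_short_half_wave_not_detected(self):
        """A 0.2 s negative half-wave falls below the 0.25 s floor."""
        t = np.arange(int(20 * FS)) / FS
        sig = np.zeros((2, t.size))
        m = (t >= 10.0) & (t <= 10.2)
        sig[0, m] = -50.0 * np.sin(np.pi * (t[m] - 10.0) / 0.2)
        sig[1] = -sig[0]
        det = op.detect_slow_waves(sig, FS, [(0, 20)])
        assert all(not (9.5 < w.t_trough < 10.7) for w in det if w.channel == 0)

    def test_detection_restricted_to_nrem(self):
        w = op.SlowWaveSpecSim(amplitude=75.0, falling_time=0.25, wave_duration=0.5,
                               onset=10.0, channel=1)
        sig, _ = op.generate_sleep_signal([w], self.quiet)
        filtered = op.filter_sleep_eeg(sig, self.quiet.sample_rate)
        det = op.detect_slow_waves(filtered, self.quiet.sample_rate, [(15.0, 30.0)])
        assert all(not (9.5 < x.t_trough < 10.7 and x.channel == 1) for x in det)

    def test_empty_nrem_empty_list(self):
        assert op.detect_slow_waves(np.zeros((2, 1000)), FS, []) == []

    def test_truth_table_round_trip(self):
        """Every detectable generator wave is recovered exactly once with
        amplitude within the filtering ripple."""
        rng = np.random.default_rng(4)
        waves, t = [], 3.0
        while t < 110:
            wd = float(rng.uniform(0.44, 0.50))
            waves.append(op.SlowWaveSpecSim(
                amplitude=float(rng.uniform(50, 120)),
                falling_time=float(rng.uniform(0.45, 0.55)) * wd,
                wave_duration=wd, onset=t, channel=int(rng.integers(8))))
            t += 2 * wd + float(rng.uniform(2.0, 3.0))  # sparse: no filter-tail bleed
        bg = op.AperiodicSpec(offset=-6.0, exponent=0.5, duration=120, n_channels=8, seed=9)
        sig, truth = op.generate_sleep_signal(waves, bg)
        filtered = op.filter_sleep_eeg(sig, bg.sample_rate)
        det = op.detect_slow_waves(filtered, bg.sample_rate, [(0, 120)])
        big = [w for w in det if w.amplitude > 25]
        for (_, row), w0 in zip(truth.iterrows(), waves):
            hits = [w for w in big
                    if w.channel == row.channel
                    and abs(w.t_trough - (row.start_s + w0.falling_time)) < 0.05]
            assert len(hits) == 1
            assert hits[0].amplitude == pytest.approx(row.amplitude_uv, rel=0.02)


class TestMatchWavesByAmplitude:
    def test_identical_lists_fully_matched(self):
        first = [wave(a) for a in (50, 60, 70)]
        last = [wave(a, hour="last") for a in (50, 60, 70)]
        pairs, frac = op.match_waves_by_amplitude(first, last)
        assert frac == 1.0
        assert all(a.amplitude == b.amplitude for a, b in pairs)

    def test_disjoint_ranges_no_matches(self):
        first = [wave(a) for a in (20, 25, 30)]
        last = [wave(a, hour="last") for a in (100, 110)]
        pairs, frac = op.match_waves_by_amplitude(first, last, tolerance=0.05)
        assert pairs == [] and frac == 0.0

    def test_greedy_without_replacement(self):
        """{50,60,70} vs {52,71} at 10%: 50-52 and 70-71 pair, 60 is left
        unmatched -- identical to the exhaustive optimal assignment."""
        first = [wave(a) for a in (50, 60, 70)]
        last = [wave(a, hour="last") for a in (52, 71)]
        pairs, frac = op.match_waves_by_amplitude(first, last, tolerance=0.10)
        got = sorted((a.amplitude, b.amplitude) for a, b in pairs)
        assert got == [(50, 52), (70, 71)]
        assert frac == pytest.approx(2 / 3)

    def test_matched_distributions_agree(self):
        """Mean amplitude difference of matched sets is bounded by the
        tolerance -- the mechanism making slopes amplitude-independent."""
        rng = np.random.default_rng(0)
        first = [wave(float(a)) for a in rng.uniform(40, 120, 100)]
        last = [wave(float(a), hour="last") for a in rng.uniform(40, 120, 100)]
        pairs, _ = op.match_waves_by_amplitude(first, last, tolerance=0.10)
        a = np.mean([p[0].amplitude for p in pairs])
        b = np.mean([p[1].amplitude for p in pairs])
        assert abs(a - b) <= 0.10 * a

    def test_scale_covariance(self):
        """Scaling all amplitudes by k scales matched amplitudes/slopes by k
        and leaves the matching structure unchanged."""
        rng = np.random.default_rng(2)
        amps_f = rng.uniform(40, 120, 30)
        amps_l = rng.uniform(40, 120, 30)
        k = 3.7
        p1, f1 = op.match_waves_by_amplitude(
            [wave(float(a)) for a in amps_f], [wave(float(a), hour="last") for a in amps_l]
        )
        p2, f2 = op.match_waves_by_amplitude(
            [wave(float(k * a)) for a in amps_f],
            [wave(float(k * a), hour="last") for a in amps_l],
        )
        assert f1 == f2
        for (a1, b1), (a2, b2) in zip(p1, p2):
            assert a2.amplitude == pytest.approx(k * a1.amplitude)
            assert b2.descending_slope == pytest.approx(k * b1.descending_slope)

    def test_empty_hour_rejected(self):
        with pytest.raises(ValueError):
            op.match_waves_by_amplitude([], [wave(50, hour="last")])


class TestSummarize:
    def test_single_wave_each_hour(self):
        f, l = wave(80.0), wave(80.0, hour="last")
        pairs, _ = op.match_waves_by_amplitude([f], [l])
        summary = op.summarize_slow_waves([f, l], pairs)
        row = summary.set_index("hour")
        assert row.loc["first", "mean_matched_slope_uv_per_s"] == pytest.approx(
            f.descending_slope
        )
        assert row.loc["last", "mean_amplitude_uv"] == pytest.approx(80.0)

    def test_slope_ratio_recovered(self):
        """First-hour slopes 10% steeper at equal amplitudes show up as a
        matched-slope ratio of about 1.10."""
        rng = np.random.default_rng(5)
        amps = rng.uniform(50, 100, 60)
        first = [wave(float(a), slope=float(a) / 0.25 * 1.10) for a in amps]
        last = [wave(float(a), slope=float(a) / 0.25, hour="last") for a in amps]
        pairs, frac = op.match_waves_by_amplitude(first, last)
        assert frac == 1.0
        summary = op.summarize_slow_waves(first + last, pairs).set_index("hour")
        ratio = (
            summary.loc["first", "mean_matched_slope_uv_per_s"]
            / summary.loc["last", "mean_matched_slope_uv_per_s"]
        )
        assert ratio == pytest.approx(1.10, abs=0.01)

    def test_no_matches_flagged_undefined(self):
        summary = op.summarize_slow_waves([wave(50.0)], [])
        assert np.isnan(summary.set_index("hour").loc["first", "mean_matched_slope_uv_per_s"])
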