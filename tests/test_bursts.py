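"""Cycle extraction, criterion scoring, and burst run detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oscipipe as op
from oscipipe.bursts import CriteriaSet, _runs_to_bursts

from conftest import FS, detect_channel_bursts, make_sinusoid


class TestNarrowbandDecompose:
    def test_passband_selectivity(self):
        """A 10 Hz tone lives in the 8-12 band; the 2-6 band passes <5%."""
        t = np.arange(int(20 * FS)) / FS
        sig = np.sin(2 * np.pi * 10.0 * t)
        out = op.narrowband_decompose(sig, FS)
        mid = slice(int(5 * FS), int(15 * FS))
        assert np.abs(out[(8, 12)][mid]).max() > 0.9
        assert np.abs(out[(2, 6)][mid]).max() < 0.05

    def test_dc_removed(self):
        sig = np.full(int(20 * FS), 7.0)
        out = op.narrowband_decompose(sig, FS)
        for band in out.values():
            assert abs(band.mean()) < 1e-3  # > 70 dB of DC rejection

    def test_band_definitions(self):
        assert op.BANDS == [(2, 6), (4, 8), (6, 10), (8, 12), (10, 14), (12, 16)]

    def test_white_noise_band_power(self):
        """Band output variance matches the analytic fraction of white-noise
        power falling in a 4 Hz passband (Monte-Carlo vs closed form)."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sig = rng.normal(0, 1.0, int(30 * FS))
            out = op.narrowband_decompose(sig, FS)
            ratios.append(np.var(out[(8, 12)]) / np.var(sig))
        # zero-phase double filtering narrows the 4 Hz band slightly
        expected = 4.0 / (FS / 2)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.2)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            op.narrowband_decompose(np.zeros(int(3 * FS)), FS)


class TestExtractCycles:
    def test_whole_sinusoid_cycles(self):
        """A tone with N positive peaks yields N-1 positive-to-positive
        cycle records, each with period 1/f to within one sample."""
        sig = make_sinusoid(10.0, 8)  # 9 peak instants
        cycles = op.extract_cycles(sig, sig, FS, (8, 12))
        assert len(cycles) == 8
        for c in cycles:
            assert c.period == pytest.approx(0.1, abs=1.0 / FS)
            assert c.frequency_ok

    def test_trough_taken_from_broadband(self):
        """A spike at a trough in the broadband trace defines the trough
        voltage even though the narrowband trace is smooth."""
        nb = make_sinusoid(10.0, 6)
        bb = nb.copy()
        troughs = np.flatnonzero((bb[1:-1] < bb[:-2]) & (bb[1:-1] < bb[2:])) + 1
        spike_at = troughs[2]
        bb[spike_at] -= 0.5
        cycles = op.extract_cycles(nb, bb, FS, (8, 12))
        assert min(c.v_trough for c in cycles) == pytest.approx(bb[spike_at])

    def test_frequency_sweep_flags_out_of_band_cycles(self):
        t = np.arange(int(10 * FS)) / FS
        sweep = np.sin(2 * np.pi * (9.0 * t + 0.2 * t**2))  # 9 -> 13 Hz
        cycles = op.extract_cycles(sweep, sweep, FS, (8, 12))
        inst = [1.0 / c.period for c in cycles]
        assert inst[-1] > 12.0
        assert not cycles[-1].frequency_ok
        assert cycles[0].frequency_ok

    def test_too_few_peaks_empty(self):
        sig = np.linspace(-1, 1, 500)
        assert op.extract_cycles(sig, sig, FS, (8, 12)) == []


class TestScoreCycles:
    def test_perfect_sinusoid_scores(self, sinusoid_cycles):
        """All consistency and monotonicity criteria hit 1 on a clean tone."""
        cycles, _ = sinusoid_cycles
        for c in cycles:
            assert c.scores["period_consistency"] == pytest.approx(1.0, abs=0.02)
            assert c.scores["amplitude_consistency"] == pytest.approx(1.0, abs=0.01)
            assert c.scores["flank_consistency"] == pytest.approx(1.0, abs=0.01)
            assert c.scores["shape_consistency"] == pytest.approx(1.0, abs=0.01)
            assert c.scores["monotonicity_time"] == 1.0
            assert c.scores["monotonicity_amplitude"] == pytest.approx(1.0, abs=1e-9)
            assert c.scores["reversal_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_period_consistency_ratio(self):
        """Adjacent periods of 100 and 125 ms give min/max = 0.8 for both."""
        sig = np.zeros(1000)
        # build two cycles by hand: peaks at 0 ms, 100 ms, 225 ms
        for i, (p, v) in enumerate([(0, 1.0), (12, -1.0), (25, 1.0), (41, -1.0), (56, 1.0)]):
            sig[p + 100] = v
        nb = np.interp(np.arange(1000), [100, 112, 125, 141, 156], [1, -1, 1, -1, 1],
                       left=0, right=0)
        cycles = op.extract_cycles(nb, nb, FS, (4, 16))
        assert len(cycles) == 2
        scored = op.score_cycles(cycles, nb)
        p0, p1 = scored[0].period, scored[1].period
        expected = min(p0, p1) / max(p0, p1)
        assert expected == pytest.approx(0.8, abs=0.02)
        for c in scored:
            assert c.scores["period_consistency"] == pytest.approx(expected, abs=1e-9)

    def test_flank_consistency_ratio(self):
        """rise 30 uV vs decay 10 uV -> flank consistency 1/3."""
        x = np.interp(np.arange(200), [10, 35, 60, 85, 110], [5, -5, 25, -5, 5],
                      left=0, right=0)
        cycles = op.extract_cycles(x, x, FS, (2, 16))
        scored = op.score_cycles(cycles, x)
        target = [c for c in scored if c.decay_amp == pytest.approx(10.0)]
        assert target and target[0].rise_amp == pytest.approx(30.0)
        assert target[0].scores["flank_consistency"] == pytest.approx(1 / 3)

    def test_zero_amplitude_scores_zero(self):
        x = np.zeros(500)
        x[100], x[150] = 1.0, 1.0  # two peaks, flat trough between
        nb = np.interp(np.arange(500), [100, 125, 150], [1, -1, 1], left=0, right=0)
        cycles = op.extract_cycles(nb, x, FS, (4, 16))
        scored = op.score_cycles(cycles, x)
        flat = [c for c in scored if c.decay_amp == 0 and c.rise_amp == 0]
        for c in flat:
            assert c.scores["flank_consistency"] == 0.0
            assert c.scores["monotonicity_amplitude"] == 0.0


class TestDetectBursts:
    def test_clean_cycles_one_merged_burst(self):
        """Seven perfect 10 Hz cycles pass all three sets; merging leaves
        exactly one burst."""
        sig = make_sinusoid(10.0, 7, amplitude=10.0, pad_s=3.0)
        bursts = detect_channel_bursts(sig)
        assert len(bursts) == 1
        assert set(bursts[0].criteria_set.split("+")) == {"set1", "set2", "set3"}
        assert bursts[0].mean_frequency == pytest.approx(10.0, rel=0.02)

    def test_three_cycles_only_strict_set(self):
        """Three-cycle bursts at the top of the low-beta band are caught
        only by the 3-cycle criteria set and last at least 187 ms."""
        freq = 15.2  # top of low beta, with margin for edge-cycle bias
        spec = op.AperiodicSpec(offset=0.5, exponent=1.5, duration=60, seed=2)
        bg = op.generate_aperiodic_background(spec)
        rms = float(np.sqrt(np.mean(bg**2)))
        injected = [
            op.BurstSpec(frequency=freq, n_cycles=3, peak_to_peak=20 * rms, onset=2.0 + 2 * i)
            for i in range(25)
        ]
        sig, truth = op.inject_bursts(bg, injected, FS)
        bursts = detect_channel_bursts(sig[0])
        matched = [
            b for b in bursts
            if any(
                min(b.end, r.end_s) - max(b.start, r.start_s)
                >= 0.7 * (r.end_s - r.start_s)
                for r in truth.itertuples()
            )
        ]
        assert len(matched) >= len(injected) // 2
        three_cycle = [b for b in matched if b.n_cycles == 3]
        assert three_cycle, "some bursts must be caught as exact 3-cycle runs"
        for b in three_cycle:
            assert "set3" in b.criteria_set
            assert b.duration >= 0.187

    def test_alternating_pass_fail_no_burst(self, sinusoid_cycles):
        cycles, _ = sinusoid_cycles
        cset = CriteriaSet("t", {"flank_consistency": 0.5}, min_cycles=3)
        flipped = []
        for i, c in enumerate(cycles):
            c2 = op.Cycle(**{f: getattr(c, f) for f in (
                "channel", "band", "i_pos_start", "i_trough", "i_pos_end",
                "t_pos_start", "t_trough", "t_pos_end",
                "v_pos_start", "v_trough", "v_pos_end")})
            c2.scores = dict(c.scores)
            c2.frequency_ok = c.frequency_ok
            c2.scores["flank_consistency"] = 1.0 if i % 2 == 0 else 0.0
            flipped.append(c2)
        assert _runs_to_bursts(flipped, cset, 0, (8, 12)) == []

    def test_threshold_passes_at_equality(self, sinusoid_cycles):
        cycles, _ = sinusoid_cycles
        score = cycles[1].scores["period_consistency"]
        cset = CriteriaSet("eq", {"period_consistency": score}, min_cycles=2)
        assert cset.passes(cycles[1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=20), st.integers(2, 5))
    def test_run_extraction_matches_window_enumeration(self, passes, min_cycles):
        """Maximal-run detection equals brute-force enumeration of all
        qualifying windows on arbitrary pass/fail sequences."""
        from oscipipe.bursts import SCORE_NAMES

        cycles = []
        for i, ok in enumerate(passes):
            c = op.Cycle(0, (8, 12), i * 25, i * 25 + 12, (i + 1) * 25,
                         i * 0.1, i * 0.1 + 0.05, (i + 1) * 0.1, 1.0, -1.0, 1.0)
            c.scores = {k: (1.0 if ok else 0.0) for k in SCORE_NAMES}
            c.frequency_ok = True
            cycles.append(c)
        cset = CriteriaSet("b", {"flank_consistency": 0.5}, min_cycles=min_cycles)
        got = {(b.cycles[0].t_pos_start, b.cycles[-1].t_pos_end)
               for b in _runs_to_bursts(cycles, cset, 0, (8, 12))}
        # oracle: maximal all-pass windows of length >= min_cycles
        expected = set()
        i = 0
        while i < len(passes):
            if passes[i]:
                j = i
                while j + 1 < len(passes) and passes[j + 1]:
                    j += 1
                if j - i + 1 >= min_cycles:
                    expected.add((cycles[i].t_pos_start, cycles[j].t_pos_end))
                i = j + 1
            else:
                i += 1
        assert got == expected

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_amplitude_blindness(self, k):
        """Scaling the whole signal leaves the detected burst set identical:
        every criterion is a ratio, amplitude is never thresholded."""
        base = make_sinusoid(10.0, 7, amplitude=3.0, pad_s=3.0)
        base = base + 0.1 * np.sin(2 * np.pi * 3.0 * np.arange(base.size) / FS)
        b1 = detect_channel_bursts(base)
        b2 = detect_channel_bursts(k * base)
        assert len(b1) == len(b2) and len(b1) > 0
        for x, y in zip(b1, b2):
            assert y.start == pytest.approx(x.start, abs=1e-9)
            assert y.end == pytest.approx(x.end, abs=1e-9)
            assert y.n_cycles == x.n_cycles
            assert y.mean_amplitude == pytest.approx(k * x.mean_amplitude, rel=1e-9)

    def test_no_burst_outside_2_16_hz(self):
        """A 20 Hz tone produces no burst: bands stop at 16 Hz."""
        sig = make_sinusoid(20.0, 12, amplitude=10.0, pad_s=3.0)
        bursts = detect_channel_bursts(sig)
        assert all(2.0 <= b.mean_frequency <= 16.0 for b in bursts)
        assert all(b.duration >= b.n_cycles / 16.0 * 0.95 for b in bursts)


class TestBurstFrequency:
    @pytest.mark.parametrize(
        "gaps,expected",
        [([0.1] * 5, 10.0), ([0.09, 0.11], 10.0), ([0.0625] * 4, 16.0)],
    )
    def test_inverse_mean_trough_distance(self, gaps, expected):
        troughs = np.concatenate([[0.0], np.cumsum(gaps)])
        assert op.burst_frequency(troughs) == pytest.approx(expected)

    def test_single_trough_rejected(self):
        with pytest.raises(ValueError):
            op.burst_frequency([0.5])
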