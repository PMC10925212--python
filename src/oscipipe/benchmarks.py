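"""End-to-end property benchmarks on synthetic ground truth.

Each function simulates inputs with the synthetic-data module, runs the
relevant pipeline stage from scratch, and measures recovery of the known
truth.  They are used both by the acceptance test suite and by the
standalone acceptance script.

Problem sizes follow the package's standard study conditions: 60-second
recordings at 250 Hz, 8 channels, a 1/f^1.5 background, bursts at four
times the background RMS, and cohorts of 100 participants with two
sessions of two tasks at two times of day.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import simulate as sim
from .burst_measures import MEASURE_BANDS, oscillation_density, pool_band_density
from .bursts import (
    DEFAULT_CRITERIA_SETS,
    detect_bursts,
    extract_cycles,
    narrowband_decompose,
    score_cycles,
)
from .slow_waves import detect_slow_waves, filter_sleep_eeg
from .spectral import PowerSpectrum, fit_aperiodic_and_peaks
from .stats import channelwise_lmm, fit_lmm

__all__ = [
    "detect_recording_bursts",
    "minimum_burst_duration",
    "burst_recovery",
    "aperiodic_recovery",
    "slow_wave_closed_form",
    "statistics_calibration",
]


def detect_recording_bursts(signal: np.ndarray, sample_rate: float) -> dict[int, list]:
    """Per-channel cycle-by-cycle burst detection on a clean recording."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    out: dict[int, list] = {}
    for ch in range(x.shape[0]):
        bands = narrowband_decompose(x[ch], sample_rate)
        scored = {}
        for band, nb in bands.items():
            cycles = extract_cycles(nb, x[ch], sample_rate, band, channel=ch)
            if cycles:
                scored[band] = score_cycles(cycles, x[ch])
        out[ch] = detect_bursts(scored, DEFAULT_CRITERIA_SETS, channel=ch)
    return out


def minimum_burst_duration(seed: int = 0) -> dict:
    """Shortest burst the detector can report, swept across low beta.

    Three-cycle bursts are injected at frequencies up to the top of the
    low-beta band; with the 3-cycle criteria set and the strict per-cycle
    frequency gate, no detected burst can be shorter than 3/16 s.
    Returns the minimum detected duration (ms) among bursts that overlap
    an injected one.
    """
    fs = 250.0
    durations = []
    for k, freq in enumerate((13.0, 14.0, 14.6, 15.0, 15.4)):
        spec = sim.AperiodicSpec(
            offset=0.5, exponent=1.5, duration=60.0, n_channels=1, seed=seed * 100 + k
        )
        bg = sim.generate_aperiodic_background(spec)
        rms = float(np.sqrt(np.mean(bg**2)))
        bursts = [
            sim.BurstSpec(frequency=freq, n_cycles=3, peak_to_peak=10 * rms, onset=2.0 + 2.0 * i)
            for i in range(27)
        ]
        signal, truth = sim.inject_bursts(bg, bursts, fs)
        detected = detect_recording_bursts(signal, fs)[0]
        for row in truth.itertuples():
            for b in detected:
                overlap = min(b.end, row.end_s) - max(b.start, row.start_s)
                if overlap >= 0.7 * (row.end_s - row.start_s):
                    durations.append(b.duration)
    return {
        "min_duration_ms": 1000.0 * float(min(durations)),
        "n_detected": len(durations),
    }


def burst_recovery(
    seed: int = 0, n_recordings: int = 20, n_background: int = 5
) -> dict:
    """Detection rate, density and amplitude errors, false-positive density.

    Twenty 60-s 8-channel recordings with 10-cycle bursts at 4x the
    background RMS (1/f^1.5 background); plus burst-free recordings for
    the false-positive rate.
    """
    fs = 250.0
    duration = 60.0
    n_channels = 8
    hits = total = 0
    amp_errors, density_errors = [], []
    for rec in range(n_recordings):
        spec = sim.AperiodicSpec(
            offset=1.0, exponent=1.5, duration=duration, n_channels=n_channels,
            seed=seed * 1000 + rec,
        )
        bg = sim.generate_aperiodic_background(spec)
        rms = float(np.sqrt(np.mean(bg**2)))
        rng = np.random.default_rng(seed * 1000 + 500 + rec)
        bursts, t = [], 2.0
        while t + 2.2 < duration - 2.0:
            freq = float(rng.uniform(5.0, 14.0))
            width = int(rng.integers(2, 5))
            start = int(rng.integers(0, n_channels - width + 1))
            bursts.append(
                sim.BurstSpec(
                    frequency=freq, n_cycles=10, peak_to_peak=4.0 * rms,
                    onset=t, channels=frozenset(range(start, start + width)),
                )
            )
            t += 10.0 / freq + float(rng.uniform(1.5, 3.0))
        signal, truth = sim.inject_bursts(bg, bursts, fs)
        detected = detect_recording_bursts(signal, fs)
        for row in truth.itertuples():
            total += 1
            best = None
            for b in detected[row.channel]:
                overlap = min(b.end, row.end_s) - max(b.start, row.start_s)
                if overlap >= 0.7 * (row.end_s - row.start_s):
                    best = b
                    break
            if best is not None:
                hits += 1
                amp_errors.append(
                    abs(best.mean_amplitude - row.amplitude_uv) / row.amplitude_uv
                )
        truth_density = 100.0 * (truth.end_s - truth.start_s).sum() / (n_channels * duration)
        det_density = float(
            np.mean([pool_band_density(bs, duration) for bs in detected.values()])
        )
        density_errors.append(abs(det_density - truth_density))
    fp = []
    for rec in range(n_background):
        spec = sim.AperiodicSpec(
            offset=1.0, exponent=1.5, duration=duration, n_channels=2,
            seed=seed * 1000 + 900 + rec,
        )
        bg = sim.generate_aperiodic_background(spec)
        detected = detect_recording_bursts(bg, fs)
        for bs in detected.values():
            for band in MEASURE_BANDS:
                fp.append(oscillation_density(bs, band, duration))
    return {
        "detection_rate_pct": 100.0 * hits / total,
        "amplitude_error_pct": 100.0 * float(np.median(amp_errors)),
        "density_error_pp": float(np.median(density_errors)),
        "false_positive_density_pct": float(np.mean(fp)),
    }


def aperiodic_recovery(seed: int = 0) -> dict:
    """Exponent/offset recovery on noiseless analytic spectra.

    Grid of exponent {0.5..2.5} x offset {-1, 0, 1}, plain and with one
    injected alpha Gaussian peak; reports worst absolute errors.
    """
    f = np.arange(0.25, 40.01, 0.25)
    plain_err = {"exponent": 0.0, "offset": 0.0}
    peak_err = {"exponent": 0.0, "offset": 0.0}
    for exponent in (0.5, 1.0, 1.5, 2.0, 2.5):
        for offset in (-1.0, 0.0, 1.0):
            logp = offset - exponent * np.log10(f)
            fit = fit_aperiodic_and_peaks(PowerSpectrum(f, 10.0**logp))
            plain_err["exponent"] = max(plain_err["exponent"], abs(fit.exponent - exponent))
            plain_err["offset"] = max(plain_err["offset"], abs(fit.offset - offset))
            peaky = logp + 0.5 * np.exp(-((f - 10.0) ** 2) / (2 * 2.0**2))
            fit = fit_aperiodic_and_peaks(PowerSpectrum(f, 10.0**peaky))
            peak_err["exponent"] = max(peak_err["exponent"], abs(fit.exponent - exponent))
            peak_err["offset"] = max(peak_err["offset"], abs(fit.offset - offset))
    return {
        "max_exponent_error": plain_err["exponent"],
        "max_offset_error": plain_err["offset"],
        "max_exponent_error_with_peak": peak_err["exponent"],
        "max_offset_error_with_peak": peak_err["offset"],
    }


def slow_wave_closed_form(seed: int = 0) -> dict:
    """Canonical-wave fidelity and the generator/detector round trip.

    The canonical wave is 75 uV with a 0.25 s falling time inside a
    0.5 s half-wave (analytic slope 300 uV/s).  The round trip injects a
    sparse population of ~1 Hz waves on 8 channels and requires each to
    be recovered exactly once.
    """
    fs = 250.0
    quiet = sim.AperiodicSpec(
        offset=-6.0, exponent=0.5, duration=30.0, n_channels=8, seed=seed
    )
    wave = sim.SlowWaveSpecSim(
        amplitude=75.0, falling_time=0.25, wave_duration=0.5, onset=10.0, channel=1
    )
    signal, _ = sim.generate_sleep_signal([wave], quiet)
    filtered = filter_sleep_eeg(signal, fs)
    det = [
        w for w in detect_slow_waves(filtered, fs, [(0.0, 30.0)])
        if w.channel == 1 and w.amplitude > 20
    ]
    canonical_amp = det[0].amplitude
    canonical_slope = det[0].descending_slope

    rng = np.random.default_rng(seed + 1)
    waves, t = [], 3.0
    while t < 110.0:
        wd = float(rng.uniform(0.44, 0.50))
        # channels round-robin: same-channel waves stay ~25 s apart so
        # filter tails of one wave cannot bleed into the next
        waves.append(
            sim.SlowWaveSpecSim(
                amplitude=float(rng.uniform(50.0, 120.0)),
                falling_time=float(rng.uniform(0.45, 0.55)) * wd,
                wave_duration=wd, onset=t, channel=len(waves) % 8,
            )
        )
        t += 2 * wd + float(rng.uniform(2.0, 3.0))
    bg = sim.AperiodicSpec(offset=-6.0, exponent=0.5, duration=120.0, n_channels=8, seed=seed)
    signal, truth = sim.generate_sleep_signal(waves, bg)
    filtered = filter_sleep_eeg(signal, fs)
    det = [w for w in detect_slow_waves(filtered, fs, [(0.0, 120.0)]) if w.amplitude > 25]
    recovered = 0
    amp_errors = []
    for row, w0 in zip(truth.itertuples(), waves):
        matches = [
            w for w in det
            if w.channel == row.channel
            and abs(w.t_trough - (row.start_s + w0.falling_time)) < 0.05
        ]
        if len(matches) == 1:
            recovered += 1
            amp_errors.append(abs(matches[0].amplitude - row.amplitude_uv) / row.amplitude_uv)
    return {
        "canonical_amplitude_uv": float(canonical_amp),
        "canonical_slope_uv_per_s": float(canonical_slope),
        "round_trip_recovered_pct": 100.0 * recovered / len(waves),
        "round_trip_max_amplitude_error_pct": 100.0 * float(np.max(amp_errors)),
    }


def statistics_calibration(
    seed: int = 0, n_coverage: int = 200, n_null: int = 12, n_channels: int = 8
) -> dict:
    """Mixed-model CI coverage and the null FDR channel-map rate.

    Coverage: the 95% interval for the age effect over seeded cohort
    replicates (true beta -0.8).  Null maps: cohorts with zero time
    effect fitted per channel and BH-corrected at q = .05.
    """
    covered = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_coverage):
            table = sim.generate_measure_table(sim.CohortSpec(seed=seed * 10000 + rep))
            lo, hi = fit_lmm(table, "measure").conf_int("age")
            covered += lo <= -0.8 <= hi
        null_betas = {
            "intercept": 10.0, "age": 0.0, "time": 0.0, "age_time": 0.0,
            "task": {"gonogo": 0.0}, "group": 0.0, "sex": 0.0,
        }
        fractions = []
        for rep in range(n_null):
            tables = {
                ch: sim.generate_measure_table(
                    sim.CohortSpec(n_participants=25, betas=null_betas,
                                   seed=seed * 10000 + 5000 + rep * 100 + ch)
                )
                for ch in range(n_channels)
            }
            out = channelwise_lmm(tables, "measure")
            fractions.append(float(out["significant"].mean()))
    return {
        "age_ci_coverage_pct": 100.0 * covered / n_coverage,
        "null_significant_channels_pct": 100.0 * float(np.mean(fractions)),
    }
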