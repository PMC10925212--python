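import numpy as np
import pytest

import oscipipe as op

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


def make_sinusoid(freq, n_cycles, fs=FS, amplitude=1.0, pad_s=1.0):
    """Whole cycles of a cosine starting/ending on a positive peak,
    zero-padded on both sides."""
    n = int(round(n_cycles / freq * fs)) + 1
    t = np.arange(n) / fs
    wave = amplitude * np.cos(2 * np.pi * freq * t)
    pad = np.zeros(int(pad_s * fs))
    return np.concatenate([pad, wave, pad])


@pytest.fixture(scope="session")
def sinusoid_cycles():
    """Scored cycles of a clean 10 Hz sinusoid (8 whole cycles -> 7 records)."""
    sig = make_sinusoid(10.0, 8, amplitude=20.0)
    cycles = op.extract_cycles(sig, sig, FS, (8.0, 12.0))
    return op.score_cycles(cycles, sig), sig


@pytest.fixture(scope="session")
def wake_recording():
    """60 s, 4-channel background with three injected 10-cycle bursts."""
    spec = op.AperiodicSpec(offset=1.0, exponent=1.5, duration=60, n_channels=4, seed=11)
    background = op.generate_aperiodic_background(spec)
    rms = float(np.sqrt(np.mean(background**2)))
    bursts = [
        op.BurstSpec(frequency=6.0, n_cycles=10, peak_to_peak=6 * rms, onset=5.0, channels=frozenset({0})),
        op.BurstSpec(frequency=10.0, n_cycles=10, peak_to_peak=6 * rms, onset=20.0, channels=frozenset({1, 2})),
        op.BurstSpec(frequency=14.0, n_cycles=10, peak_to_peak=6 * rms, onset=40.0, channels=frozenset({3})),
    ]
    signal, truth = op.inject_bursts(background, bursts, spec.sample_rate)
    return signal, truth, spec


def detect_channel_bursts(signal_1d, fs=FS, criteria_sets=None):
    """Full single-channel detection chain used across tests."""
    bands = op.narrowband_decompose(signal_1d, fs)
    scored = {}
    for band, nb in bands.items():
        cycles = op.extract_cycles(nb, signal_1d, fs, band)
        if cycles:
            scored[band] = op.score_cycles(cycles, signal_1d)
    return op.detect_bursts(scored, criteria_sets)
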