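"""Synthetic EEG with known ground truth.

Everything the pipeline consumes can be generated here: multichannel
1/f^x aperiodic background, superposed oscillation bursts, sleep signals
with negative half-wave deflections, and cohort-level measure tables with
nested random effects.  Every generator is a pure function of its spec,
including the seed, so downstream stages can be tested against exact
ground truth.

Design notes
------------
* The background is built by amplitude-shaping a random-phase spectrum to
  the target one-sided PSD ``10^offset / f^exponent`` and inverse
  transforming, independently per channel.
* Bursts are *added* onto the background (periodic + aperiodic additive
  model), not spliced, so the aperiodic statistics of the carrier are
  preserved.  Burst edges are untapered by default; a single-cycle linear
  taper is available as a flag.
* Slow waves are two half-sine segments (falling, rising) joined at the
  trough, which makes the descending slope analytic:
  ``slope = amplitude / falling_time``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AperiodicSpec",
    "BurstSpec",
    "SlowWaveSpecSim",
    "CohortSpec",
    "generate_aperiodic_background",
    "inject_bursts",
    "generate_sleep_signal",
    "generate_measure_table",
]

BURST_FREQ_RANGE = (2.0, 16.0)  # only bursts in this range are detectable
SLOW_WAVE_DURATION_RANGE = (0.25, 1.0)  # zero-crossing separation, seconds


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"invalid spec: non-finite field in {name}")


@dataclass(frozen=True)
class AperiodicSpec:
    """Target 1/f^x background: ``PSD(f) = 10^offset / f^exponent`` uV^2/Hz.

    ``channel_correlation`` is the expected pairwise correlation between
    channels, produced by mixing a common component into every channel
    (volume conduction makes neighboring EEG channels strongly
    correlated; fully independent channels would look like bad
    electrodes to the artifact heuristics).  The mixing leaves each
    channel's PSD on target.
    """

    offset: float = 1.0
    exponent: float = 1.5
    sample_rate: float = 250.0
    duration: float = 60.0
    n_channels: int = 1
    channel_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite("AperiodicSpec", self.offset, self.exponent, self.sample_rate, self.duration)
        if self.exponent < 0:
            raise ValueError("invalid spec: exponent must be >= 0")
        if self.duration <= 0:
            raise ValueError("invalid spec: duration must be > 0")
        if self.n_channels < 1:
            raise ValueError("invalid spec: n_channels must be >= 1")
        if not 0.0 <= self.channel_correlation < 1.0:
            raise ValueError("invalid spec: channel_correlation must be in [0, 1)")


@dataclass(frozen=True)
class BurstSpec:
    """One oscillation burst: ``n_cycles`` cycles at ``frequency`` Hz.

    ``waveform_asymmetry`` is the fraction of each cycle spent on the
    rising flank (0.5 = symmetric sinusoid).  The waveform starts and
    ends on a positive peak.
    """

    frequency: float
    n_cycles: int
    peak_to_peak: float
    onset: float
    channels: frozenset = frozenset({0})
    waveform_asymmetry: float = 0.5

    def __post_init__(self) -> None:
        _check_finite("BurstSpec", self.frequency, self.peak_to_peak, self.onset)
        lo, hi = BURST_FREQ_RANGE
        if not lo <= self.frequency <= hi:
            raise ValueError(f"invalid spec: burst frequency must be in [{lo}, {hi}] Hz")
        if self.n_cycles < 1:
            raise ValueError("invalid spec: n_cycles must be >= 1")
        if self.peak_to_peak <= 0:
            raise ValueError("invalid spec: peak_to_peak must be > 0")
        if not 0.0 < self.waveform_asymmetry < 1.0:
            raise ValueError("invalid spec: waveform_asymmetry must be in (0, 1)")
        object.__setattr__(self, "channels", frozenset(int(c) for c in self.channels))

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency


@dataclass(frozen=True)
class SlowWaveSpecSim:
    """A negative half-wave: zero crossing at onset and onset+wave_duration,
    trough of depth ``amplitude`` at ``onset + falling_time``."""

    amplitude: float
    falling_time: float
    wave_duration: float
    onset: float
    channel: int = 0

    def __post_init__(self) -> None:
        _check_finite(
            "SlowWaveSpecSim", self.amplitude, self.falling_time, self.wave_duration, self.onset
        )
        if self.amplitude <= 0:
            raise ValueError("invalid spec: amplitude must be > 0")
        if not 0 < self.falling_time < self.wave_duration:
            raise ValueError("invalid spec: need 0 < falling_time < wave_duration")

    @property
    def slope(self) -> float:
        """Descending slope, uV/s (trough depth / time from zero-crossing to trough)."""
        return self.amplitude / self.falling_time

    @property
    def detectable(self) -> bool:
        lo, hi = SLOW_WAVE_DURATION_RANGE
        return lo <= self.wave_duration <= hi


def generate_aperiodic_background(spec: AperiodicSpec) -> np.ndarray:
    """Multichannel signal (uV) whose one-sided PSD approximates the target.

    Construction: draw uniform random phases per rfft bin (seeded), set
    the amplitude of bin ``k`` so its periodogram equals
    ``10^offset / f_k^exponent``, inverse transform.  DC is zero.
    Returns shape ``(n_channels, n_samples)``.
    """
    n = int(round(spec.duration * spec.sample_rate))
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    target = np.zeros_like(freqs)
    target[1:] = 10.0**spec.offset / freqs[1:] ** spec.exponent
    # |X_k| such that the one-sided periodogram 2|X_k|^2/(fs*N) hits the target
    amp = np.sqrt(target * spec.sample_rate * n / 2.0)

    def _one() -> np.ndarray:
        phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
        z = amp * np.exp(1j * phases)
        z[0] = 0.0
        if n % 2 == 0:
            z[-1] = np.abs(z[-1])  # Nyquist bin must be real
        return np.fft.irfft(z, n=n)

    rho = spec.channel_correlation
    common = _one() if rho > 0 and spec.n_channels > 1 else 0.0
    out = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        local = _one()
        if spec.n_channels > 1:
            out[ch] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * local
        else:
            out[ch] = local
    return out


def _burst_waveform(spec: BurstSpec, sample_rate: float, taper: bool) -> np.ndarray:
    """Cycles from positive peak to positive peak, optionally asymmetric.

    The endpoint is included so the waveform ends exactly on its final
    positive peak."""
    n = int(round(spec.duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    cycle_pos = (t * spec.frequency) % 1.0  # position within the current cycle
    r = spec.waveform_asymmetry
    fall = cycle_pos < (1.0 - r)
    phase = np.where(
        fall,
        0.5 * cycle_pos / (1.0 - r),
        0.5 + 0.5 * (cycle_pos - (1.0 - r)) / r,
    )
    wave = 0.5 * spec.peak_to_peak * np.cos(2.0 * np.pi * phase)
    if taper and spec.n_cycles > 2:
        ramp = np.minimum(1.0, np.minimum(t, t[-1] - t) * spec.frequency)
        wave = wave * ramp
    return wave


def inject_bursts(
    background: np.ndarray,
    bursts: list[BurstSpec],
    sample_rate: float,
    taper: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Superpose bursts on the background; return (signal, truth table).

    The truth table has one row per (burst, channel) with columns
    ``channel, start_s, end_s, frequency_hz, amplitude_uv``.  Overlapping
    same-channel bursts within 1 Hz of each other are merged in the truth
    table (union interval) with a warning.
    """
    sig = np.array(background, dtype=float, copy=True)
    if sig.ndim == 1:
        sig = sig[np.newaxis, :]
    n_channels, n = sig.shape
    duration = n / sample_rate
    rows = []
    for b in bursts:
        if b.onset < 0 or b.onset + b.duration > duration + 1e-9:
            raise ValueError(f"burst at {b.onset:g}s does not fit within {duration:g}s recording")
        wave = _burst_waveform(b, sample_rate, taper)
        i0 = int(round(b.onset * sample_rate))
        i1 = min(i0 + wave.size, n)  # final peak may fall on the last sample
        for ch in sorted(b.channels):
            if not 0 <= ch < n_channels:
                raise ValueError(f"burst channel {ch} out of range")
            sig[ch, i0:i1] += wave[: i1 - i0]
            rows.append(
                {
                    "channel": ch,
                    "start_s": b.onset,
                    "end_s": b.onset + b.duration,
                    "frequency_hz": b.frequency,
                    "amplitude_uv": b.peak_to_peak,
                }
            )
    truth = pd.DataFrame(
        rows, columns=["channel", "start_s", "end_s", "frequency_hz", "amplitude_uv"]
    )
    truth = _merge_overlapping_truth(truth)
    return sig, truth


def _merge_overlapping_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Merge same-channel truth intervals that overlap within 1 Hz."""
    if truth.empty:
        return truth
    merged_rows = []
    n_merged = 0
    for ch, grp in truth.groupby("channel", sort=True):
        rows = grp.sort_values("start_s").to_dict("records")
        out: list[dict] = []
        for row in rows:
            prev = out[-1] if out else None
            if (
                prev is not None
                and row["start_s"] < prev["end_s"]
                and abs(row["frequency_hz"] - prev["frequency_hz"]) <= 1.0
            ):
                w_prev = prev["end_s"] - prev["start_s"]
                w_new = row["end_s"] - row["start_s"]
                prev["frequency_hz"] = (
                    prev["frequency_hz"] * w_prev + row["frequency_hz"] * w_new
                ) / (w_prev + w_new)
                prev["end_s"] = max(prev["end_s"], row["end_s"])
                prev["amplitude_uv"] = max(prev["amplitude_uv"], row["amplitude_uv"])
                n_merged += 1
            else:
                out.append(dict(row))
        merged_rows.extend(out)
    if n_merged:
        warnings.warn(f"merged {n_merged} overlapping same-channel burst truth intervals")
    return pd.DataFrame(merged_rows, columns=truth.columns).reset_index(drop=True)


def _slow_wave_waveform(spec: SlowWaveSpecSim, sample_rate: float, n: int) -> np.ndarray:
    """Two half-sine segments joined at the trough, flanked by up-states.

    The negative half-wave crosses zero exactly at onset and
    onset + wave_duration with the trough at onset + falling_time.
    Positive Hann-shaped lobes of duration ``wave_duration / 2`` precede
    and follow it — the up states of the slow oscillation.  Their
    amplitudes are solved so the full waveform has zero area *and* zero
    first time-moment: its spectrum then vanishes quadratically at DC,
    which keeps sub-passband content small and lets the delta-band
    band-pass of the detector preserve the trough depth.
    """
    wave = np.zeros(n)
    t = np.arange(n) / sample_rate
    rel = t - spec.onset
    falling = (rel >= 0) & (rel < spec.falling_time)
    rising = (rel >= spec.falling_time) & (rel <= spec.wave_duration)
    rise_time = spec.wave_duration - spec.falling_time
    wave[falling] = -spec.amplitude * np.sin(0.5 * np.pi * rel[falling] / spec.falling_time)
    wave[rising] = -spec.amplitude * np.cos(
        0.5 * np.pi * (rel[rising] - spec.falling_time) / rise_time
    )
    neg = (rel >= 0) & (rel <= spec.wave_duration)
    lobe = spec.wave_duration / 2.0
    before = (rel >= -lobe) & (rel < 0)
    after = (rel > spec.wave_duration) & (rel <= spec.wave_duration + lobe)
    hann_before = 0.5 * (1.0 - np.cos(2.0 * np.pi * (-rel[before]) / lobe))
    hann_after = 0.5 * (
        1.0 - np.cos(2.0 * np.pi * (rel[after] - spec.wave_duration) / lobe)
    )
    # solve the two lobe amplitudes so that area and first moment cancel
    a0n = np.trapezoid(wave[neg], rel[neg])
    a1n = np.trapezoid(wave[neg] * rel[neg], rel[neg])
    a0b = np.trapezoid(hann_before, rel[before])
    a1b = np.trapezoid(hann_before * rel[before], rel[before])
    a0a = np.trapezoid(hann_after, rel[after])
    a1a = np.trapezoid(hann_after * rel[after], rel[after])
    try:
        amp_b, amp_a = np.linalg.solve([[a0b, a0a], [a1b, a1a]], [-a0n, -a1n])
    except np.linalg.LinAlgError:  # degenerate at very short waves
        amp_b = amp_a = -a0n / max(a0b + a0a, 1e-12)
    wave[before] = amp_b * hann_before
    wave[after] = amp_a * hann_after
    return wave


def generate_sleep_signal(
    waves: list[SlowWaveSpecSim],
    background: AperiodicSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sleep EEG: aperiodic background plus negative half-wave deflections.

    Each wave is placed on its target channel with a zero-sum spatial
    pattern (``-1/(C-1)`` on the other channels), emulating the zero-mean
    topography of a referenced source so that average re-referencing in
    the detector leaves the target-channel waveform intact.

    The truth table has columns ``channel, start_s, end_s, amplitude_uv,
    slope_uv_per_s, detectable``; waves whose zero-crossing separation
    falls outside 0.25–1 s are flagged ``detectable=False``.
    """
    # footprints include the flanking up-state lobes (half a duration each side)
    def _footprint(w: SlowWaveSpecSim) -> tuple[float, float]:
        lobe = w.wave_duration / 2.0
        return w.onset - lobe, w.onset + w.wave_duration + lobe

    for i, a in enumerate(waves):
        for b in waves[i + 1 :]:
            a0, a1 = _footprint(a)
            b0, b1 = _footprint(b)
            if a.channel == b.channel and a0 < b1 and b0 < a1:
                raise ValueError("invalid spec: overlapping slow waves on one channel")
    sig = generate_aperiodic_background(background)
    n_channels, n = sig.shape
    duration = n / background.sample_rate
    rows = []
    for w in waves:
        f0, f1 = _footprint(w)
        if f0 < 0 or f1 > duration:
            raise ValueError(
                f"slow wave at {w.onset:g}s (with up-state lobes) does not fit "
                f"in {duration:g}s recording"
            )
        if not 0 <= w.channel < n_channels:
            raise ValueError(f"slow wave channel {w.channel} out of range")
        wave = _slow_wave_waveform(w, background.sample_rate, n)
        if n_channels > 1:
            sig += wave[np.newaxis, :] * (-1.0 / (n_channels - 1))
            sig[w.channel] += wave * (1.0 + 1.0 / (n_channels - 1))
        else:
            sig[0] += wave
        rows.append(
            {
                "channel": w.channel,
                "start_s": w.onset,
                "end_s": w.onset + w.wave_duration,
                "amplitude_uv": w.amplitude,
                "slope_uv_per_s": w.slope,
                "detectable": w.detectable,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["channel", "start_s", "end_s", "amplitude_uv", "slope_uv_per_s", "detectable"],
    )
    return sig, truth


# ---------------------------------------------------------------------------
# Cohort-level measure tables


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of participants with nested sessions and task/time recordings.

    ``betas`` carries the fixed effects of the generating model
    ``measure ~ task + time * age + group + sex`` with time coded 0
    (evening) / 1 (morning), group 1 for adhd, sex 1 for male, and task
    offsets relative to the oddball reference.  Random intercepts for
    participant and session-within-participant are Gaussian with the
    stated standard deviations.
    """

    n_participants: int = 100
    sessions_per_participant: int = 2
    age_range: tuple[float, float] = (3.5, 24.7)
    betas: dict = field(
        default_factory=lambda: {
            "intercept": 25.0,
            "age": -0.8,
            "time": -4.0,
            "age_time": 0.14,
            "task": {"gonogo": 0.5, "alertness": 0.0, "fixation": -0.5},
            "group": -0.6,
            "sex": -1.5,
        }
    )
    sd_participant: float = 2.0
    sd_session: float = 1.0
    sd_residual: float = 3.0
    tasks: tuple = ("oddball", "gonogo")
    adhd_fraction: float = 0.36
    female_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("invalid spec: need at least 2 participants")
        if min(self.sd_participant, self.sd_session, self.sd_residual) < 0:
            raise ValueError("invalid spec: standard deviations must be >= 0")
        if self.sessions_per_participant < 1:
            raise ValueError("invalid spec: need at least 1 session")


def generate_measure_table(spec: CohortSpec, response: str = "measure") -> pd.DataFrame:
    """Long-format table, one row per recording.

    Each session contains one recording per (task, time) pair; the
    response is the linear predictor plus participant, session and
    residual Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.betas
    task_betas = b.get("task", {})
    rows = []
    for p in range(spec.n_participants):
        pid = f"P{p:03d}"
        age = rng.uniform(*spec.age_range)
        group = "adhd" if rng.random() < spec.adhd_fraction else "control"
        sex = "female" if rng.random() < spec.female_fraction else "male"
        u_p = rng.normal(0.0, spec.sd_participant)
        for s in range(spec.sessions_per_participant):
            sid = f"S{s + 1}"
            u_s = rng.normal(0.0, spec.sd_session)
            for task in spec.tasks:
                for time_label, time_code in (("evening", 0.0), ("morning", 1.0)):
                    mu = (
                        b["intercept"]
                        + b["age"] * age
                        + b["time"] * time_code
                        + b["age_time"] * age * time_code
                        + task_betas.get(task, 0.0)
                        + b["group"] * (group == "adhd")
                        + b["sex"] * (sex == "male")
                    )
                    y = mu + u_p + u_s + rng.normal(0.0, spec.sd_residual)
                    rows.append(
                        {
                            "participant": pid,
                            "session": sid,
                            "task": task,
                            "time": time_label,
                            "age": age,
                            "group": group,
                            "sex": sex,
                            response: y,
                        }
                    )
    return pd.DataFrame(rows)
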