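"""Cycle-by-cycle detection of oscillation bursts.

The signal is narrow-band filtered in overlapping 4-Hz-wide bands
(2-6, 4-8, ... 12-16 Hz).  Zero-crossings are taken from the narrowband
trace; extrema are then located in the broadband (0.5-40 Hz) trace
between crossings, and a *cycle* runs from one positive peak to the
next, through the trough between them.  Each cycle is scored on a set of
waveform-consistency criteria, all of which are ratios in [0, 1]:
amplitude itself is never thresholded, so detection is invariant to an
overall rescaling of the signal.  A *burst* is a maximal run of
consecutive cycles that jointly pass one of three criteria sets, with a
set-specific minimum run length; runs found by different sets or in
different bands are merged within a channel when they overlap in time
and agree in frequency to within 1 Hz.

Criterion scores (edge cycles use their single existing neighbor):

* ``period_consistency``   min over neighbors of min/max period ratio
* ``amplitude_consistency``  the same ratio on (decay+rise)/2 amplitude
* ``flank_consistency``    min(decay, rise) / max(decay, rise)
* ``shape_consistency``    waveforms resampled to 100 points and
  z-scored; mean over neighbors of the positive part of Pearson r
* ``monotonicity_time``    fraction of sample-to-sample steps moving in
  the flank direction (down on the decay, up on the rise)
* ``monotonicity_amplitude``  net directed change / total absolute
  change, averaged over the two flanks, floored at 0
* ``reversal_ratio``       1 minus the largest counter-direction
  excursion relative to the flank amplitude, worst flank, floored at 0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "Cycle",
    "CriteriaSet",
    "Burst",
    "DEFAULT_CRITERIA_SETS",
    "narrowband_decompose",
    "extract_cycles",
    "score_cycles",
    "detect_bursts",
    "burst_frequency",
]

# overlapping narrowband filter ranges: 4 Hz wide, stepped by 2 Hz
BANDS: list[tuple[float, float]] = [(2, 6), (4, 8), (6, 10), (8, 12), (10, 14), (12, 16)]

SCORE_NAMES = (
    "period_consistency",
    "amplitude_consistency",
    "flank_consistency",
    "shape_consistency",
    "monotonicity_time",
    "monotonicity_amplitude",
    "reversal_ratio",
)


@dataclass
class Cycle:
    """One oscillation cycle, positive peak to positive peak."""

    channel: int
    band: tuple[float, float]
    i_pos_start: int
    i_trough: int
    i_pos_end: int
    t_pos_start: float
    t_trough: float
    t_pos_end: float
    v_pos_start: float
    v_trough: float
    v_pos_end: float
    scores: dict = field(default_factory=dict)
    frequency_ok: bool = False

    @property
    def period(self) -> float:
        return self.t_pos_end - self.t_pos_start

    @property
    def decay_amp(self) -> float:
        return self.v_pos_start - self.v_trough

    @property
    def rise_amp(self) -> float:
        return self.v_pos_end - self.v_trough

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.decay_amp + self.rise_amp)


@dataclass(frozen=True)
class CriteriaSet:
    """Named thresholds applied jointly to every cycle of a candidate run."""

    name: str
    thresholds: dict
    min_cycles: int
    require_frequency: bool = False

    def __post_init__(self) -> None:
        for k, v in self.thresholds.items():
            if k not in SCORE_NAMES:
                raise ValueError(f"unknown criterion {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {k}={v} outside [0, 1]")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")

    def passes(self, cycle: Cycle) -> bool:
        if self.require_frequency and not cycle.frequency_ok:
            return False
        return all(cycle.scores[k] >= v for k, v in self.thresholds.items())


# the three detection criteria sets used as defaults: a many-criterion
# low-threshold set, a fewer-criterion set requiring longer runs, and a
# short-run set with strict monotonicity
DEFAULT_CRITERIA_SETS: list[CriteriaSet] = [
    CriteriaSet(
        name="set1",
        thresholds={
            "period_consistency": 0.5,
            "amplitude_consistency": 0.4,
            "flank_consistency": 0.5,
            "shape_consistency": 0.2,
            "monotonicity_time": 0.4,
            "monotonicity_amplitude": 0.4,
            "reversal_ratio": 0.6,
        },
        min_cycles=4,
        require_frequency=True,
    ),
    CriteriaSet(
        name="set2",
        thresholds={
            "period_consistency": 0.6,
            "amplitude_consistency": 0.6,
            "monotonicity_amplitude": 0.6,
            "flank_consistency": 0.6,
        },
        min_cycles=5,
    ),
    CriteriaSet(
        name="set3",
        thresholds={
            "period_consistency": 0.7,
            "flank_consistency": 0.3,
            "monotonicity_amplitude": 0.9,
        },
        min_cycles=3,
        require_frequency=True,
    ),
]


@dataclass
class Burst:
    """A run of accepted consecutive cycles in one channel."""

    channel: int
    cycles: list
    start: float
    end: float
    mean_frequency: float
    mean_amplitude: float
    criteria_set: str
    band: tuple[float, float] | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def narrowband_decompose(
    signal: np.ndarray,
    sample_rate: float,
    bands: list[tuple[float, float]] | None = None,
    transition_hz: float = 1.0,
) -> dict[tuple[float, float], np.ndarray]:
    """Zero-phase FIR band-pass outputs for the overlapping burst bands."""
    if sample_rate < 100:
        raise ValueError("sample_rate must be >= 100 Hz")
    bands = bands if bands is not None else BANDS
    x = np.asarray(signal, dtype=float)
    min_lo = min(lo for lo, _ in bands)
    min_duration = 10.0 / min_lo  # ten cycles of the slowest band
    if x.shape[-1] / sample_rate < min_duration:
        raise ValueError(f"signal shorter than {min_duration:g} s minimum for band filtering")
    numtaps = int(3.3 * sample_rate / transition_hz)
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    out = {}
    for lo, hi in bands:
        taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sample_rate)
        out[(lo, hi)] = sps.filtfilt(taps, [1.0], x, padlen=min(x.shape[-1] - 1, 3 * numtaps))
    return out


def extract_cycles(
    narrowband: np.ndarray,
    broadband: np.ndarray,
    sample_rate: float,
    band: tuple[float, float],
    channel: int = 0,
) -> list[Cycle]:
    """Assemble positive-peak-to-positive-peak cycles.

    Zero-crossings come from the narrowband trace; the trough between a
    falling and the next rising crossing, and the positive peaks between
    rising and falling crossings, are located in the broadband trace.
    """
    nb = np.asarray(narrowband, dtype=float)
    bb = np.asarray(broadband, dtype=float)
    if nb.shape != bb.shape:
        raise ValueError("narrowband and broadband signals must be aligned and equal length")
    pos = nb >= 0
    # crossing index = last sample before the sign change
    falling = np.flatnonzero(pos[:-1] & ~pos[1:])
    rising = np.flatnonzero(~pos[:-1] & pos[1:])
    events = sorted(
        [(int(i), "fall") for i in falling] + [(int(i), "rise") for i in rising]
    )
    if not events:
        return []
    # pseudo-crossings at the signal boundaries so the extremum before the
    # first and after the last crossing is usable (cycles = peaks - 1)
    events.insert(0, (-1, "rise" if events[0][1] == "fall" else "fall"))
    events.append((nb.size - 1, "rise" if events[-1][1] == "fall" else "fall"))
    def _refined_time(j: int) -> float:
        """Sub-sample extremum time by parabolic interpolation."""
        if j <= 0 or j >= bb.size - 1:
            return j / sample_rate
        y0, y1, y2 = bb[j - 1], bb[j], bb[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom == 0:
            return j / sample_rate
        shift = 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
        return (j + shift) / sample_rate

    peaks: list[int] = []
    sequence: list[tuple[int, str]] = []  # alternating extrema in time order
    for (i0, kind0), (i1, _kind1) in zip(events[:-1], events[1:]):
        lo, hi = i0 + 1, i1 + 1
        if hi <= lo:
            continue
        if kind0 == "rise":  # rising -> falling: a positive peak in between
            j = lo + int(np.argmax(bb[lo:hi]))
            peaks.append(j)
            sequence.append((j, "peak"))
        else:  # falling -> rising: a trough
            j = lo + int(np.argmin(bb[lo:hi]))
            sequence.append((j, "trough"))
    if len(peaks) < 2:
        return []
    cycles: list[Cycle] = []
    for k in range(len(sequence) - 2):
        (i_a, kind_a), (i_t, kind_t), (i_b, kind_b) = sequence[k : k + 3]
        if (kind_a, kind_t, kind_b) != ("peak", "trough", "peak"):
            continue
        t_a, t_t, t_b = _refined_time(i_a), _refined_time(i_t), _refined_time(i_b)
        period = t_b - t_a
        lo_f, hi_f = band
        # strict gate on the sub-sample period: every in-band cycle is at
        # least 1/hi_f long, so a burst can never be shorter than
        # min_cycles/hi_f seconds
        freq_ok = period > 0 and lo_f <= 1.0 / period <= hi_f
        cycles.append(
            Cycle(
                channel=channel,
                band=band,
                i_pos_start=i_a,
                i_trough=i_t,
                i_pos_end=i_b,
                t_pos_start=t_a,
                t_trough=t_t,
                t_pos_end=t_b,
                v_pos_start=float(bb[i_a]),
                v_trough=float(bb[i_t]),
                v_pos_end=float(bb[i_b]),
                frequency_ok=freq_ok,
            )
        )
    return cycles


def _ratio(a: float, b: float) -> float:
    hi = max(a, b)
    if hi <= 0:
        return 0.0
    return max(0.0, min(a, b) / hi)


def _flank_monotonicity_time(seg: np.ndarray, direction: int) -> tuple[int, int]:
    d = np.diff(seg)
    if d.size == 0:
        return 0, 0
    # zero steps are not counter-directional: monotone non-strictly
    return int(np.sum(d * direction >= 0)), d.size


def _flank_monotonicity_amplitude(seg: np.ndarray, direction: int) -> float:
    d = np.diff(seg)
    total = float(np.sum(np.abs(d)))
    if total == 0:
        return 0.0
    net = float(seg[-1] - seg[0]) * direction
    return max(0.0, net / total)


def _counter_excursion(seg: np.ndarray, direction: int) -> float:
    """Largest contiguous movement in ``direction`` within the flank."""
    v = seg * direction  # movement in `direction` is now a rise of v
    return float(np.max(v - np.minimum.accumulate(v)))


def _reversal_ratio_flank(seg: np.ndarray, direction: int) -> float:
    amp = abs(float(seg[-1] - seg[0]))
    if amp == 0:
        return 0.0
    exc = _counter_excursion(seg, -direction)
    return max(0.0, 1.0 - exc / amp)


def _resampled_shape(bb: np.ndarray, cycle: Cycle, n: int = 100) -> np.ndarray:
    seg = bb[cycle.i_pos_start : cycle.i_pos_end + 1]
    x_old = np.linspace(0.0, 1.0, seg.size)
    x_new = np.linspace(0.0, 1.0, n)
    resampled = np.interp(x_new, x_old, seg)
    sd = resampled.std()
    if sd == 0:
        return np.zeros(n)
    return (resampled - resampled.mean()) / sd


def score_cycles(
    cycles: list[Cycle],
    broadband: np.ndarray,
    sample_rate: float | None = None,
) -> list[Cycle]:
    """Fill every criterion score in place; returns the same list.

    Edge cycles use only their existing neighbor for the consistency
    scores; zero-amplitude cycles get 0 on all ratio-based scores.
    """
    if not cycles:
        raise ValueError("score_cycles requires at least one cycle")
    bb = np.asarray(broadband, dtype=float)
    shapes = [_resampled_shape(bb, c) for c in cycles]
    n = len(cycles)
    for i, c in enumerate(cycles):
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < n]
        if not neighbors:  # a lone cycle has no consistency evidence
            c.scores["period_consistency"] = 0.0
            c.scores["amplitude_consistency"] = 0.0
        else:
            c.scores["period_consistency"] = min(
                _ratio(c.period, cycles[j].period) for j in neighbors
            )
            c.scores["amplitude_consistency"] = min(
                _ratio(c.amplitude, cycles[j].amplitude) for j in neighbors
            )
        c.scores["flank_consistency"] = _ratio(c.decay_amp, c.rise_amp)
        corr = []
        for j in neighbors:
            if shapes[i].std() == 0 or shapes[j].std() == 0:
                corr.append(0.0)
            else:
                corr.append(max(0.0, float(np.corrcoef(shapes[i], shapes[j])[0, 1])))
        c.scores["shape_consistency"] = float(np.mean(corr)) if corr else 0.0
        decay_seg = bb[c.i_pos_start : c.i_trough + 1]
        rise_seg = bb[c.i_trough : c.i_pos_end + 1]
        good_d, tot_d = _flank_monotonicity_time(decay_seg, -1)
        good_r, tot_r = _flank_monotonicity_time(rise_seg, +1)
        c.scores["monotonicity_time"] = (
            (good_d + good_r) / (tot_d + tot_r) if (tot_d + tot_r) else 0.0
        )
        c.scores["monotonicity_amplitude"] = 0.5 * (
            _flank_monotonicity_amplitude(decay_seg, -1)
            + _flank_monotonicity_amplitude(rise_seg, +1)
        )
        c.scores["reversal_ratio"] = min(
            _reversal_ratio_flank(decay_seg, -1), _reversal_ratio_flank(rise_seg, +1)
        )
    return cycles


def burst_frequency(trough_times: np.ndarray) -> float:
    """Inverse of the mean distance between successive troughs."""
    t = np.sort(np.asarray(trough_times, dtype=float))
    if t.size < 2:
        raise ValueError("need at least 2 troughs to estimate burst frequency")
    return 1.0 / float(np.mean(np.diff(t)))


def _runs_to_bursts(
    cycles: list[Cycle], cset: CriteriaSet, channel: int, band
) -> list[Burst]:
    ok = [cset.passes(c) for c in cycles]
    bursts = []
    i = 0
    n = len(cycles)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        run = cycles[i : j + 1]
        if len(run) >= cset.min_cycles:
            troughs = np.array([c.t_trough for c in run])
            bursts.append(
                Burst(
                    channel=channel,
                    cycles=list(run),
                    start=run[0].t_pos_start,
                    end=run[-1].t_pos_end,
                    mean_frequency=burst_frequency(troughs),
                    mean_amplitude=float(np.mean([c.rise_amp for c in run])),
                    criteria_set=cset.name,
                    band=band,
                )
            )
        i = j + 1
    return bursts


def _merge_pair(a: Burst, b: Burst) -> Burst:
    cycles = list(a.cycles)
    seen = {round(c.t_trough, 9) for c in cycles}
    for c in b.cycles:
        if round(c.t_trough, 9) not in seen:
            cycles.append(c)
            seen.add(round(c.t_trough, 9))
    cycles.sort(key=lambda c: c.t_trough)
    troughs = np.array([c.t_trough for c in cycles])
    freq = burst_frequency(troughs) if troughs.size >= 2 else a.mean_frequency
    return Burst(
        channel=a.channel,
        cycles=cycles,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        mean_frequency=freq,
        mean_amplitude=float(np.mean([c.rise_amp for c in cycles])),
        criteria_set="+".join(
            sorted(set(a.criteria_set.split("+")) | set(b.criteria_set.split("+")))
        ),
        band=a.band if a.band == b.band else None,
    )


def merge_channel_bursts(bursts: list[Burst], freq_tol: float = 1.0) -> list[Burst]:
    """Merge same-channel bursts that overlap in time within ``freq_tol`` Hz."""
    pending = sorted(bursts, key=lambda b: (b.start, b.end))
    merged: list[Burst] = []
    while pending:
        cur = pending.pop(0)
        changed = True
        while changed:
            changed = False
            for k, other in enumerate(pending):
                overlap = min(cur.end, other.end) - max(cur.start, other.start)
                if overlap > 0 and abs(cur.mean_frequency - other.mean_frequency) <= freq_tol:
                    cur = _merge_pair(cur, other)
                    pending.pop(k)
                    changed = True
                    break
        merged.append(cur)
    return merged


def detect_bursts(
    scored_cycles_by_band: dict,
    criteria_sets: list[CriteriaSet] | None = None,
    channel: int = 0,
    merge: bool = True,
) -> list[Burst]:
    """Detect bursts for one channel.

    ``scored_cycles_by_band`` maps band -> time-ordered scored cycles.
    Each criteria set is applied independently to each band; qualifying
    runs become bursts, and bursts from different sets or bands that
    overlap in time within 1 Hz of frequency are merged (union interval,
    cycle lists united).  Amplitude is never thresholded.
    """
    criteria_sets = criteria_sets if criteria_sets is not None else DEFAULT_CRITERIA_SETS
    bursts: list[Burst] = []
    for band, cycles in scored_cycles_by_band.items():
        for cset in criteria_sets:
            bursts.extend(_runs_to_bursts(cycles, cset, channel, band))
    if merge:
        bursts = merge_channel_bursts(bursts)
    return sorted(bursts, key=lambda b: b.start)
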