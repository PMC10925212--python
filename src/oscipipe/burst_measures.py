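"""Burst clustering across channels and the two oscillation measures.

Bursts detected independently per channel are grouped into *clusters*
when they co-occur across channels at roughly the same frequency: two
bursts are related if their overlap covers at least 50% of the shorter
one and their frequencies are within 1 Hz; clusters are the connected
components of that relation.  Per-channel bursts feed topographic maps,
clusters feed global (channel-pooled) measures, so a burst spreading
across many channels is not counted once per channel.

Measures, per frequency band (theta 4-7, alpha 8-11, low-beta 12-16 Hz,
inclusive edges with 1-Hz gaps in between, plus the pooled 4-16 range):

* amplitude — mean trough-to-positive-peak voltage over every cycle of
  every in-band burst (uV); undefined (NaN) when no burst exists;
* density — summed burst duration as a percentage of the recording;
  pooling across bands sums durations, so pooled density can exceed
  100% when bursts of different frequencies co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst

__all__ = [
    "MEASURE_BANDS",
    "BurstCluster",
    "cluster_bursts",
    "band_of",
    "oscillation_amplitude",
    "oscillation_density",
    "pool_band_density",
    "measures_table",
]

MEASURE_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 11.0),
    "lowbeta": (12.0, 16.0),
}
POOLED_BAND = (4.0, 16.0)


@dataclass
class BurstCluster:
    """Cross-channel group of co-occurring, same-frequency bursts."""

    members: list
    start: float
    end: float
    frequency: float  # duration-weighted mean of member frequencies

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_channels(self) -> int:
        return len({b.channel for b in self.members})


def _related(a: Burst, b: Burst, min_overlap: float = 0.5, freq_tol: float = 1.0) -> bool:
    overlap = min(a.end, b.end) - max(a.start, b.start)
    shorter = min(a.duration, b.duration)
    if shorter <= 0:
        return False
    return overlap >= min_overlap * shorter and abs(a.mean_frequency - b.mean_frequency) <= freq_tol


def cluster_bursts(
    bursts: list[Burst], min_overlap: float = 0.5, freq_tol: float = 1.0
) -> list[BurstCluster]:
    """Connected components of the overlap/frequency relation."""
    n = len(bursts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: bursts[i].start)
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            if bursts[j].start > bursts[i].end:
                break
            if _related(bursts[i], bursts[j], min_overlap, freq_tol):
                parent[find(i)] = find(j)
    groups: dict[int, list[Burst]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(bursts[i])
    clusters = []
    for members in groups.values():
        durations = np.array([b.duration for b in members])
        freqs = np.array([b.mean_frequency for b in members])
        clusters.append(
            BurstCluster(
                members=members,
                start=min(b.start for b in members),
                end=max(b.end for b in members),
                frequency=float(np.average(freqs, weights=durations)),
            )
        )
    return sorted(clusters, key=lambda c: c.start)


def band_of(frequency: float) -> str | None:
    """Band label for a frequency, or None in the 7-8 / 11-12 Hz gaps."""
    for name, (lo, hi) in MEASURE_BANDS.items():
        if lo <= frequency <= hi:
            return name
    return None


def _in_band(freq: float, band: str | tuple[float, float]) -> bool:
    if band == "pooled":
        return band_of(freq) is not None
    if isinstance(band, str):
        lo, hi = MEASURE_BANDS[band]
    else:
        lo, hi = band
    return lo <= freq <= hi


def oscillation_amplitude(bursts: list[Burst], band: str | tuple[float, float]) -> float:
    """Mean trough-to-positive-peak voltage of all in-band burst cycles.

    Returns NaN (undefined) when no in-band burst exists.  For the
    pooled measure, bursts falling in the inter-band gaps contribute to
    no band.
    """
    amps = [
        c.rise_amp
        for b in bursts
        if _in_band(b.mean_frequency, band)
        for c in b.cycles
    ]
    if not amps:
        return float("nan")
    return float(np.mean(amps))


def oscillation_density(
    bursts_or_clusters: list,
    band: str | tuple[float, float],
    recording_duration: float,
) -> float:
    """Summed in-band burst duration as a percentage of the recording."""
    if recording_duration <= 0:
        raise ValueError("recording_duration must be > 0")
    freq_of = lambda item: item.frequency if isinstance(item, BurstCluster) else item.mean_frequency
    total = sum(
        item.duration for item in bursts_or_clusters if _in_band(freq_of(item), band)
    )
    return 100.0 * total / recording_duration


def pool_band_density(bursts_or_clusters: list, recording_duration: float) -> float:
    """Pooled 4-16 Hz density: durations summed over every in-band burst.

    Bands are pooled, not averaged; a burst is counted once, in the one
    band containing its frequency, and co-occurring bursts of different
    frequencies can push the pooled density past 100%.
    """
    return oscillation_density(bursts_or_clusters, "pooled", recording_duration)


def measures_table(
    bursts_by_channel: dict[int, list],
    clusters: list,
    recording_duration: float,
    recording_id: str = "rec",
) -> pd.DataFrame:
    """Long table of amplitude/density per scope (channel or global) and band."""
    rows = []
    band_keys = list(MEASURE_BANDS) + ["pooled"]
    for ch, bursts in sorted(bursts_by_channel.items()):
        for band in band_keys:
            rows.append(
                {
                    "recording_id": recording_id,
                    "scope": str(ch),
                    "band": band,
                    "amplitude_uv": oscillation_amplitude(bursts, band),
                    "density_pct": oscillation_density(bursts, band, recording_duration),
                    "n_bursts": sum(_in_band(b.mean_frequency, band) for b in bursts),
                }
            )
    all_member_bursts = [b for c in clusters for b in c.members]
    for band in band_keys:
        rows.append(
            {
                "recording_id": recording_id,
                "scope": "global",
                "band": band,
                "amplitude_uv": oscillation_amplitude(all_member_bursts, band),
                "density_pct": oscillation_density(clusters, band, recording_duration),
                "n_bursts": sum(_in_band(c.frequency, band) for c in clusters),
            }
        )
    return pd.DataFrame(rows)
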