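"""Automated gross-artifact heuristics and recording quality gate.

Recordings are screened in 3-second segments per channel.  A segment is
a *major* artifact if its absolute voltage exceeds 500 uV, *minor* if its
best absolute Pearson correlation with the topological neighbor channels
in the same segment is below .3, and *flat* if it has zero variance
(correlation is undefined there; flats are treated as minor during
resolution).  Majors are eliminated first, each by removing either the
whole channel or the whole 3-s segment, whichever destroys less clean
data; minors are then removed greedily until every remaining channel and
segment carries at most 30% minor cells.

A separate screen rejects externally computed decomposition components
whose aperiodic exponent over 8-30 Hz is shallower than 0.5 (near-flat
spectra reflect muscle or non-physiological noise).

The final gate drops residual cells still exceeding 140 uV and fails the
recording if more than 25 channels were removed or less than one minute
of clean data survives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import FitSettings, PowerSpectrum, fit_aperiodic_and_peaks

__all__ = [
    "ArtifactConfig",
    "ArtifactMask",
    "ComponentSpectrum",
    "GateResult",
    "EmptyRecordingError",
    "detect_gross_artifacts",
    "resolve_artifacts",
    "screen_components_by_exponent",
    "final_quality_gate",
]

logger = logging.getLogger(__name__)

CLEAN, MINOR, MAJOR, FLAT = 0, 1, 2, 3
_LABELS = {CLEAN: "clean", MINOR: "minor", MAJOR: "major", FLAT: "flat"}


class EmptyRecordingError(RuntimeError):
    """Raised when artifact resolution would remove the entire recording."""


@dataclass(frozen=True)
class ArtifactConfig:
    major_uv: float = 500.0
    minor_corr: float = 0.3
    minor_frac: float = 0.30
    residual_uv: float = 140.0
    max_removed_channels: int = 25
    min_clean_s: float = 60.0
    exponent_floor: float = 0.5
    segment_s: float = 3.0


@dataclass
class ArtifactMask:
    """Grid of artifact labels indexed by (channel, 3-s segment)."""

    labels: np.ndarray  # int codes, shape (n_channels, n_segments)
    segment_s: float = 3.0
    removed_channels: set = field(default_factory=set)
    removed_segments: set = field(default_factory=set)

    @property
    def n_channels(self) -> int:
        return self.labels.shape[0]

    @property
    def n_segments(self) -> int:
        return self.labels.shape[1]

    def kept_channels(self) -> np.ndarray:
        return np.array([c for c in range(self.n_channels) if c not in self.removed_channels])

    def kept_segments(self) -> np.ndarray:
        return np.array([s for s in range(self.n_segments) if s not in self.removed_segments])

    def to_dataframe(self) -> pd.DataFrame:
        ch, seg = np.meshgrid(
            np.arange(self.n_channels), np.arange(self.n_segments), indexing="ij"
        )
        return pd.DataFrame(
            {
                "channel": ch.ravel(),
                "segment_index": seg.ravel(),
                "label": [_LABELS[v] for v in self.labels.ravel()],
            }
        )


@dataclass
class ComponentSpectrum:
    """Log-power spectrum of one externally computed decomposition component."""

    frequencies: np.ndarray
    log_power: np.ndarray
    component_id: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.log_power = np.asarray(self.log_power, dtype=float)
        if self.frequencies[0] > 8.0 or self.frequencies[-1] < 30.0:
            raise ValueError("component spectrum must cover at least 8-30 Hz")


def detect_gross_artifacts(
    eeg: np.ndarray,
    sample_rate: float,
    neighbor_map: dict,
    config: ArtifactConfig | None = None,
) -> ArtifactMask:
    """Label every (channel, 3-s segment) cell of a 1-40 Hz filtered recording.

    ``neighbor_map`` maps each channel index to its topological neighbors
    and must cover all channels.  The trailing partial segment, if any,
    is dropped.
    """
    config = config or ArtifactConfig()
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    n_channels, n = eeg.shape
    if n_channels < 2:
        raise ValueError("artifact detection requires at least 2 channels")
    missing = [c for c in range(n_channels) if c not in neighbor_map]
    if missing:
        raise ValueError(f"neighbor_map does not cover channels {missing}")
    seg_len = int(round(config.segment_s * sample_rate))
    n_segments = n // seg_len
    if n % seg_len:
        logger.info(
            "dropping trailing partial segment of %.2f s", (n % seg_len) / sample_rate
        )
    labels = np.full((n_channels, n_segments), CLEAN, dtype=np.int8)
    for s in range(n_segments):
        chunk = eeg[:, s * seg_len : (s + 1) * seg_len]
        sd = chunk.std(axis=1)
        for c in range(n_channels):
            if np.max(np.abs(chunk[c])) > config.major_uv:
                labels[c, s] = MAJOR
            elif sd[c] == 0.0:
                labels[c, s] = FLAT
            else:
                neighbors = [nb for nb in neighbor_map[c] if sd[nb] > 0.0]
                if not neighbors:
                    labels[c, s] = MINOR
                    continue
                best = max(
                    abs(float(np.corrcoef(chunk[c], chunk[nb])[0, 1])) for nb in neighbors
                )
                if best < config.minor_corr:
                    labels[c, s] = MINOR
    return ArtifactMask(labels, segment_s=config.segment_s)


def _clean_cost_channel(labels, kept_ch, kept_seg, c) -> int:
    return int(np.sum(labels[c, list(kept_seg)] == CLEAN))


def _clean_cost_segment(labels, kept_ch, kept_seg, s) -> int:
    return int(np.sum(labels[list(kept_ch), s] == CLEAN))


def resolve_artifacts(
    mask: ArtifactMask, config: ArtifactConfig | None = None
) -> tuple[set, set, ArtifactMask]:
    """Remove channels/segments until the mask satisfies the minor budget.

    Majors first: each is eliminated by removing its whole channel or
    whole segment, whichever destroys fewer clean cells (ties prefer the
    segment, preserving spatial coverage).  Then channels or segments
    with the most minor cells are removed greedily — picking whichever
    removal clears more minor cells per clean cell destroyed — until all
    remaining channels and segments have at most ``minor_frac`` minor
    cells.  Flat cells count as minor.
    """
    config = config or ArtifactConfig()
    labels = mask.labels.copy()
    kept_ch = set(range(mask.n_channels))
    kept_seg = set(range(mask.n_segments))
    removed_ch: set = set()
    removed_seg: set = set()

    def _check_nonempty():
        if not kept_ch or not kept_seg:
            raise EmptyRecordingError("artifact resolution removed the entire recording")

    # phase 1: majors
    while True:
        _check_nonempty()
        majors = [
            (c, s) for c in kept_ch for s in kept_seg if labels[c, s] == MAJOR
        ]
        if not majors:
            break
        c, s = majors[0]
        cost_ch = _clean_cost_channel(labels, kept_ch, kept_seg, c)
        cost_seg = _clean_cost_segment(labels, kept_ch, kept_seg, s)
        if cost_ch < cost_seg:
            kept_ch.discard(c)
            removed_ch.add(c)
        else:
            kept_seg.discard(s)
            removed_seg.add(s)

    # phase 2: minors (flat counts as minor)
    def _minorish(block) -> np.ndarray:
        return (block == MINOR) | (block == FLAT)

    while True:
        _check_nonempty()
        ch_idx = sorted(kept_ch)
        seg_idx = sorted(kept_seg)
        sub = labels[np.ix_(ch_idx, seg_idx)]
        m = _minorish(sub)
        ch_frac = m.mean(axis=1)
        seg_frac = m.mean(axis=0)
        if ch_frac.max(initial=0.0) <= config.minor_frac and seg_frac.max(
            initial=0.0
        ) <= config.minor_frac:
            break
        ch_counts = m.sum(axis=1)
        seg_counts = m.sum(axis=0)
        ci = int(np.argmax(ch_counts))
        si = int(np.argmax(seg_counts))
        clean_ch = int(np.sum(sub[ci] == CLEAN))
        clean_seg = int(np.sum(sub[:, si] == CLEAN))
        # minor cells cleared per clean cell destroyed; +1 avoids div-by-zero
        gain_ch = ch_counts[ci] / (clean_ch + 1)
        gain_seg = seg_counts[si] / (clean_seg + 1)
        if gain_ch > gain_seg:
            c = ch_idx[ci]
            kept_ch.discard(c)
            removed_ch.add(c)
        else:  # tie prefers the segment
            s = seg_idx[si]
            kept_seg.discard(s)
            removed_seg.add(s)

    out = ArtifactMask(
        labels,
        segment_s=mask.segment_s,
        removed_channels=removed_ch,
        removed_segments=removed_seg,
    )
    return removed_ch, removed_seg, out


def screen_components_by_exponent(
    components: list[ComponentSpectrum],
    exponent_floor: float = 0.5,
) -> list[bool]:
    """Keep flags for decomposition components, by aperiodic exponent.

    The aperiodic model is fitted on 8-30 Hz; a component is rejected iff
    its exponent is strictly shallower than ``exponent_floor`` (an
    exactly-0.5 exponent is kept).  A failed fit rejects the component.
    """
    keep = []
    for comp in components:
        try:
            spectrum = PowerSpectrum(comp.frequencies, 10.0**comp.log_power)
            fit = fit_aperiodic_and_peaks(spectrum, f_range=(8.0, 30.0), settings=FitSettings())
        except Exception as exc:  # fit failure rejects, with reason
            logger.warning("component %s rejected: fit failed (%s)", comp.component_id, exc)
            keep.append(False)
            continue
        keep.append(bool(fit.exponent >= exponent_floor))
    return keep


@dataclass
class GateResult:
    passed: bool
    n_removed_channels: int
    clean_duration_s: float
    residual_cells_removed: int
    mask: ArtifactMask

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "n_removed_channels": self.n_removed_channels,
                "clean_duration_s": self.clean_duration_s,
                "residual_cells_removed": self.residual_cells_removed,
            }
        )


def final_quality_gate(
    eeg: np.ndarray,
    sample_rate: float,
    mask: ArtifactMask,
    config: ArtifactConfig | None = None,
) -> GateResult:
    """Second-pass amplitude sweep and the recording-level pass/fail gate.

    Remaining cells whose absolute voltage still exceeds ``residual_uv``
    are removed (labelled major in the returned mask; a channel losing
    all its cells counts as removed).  The recording fails iff more than
    ``max_removed_channels`` channels were removed in total or fewer than
    ``min_clean_s`` seconds of segments survive.
    """
    config = config or ArtifactConfig()
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    labels = mask.labels.copy()
    seg_len = int(round(mask.segment_s * sample_rate))
    kept_ch = set(range(mask.n_channels)) - set(mask.removed_channels)
    kept_seg = set(range(mask.n_segments)) - set(mask.removed_segments)
    n_residual = 0
    for c in sorted(kept_ch):
        for s in sorted(kept_seg):
            chunk = eeg[c, s * seg_len : (s + 1) * seg_len]
            if chunk.size and np.max(np.abs(chunk)) > config.residual_uv:
                labels[c, s] = MAJOR
                n_residual += 1
    removed_ch = set(mask.removed_channels)
    for c in sorted(kept_ch):
        if kept_seg and all(labels[c, s] == MAJOR for s in kept_seg):
            removed_ch.add(c)
    out = ArtifactMask(
        labels,
        segment_s=mask.segment_s,
        removed_channels=removed_ch,
        removed_segments=set(mask.removed_segments),
    )
    clean_duration = len(kept_seg) * mask.segment_s
    passed = (
        len(removed_ch) <= config.max_removed_channels
        and clean_duration >= config.min_clean_s
    )
    return GateResult(
        passed=bool(passed),
        n_removed_channels=len(removed_ch),
        clean_duration_s=float(clean_duration),
        residual_cells_removed=n_residual,
        mask=out,
    )
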