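"""Run configuration, I/O, and stage orchestration.

Ties the stages into reproducible runs: preprocessing filter chain,
artifact rejection, burst detection and measures, spectral measures,
slow waves, and the statistics layer.  Every run can write a manifest
(config hash, seed, package version, input checksums) so identical
manifests imply identical outputs.

Recordings are read either from EDF (via :mod:`mne`, if installed) or
from a raw float32 array with a JSON sidecar
``{sample_rate, channel_names, seed, truth_path}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from . import __version__
from .artifacts import (
    ArtifactConfig,
    EmptyRecordingError,
    GateResult,
    detect_gross_artifacts,
    final_quality_gate,
    resolve_artifacts,
)
from .burst_measures import cluster_bursts, measures_table
from .bursts import (
    DEFAULT_CRITERIA_SETS,
    detect_bursts,
    extract_cycles,
    narrowband_decompose,
    score_cycles,
)
from .slow_waves import (
    detect_slow_waves,
    filter_sleep_eeg,
    match_waves_by_amplitude,
    summarize_slow_waves,
    waves_to_table,
)
from .spectral import (
    FitSettings,
    band_log_power,
    fit_aperiodic_and_peaks,
    periodic_power,
    smooth_spectrum,
    welch_psd,
)

__all__ = [
    "FilterChainConfig",
    "RunConfig",
    "preprocess_raw",
    "detection_filter",
    "run_wake_recording",
    "run_sleep_recording",
    "run_stats",
    "save_recording",
    "load_recording",
    "write_manifest",
    "write_channel_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterChainConfig:
    """The standard preprocessing chain: mean-center, 40 Hz lowpass,
    notch, downsample to 250 Hz, 0.5 Hz Kaiser highpass."""

    lowpass_hz: float = 40.0
    lowpass_transition_hz: float = 10.0
    notch_hz: float = 50.0
    notch_harmonics: bool = True
    target_rate: float = 250.0
    highpass_hz: float = 0.5
    highpass_stopband_hz: float = 0.25
    highpass_attenuation_db: float = 60.0
    highpass_ripple: float = 0.05


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults carry the standard values."""

    seed: int = 0
    filter_chain: FilterChainConfig = field(default_factory=FilterChainConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    spectral: FitSettings = field(default_factory=FitSettings)
    spectral_fit_range: tuple[float, float] = (2.0, 35.0)
    measure_band: tuple[float, float] = (4.0, 16.0)
    slow_wave_match_tolerance: float = 0.10
    edge_channels: tuple[int, ...] = ()
    output_dir: str = "."

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = dict(raw)
        if "filter_chain" in kwargs:
            kwargs["filter_chain"] = FilterChainConfig(**kwargs["filter_chain"])
        if "artifacts" in kwargs:
            kwargs["artifacts"] = ArtifactConfig(**kwargs["artifacts"])
        if "spectral" in kwargs:
            sp = dict(kwargs["spectral"])
            if "peak_width_limits" in sp:
                sp["peak_width_limits"] = tuple(sp["peak_width_limits"])
            kwargs["spectral"] = FitSettings(**sp)
        for key in ("spectral_fit_range", "measure_band", "edge_channels"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _fir_lowpass(x: np.ndarray, fs: float, cutoff: float, transition: float) -> np.ndarray:
    numtaps = int(3.3 * fs / transition)
    numtaps += 1 - numtaps % 2
    taps = sps.firwin(numtaps, cutoff, fs=fs)
    return sps.filtfilt(taps, [1.0], x, padlen=min(x.shape[-1] - 1, 3 * numtaps))


def _notch(x: np.ndarray, fs: float, base: float, harmonics: bool) -> np.ndarray:
    freqs = [base]
    if harmonics:
        k = 2
        while k * base < 0.9 * fs / 2:
            freqs.append(k * base)
            k += 1
    for f0 in freqs:
        b, a = sps.iirnotch(f0, Q=30.0, fs=fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    return x


def preprocess_raw(
    eeg: np.ndarray, sample_rate: float, config: FilterChainConfig | None = None
) -> tuple[np.ndarray, float]:
    """Mean-center, lowpass, notch, downsample, Kaiser highpass."""
    config = config or FilterChainConfig()
    x = np.atleast_2d(np.asarray(eeg, dtype=float))
    x = x - x.mean(axis=-1, keepdims=True)
    fs = float(sample_rate)
    x = _fir_lowpass(x, fs, config.lowpass_hz, config.lowpass_transition_hz)
    if config.notch_hz and config.notch_hz < 0.9 * fs / 2:
        x = _notch(x, fs, config.notch_hz, config.notch_harmonics)
    if fs != config.target_rate:
        up, down = (int(config.target_rate), int(fs))
        g = np.gcd(up, down)
        x = sps.resample_poly(x, up // g, down // g, axis=-1)
        fs = config.target_rate
    # Kaiser highpass: passband edge at highpass_hz, stopband at
    # highpass_stopband_hz with the configured attenuation/ripple
    width = (config.highpass_hz - config.highpass_stopband_hz) / (fs / 2)
    atten = max(
        config.highpass_attenuation_db, -20 * np.log10(config.highpass_ripple)
    )
    numtaps, beta = sps.kaiserord(atten, width)
    numtaps += 1 - numtaps % 2
    cutoff = (config.highpass_hz + config.highpass_stopband_hz) / 2
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), pass_zero=False, fs=fs)
    x = sps.filtfilt(taps, [1.0], x, padlen=min(x.shape[-1] - 1, 3 * numtaps))
    return x, fs


def detection_filter(eeg: np.ndarray, sample_rate: float) -> np.ndarray:
    """1-40 Hz band-pass used only for gross-artifact detection."""
    x = np.atleast_2d(np.asarray(eeg, dtype=float))
    numtaps = int(3.3 * sample_rate / 1.0)
    numtaps += 1 - numtaps % 2
    taps = sps.firwin(numtaps, [1.0, 40.0], pass_zero=False, fs=sample_rate)
    return sps.filtfilt(taps, [1.0], x, padlen=min(x.shape[-1] - 1, 3 * numtaps))


def _splice_segments(eeg: np.ndarray, sample_rate: float, mask) -> np.ndarray:
    if not mask.removed_segments:
        return eeg
    seg_len = int(round(mask.segment_s * sample_rate))
    keep = [s for s in range(mask.n_segments) if s not in mask.removed_segments]
    parts = [eeg[:, s * seg_len : (s + 1) * seg_len] for s in keep]
    return np.concatenate(parts, axis=-1) if parts else eeg[:, :0]


def run_wake_recording(
    eeg: np.ndarray,
    sample_rate: float,
    neighbor_map: dict,
    config: RunConfig | None = None,
    recording_id: str = "rec",
    preprocessed: bool = False,
) -> dict:
    """Full wake analysis of one recording.

    Returns a dict with the gate result, per-channel burst lists,
    clusters, the per-band measures table, the spectral fit, and a
    single channel-averaged summary row (or ``None`` if the recording
    fails the quality gate).
    """
    config = config or RunConfig()
    x = np.atleast_2d(np.asarray(eeg, dtype=float))
    fs = float(sample_rate)
    if not preprocessed:
        x, fs = preprocess_raw(x, fs, config.filter_chain)
    det = detection_filter(x, fs)
    mask = detect_gross_artifacts(det, fs, neighbor_map, config.artifacts)
    try:
        _, _, resolved = resolve_artifacts(mask, config.artifacts)
    except EmptyRecordingError:
        logger.warning("recording %s had no clean data; skipped", recording_id)
        mask.removed_channels = set(range(mask.n_channels))
        mask.removed_segments = set(range(mask.n_segments))
        gate = GateResult(
            passed=False,
            n_removed_channels=mask.n_channels,
            clean_duration_s=0.0,
            residual_cells_removed=0,
            mask=mask,
        )
        return {"gate": gate, "summary_row": None}
    gate = final_quality_gate(x, fs, resolved, config.artifacts)
    if not gate.passed:
        logger.warning("recording %s failed the quality gate; skipped", recording_id)
        return {"gate": gate, "summary_row": None}
    clean = _splice_segments(x, fs, gate.mask)
    kept_ch = [c for c in range(x.shape[0]) if c not in gate.mask.removed_channels]
    clean = clean[kept_ch]
    duration = clean.shape[-1] / fs

    bursts_by_channel: dict[int, list] = {}
    for row, ch in enumerate(kept_ch):
        bands = narrowband_decompose(clean[row], fs)
        scored = {}
        for band, nb in bands.items():
            cycles = extract_cycles(nb, clean[row], fs, band, channel=ch)
            if cycles:
                scored[band] = score_cycles(cycles, clean[row])
        bursts_by_channel[ch] = detect_bursts(scored, DEFAULT_CRITERIA_SETS, channel=ch)
    all_bursts = [b for bs in bursts_by_channel.values() for b in bs]
    clusters = cluster_bursts(all_bursts)
    measures = measures_table(bursts_by_channel, clusters, duration, recording_id)

    non_edge = [i for i, ch in enumerate(kept_ch) if ch not in config.edge_channels]
    spectrum = welch_psd(clean[non_edge], fs).mean_channels()
    smoothed = smooth_spectrum(spectrum)
    fit = fit_aperiodic_and_peaks(smoothed, config.spectral_fit_range, config.spectral)
    g = measures[(measures["scope"] == "global") & (measures["band"] == "pooled")].iloc[0]
    summary_row = {
        "recording_id": recording_id,
        "amplitude": float(g["amplitude_uv"]),
        "density": float(g["density_pct"]),
        "exponent": fit.exponent,
        "offset": fit.offset,
        "power": band_log_power(smoothed, config.measure_band),
        "periodic_power": periodic_power(smoothed, fit, config.measure_band),
        "fit_r_squared": fit.r_squared,
        "fit_mae": fit.mae,
        "clean_duration_s": duration,
    }
    return {
        "gate": gate,
        "bursts_by_channel": bursts_by_channel,
        "clusters": clusters,
        "measures": measures,
        "spectral_fit": fit,
        "spectrum": smoothed,
        "summary_row": summary_row,
    }


def run_sleep_recording(
    eeg: np.ndarray,
    sample_rate: float,
    first_hour: list[tuple[float, float]],
    last_hour: list[tuple[float, float]],
    config: RunConfig | None = None,
) -> dict:
    """Slow-wave detection, amplitude matching, and hour summaries."""
    config = config or RunConfig()
    filtered = filter_sleep_eeg(eeg, sample_rate)
    waves_first = detect_slow_waves(filtered, sample_rate, first_hour, hour_label="first")
    waves_last = detect_slow_waves(filtered, sample_rate, last_hour, hour_label="last")
    waves = waves_first + waves_last
    if waves_first and waves_last:
        pairs, matched_fraction = match_waves_by_amplitude(
            waves_first, waves_last, config.slow_wave_match_tolerance
        )
    else:
        pairs, matched_fraction = [], float("nan")
    return {
        "waves": waves,
        "pairs": pairs,
        "matched_fraction": matched_fraction,
        "table": waves_to_table(waves, pairs),
        "summary": summarize_slow_waves(waves, pairs),
    }


def run_stats(table: pd.DataFrame, responses: list[str], config: RunConfig | None = None) -> dict:
    """The statistics layer over a MeasureTable: one mixed model and one
    set of age correlations per response column."""
    from .stats import fit_lmm, pearson_by_age

    required = {"participant", "session", "task", "time", "age"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"MeasureTable missing required columns: {sorted(missing)}")
    out = {}
    for resp in responses:
        if resp not in table.columns:
            raise ValueError(f"MeasureTable missing measure column: {resp}")
        fixed = ["task", "time * age"]
        if "group" in table.columns:
            fixed.append("group")
        if "sex" in table.columns:
            fixed.append("sex")
        out[resp] = {
            "lmm": fit_lmm(table, resp, fixed_terms=fixed),
            "pearson": pearson_by_age(table, resp),
        }
    return out


# ---------------------------------------------------------------------------
# I/O


def save_recording(
    prefix: str | Path,
    signal: np.ndarray,
    sample_rate: float,
    channel_names: list[str] | None = None,
    seed: int | None = None,
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write a float32 raw array plus JSON sidecar (and optional truth CSV)."""
    prefix = Path(prefix)
    x = np.atleast_2d(np.asarray(signal, dtype=np.float32))
    bin_path = prefix.with_suffix(".bin")
    x.tofile(bin_path)
    truth_path = None
    if truth is not None:
        truth_path = prefix.with_name(prefix.name + "_truth.csv")
        truth.to_csv(truth_path, index=False)
    sidecar = {
        "sample_rate": sample_rate,
        "n_channels": int(x.shape[0]),
        "n_samples": int(x.shape[1]),
        "channel_names": channel_names or [f"ch{i}" for i in range(x.shape[0])],
        "seed": seed,
        "truth_path": truth_path.name if truth_path else None,
        "units": "uV",
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    return json_path


def load_recording(path: str | Path) -> tuple[np.ndarray, float, dict]:
    """Read an EDF file or a JSON-sidecar raw recording."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, EDF input only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data() * 1e6, float(raw.info["sfreq"]), {
            "channel_names": raw.ch_names
        }
    meta = json.loads(path.read_text())
    x = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
    x = x.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return x, float(meta["sample_rate"]), meta


def write_manifest(
    out_dir: str | Path, config: RunConfig, input_paths: list[str | Path] | None = None
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for p in input_paths or []:
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "input_checksums": checksums,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_channel_map(path: str | Path, values_by_channel: dict) -> Path:
    """Minimal channel-value map: a two-column CSV for topographic plotting."""
    path = Path(path)
    pd.DataFrame(
        {"channel": list(values_by_channel), "value": list(values_by_channel.values())}
    ).to_csv(path, index=False)
    return path
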