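"""Welch spectra and aperiodic / periodic spectral decomposition.

The EEG power spectrum is modelled as the sum (in log10 space) of an
aperiodic component ``log10 P(f) = offset - exponent * log10 f`` — a line
on log-log axes — and a set of Gaussian peaks riding on top of it.  The
offset is the log10 power of the aperiodic line at 1 Hz; the exponent is
the ``x`` of a ``1/f^x`` power law, so positive exponents describe a
downward-sloping spectrum and larger values a steeper one.

Four scalar measures are derived per spectrum:

* ``offset`` and ``exponent`` of the aperiodic fit (2–35 Hz),
* band log-power: mean log10 power over 4–16 Hz,
* periodic power: mean log10 power over 4–16 Hz after subtracting the
  aperiodic line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

__all__ = [
    "PowerSpectrum",
    "SpectralFit",
    "FitSettings",
    "welch_psd",
    "smooth_spectrum",
    "fit_aperiodic_and_peaks",
    "band_log_power",
    "periodic_power",
]

# power values below this floor (uV^2/Hz) are clipped before log10
_POWER_FLOOR = 1e-20


@dataclass
class PowerSpectrum:
    """One-sided power spectral density.

    ``power`` is linear (uV^2/Hz); shape is ``(n_freqs,)`` for a single
    channel or ``(n_channels, n_freqs)`` for a multichannel spectrum.
    """

    frequencies: np.ndarray
    power: np.ndarray
    scope: str = "channel"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.ndim != 1:
            raise ValueError("frequencies must be 1-D")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.power.shape[-1] != self.frequencies.size:
            raise ValueError("power and frequencies length mismatch")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(np.maximum(self.power, _POWER_FLOOR))

    def mean_channels(self) -> "PowerSpectrum":
        """Average linear power over channels (no-op on 1-D spectra)."""
        if self.power.ndim == 1:
            return self
        return PowerSpectrum(self.frequencies, self.power.mean(axis=0), scope="global")


@dataclass
class FitSettings:
    """Settings of the aperiodic + peaks fit.

    ``peak_width_limits`` bounds the full width (2 sigma) of each Gaussian
    in Hz; ``peak_threshold`` is in units of the flattened spectrum's
    standard deviation; ``robust_quantile`` is the fraction of
    lowest-residual points kept for the final aperiodic refit.
    """

    peak_width_limits: tuple[float, float] = (0.5, 12.0)
    max_n_peaks: int = 40  # effectively unlimited for EEG spectra
    min_peak_height: float = 0.0
    peak_threshold: float = 2.0
    robust_quantile: float = 0.5


@dataclass
class SpectralFit:
    """Aperiodic line, Gaussian peaks and fit quality for one spectrum."""

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    r_squared: float = np.nan
    mae: float = np.nan
    f_range: tuple[float, float] = (2.0, 35.0)

    def aperiodic_log_power(self, frequencies: np.ndarray) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        return self.offset - self.exponent * np.log10(f)

    def model_log_power(self, frequencies: np.ndarray) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        model = self.aperiodic_log_power(f)
        for center, height, width in self.peaks:
            model = model + height * np.exp(-((f - center) ** 2) / (2.0 * width**2))
        return model


def welch_psd(signal: np.ndarray, sample_rate: float, window_s: float = 4.0) -> PowerSpectrum:
    """Welch PSD with Hann windows of ``window_s`` seconds and 50% overlap.

    Requires at least two windows (8 s at the default); frequency
    resolution is ``1 / window_s`` (0.25 Hz at the default).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    nperseg = int(round(window_s * sample_rate))
    min_s = 2 * window_s
    if n < 2 * nperseg:
        raise ValueError(
            f"signal too short for Welch PSD: need at least {min_s:g} s "
            f"({2 * nperseg} samples), got {n / sample_rate:g} s"
        )
    freqs, pxx = sps.welch(
        x, fs=sample_rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    scope = "channel" if x.ndim == 1 else "multichannel"
    return PowerSpectrum(freqs, pxx, scope=scope)


def smooth_spectrum(spectrum: PowerSpectrum, window_hz: float = 2.0) -> PowerSpectrum:
    """Centered moving average of log10 power over ``window_hz``.

    Endpoints shrink the window symmetrically so the smoother has no
    phase shift and leaves a linear (in bin index) log-spectrum unchanged
    in the interior.
    """
    df = float(np.median(np.diff(spectrum.frequencies)))
    if window_hz < df:
        raise ValueError("smoothing window narrower than frequency resolution")
    half = int(round(window_hz / df / 2.0))
    logp = np.atleast_2d(spectrum.log_power)
    out = np.empty_like(logp)
    n = logp.shape[-1]
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[:, i] = logp[:, i - h : i + h + 1].mean(axis=-1)
    smoothed = 10.0 ** (out if spectrum.power.ndim > 1 else out[0])
    return PowerSpectrum(spectrum.frequencies, smoothed, scope=spectrum.scope)


def _gaussian(f: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * width**2))


def _linfit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return intercept, slope


def fit_aperiodic_and_peaks(
    spectrum: PowerSpectrum,
    f_range: tuple[float, float] = (2.0, 35.0),
    settings: FitSettings | None = None,
) -> SpectralFit:
    """Decompose one log-power spectrum into an aperiodic line plus peaks.

    Procedure: (1) ordinary least-squares line on log-log axes; (2)
    flatten; (3) repeatedly fit and subtract the tallest Gaussian while
    its height exceeds ``peak_threshold`` standard deviations of the
    flattened spectrum (and ``min_peak_height``), with the Gaussian
    sigma constrained to half of ``peak_width_limits``; (4) refit the
    line on the peak-subtracted spectrum using only the
    ``robust_quantile`` fraction of points with smallest absolute
    residual.  ``r_squared`` and ``mae`` score the full model on log
    power within ``f_range``.
    """
    settings = settings or FitSettings()
    if spectrum.power.ndim != 1:
        raise ValueError("fit operates on a single-channel spectrum; average channels first")
    lo, hi = f_range
    if spectrum.frequencies[0] > lo or spectrum.frequencies[-1] < hi:
        raise ValueError(f"spectrum does not cover fit range {f_range}")
    sel = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    f = spectrum.frequencies[sel]
    logp = spectrum.log_power[sel]
    logf = np.log10(f)

    sig_lo = settings.peak_width_limits[0] / 2.0
    sig_hi = settings.peak_width_limits[1] / 2.0
    # absolute numerical floor so a noiseless power law yields zero peaks
    height_floor = max(settings.min_peak_height, 1e-9)

    def _extract_peaks(flat: np.ndarray) -> list[tuple[float, float, float]]:
        flat = flat.copy()
        found: list[tuple[float, float, float]] = []
        for _ in range(settings.max_n_peaks):
            idx = int(np.argmax(flat))
            height = float(flat[idx])
            if height <= max(settings.peak_threshold * float(np.std(flat)), height_floor):
                break
            center0 = float(f[idx])
            # half-height crossing gives the initial sigma guess
            above = flat >= height / 2.0
            left = idx
            while left > 0 and above[left - 1]:
                left -= 1
            right = idx
            while right < f.size - 1 and above[right + 1]:
                right += 1
            fwhm = max(float(f[right] - f[left]), sig_lo * 2.355)
            sigma0 = float(np.clip(fwhm / 2.355, sig_lo, sig_hi))
            try:
                popt, _ = curve_fit(
                    _gaussian,
                    f,
                    flat,
                    p0=(center0, height, sigma0),
                    bounds=((lo, 0.0, sig_lo), (hi, np.inf, sig_hi)),
                    maxfev=2000,
                )
            except RuntimeError:
                warnings.warn(
                    f"Gaussian peak fit did not converge near {center0:.1f} Hz; peak skipped"
                )
                flat = flat - _gaussian(f, center0, height, sigma0)
                continue
            found.append((float(popt[0]), float(popt[1]), float(popt[2])))
            flat = flat - _gaussian(f, *popt)
        return found

    def _joint_refit(flat: np.ndarray, peaks: list) -> list[tuple[float, float, float]]:
        if not peaks:
            return peaks

        def model(x, *params):
            out = np.zeros_like(x)
            for k in range(0, len(params), 3):
                out = out + _gaussian(x, params[k], params[k + 1], params[k + 2])
            return out

        p0 = [v for peak in peaks for v in peak]
        lower = [lo, 0.0, sig_lo] * len(peaks)
        upper = [hi, np.inf, sig_hi] * len(peaks)
        try:
            popt, _ = curve_fit(model, f, flat, p0=p0, bounds=(lower, upper), maxfev=3000)
        except RuntimeError:
            return peaks
        return [tuple(map(float, popt[k : k + 3])) for k in range(0, len(popt), 3)]

    def _robust_line(residual_spec: np.ndarray) -> tuple[float, float]:
        off, slp = _linfit(logf, residual_spec)
        resid = np.abs(residual_spec - (off + slp * logf))
        keep = resid <= np.quantile(resid, settings.robust_quantile)
        if keep.sum() >= 2:
            off, slp = _linfit(logf[keep], residual_spec[keep])
        return off, slp

    # alternate aperiodic-line and peak fits; the second pass removes the
    # upward bias that peaks impose on the initial line
    offset1, slope1 = _linfit(logf, logp)
    peaks: list[tuple[float, float, float]] = []
    for _ in range(2):
        flat = logp - (offset1 + slope1 * logf)
        peaks = _extract_peaks(flat)
        peaks = _joint_refit(flat, peaks)
        peak_model = np.zeros_like(f)
        for center, height, width in peaks:
            peak_model += _gaussian(f, center, height, width)
        offset1, slope1 = _robust_line(logp - peak_model)

    fit = SpectralFit(
        offset=float(offset1),
        exponent=float(-slope1),
        peaks=peaks,
        f_range=(float(lo), float(hi)),
    )
    model = fit.model_log_power(f)
    err = logp - model
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit.mae = float(np.mean(np.abs(err)))
    return fit


def band_log_power(spectrum: PowerSpectrum, band: tuple[float, float] = (4.0, 16.0)) -> float:
    """Mean log10 power over the in-band frequency bins."""
    if spectrum.power.ndim != 1:
        raise ValueError("band_log_power operates on a single spectrum")
    lo, hi = band
    if spectrum.frequencies[0] > lo or spectrum.frequencies[-1] < hi:
        raise ValueError(f"spectrum does not cover band {band}")
    sel = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    return float(spectrum.log_power[sel].mean())


def periodic_power(
    spectrum: PowerSpectrum,
    fit: SpectralFit,
    band: tuple[float, float] = (4.0, 16.0),
) -> float:
    """Mean in-band log10 power above the fitted aperiodic line."""
    if spectrum.power.ndim != 1:
        raise ValueError("periodic_power operates on a single spectrum")
    lo, hi = band
    if lo < fit.f_range[0] or hi > fit.f_range[1]:
        raise ValueError("band extends outside the aperiodic fit range")
    sel = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    f = spectrum.frequencies[sel]
    return float((spectrum.log_power[sel] - fit.aperiodic_log_power(f)).mean())
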