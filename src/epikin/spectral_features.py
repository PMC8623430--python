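"""Frequency-domain predictors of the periodic marker motion.

Seven features are computed per coordinate axis (14 per recording):
band power, 3 dB (half-power) bandwidth, 99% occupied bandwidth, SFDR,
SINAD, SNR and normalized spectral entropy.

All spectral metrics share one power-spectral-density estimate: a
modified periodogram of the mean-removed signal under a Kaiser window
with shape parameter beta = 38 (sidelobes far below double-precision
noise, so spectral leakage never masquerades as signal).  Tone power is
measured by integrating the PSD over the window's main lobe (half-width
computed numerically from the window transform) around the identified
peak:

* SNR  = 10 log10(P_fund / P_noise), with the DC lobe, the fundamental
  lobe and the lobes of harmonics 2..n_harmonics excluded from the
  noise; excluded lobes are back-filled with the median noise density
  so the noise estimate covers the full band.
* SINAD uses the same numerator but keeps harmonic distortion in the
  denominator (only DC and the fundamental lobe are excluded).  The
  harmonic contribution to the SNR denominator is only its
  above-median-floor excess, which guarantees SINAD <= SNR.
* SFDR = fundamental-lobe power over the largest other (non-DC) lobe,
  harmonics included in the spur search.

Band power is the plain mean square of the *raw* signal (DC included);
every other metric works on the mean-removed signal.  dB values are
clipped to +-300 dB to keep feature matrices finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DegenerateSignalError
from .recording import TrajectoryRecording

__all__ = [
    "PowerSpectrum",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "psd_estimate",
    "band_power",
    "fundamental_estimate",
    "snr_db",
    "sinad_db",
    "sfdr_db",
    "power_bandwidth",
    "occupied_bandwidth",
    "spectral_entropy",
    "extract_feature_vector",
    "build_feature_table",
]

#: Kaiser window shape parameter shared by all lobe-integrating metrics.
KAISER_BETA = 38.0
#: Number of harmonics (2..N) excluded from the SNR noise estimate.
DEFAULT_N_HARMONICS = 6
#: Clip for dB-valued features.
DB_CAP = 300.0
#: Minimum samples for a meaningful windowed periodogram.
MIN_SAMPLES = 64

#: Per-axis feature names, in table order.
FEATURE_NAMES = (
    "band_power",
    "power_bandwidth",
    "occupied_bandwidth",
    "sfdr",
    "sinad",
    "snr",
    "spectral_entropy",
)
#: The 14 feature-table columns: all x-axis features, then all y-axis.
FEATURE_COLUMNS = tuple(f"{name}_{axis}" for axis in ("x", "y") for name in FEATURE_NAMES)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided PSD of a recording axis with its window metadata."""

    frequencies: np.ndarray  # Hz, DC to Nyquist, strictly increasing
    psd: np.ndarray  # power per Hz
    window: tuple[str, float]  # (name, shape parameter)
    resolution_bw: float  # Hz, equivalent noise bandwidth of the window
    n_samples: int
    mainlobe_halfwidth: float  # Hz, half-width of the window main lobe

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    @property
    def total_power(self) -> float:
        """Integral of the PSD over frequency (rectangle rule, exact Parseval)."""
        return float(np.sum(self.psd) * self.df)


@lru_cache(maxsize=64)
def _mainlobe_halfwidth_bins(n: int, beta: float, pad: int = 32) -> float:
    """Half-width of the Kaiser window's spectral main lobe, in DFT bins.

    Located numerically as the first null of the zero-padded window
    transform; for beta = 38 this is ~12.1 bins.
    """
    w = np.kaiser(n, beta)
    mag = np.abs(np.fft.rfft(w, pad * n))
    rising = np.nonzero(np.diff(mag) > 0)[0]
    first_null = rising[0] if rising.size else mag.size - 1
    return first_null / pad


def psd_estimate(signal, sampling_rate: float, beta: float = KAISER_BETA) -> PowerSpectrum:
    """Modified periodogram of the mean-removed signal (one-sided PSD).

    The integral of the PSD equals the window-weighted mean square of
    the detrended signal, sum((w*x)^2)/sum(w^2) (Parseval).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"signal must have at least {MIN_SAMPLES} samples, got {x.size}")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    x = x - x.mean()
    w = np.kaiser(x.size, beta)
    freqs, psd = sps.periodogram(x, fs=sampling_rate, window=w, detrend=False, scaling="density")
    enbw = sampling_rate * np.sum(w**2) / np.sum(w) ** 2
    halfwidth_hz = _mainlobe_halfwidth_bins(x.size, beta) * sampling_rate / x.size
    return PowerSpectrum(
        frequencies=freqs,
        psd=psd,
        window=("kaiser", beta),
        resolution_bw=float(enbw),
        n_samples=x.size,
        mainlobe_halfwidth=float(halfwidth_hz),
    )


def band_power(signal) -> float:
    """Average power (mean squared sample) of the raw signal, DC included."""
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValueError("band_power requires a non-empty signal")
    return float(np.mean(x**2))


def _dc_mask(spectrum: PowerSpectrum) -> np.ndarray:
    """Bins belonging to the residual DC lobe.

    Walks up from DC while the PSD decreases (the signal is mean-removed,
    so this is usually just bin 0); stops as soon as the PSD rises toward
    the first real spectral peak.
    """
    psd = spectrum.psd
    i = 0
    while i + 1 < psd.size and psd[i + 1] < psd[i]:
        i += 1
    mask = np.zeros(psd.size, dtype=bool)
    mask[: i + 1] = True
    return mask


def _lobe_mask(spectrum: PowerSpectrum, f0: float) -> np.ndarray:
    return np.abs(spectrum.frequencies - f0) <= spectrum.mainlobe_halfwidth


def fundamental_estimate(spectrum: PowerSpectrum) -> tuple[float, float]:
    """Frequency and lobe-integrated power of the dominant component.

    Returns (f0 in Hz, power in signal units^2).  Raises
    :class:`DegenerateSignalError` when the spectrum has no non-DC
    content (e.g. a constant trace).
    """
    dc = _dc_mask(spectrum)
    candidates = np.where(dc, -np.inf, spectrum.psd)
    if not np.isfinite(candidates).any() or np.nanmax(candidates) <= 0:
        raise DegenerateSignalError("spectrum has no non-DC content")
    i0 = int(np.argmax(candidates))
    f0 = float(spectrum.frequencies[i0])
    lobe = _lobe_mask(spectrum, f0)
    power = float(np.sum(spectrum.psd[lobe]) * spectrum.df)
    return f0, power


def _db(ratio_num: float, ratio_den: float, context: str) -> float:
    if ratio_den <= 0:
        warnings.warn(f"{context}: non-positive denominator power; capping at +{DB_CAP} dB", RuntimeWarning)
        return DB_CAP
    return float(np.clip(10.0 * np.log10(ratio_num / ratio_den), -DB_CAP, DB_CAP))


def _tone_decomposition(spectrum: PowerSpectrum, n_harmonics: int):
    """Masks for DC lobe, fundamental lobe and harmonic lobes.

    Harmonics falling beyond Nyquist are ignored (not folded).  Masks are
    disjoint: the fundamental keeps overlapping bins, DC keeps bins not
    claimed by the fundamental, harmonics keep the rest.
    """
    f0, fund_power = fundamental_estimate(spectrum)
    fund = _lobe_mask(spectrum, f0)
    dc = _dc_mask(spectrum) & ~fund
    harm = np.zeros_like(fund)
    for h in range(2, n_harmonics + 1):
        fh = h * f0
        if fh > spectrum.nyquist + spectrum.mainlobe_halfwidth:
            break
        harm |= _lobe_mask(spectrum, fh)
    harm &= ~(fund | dc)
    return f0, fund_power, dc, fund, harm


def _snr_sinad_from_spectrum(
    spectrum: PowerSpectrum, n_harmonics: int, which: tuple[str, ...] = ("snr", "sinad")
) -> tuple[float | None, float | None]:
    _, fund_power, dc, fund, harm = _tone_decomposition(spectrum, n_harmonics)
    noise_only = ~(dc | fund | harm)
    df = spectrum.df
    psd = spectrum.psd
    median_floor = float(np.median(psd[noise_only])) if noise_only.any() else 0.0
    harm_power = float(np.sum(psd[harm]) * df)
    # SINAD denominator: everything except DC and the fundamental, with the
    # fundamental lobe's noise back-filled at the median floor.
    sinad_den = float(np.sum(psd[noise_only]) * df) + harm_power + median_floor * fund.sum() * df
    # SNR denominator additionally strips the harmonics' above-floor excess.
    harm_excess = max(0.0, harm_power - median_floor * harm.sum() * df)
    snr_den = sinad_den - harm_excess
    snr = _db(fund_power, snr_den, "snr") if "snr" in which else None
    sinad = _db(fund_power, sinad_den, "sinad") if "sinad" in which else None
    return snr, sinad


def snr_db(signal, sampling_rate: float, n_harmonics: int = DEFAULT_N_HARMONICS) -> float:
    """Signal-to-noise ratio (dB): fundamental power over noise power,
    with DC and harmonic distortion excluded from the noise."""
    spectrum = psd_estimate(signal, sampling_rate)
    return _snr_sinad_from_spectrum(spectrum, n_harmonics, which=("snr",))[0]


def sinad_db(signal, sampling_rate: float, n_harmonics: int = DEFAULT_N_HARMONICS) -> float:
    """Signal to noise-and-distortion ratio (dB): fundamental power over
    all remaining non-DC power (noise plus harmonics)."""
    spectrum = psd_estimate(signal, sampling_rate)
    return _snr_sinad_from_spectrum(spectrum, n_harmonics, which=("sinad",))[1]


def _sfdr_from_spectrum(spectrum: PowerSpectrum) -> float:
    _, fund_power, dc, fund, _ = _tone_decomposition(spectrum, 1)
    masked = np.where(dc | fund, -np.inf, spectrum.psd)
    if not np.isfinite(masked).any() or np.nanmax(masked) <= 0:
        warnings.warn("sfdr: no spur found outside the fundamental; capping", RuntimeWarning)
        return DB_CAP
    i_spur = int(np.argmax(masked))
    spur_lobe = _lobe_mask(spectrum, float(spectrum.frequencies[i_spur])) & ~fund
    spur_power = float(np.sum(spectrum.psd[spur_lobe]) * spectrum.df)
    return _db(fund_power, spur_power, "sfdr")


def sfdr_db(signal, sampling_rate: float) -> float:
    """Spurious-free dynamic range (dB): fundamental lobe power over the
    largest other lobe (spur search includes harmonics)."""
    return _sfdr_from_spectrum(psd_estimate(signal, sampling_rate))


def power_bandwidth(spectrum: PowerSpectrum) -> float:
    """3 dB (half-power) bandwidth around the global PSD peak (Hz).

    The first bins on either side of the peak falling below half the
    peak density bound the band, with linear interpolation between bins;
    a flat or empty spectrum yields the full band with a warning.
    """
    psd, freqs = spectrum.psd, spectrum.frequencies
    peak = float(psd.max())
    full_band = float(freqs[-1] - freqs[0])
    if peak <= 0 or np.allclose(psd, psd[0]):
        warnings.warn("power_bandwidth: flat spectrum; returning the full band", RuntimeWarning)
        return full_band
    i0 = int(np.argmax(psd))
    half = peak / 2.0

    def cross(direction: int) -> float:
        i = i0
        while 0 <= i + direction < psd.size and psd[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= psd.size:
            return float(freqs[i])
        # linear interpolation between the last bin >= half and the first below
        frac = (psd[i] - half) / (psd[i] - psd[j])
        return float(freqs[i] + frac * (freqs[j] - freqs[i]))

    lo, hi = cross(-1), cross(+1)
    return float(np.clip(hi - lo, 0.0, spectrum.nyquist))


def occupied_bandwidth(spectrum: PowerSpectrum, fraction: float = 0.99) -> float:
    """Bandwidth containing ``fraction`` of the total PSD power (Hz).

    The band excludes (1-fraction)/2 of the power on each side;
    crossings are located by linear interpolation of the cumulative
    power over frequency.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = spectrum.total_power
    if total <= 0:
        raise DegenerateSignalError("zero-power spectrum")
    cum = np.cumsum(spectrum.psd) * spectrum.df
    tail = (1.0 - fraction) / 2.0 * total
    f_lo = float(np.interp(tail, cum, spectrum.frequencies))
    f_hi = float(np.interp(total - tail, cum, spectrum.frequencies))
    return f_hi - f_lo


def spectral_entropy(spectrum: PowerSpectrum) -> float:
    """Normalized Shannon entropy of the PSD, in [0, 1].

    H = -sum(p log2 p) / log2(M) with p the PSD normalized to unit sum
    over its M bins; 0 for a single-bin spectrum (pure tone), 1 for an
    exactly flat one (white noise limit).
    """
    total = float(np.sum(spectrum.psd))
    if total <= 0:
        raise DegenerateSignalError("zero-power spectrum")
    p = spectrum.psd / total
    nz = p > 0
    h = -float(np.sum(p[nz] * np.log2(p[nz])))
    return h / np.log2(p.size)


def _axis_features(values: np.ndarray, sampling_rate: float, n_harmonics: int) -> dict[str, float]:
    spectrum = psd_estimate(values, sampling_rate)
    snr, sinad = _snr_sinad_from_spectrum(spectrum, n_harmonics)
    return {
        "band_power": band_power(values),
        "power_bandwidth": power_bandwidth(spectrum),
        "occupied_bandwidth": occupied_bandwidth(spectrum),
        "sfdr": _sfdr_from_spectrum(spectrum),
        "sinad": sinad,
        "snr": snr,
        "spectral_entropy": spectral_entropy(spectrum),
    }


def extract_feature_vector(
    recording: TrajectoryRecording, n_harmonics: int = DEFAULT_N_HARMONICS
) -> pd.Series:
    """The 14 frequency-domain predictors of one recording.

    Returns a Series indexed by :data:`FEATURE_COLUMNS` (x-axis features
    first).  Degenerate axes (no oscillatory content) raise
    :class:`DegenerateSignalError` naming the failing axis.
    """
    out: dict[str, float] = {}
    for axis, values in (("x", recording.x), ("y", recording.y)):
        try:
            feats = _axis_features(values, recording.sampling_rate, n_harmonics)
        except DegenerateSignalError as err:
            raise DegenerateSignalError(
                f"recording {recording.recording_id or recording.patient_id!r}, axis {axis}: {err}"
            ) from err
        for name in FEATURE_NAMES:
            out[f"{name}_{axis}"] = feats[name]
    return pd.Series(out, index=list(FEATURE_COLUMNS), dtype=float)


def build_feature_table(
    recordings: list[TrajectoryRecording], n_harmonics: int = DEFAULT_N_HARMONICS
) -> pd.DataFrame:
    """Feature table for a recording list: identifiers, 14 features, label."""
    rows = []
    for rec in recordings:
        row = {"patient_id": rec.patient_id, "phase": rec.phase, "recording_id": rec.recording_id}
        row.update(extract_feature_vector(rec, n_harmonics).to_dict())
        row["label"] = rec.label
        rows.append(row)
    columns = ["patient_id", "phase", "recording_id", *FEATURE_COLUMNS, "label"]
    return pd.DataFrame(rows, columns=columns)
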