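"""Filtering, spectral estimation and analytic-signal extraction.

All band filtering is zero-phase: windowed-sinc (Hamming) FIR kernels applied
forward-backward, with reflect padding so edge transients stay out of the
analysis span.  PSDs use Welch's method with 6-second non-overlapping windows
(nfft defaults to 8096), and relative band power normalizes each band by the
total power between 0 and 55 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import BandDefinition, DEFAULT_BANDS, THETA_SPLIT_BANDS

__all__ = [
    "notch_filter",
    "bandpass_fir",
    "welch_psd",
    "relative_band_power",
    "analytic_signal",
    "SpectralResult",
]


@dataclass
class SpectralResult:
    """Welch PSD on a frequency grid plus per-band relative power."""

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    rel_power: dict[str, float] = field(default_factory=dict)


def notch_filter(
    signal: np.ndarray, fs: float, line_hz: float = 60.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch at the line frequency (>= 30 dB attenuation)."""
    if fs <= 2 * line_hz:
        raise ValueError("sampling rate too low for the requested notch")
    b, a = sps.iirnotch(line_hz, q, fs=fs)
    # two cascaded passes (filtfilt runs each once forward and once backward)
    return sps.filtfilt(b, a, sps.filtfilt(b, a, signal))


def _fir_kernel(fs: float, band: BandDefinition) -> np.ndarray:
    """Hamming windowed-sinc bandpass kernel.

    Transition width is 20% of the lower band edge (at least 0.5 Hz), which
    with a Hamming window gives > 50 dB stopband attenuation.
    """
    trans = max(0.2 * band.f_lo, 0.5)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps |= 1  # odd length -> exactly symmetric, linear phase
    return sps.firwin(
        numtaps, [band.f_lo, band.f_hi], pass_zero=False, window="hamming", fs=fs
    )


def bandpass_fir(
    signal: np.ndarray, fs: float, band: BandDefinition | str
) -> np.ndarray:
    """Zero-phase FIR bandpass via forward-backward filtering.

    Reflect padding of three kernel lengths keeps edge transients outside the
    returned span; the first/last second should still be treated as
    unreliable for envelope/phase work.
    """
    if isinstance(band, str):
        band = {**DEFAULT_BANDS, **THETA_SPLIT_BANDS}[band]
    if band.f_hi >= fs / 2:
        raise ValueError("band edge above Nyquist")
    taps = _fir_kernel(fs, band)
    if len(signal) < 3 * len(taps) // 2:
        raise ValueError(
            f"signal too short ({len(signal)} samples) for filter length {len(taps)}"
        )
    pad = min(3 * len(taps), len(signal) - 1)
    return sps.filtfilt(taps, [1.0], signal, padtype="even", padlen=pad)


def welch_psd(
    signal: np.ndarray,
    fs: float,
    win_s: float = 6.0,
    nfft: int = 8096,
    overlap: float = 0.0,
    bands: dict[str, BandDefinition] | None = None,
) -> SpectralResult:
    """Welch PSD with ``win_s``-second windows (non-overlapping by default).

    ``nfft`` defaults to 8096; pass 8192 for a power-of-two grid.  Relative
    band power is filled for every requested band lying inside 0-55 Hz.
    """
    if len(signal) == 0:
        raise ValueError("empty signal")
    nperseg = int(round(win_s * fs))
    nperseg = min(nperseg, len(signal))
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(
        signal,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=max(nfft, nperseg),
        detrend="constant",
    )
    result = SpectralResult(freqs=freqs, psd=psd, fs=fs)
    for name, band in (bands or DEFAULT_BANDS).items():
        if band.f_hi <= 55.0:
            result.rel_power[name] = relative_band_power(result, band)
    return result


def relative_band_power(spec: SpectralResult, band: BandDefinition | str) -> float:
    """Fraction of 0-55 Hz power falling in ``band`` (trapezoidal integral)."""
    if isinstance(band, str):
        band = {**DEFAULT_BANDS, **THETA_SPLIT_BANDS}[band]
    if band.f_hi > 55.0:
        raise ValueError("relative power is normalized over 0-55 Hz only")
    f, p = spec.freqs, spec.psd
    total_mask = f <= 55.0
    total = np.trapezoid(p[total_mask], f[total_mask])
    if total <= 0:
        raise ValueError("zero total power in 0-55 Hz")
    band_mask = (f >= band.f_lo) & (f <= band.f_hi)
    return float(np.trapezoid(p[band_mask], f[band_mask]) / total)


def analytic_signal(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert envelope and instantaneous phase of a narrowband signal.

    Returns ``(envelope, phase)`` with envelope >= 0 and phase in (-pi, pi].
    The input must already be bandpassed; a (near-)constant signal has no
    meaningful phase and is rejected.
    """
    signal = np.asarray(signal, dtype=float)
    if np.ptp(signal) == 0:
        raise ValueError("constant signal: instantaneous phase undefined")
    analytic = sps.hilbert(signal)
    return np.abs(analytic), np.angle(analytic)


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous frequency (Hz) from unwrapped phase, central differences."""
    return np.gradient(np.unwrap(phase)) * fs / (2 * np.pi)
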