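"""Theta rhythmic stability (lagged coherence) and inter-regional envelope lags.

Lagged coherence quantifies how consistent an oscillation's phase is across
consecutive epochs of the same signal: the signal is tiled into epochs of
``n_cycles`` at each probe frequency, and the normalized product of Fourier
coefficients of neighboring epochs is accumulated.  A perfectly rhythmic
signal scores 1, phase-scrambled activity falls to the noise floor.

Envelope lags estimate MS->CA1 lead/lag from the peak of the normalized
cross-correlation of theta amplitude envelopes in overlapping windows, with
parabolic interpolation for sub-sample precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "LaggedCoherenceResult",
    "LagSeries",
    "lagged_coherence",
    "lagged_coherence_timecourse",
    "envelope_lag",
    "lag_dispersion",
    "condition_sd_ratio",
]


@dataclass
class LaggedCoherenceResult:
    value: float
    band: tuple[float, float]
    n_cycles: int
    per_freq: dict[float, float]


@dataclass
class LagSeries:
    """Windowed MS->CA1 envelope lags (positive lag: MS leads CA1)."""

    window_starts_s: np.ndarray
    lag_s: np.ndarray

    @property
    def centered_lag_s(self) -> np.ndarray:
        return self.lag_s - np.median(self.lag_s)

    @property
    def sd_lag_s(self) -> float:
        return float(np.std(self.lag_s, ddof=1)) if len(self.lag_s) > 1 else 0.0


def _lagged_coherence_at(
    signal: np.ndarray, fs: float, f: float, n_cycles: int
) -> float:
    ep_len = int(round(n_cycles / f * fs))
    n_ep = len(signal) // ep_len
    if n_ep < 2:
        raise ValueError(
            f"signal too short: {n_ep} epoch(s) of {n_cycles} cycles at {f} Hz"
        )
    segs = signal[: n_ep * ep_len].reshape(n_ep, ep_len)
    taper = np.hanning(ep_len)
    t = np.arange(ep_len) / fs
    basis = taper * np.exp(-2j * np.pi * f * t)
    coeffs = segs @ basis
    a, b = coeffs[:-1], coeffs[1:]
    num = np.abs(np.sum(a * np.conj(b)))
    den = np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2))
    return float(num / den) if den > 0 else 0.0


def lagged_coherence(
    signal: np.ndarray,
    fs: float,
    f_range: tuple[float, float] = (5.0, 12.0),
    n_cycles: int = 3,
    f_step: float = 1.0,
) -> LaggedCoherenceResult:
    """Mean lagged coherence over probe frequencies spanning ``f_range``."""
    freqs = np.arange(f_range[0], f_range[1] + 1e-9, f_step)
    per_freq = {float(f): _lagged_coherence_at(signal, fs, f, n_cycles) for f in freqs}
    return LaggedCoherenceResult(
        value=float(np.mean(list(per_freq.values()))),
        band=f_range,
        n_cycles=n_cycles,
        per_freq=per_freq,
    )


def lagged_coherence_timecourse(
    signal: np.ndarray,
    fs: float,
    bin_s: float = 150.0,
    f_range: tuple[float, float] = (5.0, 12.0),
    n_cycles: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged coherence per non-overlapping ``bin_s`` bin (default 2.5 min).

    Returns (bin_start_times_s, values); the trailing partial bin is dropped.
    """
    step = int(round(bin_s * fs))
    n_bins = len(signal) // step
    starts = np.arange(n_bins) * bin_s
    vals = np.array(
        [
            lagged_coherence(signal[i * step : (i + 1) * step], fs, f_range, n_cycles).value
            for i in range(n_bins)
        ]
    )
    return starts, vals


def envelope_lag(
    ms_env: np.ndarray,
    ca1_env: np.ndarray,
    fs: float,
    win_s: float = 10.0,
    step_s: float = 5.0,
    max_lag_s: float = 0.25,
) -> LagSeries:
    """Windowed envelope cross-correlation lag, positive when MS leads CA1.

    Per window the envelopes are mean-subtracted and the normalized
    cross-correlation is maximized over lags within +/- ``max_lag_s``; the
    integer-lag peak is refined by parabolic interpolation.  Zero-variance
    windows are skipped.
    """
    if len(ms_env) != len(ca1_env):
        raise ValueError("envelopes must have equal length")
    if max_lag_s >= win_s / 2:
        raise ValueError("max_lag_s must be below half the window length")
    win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    max_lag = int(round(max_lag_s * fs))
    starts, lags = [], []
    for i0 in range(0, len(ms_env) - win + 1, step):
        a = ms_env[i0 : i0 + win] - np.mean(ms_env[i0 : i0 + win])
        b = ca1_env[i0 : i0 + win] - np.mean(ca1_env[i0 : i0 + win])
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            continue
        # full cross-correlation; c[k] peaks at k = d when b lags a by d
        c = sps.correlate(b, a, mode="full") / (sa * sb * win)
        lag_axis = np.arange(-(win - 1), win)
        sel = np.abs(lag_axis) <= max_lag
        c, lag_axis = c[sel], lag_axis[sel]
        k = int(np.argmax(c))
        lag = float(lag_axis[k])
        if 0 < k < len(c) - 1:
            denom = c[k - 1] - 2 * c[k] + c[k + 1]
            if denom < 0:
                lag += 0.5 * (c[k - 1] - c[k + 1]) / denom
        starts.append(i0 / fs)
        lags.append(lag / fs)
    return LagSeries(window_starts_s=np.array(starts), lag_s=np.array(lags))


def lag_dispersion(lags: LagSeries) -> tuple[float, np.ndarray]:
    """Within-session lag variability: (sd over windows, median-centered lags)."""
    if len(lags.lag_s) < 2:
        raise ValueError("need at least 2 window lags")
    return lags.sd_lag_s, lags.centered_lag_s


def condition_sd_ratio(lags_num: LagSeries, lags_den: LagSeries) -> float:
    """Ratio of lag standard deviations between two sessions of one subject."""
    sd_den = lags_den.sd_lag_s
    if sd_den == 0:
        raise ValueError("denominator session has zero lag variability")
    return lags_num.sd_lag_s / sd_den
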