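"""Phase-locking values: session-windowed, peri-burst, and post-burst offsets.

PLV between two instantaneous-phase series is the magnitude of the circular
mean of their phase differences: 1 for perfect locking (any constant offset),
0 for uniformly dispersed differences.  Session PLV is computed in 8-second
non-overlapping windows and averaged; peri-burst PLV compares 2-second
pre/during/post epochs around coupled MS->CA1 burst events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burst_detection import BurstEvent
from .circstats import circ_mean
from .coupling import BurstPair

__all__ = [
    "plv",
    "PlvSeries",
    "windowed_plv",
    "classify_coupling",
    "PeriBurstPlv",
    "peri_burst_plv",
    "post_burst_phase_offsets",
]


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """|mean exp(i (phi_a - phi_b))| over the sample."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


@dataclass
class PlvSeries:
    """PLV per non-overlapping window plus session and 5-min-bin means."""

    window_starts_s: np.ndarray
    plv: np.ndarray
    win_s: float

    @property
    def session_mean(self) -> float:
        return float(np.mean(self.plv))

    def binned(self, bin_s: float = 300.0) -> tuple[np.ndarray, np.ndarray]:
        """Mean of window PLVs per ``bin_s`` bin of window start times."""
        n_bins = int(np.ceil((self.window_starts_s[-1] + self.win_s) / bin_s))
        starts = np.arange(n_bins) * bin_s
        idx = np.minimum((self.window_starts_s // bin_s).astype(int), n_bins - 1)
        vals = np.array(
            [self.plv[idx == k].mean() if np.any(idx == k) else np.nan
             for k in range(n_bins)]
        )
        return starts, vals


def windowed_plv(
    phase_a: np.ndarray, phase_b: np.ndarray, fs: float, win_s: float = 8.0
) -> PlvSeries:
    """PLV in non-overlapping ``win_s``-second windows (remainder dropped)."""
    if len(phase_a) != len(phase_b):
        raise ValueError("phase series must have equal length")
    step = int(round(win_s * fs))
    n_win = len(phase_a) // step
    if n_win == 0:
        raise ValueError("signal shorter than one window")
    vals = np.array(
        [
            plv(phase_a[i * step : (i + 1) * step], phase_b[i * step : (i + 1) * step])
            for i in range(n_win)
        ]
    )
    return PlvSeries(
        window_starts_s=np.arange(n_win) * win_s, plv=vals, win_s=win_s
    )


def classify_coupling(
    ca1_bursts: list[BurstEvent],
    ms_bursts: list[BurstEvent],
    window_s: float = 0.4,
    mode: str = "offset",
) -> np.ndarray:
    """Flag each CA1 burst as coupled if an MS burst precedes it closely.

    A CA1 burst is coupled when some MS burst's completion (``mode='offset'``,
    default) or onset (``mode='onset'``) falls within ``window_s`` before the
    CA1 burst onset.  The window is inclusive at both ends.
    """
    if mode not in ("offset", "onset"):
        raise ValueError("mode must be 'offset' or 'onset'")
    ref = np.array(
        [b.offset_s if mode == "offset" else b.onset_s for b in ms_bursts]
    )
    ref.sort()
    flags = np.zeros(len(ca1_bursts), dtype=bool)
    for i, ca1 in enumerate(ca1_bursts):
        j = np.searchsorted(ref, ca1.onset_s, side="right")
        if j > 0 and ca1.onset_s - ref[j - 1] <= window_s:
            flags[i] = True
    return flags


@dataclass
class PeriBurstPlv:
    """PLV in the pre / during / post epochs around one burst event."""

    pre_plv: float
    during_plv: float
    post_plv: float
    coupled: bool = True

    @property
    def ratio(self) -> float:
        return self.post_plv / self.pre_plv


def peri_burst_plv(
    pair: BurstPair,
    phase_ms: np.ndarray,
    phase_ca1: np.ndarray,
    fs: float,
    pre_s: float = 2.0,
    post_s: float = 2.0,
    coupled: bool = True,
) -> PeriBurstPlv | None:
    """PLV over pre / during / post epochs of one MS->CA1 burst event.

    Pre spans ``pre_s`` seconds before MS burst onset, during spans MS onset
    to CA1 offset, post spans ``post_s`` seconds after CA1 burst offset.
    Events whose windows fall outside the recording are skipped (None).
    """
    n = len(phase_ms)
    i_pre0 = int(round((pair.ms_burst.onset_s - pre_s) * fs))
    i_on = int(round(pair.ms_burst.onset_s * fs))
    i_off = int(round(pair.ca1_burst.offset_s * fs))
    i_post1 = int(round((pair.ca1_burst.offset_s + post_s) * fs))
    if i_pre0 < 0 or i_post1 > n or i_off <= i_on + 1:
        return None
    return PeriBurstPlv(
        pre_plv=plv(phase_ms[i_pre0:i_on], phase_ca1[i_pre0:i_on]),
        during_plv=plv(phase_ms[i_on:i_off], phase_ca1[i_on:i_off]),
        post_plv=plv(phase_ms[i_off:i_post1], phase_ca1[i_off:i_post1]),
        coupled=coupled,
    )


def post_burst_phase_offsets(
    pairs: list[BurstPair],
    phase_ms: np.ndarray,
    phase_ca1: np.ndarray,
    fs: float,
    window_s: float = 1.25,
    precede_s: float = 0.2,
) -> np.ndarray:
    """One circular-mean MS-CA1 phase offset per qualifying burst pair.

    Only pairs whose MS burst completed within ``precede_s`` of the CA1 burst
    onset qualify; the offset is the circular mean of (phi_MS - phi_CA1) over
    the ``window_s`` window following the CA1 burst offset.
    """
    n = len(phase_ms)
    offsets = []
    for pair in pairs:
        if pair.delay_s > precede_s:
            continue
        i0 = int(round(pair.ca1_burst.offset_s * fs))
        i1 = int(round((pair.ca1_burst.offset_s + window_s) * fs))
        if i0 < 0 or i1 > n or i1 - i0 < 2:
            continue
        diff = phase_ms[i0:i1] - phase_ca1[i0:i1]
        offsets.append(circ_mean(diff))
    return np.array(offsets)
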