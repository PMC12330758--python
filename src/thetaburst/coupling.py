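"""MS->CA1 burst pairing and delay/duration coupling analyses.

An MS burst is paired with the first CA1 burst whose onset falls within a
maximum delay (default 1 s) of the MS burst's completion, greedily left to
right with each CA1 burst consumed at most once.  Pairs are split into short-
and long-latency groups at the 25th/75th percentiles of the pooled empirical
delay distribution, and duration coupling across groups/conditions is
compared with Fisher's r-to-z test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .burst_detection import BurstEvent

__all__ = [
    "BurstPair",
    "CorrelationComparison",
    "pair_bursts",
    "delay_kde_compare",
    "latency_split",
    "duration_correlation",
    "fisher_z_compare",
]


@dataclass
class BurstPair:
    """An MS burst linked to the next CA1 burst within the delay window."""

    ms_burst: BurstEvent
    ca1_burst: BurstEvent
    delay_s: float  # CA1 onset minus MS offset
    latency_group: str = ""


@dataclass
class CorrelationComparison:
    """Fisher r-to-z comparison of two independent Pearson correlations."""

    r_a: float
    r_b: float
    n_a: int
    n_b: int
    z: float
    p: float


def pair_bursts(
    ms_bursts: list[BurstEvent],
    ca1_bursts: list[BurstEvent],
    max_delay_s: float = 1.0,
) -> list[BurstPair]:
    """Greedy first-match pairing; delays constrained to (0, max_delay_s].

    CA1 bursts whose onset does not fall within ``max_delay_s`` of an MS
    burst's completion are never paired, and no CA1 burst is reused.
    """
    ms_sorted = sorted(ms_bursts, key=lambda b: b.onset_s)
    ca1_sorted = sorted(ca1_bursts, key=lambda b: b.onset_s)
    pairs: list[BurstPair] = []
    j = 0
    for ms in ms_sorted:
        while j < len(ca1_sorted) and ca1_sorted[j].onset_s <= ms.offset_s:
            j += 1
        if j == len(ca1_sorted):
            break
        ca1 = ca1_sorted[j]
        delay = ca1.onset_s - ms.offset_s
        if delay <= max_delay_s:
            pairs.append(BurstPair(ms_burst=ms, ca1_burst=ca1, delay_s=delay))
            j += 1
    return pairs


def delay_kde_compare(
    pairs_a: list[BurstPair],
    pairs_b: list[BurstPair],
    max_delay_s: float = 1.0,
    grid_n: int = 512,
) -> dict:
    """Gaussian-kernel delay KDEs per condition plus a Mann-Whitney U test.

    Bandwidth follows Silverman's rule (scipy default).  Returns a dict with
    the common grid, both density curves, and the two-sided U test.
    """
    da = np.array([p.delay_s for p in pairs_a])
    db = np.array([p.delay_s for p in pairs_b])
    if len(da) < 10 or len(db) < 10:
        raise ValueError("need at least 10 pairs per condition")
    grid = np.linspace(0.0, max_delay_s, grid_n)
    out = {"grid_s": grid}
    for key, d in (("kde_a", da), ("kde_b", db)):
        if np.ptp(d) > 0:
            kde = spstats.gaussian_kde(d, bw_method="silverman")
            out[key] = kde(grid)
        else:
            raise ValueError("degenerate (all-equal) delay sample")
    u = spstats.mannwhitneyu(da, db, alternative="two-sided")
    out["u_statistic"] = float(u.statistic)
    out["p"] = float(u.pvalue)
    return out


def latency_split(pairs: list[BurstPair]) -> list[BurstPair]:
    """Label pairs short/long/mid at the pooled 25th/75th delay percentiles.

    ``delay <= Q25`` -> short, ``delay >= Q75`` -> long, else mid.  In the
    degenerate all-equal case every pair would satisfy both rules; such ties
    are resolved to mid.
    """
    if len(pairs) < 8:
        raise ValueError("need at least 8 pairs for a quartile split")
    delays = np.array([p.delay_s for p in pairs])
    q25, q75 = np.percentile(delays, [25, 75])
    for p in pairs:
        if p.delay_s <= q25 and p.delay_s >= q75:
            p.latency_group = "mid"  # degenerate tie: both rules fire
        elif p.delay_s <= q25:
            p.latency_group = "short"
        elif p.delay_s >= q75:
            p.latency_group = "long"
        else:
            p.latency_group = "mid"
    return pairs


def duration_correlation(pairs: list[BurstPair]) -> tuple[float, int]:
    """Pearson r between MS and CA1 burst durations over pairs."""
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs")
    ms = np.array([p.ms_burst.duration_s for p in pairs])
    ca1 = np.array([p.ca1_burst.duration_s for p in pairs])
    if np.ptp(ms) == 0 or np.ptp(ca1) == 0:
        raise ValueError("zero variance in burst durations")
    r = float(np.corrcoef(ms, ca1)[0, 1])
    return r, len(pairs)


def fisher_z_compare(
    r_a: float, n_a: int, r_b: float, n_b: int
) -> CorrelationComparison:
    """Fisher r-to-z test for equality of two independent correlations.

    z = (atanh(r_a) - atanh(r_b)) / sqrt(1/(n_a-3) + 1/(n_b-3)), with a
    two-sided normal p value.
    """
    for r, n in ((r_a, n_a), (r_b, n_b)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be below 1")
        if n < 4:
            raise ValueError("need n >= 4 per group")
    z = (np.arctanh(r_a) - np.arctanh(r_b)) / np.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    p = 2.0 * spstats.norm.sf(abs(z))
    return CorrelationComparison(
        r_a=r_a, r_b=r_b, n_a=n_a, n_b=n_b, z=float(z), p=float(p)
    )
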