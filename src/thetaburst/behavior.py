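"""Kinematics, rest/movement detection and burst-behavior alignment.

Positions arrive at the video frame rate (20 fps).  Velocity comes from
central differences of the track (after a short moving-average smoothing of
the speed for thresholding); heading is the arctangent of the velocity
components and is only defined while the animal moves.  Rest is velocity
below 0.5 cm/s for at least 2 s; a movement initiation is the transition
from such rest to sustained movement above 1.5 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .burst_detection import BurstEvent
from .session import BehaviorTrack

__all__ = [
    "MovementEvent",
    "compute_kinematics",
    "detect_rest_periods",
    "detect_movement_initiations",
    "detect_movement_bouts",
    "bursts_near_events",
    "bout_burst_precedence",
    "burst_triggered_velocity",
    "theta_power_velocity_correlation",
    "lme_design_table",
]


@dataclass
class MovementEvent:
    """A rest period, movement bout, or (instantaneous) movement initiation."""

    kind: str  # rest | initiation | bout
    start_s: float
    end_s: float
    mean_velocity_cms: float = float("nan")
    preceded_by_burst: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def compute_kinematics(
    x: np.ndarray, y: np.ndarray, fps: float = 20.0, smooth_frames: int = 5
) -> BehaviorTrack:
    """Velocity, acceleration and heading from a 2-D position track.

    Central-difference velocity components; speed = hypot(vx, vy), smoothed
    with a ``smooth_frames`` moving average for downstream thresholding;
    heading = atan2(vy, vx), NaN where the (unsmoothed) speed is zero;
    acceleration is the time derivative of speed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    dt = 1.0 / fps
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = np.hypot(vx, vy)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        speed_s = ndimage.convolve1d(speed, kernel, mode="nearest")
    else:
        speed_s = speed
    heading = np.where(speed > 0, np.arctan2(vy, vx), np.nan)
    accel = np.gradient(speed_s, dt)
    return BehaviorTrack(
        t_s=np.arange(len(x)) / fps,
        x_cm=x,
        y_cm=y,
        fps=fps,
        velocity_cms=speed_s,
        accel_cms2=accel,
        heading_rad=heading,
    )


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs."""
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_rest_periods(
    track: BehaviorTrack, v_max: float = 0.5, min_dur_s: float = 2.0
) -> list[MovementEvent]:
    """Maximal intervals with velocity < ``v_max`` lasting >= ``min_dur_s``."""
    v = track.velocity_cms
    if v is None:
        raise ValueError("track has no velocity; run compute_kinematics first")
    out = []
    for i0, i1 in _runs_below(v < v_max):
        if (i1 - i0) / track.fps >= min_dur_s:
            out.append(
                MovementEvent(
                    kind="rest",
                    start_s=i0 / track.fps,
                    end_s=i1 / track.fps,
                    mean_velocity_cms=float(v[i0:i1].mean()),
                )
            )
    return out


def detect_movement_initiations(
    track: BehaviorTrack,
    rest_s: float = 2.0,
    v_rest: float = 0.5,
    v_move: float = 1.5,
    sustain_s: float = 0.5,
    transition_s: float = 0.5,
) -> list[MovementEvent]:
    """Transitions from >= ``rest_s`` of rest to sustained movement.

    An initiation is the first sample exceeding ``v_move`` that (a) follows
    at least ``rest_s`` of velocity below ``v_rest`` ending no more than
    ``transition_s`` earlier (the acceleration ramp between the thresholds),
    and (b) is followed by velocity above ``v_move`` for ``sustain_s``.
    Initiations are time points.
    """
    v = track.velocity_cms
    if v is None:
        raise ValueError("track has no velocity; run compute_kinematics first")
    fps = track.fps
    n_rest = int(round(rest_s * fps))
    n_sus = int(round(sustain_s * fps))
    n_gap = int(round(transition_s * fps))
    below = v < v_rest
    above = v > v_move
    out = []
    i = n_rest
    while i < len(v):
        if above[i]:
            # last below-threshold sample within the transition allowance
            j0 = max(i - n_gap, 1)
            rest_ok = False
            for j in range(i - 1, j0 - 1, -1):
                if below[j]:
                    rest_ok = j >= n_rest and below[j - n_rest + 1 : j + 1].all()
                    break
            seg = above[i : i + n_sus]
            if rest_ok and len(seg) == n_sus and seg.all():
                t = i / fps
                out.append(MovementEvent(kind="initiation", start_s=t, end_s=t))
                # skip ahead past this movement epoch's start
                i += n_sus
                continue
        i += 1
    return out


def detect_movement_bouts(
    track: BehaviorTrack,
    v_move: float = 1.5,
    v_rest: float = 0.5,
    end_below_s: float = 0.5,
    min_bout_s: float = 0.0,
) -> list[MovementEvent]:
    """Movement bouts: from a crossing of ``v_move`` until velocity has
    stayed below ``v_rest`` for ``end_below_s``."""
    v = track.velocity_cms
    if v is None:
        raise ValueError("track has no velocity; run compute_kinematics first")
    fps = track.fps
    n_end = int(round(end_below_s * fps))
    out = []
    i = 0
    n = len(v)
    while i < n:
        if v[i] > v_move:
            j = i
            low = 0
            while j < n:
                low = low + 1 if v[j] < v_rest else 0
                if low >= n_end:
                    break
                j += 1
            end = j - low + 1 if j < n else n
            dur = (end - i) / fps
            if dur >= min_bout_s:
                out.append(
                    MovementEvent(
                        kind="bout",
                        start_s=i / fps,
                        end_s=end / fps,
                        mean_velocity_cms=float(v[i:end].mean()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return out


def bursts_near_events(
    bursts_by_subject: dict[str, list[BurstEvent]],
    events_by_subject: dict[str, list[MovementEvent]],
    half_window_s: float = 2.0,
    bin_s: float = 0.25,
    sigma_bins: float = 1.0,
) -> dict:
    """Burst occurrence around events, with a subject-averaged aligned histogram.

    For every event, counts whether any burst onset falls within
    +/- ``half_window_s``.  Per subject, burst times relative to events are
    histogrammed (``bin_s`` bins), Gaussian-smoothed (sigma = ``sigma_bins``
    bins), normalized to unit area, then averaged across subjects.
    """
    edges = np.arange(-half_window_s, half_window_s + 1e-9, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    per_subject_hists = []
    n_events = 0
    n_with_burst = 0
    for subj, events in events_by_subject.items():
        if not events:
            continue
        onsets = np.array([b.onset_s for b in bursts_by_subject.get(subj, [])])
        rel_times = []
        for ev in events:
            if len(onsets):
                rel = onsets - ev.start_s
                hit = np.abs(rel) <= half_window_s
                rel_times.extend(rel[hit])
                n_with_burst += bool(hit.any())
            n_events += 1
        hist, _ = np.histogram(rel_times, bins=edges)
        if hist.sum() == 0:
            continue
        smoothed = ndimage.gaussian_filter1d(hist.astype(float), sigma_bins)
        smoothed /= smoothed.sum() * bin_s  # unit area
        per_subject_hists.append(smoothed)
    mean_hist = (
        np.mean(per_subject_hists, axis=0) if per_subject_hists else np.zeros(len(centers))
    )
    return {
        "fraction_events_with_burst": n_with_burst / n_events if n_events else np.nan,
        "bin_centers_s": centers,
        "mean_density": mean_hist,
        "n_subjects": len(per_subject_hists),
    }


def bout_burst_precedence(
    bouts: list[MovementEvent],
    bursts: list[BurstEvent],
    lookback_s: float = 2.0,
    min_bout_s: float = 1.0,
) -> pd.DataFrame:
    """Label bouts (> ``min_bout_s``) by whether a burst preceded them.

    A bout is preceded when some burst onset falls within ``lookback_s``
    before the bout start.  Returns one row per qualifying bout with its
    duration, mean velocity and the precedence flag.
    """
    onsets = np.sort([b.onset_s for b in bursts])
    rows = []
    for bout in bouts:
        if bout.duration_s <= min_bout_s:
            continue
        j = np.searchsorted(onsets, bout.start_s, side="right")
        preceded = j > 0 and bout.start_s - onsets[j - 1] <= lookback_s
        bout.preceded_by_burst = bool(preceded)
        rows.append(
            {
                "start_s": bout.start_s,
                "duration_s": bout.duration_s,
                "mean_velocity_cms": bout.mean_velocity_cms,
                "preceded_by_burst": bool(preceded),
            }
        )
    return pd.DataFrame(rows)


def burst_triggered_velocity(
    bursts_by_subject: dict[str, list[BurstEvent]],
    tracks_by_subject: dict[str, BehaviorTrack],
    window_s: tuple[float, float] = (-3.0, 3.0),
    min_burst_s: float = 0.2,
    alpha: float = 0.05,
) -> dict:
    """Velocity traces aligned to burst onset with binwise FDR t-tests.

    Per subject, velocity traces around every qualifying burst (duration >=
    ``min_burst_s``, full window inside the session) are averaged.  Each
    post-onset time bin is then compared across subjects against that
    subject's pre-onset baseline mean with paired t-tests, Benjamini-Hochberg
    corrected at ``alpha``.
    """
    subj_traces = {}
    n_rel = None
    for subj, bursts in bursts_by_subject.items():
        track = tracks_by_subject[subj]
        v = track.velocity_cms
        fps = track.fps
        pre = int(round(-window_s[0] * fps))
        post = int(round(window_s[1] * fps))
        if n_rel is None:
            n_rel = pre + post + 1
        traces = []
        for b in bursts:
            if b.duration_s < min_burst_s:
                continue
            i = int(round(b.onset_s * fps))
            if i - pre < 0 or i + post + 1 > len(v):
                continue
            traces.append(v[i - pre : i + post + 1])
        if traces:
            subj_traces[subj] = np.mean(traces, axis=0)
    if not subj_traces:
        raise ValueError("no qualifying bursts in any subject")
    fps = next(iter(tracks_by_subject.values())).fps
    t_rel = (np.arange(n_rel) - int(round(-window_s[0] * fps))) / fps
    mat = np.array(list(subj_traces.values()))  # subjects x time
    pre_mask = t_rel < 0
    baseline = mat[:, pre_mask].mean(axis=1)
    post_idx = np.flatnonzero(t_rel >= 0)
    pvals = np.ones(len(post_idx))
    for k, j in enumerate(post_idx):
        col = mat[:, j]
        if len(col) > 1 and np.ptp(col - baseline) > 0:
            pvals[k] = spstats.ttest_rel(col, baseline).pvalue
    if len(mat) > 1:
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        reject = np.zeros(len(post_idx), dtype=bool)
    return {
        "t_rel_s": t_rel,
        "mean_trace": mat.mean(axis=0),
        "sem_trace": mat.std(axis=0, ddof=1) / np.sqrt(len(mat)) if len(mat) > 1 else np.zeros(n_rel),
        "per_subject": subj_traces,
        "post_bin_times_s": t_rel[post_idx],
        "post_bin_p": pvals,
        "significant_bins": t_rel[post_idx][reject],
    }


def theta_power_velocity_correlation(
    theta_env_by_session: dict[str, np.ndarray],
    velocity_by_session: dict[str, np.ndarray],
    condition_by_session: dict[str, str],
) -> dict:
    """Per-condition Pearson r of z-scored theta power vs z-scored velocity,
    plus a power x condition interaction from an ordinary linear model.

    The envelope must already be resampled to the behavior frame times.
    Returns per-condition r, the interaction coefficient and its p value.
    """
    rows = []
    for sid, env in theta_env_by_session.items():
        v = velocity_by_session[sid]
        if len(env) != len(v):
            raise ValueError(f"length mismatch for session {sid}")
        env_z = (env - env.mean()) / env.std()
        v_z = (v - v.mean()) / v.std()
        rows.append(
            pd.DataFrame(
                {"power": env_z, "velocity": v_z,
                 "condition": condition_by_session[sid], "session": sid}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    out = {"per_condition_r": {}}
    for cond, g in df.groupby("condition"):
        out["per_condition_r"][cond] = float(
            np.corrcoef(g["power"], g["velocity"])[0, 1]
        )
    conds = sorted(df["condition"].unique())
    if len(conds) == 2:
        import statsmodels.formula.api as smf

        df["cond_bin"] = (df["condition"] == conds[1]).astype(float)
        fit = smf.ols("velocity ~ power * cond_bin", data=df).fit()
        out["interaction_coef"] = float(fit.params["power:cond_bin"])
        out["interaction_p"] = float(fit.pvalues["power:cond_bin"])
    return out


def lme_design_table(
    traces_by_subject_condition: dict[tuple[str, str], np.ndarray],
    t_rel_s: np.ndarray,
) -> pd.DataFrame:
    """Long-format design table for a mixed model on aligned velocity traces.

    Columns: subject, condition, time_s, velocity — ready for a standard
    mixed-model fit (fixed: condition, time, interaction; random intercept
    per subject), which is delegated to a statistics package.
    """
    rows = []
    for (subj, cond), trace in traces_by_subject_condition.items():
        rows.append(
            pd.DataFrame(
                {"subject": subj, "condition": cond, "time_s": t_rel_s,
                 "velocity": trace}
            )
        )
    return pd.concat(rows, ignore_index=True)
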