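"""Synthetic multi-region LFP sessions with known burst/coupling ground truth.

The generator emulates the statistical structure the downstream analyses
assume: three regions (MS, CA1, mPFC) of 1/f background noise carrying
Hann-enveloped sinusoidal theta bursts; an MS->CA1 propagation rule in which
an MS burst spawns, with configurable probability, a CA1 burst at a (truncated
normal, non-negative) delay after MS burst completion, copying the MS carrier
frequency and imposing a fixed phase lag; and an optional lower-amplitude
phase-locked theta tail sustained in both regions after coupled CA1 bursts,
which models the post-burst coherence elevation the peri-burst analyses
measure.  A two-state (rest/move) semi-Markov behavior track is generated at
the video frame rate, optionally time-locking movement onsets to CA1 bursts.

Everything injected is logged in :class:`~thetaburst.session.GroundTruth`, so
every detector and estimator in the package can be scored against truth.
"""

from __future__ import annotations

import numpy as np

from .config import REGIONS, SynthConfig
from .session import BehaviorTrack, GroundTruth, LfpSession

__all__ = [
    "powerlaw_noise",
    "generate_lfp_session",
    "generate_behavior_track",
    "generate_condition_dataset",
    "delayed_copy",
]


def powerlaw_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f**exponent.

    Spectrally shaped by scaling the rFFT of white noise with an
    f**(-exponent/2) amplitude profile (DC bin copied from the first nonzero
    frequency).  Output is normalized to unit RMS.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.empty_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = amp[1]
    sig = np.fft.irfft(spec * amp, n=n)
    return sig / np.std(sig)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_independent_bursts(
    rng: np.random.Generator,
    rate_per_min: float,
    duration_s: float,
    dur_mu: float,
    dur_sigma: float,
    freq_hz: float,
    occupied: list[tuple[float, float]],
    edge_s: float = 2.0,
    max_tries: int = 100,
) -> tuple[list[tuple[float, float, float, float]], int]:
    """Poisson-count bursts with non-overlapping placements.

    Returns (bursts, n_redraws) where each burst is
    (onset_s, offset_s, freq_hz, phase0).  Placements overlapping an already
    occupied interval are re-drawn; after ``max_tries`` the event is dropped
    and counted as a merge.
    """
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    bursts: list[tuple[float, float, float, float]] = []
    merges = 0
    for _ in range(n):
        dur = float(rng.lognormal(dur_mu, dur_sigma))
        dur = min(dur, duration_s / 4.0)
        placed = False
        for _try in range(max_tries):
            onset = float(rng.uniform(edge_s, duration_s - edge_s - dur))
            if all(
                onset >= b or onset + dur <= a for a, b in occupied
            ):
                placed = True
                break
            merges += 1
        if not placed:
            continue
        phase0 = float(rng.uniform(-np.pi, np.pi))
        occupied.append((onset - 0.05, onset + dur + 0.05))
        bursts.append((onset, onset + dur, freq_hz, phase0))
    bursts.sort()
    return bursts, merges


def _render_burst(
    signal: np.ndarray,
    fs: float,
    onset: float,
    offset: float,
    freq: float,
    amp: float,
    phase_ref_t: float,
    phase0: float,
) -> None:
    """Add a Hann-enveloped sinusoid in place.

    The carrier phase is referenced to ``phase_ref_t`` so two bursts sharing a
    reference time and frequency have an exactly known phase relation.
    """
    i0 = int(round(onset * fs))
    i1 = min(int(round(offset * fs)), len(signal))
    if i1 - i0 < 2:
        return
    t = np.arange(i0, i1) / fs
    env = np.hanning(i1 - i0)
    signal[i0:i1] += amp * env * np.cos(2 * np.pi * freq * (t - phase_ref_t) + phase0)


def _render_tail(
    signal: np.ndarray,
    fs: float,
    start: float,
    hold_s: float,
    decay_s: float,
    freq: float,
    amp: float,
    phase_ref_t: float,
    phase0: float,
) -> None:
    """Add a locked theta component: constant amplitude then linear decay."""
    i0 = int(round(start * fs))
    i1 = min(int(round((start + hold_s + decay_s) * fs)), len(signal))
    if i1 - i0 < 2:
        return
    t = np.arange(i0, i1) / fs
    env = np.ones(i1 - i0)
    n_hold = min(int(round(hold_s * fs)), i1 - i0)
    n_dec = i1 - i0 - n_hold
    if n_dec > 0:
        env[n_hold:] = np.linspace(1.0, 0.0, n_dec)
    signal[i0:i1] += amp * env * np.cos(2 * np.pi * freq * (t - phase_ref_t) + phase0)


def generate_lfp_session(config: SynthConfig) -> tuple[LfpSession, GroundTruth]:
    """Generate a three-region LFP session plus its ground-truth event log.

    Identical config (including seed) gives bit-identical output.  Burst peak
    amplitude is ``config.snr`` times the background RMS (which is 1).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    signals = {r: powerlaw_noise(n, cfg.fs, cfg.noise_exponent, rng) for r in REGIONS}

    gt = GroundTruth(true_phase_lag_rad=cfg.phase_lag_rad)
    amp = cfg.snr
    dur_mu, dur_sigma = _lognormal_params(cfg.burst_dur_mean_s, cfg.burst_dur_sd_s)

    if cfg.snr == 0 or cfg.burst_rate_per_min == 0:
        rate_ms = rate_pfc = 0.0
    else:
        rate_ms = rate_pfc = cfg.burst_rate_per_min
    ca1_rate = (
        cfg.ca1_independent_rate_per_min
        if cfg.ca1_independent_rate_per_min is not None
        else rate_ms
    )
    if cfg.snr == 0:
        ca1_rate = 0.0

    occupied: dict[str, list[tuple[float, float]]] = {r: [] for r in REGIONS}

    ms_bursts, m1 = _draw_independent_bursts(
        rng, rate_ms, cfg.duration_s, dur_mu, dur_sigma, cfg.burst_freq_hz,
        occupied["MS"],
    )
    gt.merges += m1

    # MS -> CA1 propagation: each MS burst spawns a coupled CA1 burst with
    # probability coupling_prob at a truncated-normal (>= 0) delay measured
    # from MS burst completion; the CA1 burst copies the MS carrier frequency
    # and lags its phase by phase_lag_rad.
    coupled_ca1: list[tuple[float, float, float, float, float, int]] = []
    for ms_idx, (on, off, f, ph) in enumerate(ms_bursts):
        if rng.uniform() >= cfg.coupling_prob:
            continue
        placed = False
        for _try in range(20):  # re-draw delay/duration on collision
            delay = rng.normal(cfg.coupling_delay_mean_s, cfg.coupling_delay_sd_s)
            if delay < 0:
                continue
            dur = min(float(rng.lognormal(dur_mu, dur_sigma)), cfg.duration_s / 4.0)
            c_on = off + delay
            c_off = c_on + dur
            if c_off + cfg.lock_tail_s >= cfg.duration_s - 0.5:
                continue
            if any(c_on < b and c_off > a for a, b in occupied["CA1"]):
                gt.merges += 1
                continue
            placed = True
            break
        if not placed:
            continue
        occupied["CA1"].append((c_on - 0.05, c_off + 0.05))
        # CA1 phase referenced to the same origin as its parent MS burst so
        # that phi_MS - phi_CA1 == phase_lag_rad exactly during overlap.
        coupled_ca1.append((c_on, c_off, f, ph - cfg.phase_lag_rad, on, ms_idx))

    ca1_ind, m2 = _draw_independent_bursts(
        rng, ca1_rate, cfg.duration_s, dur_mu, dur_sigma, cfg.burst_freq_hz,
        occupied["CA1"],
    )
    gt.merges += m2
    pfc_bursts, m3 = _draw_independent_bursts(
        rng, rate_pfc, cfg.duration_s, dur_mu, dur_sigma, cfg.burst_freq_hz,
        occupied["mPFC"],
    )
    gt.merges += m3

    # render MS / mPFC independent bursts
    for on, off, f, ph in ms_bursts:
        _render_burst(signals["MS"], cfg.fs, on, off, f, amp, on, ph)
    for on, off, f, ph in pfc_bursts:
        _render_burst(signals["mPFC"], cfg.fs, on, off, f, amp, on, ph)
    for on, off, f, ph in ca1_ind:
        _render_burst(signals["CA1"], cfg.fs, on, off, f, amp, on, ph)

    # render coupled CA1 bursts plus the locked low-amplitude components that
    # keep the two regions phase-locked across the whole event (MS onset ->
    # CA1 offset) and through a decaying post-burst tail
    tail_amp = cfg.lock_tail_gain * amp
    for c_on, c_off, f, ph_ca1, ms_on, ms_idx in coupled_ca1:
        _render_burst(signals["CA1"], cfg.fs, c_on, c_off, f, amp, ms_on, ph_ca1)
        if cfg.lock_tail_s > 0 and tail_amp > 0:
            ph_ms = ph_ca1 + cfg.phase_lag_rad
            ms_off = ms_bursts[ms_idx][1]
            # MS stays locked from its burst end through the CA1 burst
            _render_tail(
                signals["MS"], cfg.fs, ms_off, c_off - ms_off, cfg.lock_tail_s,
                f, tail_amp, ms_on, ph_ms,
            )
            # CA1 is entrained from MS burst onset and rings out afterwards
            _render_tail(
                signals["CA1"], cfg.fs, ms_on, c_on - ms_on, 0.0,
                f, tail_amp, ms_on, ph_ca1,
            )
            _render_tail(
                signals["CA1"], cfg.fs, c_off, 0.0, cfg.lock_tail_s,
                f, tail_amp, ms_on, ph_ca1,
            )

    # assemble ground-truth burst table (per-region onset ordering)
    ca1_all = sorted(
        [(on, off, f) for on, off, f, _ph in ca1_ind]
        + [(on, off, f) for on, off, f, _p, _m, _i in coupled_ca1]
    )
    for on, off, f, _ph in ms_bursts:
        gt.true_bursts.append(("MS", on, off, f))
    for on, off, f in ca1_all:
        gt.true_bursts.append(("CA1", on, off, f))
    for on, off, f, _ph in pfc_bursts:
        gt.true_bursts.append(("mPFC", on, off, f))

    ca1_onsets = [on for on, _off, _f in ca1_all]
    for c_on, c_off, f, _ph, _ms_on, ms_idx in coupled_ca1:
        ca1_idx = int(np.searchsorted(ca1_onsets, c_on))
        delay = c_on - ms_bursts[ms_idx][1]
        gt.true_pairs.append((ms_idx, ca1_idx, float(max(delay, 0.0))))
    gt.true_pairs.sort()

    session = LfpSession(
        signals=signals,
        fs=cfg.fs,
        condition="synthetic",
        subject_id=f"synth-{cfg.seed}",
    )
    return session, gt


def generate_behavior_track(
    config: SynthConfig, ground_truth: GroundTruth | None = None
) -> BehaviorTrack:
    """Two-state (rest/move) semi-Markov position track at ``config.fps``.

    Rest epochs hold speed near ``rest_speed_cms`` (< 0.5 cm/s), movement
    epochs near ``move_speed_cms`` (> 1.5 cm/s), with Gaussian speed noise and
    a slowly drifting heading.  When ``lock_fraction`` > 0 and CA1 ground
    truth is supplied, that fraction of movement onsets is placed exactly
    ``lock_delay_s`` after a CA1 burst onset.  State epochs and the realized
    mean speed are recorded in the ground-truth log when one is passed.
    """
    cfg = config
    # independent stream so the track does not perturb LFP reproducibility
    rng = np.random.default_rng((cfg.seed, 0xBEE))
    n = int(round(cfg.duration_s * cfg.fps))
    dt = 1.0 / cfg.fps

    triggers: list[float] = []
    if cfg.lock_fraction > 0 and ground_truth is not None:
        ca1 = [on for on, _off, _f in ground_truth.bursts_in("CA1")]
        if ca1:
            k = max(1, int(round(cfg.lock_fraction * len(ca1))))
            pick = sorted(rng.choice(len(ca1), size=min(k, len(ca1)), replace=False))
            triggers = [ca1[i] + cfg.lock_delay_s for i in pick]

    min_rest = 3.0  # rests must be detectable by the >= 2 s rest criterion
    epochs: list[tuple[str, float, float]] = []
    t = 0.0
    ti = 0
    state = "rest"
    while t < cfg.duration_s:
        if state == "rest":
            # advance past triggers that are no longer usable
            while ti < len(triggers) and triggers[ti] < t + min_rest:
                ti += 1
            if ti < len(triggers):
                end = triggers[ti]
                ti += 1
            elif triggers:
                end = cfg.duration_s  # no more locked onsets: rest out
            else:
                end = t + min_rest + rng.exponential(
                    max(cfg.rest_dur_mean_s - min_rest, 0.5)
                )
            epochs.append(("rest", t, min(end, cfg.duration_s)))
            state = "move"
        else:
            dur = 2.0 + rng.exponential(max(cfg.move_dur_mean_s - 2.0, 0.5))
            end = t + dur
            epochs.append(("move", t, min(end, cfg.duration_s)))
            state = "rest"
        t = end

    speed = np.empty(n)
    for kind, a, b in epochs:
        i0, i1 = int(round(a * cfg.fps)), min(int(round(b * cfg.fps)), n)
        base = cfg.rest_speed_cms if kind == "rest" else cfg.move_speed_cms
        sd = cfg.speed_sd_cms * (0.2 if kind == "rest" else 1.0)
        speed[i0:i1] = base + sd * rng.standard_normal(max(i1 - i0, 0))
    np.clip(speed, 0.0, None, out=speed)

    # slowly drifting heading; reflect positions at the arena walls
    heading = np.cumsum(0.08 * rng.standard_normal(n))
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = 10.0, 16.0
    for i in range(1, n):
        x[i] = x[i - 1] + speed[i] * dt * np.cos(heading[i])
        y[i] = y[i - 1] + speed[i] * dt * np.sin(heading[i])
        if not 0.0 <= x[i] <= 20.3:  # 8 in arena width
            heading[i:] = np.pi - heading[i:]
            x[i] = np.clip(x[i], 0.0, 20.3)
        if not 0.0 <= y[i] <= 33.0:  # 13 in arena length
            heading[i:] = -heading[i:]
            y[i] = np.clip(y[i], 0.0, 33.0)

    if ground_truth is not None:
        ground_truth.behavior_events = [
            (k, float(a), float(b)) for k, a, b in epochs
        ]
        ground_truth.target_mean_velocity_cms = float(np.mean(speed))

    return BehaviorTrack(
        t_s=np.arange(n) / cfg.fps, x_cm=x, y_cm=y, fps=cfg.fps
    )


def generate_condition_dataset(
    config_a: SynthConfig,
    config_b: SynthConfig,
    n_sessions: int,
    labels: tuple[str, str] = ("saline", "etoh"),
) -> list[tuple[LfpSession, GroundTruth]]:
    """Balanced two-condition collection of sessions with recorded seeds.

    ``n_sessions`` sessions per condition; session i of condition c uses seed
    ``base_seed + 1000*c + i`` so the collection is reproducible and each
    session is independent.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions per label")
    out: list[tuple[LfpSession, GroundTruth]] = []
    for ci, (cfg, label) in enumerate(zip((config_a, config_b), labels)):
        for i in range(n_sessions):
            c = cfg.replace(seed=int(cfg.seed) + 1000 * ci + i)
            sess, gt = generate_lfp_session(c)
            sess.condition = label
            sess.subject_id = f"{label}-{i}"
            out.append((sess, gt))
    return out


def burst_match_score(
    detected, truth: list[tuple[float, float, float]], tol_s: float = 0.1
) -> dict:
    """Score detected bursts against ground truth by onset proximity.

    One-to-one greedy matching: each true burst claims the nearest unused
    detected onset within ``tol_s``.  Returns precision, recall, F1 and the
    matched onset errors.
    """
    t_on = np.array([t[0] for t in truth])
    d_on = np.array([b.onset_s for b in detected])
    used = np.zeros(len(d_on), dtype=bool)
    errors = []
    for t in t_on:
        if not len(d_on):
            break
        err = np.abs(d_on - t)
        err[used] = np.inf
        j = int(np.argmin(err))
        if err[j] <= tol_s:
            used[j] = True
            errors.append(d_on[j] - t)
    tp = len(errors)
    precision = tp / len(d_on) if len(d_on) else 0.0
    recall = tp / len(t_on) if len(t_on) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "onset_errors_s": np.array(errors),
        "n_true": len(t_on),
        "n_detected": len(d_on),
    }


def pairs_from_ground_truth(gt: GroundTruth):
    """Build :class:`~thetaburst.coupling.BurstPair` objects from the
    generator's true event times (bypassing detection), for estimator
    recovery analyses."""
    from .burst_detection import BurstEvent
    from .coupling import BurstPair

    ms = gt.bursts_in("MS")
    ca1 = gt.bursts_in("CA1")
    pairs = []
    for ms_idx, ca1_idx, delay in gt.true_pairs:
        m_on, m_off, m_f = ms[ms_idx]
        c_on, c_off, c_f = ca1[ca1_idx]
        pairs.append(
            BurstPair(
                ms_burst=BurstEvent("MS", "theta", m_on, m_off, np.nan, np.nan, m_f),
                ca1_burst=BurstEvent("CA1", "theta", c_on, c_off, np.nan, np.nan, c_f),
                delay_s=delay,
            )
        )
    return pairs


def delayed_copy(signal: np.ndarray, fs: float, delay_s: float) -> np.ndarray:
    """Copy of ``signal`` delayed by ``delay_s`` (possibly a fraction of a
    sample) via a linear-phase shift in the frequency domain.

    Used to construct signals with an exactly known inter-regional envelope
    delay for lag-recovery checks.  The shift is circular; keep the delay
    small relative to the signal length.
    """
    n = len(signal)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(signal) * np.exp(-2j * np.pi * freqs * delay_s)
    return np.fft.irfft(spec, n=n)
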