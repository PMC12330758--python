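"""End-to-end orchestration: preprocessing -> bursts -> rhythmicity/lag ->
coupling -> phase -> behavior, with CSV/JSON outputs and a run manifest.

Every output embeds the configuration hash; identical config and seed give
identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    bursts_near_events,
    compute_kinematics,
    detect_movement_initiations,
    detect_rest_periods,
)
from .burst_detection import detect_theta_bursts, summarize_bursts
from .config import PipelineConfig, SynthConfig
from .coupling import latency_split, pair_bursts
from .phase import peri_burst_plv, post_burst_phase_offsets, windowed_plv
from .preprocessing import analytic_signal, bandpass_fir, welch_psd
from .rhythmicity import envelope_lag, lagged_coherence
from .session import BehaviorTrack, LfpSession
from .synthetic import generate_behavior_track, generate_lfp_session

logger = logging.getLogger("thetaburst")

__all__ = ["run_pipeline", "validate_inputs"]


def run_pipeline(
    config: PipelineConfig,
    session: LfpSession | None = None,
    track: BehaviorTrack | None = None,
    synth_config: SynthConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on one session and return (and optionally write) the
    result bundle.

    Either pass a ``session`` (with optional behavior ``track``) or a
    ``synth_config`` to generate one.  Writes burst/pair/PLV/lag tables as
    CSV and a summary JSON with the config hash when ``out_dir`` is given.
    """
    if session is None:
        if synth_config is None:
            raise ValueError("pass a session or a synth_config")
        session, gt = generate_lfp_session(synth_config)
        if track is None:
            track = generate_behavior_track(synth_config, gt)
    for region in ("MS", "CA1"):
        if region not in session.signals:
            raise ValueError(f"session is missing required region {region!r}")

    fs = session.fs
    results: dict = {"config_hash": config.config_hash(), "fs": fs}

    # preprocessing: per-region theta analytic signal + PSD
    env, phase, psd = {}, {}, {}
    for region, sig in session.signals.items():
        filt = bandpass_fir(sig, fs, "theta")
        env[region], phase[region] = analytic_signal(filt)
        psd[region] = welch_psd(sig, fs, win_s=config.welch_win_s, nfft=config.nfft)
    results["rel_power"] = {r: s.rel_power for r, s in psd.items()}

    # burst detection
    bursts = {
        r: detect_theta_bursts(
            session.signals[r], fs, region=r,
            high_k=config.high_k, low_k=config.low_k,
            baseline_stat=config.baseline_stat,
            n_cycles=config.min_cycles, ref_freq_hz=config.ref_freq_hz,
        )
        for r in session.signals
    }
    results["bursts"] = bursts
    results["burst_summary"] = {
        r: summarize_bursts(b, session.duration_s) for r, b in bursts.items()
    }
    logger.info("bursts detected: %s", {r: len(b) for r, b in bursts.items()})

    # rhythmicity and envelope lag
    results["lagged_coherence"] = {
        r: lagged_coherence(session.signals[r], fs).value for r in session.signals
    }
    results["lag_series"] = envelope_lag(
        env["MS"], env["CA1"], fs,
        win_s=config.lag_win_s, step_s=config.lag_step_s,
        max_lag_s=config.max_lag_s,
    )

    # MS->CA1 coupling
    pairs = pair_bursts(bursts["MS"], bursts["CA1"], config.pair_max_delay_s)
    if len(pairs) >= 8:
        pairs = latency_split(pairs)
    results["pairs"] = pairs
    logger.info("pairs formed: %d", len(pairs))

    # phase metrics
    results["plv_series"] = windowed_plv(
        phase["MS"], phase["CA1"], fs, win_s=config.plv_win_s
    )
    peri = [
        p
        for pair in pairs
        if (
            p := peri_burst_plv(
                pair, phase["MS"], phase["CA1"], fs,
                pre_s=config.peri_pre_s, post_s=config.peri_post_s,
            )
        )
        is not None
    ]
    results["peri_burst_plv"] = peri
    results["phase_offsets"] = post_burst_phase_offsets(
        pairs, phase["MS"], phase["CA1"], fs,
        window_s=config.offset_window_s, precede_s=config.phase_precede_s,
    )

    # behavior alignment
    if track is not None:
        kin = compute_kinematics(track.x_cm, track.y_cm, fps=track.fps)
        rests = detect_rest_periods(kin, config.v_rest_cms, config.rest_min_s)
        inits = detect_movement_initiations(
            kin, rest_s=config.rest_min_s, v_rest=config.v_rest_cms,
            v_move=config.v_move_cms, sustain_s=config.sustain_s,
        )
        results["track"] = kin
        results["rest_periods"] = rests
        results["initiations"] = inits
        results["burst_event_alignment"] = bursts_near_events(
            {session.subject_id: bursts["CA1"]}, {session.subject_id: inits}
        )

    if out_dir is not None:
        _write_bundle(results, session, config, Path(out_dir))
    return results


def _write_bundle(
    results: dict, session: LfpSession, config: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    chash = results["config_hash"]
    burst_rows = [
        {
            "session_id": session.subject_id, "region": b.region, "band": b.band,
            "onset_s": b.onset_s, "offset_s": b.offset_s,
            "duration_s": b.duration_s, "peak_env": b.peak_env,
            "mean_env": b.mean_env, "peak_freq_hz": b.peak_freq_hz,
            "config_hash": chash,
        }
        for blist in results["bursts"].values()
        for b in blist
    ]
    pd.DataFrame(burst_rows).to_csv(out / "bursts.csv", index=False)
    pair_rows = [
        {
            "session_id": session.subject_id,
            "ms_onset": p.ms_burst.onset_s, "ms_offset": p.ms_burst.offset_s,
            "ca1_onset": p.ca1_burst.onset_s, "delay_s": p.delay_s,
            "latency_group": p.latency_group,
            "ms_dur": p.ms_burst.duration_s, "ca1_dur": p.ca1_burst.duration_s,
            "config_hash": chash,
        }
        for p in results["pairs"]
    ]
    pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False)
    plv = results["plv_series"]
    pd.DataFrame(
        {"window_start_s": plv.window_starts_s, "plv": plv.plv, "config_hash": chash}
    ).to_csv(out / "plv.csv", index=False)
    lags = results["lag_series"]
    pd.DataFrame(
        {
            "session_id": session.subject_id,
            "window_start_s": lags.window_starts_s,
            "lag_s": lags.lag_s,
            "centered_lag_s": lags.centered_lag_s,
            "config_hash": chash,
        }
    ).to_csv(out / "lags.csv", index=False)
    summary = {
        "config_hash": chash,
        "config": config.to_dict(),
        "version": __version__,
        "session_id": session.subject_id,
        "condition": session.condition,
        "n_bursts": {r: len(b) for r, b in results["bursts"].items()},
        "n_pairs": len(results["pairs"]),
        "plv_session_mean": plv.session_mean,
        "lagged_coherence": results["lagged_coherence"],
        "lag_sd_s": lags.sd_lag_s,
        "rel_power": results["rel_power"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def validate_inputs(session_dir: str | Path, fps: float = 20.0) -> list[str]:
    """Report-only validation of an on-disk session directory.

    Checks the sidecar, region arrays (presence, equal length, NaN blocks)
    and behavior/LFP time alignment.  Returns a list of human-readable
    issues; an empty list means the session looks well formed.
    """
    d = Path(session_dir)
    issues: list[str] = []
    meta_path = d / "session.json"
    if not meta_path.exists():
        return [f"missing sidecar {meta_path}"]
    meta = json.loads(meta_path.read_text())
    if meta.get("fs", 0) <= 0:
        issues.append(f"invalid sampling rate: {meta.get('fs')}")
    lengths = {}
    for region in meta.get("regions", []):
        path = d / f"{region}.npy"
        if not path.exists():
            issues.append(f"missing region array {path.name}")
            continue
        arr = np.load(path)
        lengths[region] = len(arr)
        nan_idx = np.flatnonzero(np.isnan(arr))
        if len(nan_idx):
            issues.append(
                f"region {region}: {len(nan_idx)} NaN samples "
                f"(first at {nan_idx[0]}, last at {nan_idx[-1]})"
            )
    if len(set(lengths.values())) > 1:
        issues.append(f"region length mismatch: {lengths}")
    behavior = d / "behavior.csv"
    if behavior.exists() and lengths:
        n_frames = len(pd.read_csv(behavior))
        lfp_dur = next(iter(lengths.values())) / meta["fs"]
        beh_dur = n_frames / fps
        if abs(beh_dur - lfp_dur) > 1.0:
            issues.append(
                f"behavior/LFP misalignment: track spans {beh_dur:.1f} s, "
                f"LFP spans {lfp_dur:.1f} s"
            )
    return issues
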