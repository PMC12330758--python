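"""Per-burst feature extraction and condition classification.

Each detected burst yields waveform features (envelope skewness,
rise/decay asymmetry, peak/mean envelope), spectral features (normalized
Shannon entropy over 4-20 Hz, peak frequency) and contextual features
(inter-burst interval, session time).  A gradient-boosted tree classifier
(engine delegated to xgboost) is trained to predict the condition label,
evaluated with session-grouped cross-validation so no session leaks across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .burst_detection import BurstEvent
from .metrics import roc_pr_confusion

__all__ = [
    "FEATURE_COLUMNS",
    "extract_features",
    "session_feature_table",
    "train_eval",
]

FEATURE_COLUMNS = [
    "duration_s",
    "peak_env",
    "mean_env",
    "envelope_skewness",
    "spectral_entropy",
    "peak_freq_hz",
    "rise_decay_asymmetry",
    "n_cycles",
    "inter_burst_interval_s",
    "session_time_s",
]


def extract_features(
    burst: BurstEvent,
    band_signal: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    prev_burst_offset_s: float | None = None,
) -> dict:
    """Feature vector for one burst.

    Waveform features come from the burst's envelope segment, spectral
    features from the band signal segment's periodogram restricted to
    4-20 Hz (entropy normalized to [0, 1] by log of the bin count), and
    contextual features from the burst's position in the session.
    """
    i0 = int(round(burst.onset_s * fs))
    i1 = int(round(burst.offset_s * fs))
    if i1 - i0 < 4:
        raise ValueError("burst shorter than 4 samples")
    env_seg = envelope[i0:i1]
    sig_seg = band_signal[i0:i1]

    skew = float(spstats.skew(env_seg)) if np.ptp(env_seg) > 0 else 0.0
    asym = float(np.argmax(env_seg)) / len(env_seg)

    freqs = np.fft.rfftfreq(len(sig_seg), d=1.0 / fs)
    power = np.abs(np.fft.rfft(sig_seg - sig_seg.mean())) ** 2
    band_mask = (freqs >= 4.0) & (freqs <= 20.0)
    p_band = power[band_mask]
    if p_band.sum() > 0 and len(p_band) > 1:
        p_norm = p_band / p_band.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p_norm > 0, p_norm * np.log(p_norm), 0.0))
        entropy = float(h / np.log(len(p_band)))
        peak_freq = float(freqs[band_mask][np.argmax(p_band)])
    else:
        entropy, peak_freq = 1.0, float("nan")

    ibi = (
        burst.onset_s - prev_burst_offset_s
        if prev_burst_offset_s is not None
        else np.nan
    )
    return {
        "duration_s": burst.duration_s,
        "peak_env": burst.peak_env,
        "mean_env": burst.mean_env,
        "envelope_skewness": skew,
        "spectral_entropy": entropy,
        "peak_freq_hz": peak_freq,
        "rise_decay_asymmetry": asym,
        "n_cycles": burst.duration_s * (peak_freq if np.isfinite(peak_freq) else 8.0),
        "inter_burst_interval_s": ibi,
        "session_time_s": burst.onset_s,
    }


def session_feature_table(
    bursts: list[BurstEvent],
    band_signal: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    label: str,
    session_id: str,
) -> pd.DataFrame:
    """Feature rows for every burst of one session, condition-labeled."""
    rows = []
    prev_off = None
    for b in sorted(bursts, key=lambda b: b.onset_s):
        try:
            feats = extract_features(b, band_signal, envelope, fs, prev_off)
        except ValueError:
            continue
        feats["label"] = label
        feats["session_id"] = session_id
        rows.append(feats)
        prev_off = b.offset_s
    return pd.DataFrame(rows)


def train_eval(
    features: pd.DataFrame,
    seed: int = 0,
    n_splits: int = 5,
    positive_label: str | None = None,
    allow_leakage: bool = False,
    threshold: float = 0.5,
) -> dict:
    """Grouped cross-validated gradient-boosting classification report.

    Features are z-normalized on each training fold only; folds hold out
    whole sessions (GroupKFold by ``session_id``) unless ``allow_leakage``
    deliberately demonstrates pooled-split inflation.  Out-of-fold predicted
    probabilities feed the in-package ROC/PR/confusion metrics.
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
    from xgboost import XGBClassifier

    labels = sorted(features["label"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    pos = positive_label if positive_label is not None else labels[1]
    y = (features["label"] == pos).to_numpy(int)
    x = features[FEATURE_COLUMNS].to_numpy(float)
    groups = features["session_id"].to_numpy()

    if allow_leakage:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(x, y)
    else:
        # whole sessions held out, with both classes kept in every fold so
        # pooled out-of-fold probabilities stay comparable
        n_groups = len(np.unique(groups))
        splitter = StratifiedGroupKFold(
            n_splits=min(n_splits, n_groups // 2), shuffle=True, random_state=seed
        )
        split_iter = splitter.split(x, y, groups)

    y_prob = np.full(len(y), np.nan)
    for train_idx, test_idx in split_iter:
        mu = np.nanmean(x[train_idx], axis=0)
        sd = np.nanstd(x[train_idx], axis=0)
        sd[sd == 0] = 1.0
        xt = (x - mu) / sd
        xt = np.nan_to_num(xt, nan=0.0)
        model = XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            subsample=0.9,
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
        )
        model.fit(xt[train_idx], y[train_idx])
        y_prob[test_idx] = model.predict_proba(xt[test_idx])[:, 1]

    valid = np.isfinite(y_prob)
    report = roc_pr_confusion(y[valid], y_prob[valid], threshold=threshold)
    report["positive_label"] = pos
    report["n_bursts"] = int(valid.sum())
    report["y_true"] = y[valid]
    report["y_prob"] = y_prob[valid]
    report["hyperparameters"] = {
        "n_estimators": 200, "max_depth": 3, "learning_rate": 0.1,
        "subsample": 0.9, "seed": seed, "grouped_split": not allow_leakage,
    }
    return report
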