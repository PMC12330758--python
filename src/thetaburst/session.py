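"""In-memory containers for a recording session and its derived objects."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LfpSession:
    """Multi-region LFP recording: one signal array per region at a common fs.

    Parameters
    ----------
    signals : dict mapping region name -> 1-D float array (volts, arbitrary gain)
    fs : sampling rate in Hz
    condition : experimental condition label (e.g. ``"saline"`` or ``"etoh"``)
    subject_id : subject label
    t0 : session start time in seconds
    """

    signals: dict[str, np.ndarray]
    fs: float
    condition: str = "saline"
    subject_id: str = "s0"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {k: len(v) for k, v in self.signals.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"region signals differ in length: {lengths}")
        for name, sig in self.signals.items():
            arr = np.asarray(sig, dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"NaN samples in region {name}")
            self.signals[name] = arr

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def regions(self) -> list[str]:
        return list(self.signals)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    # -- disk round trip: one array file per region + JSON sidecar ---------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for region, sig in self.signals.items():
            np.save(out / f"{region}.npy", sig)
        meta = {
            "fs": self.fs,
            "regions": self.regions,
            "condition": self.condition,
            "subject_id": self.subject_id,
            "t0": self.t0,
        }
        (out / "session.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def load(cls, session_dir: str | Path) -> "LfpSession":
        d = Path(session_dir)
        meta = json.loads((d / "session.json").read_text())
        signals = {r: np.load(d / f"{r}.npy") for r in meta["regions"]}
        return cls(
            signals=signals,
            fs=meta["fs"],
            condition=meta.get("condition", "saline"),
            subject_id=meta.get("subject_id", "s0"),
            t0=meta.get("t0", 0.0),
        )


@dataclass
class GroundTruth:
    """Event log of everything the synthetic generator injected.

    ``true_bursts`` rows: (region, onset_s, offset_s, freq_hz).
    ``true_pairs`` rows: (ms_index, ca1_index, delay_s) where indices refer to
    the per-region ordering of ``true_bursts`` and delay is CA1 onset minus
    MS offset.  ``merges`` counts burst placements that had to be re-drawn or
    merged to avoid within-region overlap.
    """

    true_bursts: list[tuple[str, float, float, float]] = field(default_factory=list)
    true_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    true_phase_lag_rad: float = 0.0
    behavior_events: list[tuple[str, float, float]] = field(default_factory=list)
    merges: int = 0
    target_mean_velocity_cms: float = float("nan")

    def bursts_in(self, region: str) -> list[tuple[float, float, float]]:
        """(onset, offset, freq) tuples for one region, onset-sorted."""
        rows = [(o, f, fr) for r, o, f, fr in self.true_bursts if r == region]
        return sorted(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.true_bursts, columns=["region", "onset_s", "offset_s", "freq_hz"]
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "true_bursts.csv", index=False)
        pd.DataFrame(
            self.true_pairs, columns=["ms_index", "ca1_index", "delay_s"]
        ).to_csv(out / "true_pairs.csv", index=False)
        pd.DataFrame(
            self.behavior_events, columns=["kind", "start_s", "end_s"]
        ).to_csv(out / "behavior_events.csv", index=False)


@dataclass
class BehaviorTrack:
    """Position track at the video frame rate with derived kinematics."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    fps: float = 20.0
    velocity_cms: np.ndarray | None = None
    accel_cms2: np.ndarray | None = None
    heading_rad: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"frame": np.arange(len(self.t_s)), "x_cm": self.x_cm, "y_cm": self.y_cm}
        )
        return out

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, fps: float = 20.0) -> "BehaviorTrack":
        df = pd.read_csv(path)
        t = df["frame"].to_numpy(float) / fps
        return cls(
            t_s=t,
            x_cm=df["x_cm"].to_numpy(float),
            y_cm=df["y_cm"].to_numpy(float),
            fps=fps,
        )
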