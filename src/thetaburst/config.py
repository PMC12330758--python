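"""Configuration objects and the frequency-band tables used across the pipeline.

Two band tables are maintained: the primary analysis bands (theta 5-12 Hz is
the burst-detection band) and a low/high theta split (4-8 / 8-12 Hz) used for
the relative-power contrast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges: {self.f_lo}..{self.f_hi}")


#: Standard analysis bands.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 5.0, 12.0),
        BandDefinition("beta", 13.0, 20.0),
        BandDefinition("low_gamma", 30.0, 55.0),
        BandDefinition("high_gamma", 65.0, 100.0),
    )
}

#: Low/high theta split used for the relative-power contrast.
THETA_SPLIT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("low_theta", 4.0, 8.0),
        BandDefinition("high_theta", 8.0, 12.0),
    )
}

REGIONS = ("MS", "CA1", "mPFC")


@dataclass
class SynthConfig:
    """Parameters of the synthetic multi-region LFP generator.

    The generator emulates 20-minute, three-region (MS / CA1 / mPFC)
    recordings: 1/f background noise with Hann-enveloped theta bursts, an
    MS->CA1 burst-propagation rule with configurable probability, delay and
    imposed phase lag, and a two-state (rest/move) behavior track.
    """

    duration_s: float = 1200.0
    fs: float = 1017.0
    noise_exponent: float = 1.0
    burst_rate_per_min: float = 6.0
    burst_dur_mean_s: float = 0.35
    burst_dur_sd_s: float = 0.15
    burst_freq_hz: float = 8.0
    snr: float = 3.0
    #: rate of CA1 bursts that arise independently of MS (None -> same as
    #: burst_rate_per_min); coupled CA1 bursts are spawned from MS on top.
    ca1_independent_rate_per_min: float | None = None
    coupling_prob: float = 0.6
    coupling_delay_mean_s: float = 0.25
    coupling_delay_sd_s: float = 0.10
    phase_lag_rad: float = 0.0
    #: duration of the lower-amplitude phase-locked theta tail sustained in
    #: both regions after a coupled CA1 burst (models post-burst coherence).
    lock_tail_s: float = 1.5
    #: tail amplitude as a fraction of the burst peak amplitude.
    lock_tail_gain: float = 0.4
    # behavior-track parameters (20 fps overhead tracking)
    fps: float = 20.0
    rest_dur_mean_s: float = 6.0
    move_dur_mean_s: float = 8.0
    rest_speed_cms: float = 0.15
    move_speed_cms: float = 4.0
    speed_sd_cms: float = 0.6
    #: fraction of movement initiations time-locked after a CA1 burst
    lock_fraction: float = 0.0
    lock_delay_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 200.0:
            raise ValueError("fs must exceed twice the highest band edge (100 Hz)")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError("coupling_prob must be in [0, 1]")
        if self.burst_dur_mean_s <= 0:
            raise ValueError("burst_dur_mean_s must be positive")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """Every tunable constant of the end-to-end pipeline in one place.

    Stage code never hard-codes these; the config is serialized (with a
    stable hash) into every output so a run is fully reconstructible.
    """

    # burst detection
    high_k: float = 2.0
    low_k: float = 1.0
    baseline_stat: str = "median"
    min_cycles: float = 1.5
    ref_freq_hz: float = 7.5  # reproduces the printed 200 ms theta minimum
    # coupling windows (seconds); each analysis names its own window
    pair_max_delay_s: float = 1.0
    phase_precede_s: float = 0.2
    coupled_window_s: float = 0.4
    # PLV windows
    plv_win_s: float = 8.0
    peri_pre_s: float = 2.0
    peri_post_s: float = 2.0
    offset_window_s: float = 1.25
    # lag analysis
    lag_win_s: float = 10.0
    lag_step_s: float = 5.0
    max_lag_s: float = 0.25
    # behavior thresholds
    v_rest_cms: float = 0.5
    v_move_cms: float = 1.5
    rest_min_s: float = 2.0
    sustain_s: float = 0.5
    # spectral estimation
    welch_win_s: float = 6.0
    nfft: int = 8096
    # statistics
    alpha: float = 0.05
    n_perm: int = 5000
    fdr_method: str = "bh"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
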