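"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from thetaburst import SynthConfig
from thetaburst.preprocessing import analytic_signal, bandpass_fir
from thetaburst.synthetic import generate_lfp_session

FS = 1017.0


@pytest.fixture(scope="session")
def short_session():
    """300-s three-region session at defaults (seed 9, no lock tails)."""
    cfg = SynthConfig(duration_s=300.0, seed=9, lock_tail_gain=0.0)
    session, gt = generate_lfp_session(cfg)
    return cfg, session, gt


@pytest.fixture(scope="session")
def coupled_session():
    """1200-s session with guaranteed MS->CA1 coupling and a pi/4 phase lag."""
    cfg = SynthConfig(
        duration_s=1200.0,
        seed=5,
        coupling_prob=1.0,
        burst_rate_per_min=12.0,
        ca1_independent_rate_per_min=0.0,
        phase_lag_rad=np.pi / 4,
    )
    session, gt = generate_lfp_session(cfg)
    return cfg, session, gt


@pytest.fixture(scope="session")
def coupled_theta_phases(coupled_session):
    """Theta instantaneous phases of MS and CA1 for the coupled session."""
    _, session, _ = coupled_session
    _, p_ms = analytic_signal(bandpass_fir(session.signals["MS"], session.fs, "theta"))
    _, p_ca1 = analytic_signal(bandpass_fir(session.signals["CA1"], session.fs, "theta"))
    return p_ms, p_ca1


def sine(freq_hz: float, dur_s: float = 10.0, fs: float = FS, amp: float = 1.0):
    t = np.arange(0.0, dur_s, 1.0 / fs)
    return t, amp * np.cos(2 * np.pi * freq_hz * t)
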