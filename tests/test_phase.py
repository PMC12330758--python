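"""PLV identities, peri-burst epochs, and phase-offset recovery."""

import numpy as np
import pytest

from thetaburst import SynthConfig
from thetaburst.burst_detection import BurstEvent
from thetaburst.circstats import circ_mean
from thetaburst.coupling import BurstPair
from thetaburst.phase import (
    classify_coupling,
    peri_burst_plv,
    plv,
    post_burst_phase_offsets,
    windowed_plv,
)
from thetaburst.preprocessing import analytic_signal, bandpass_fir
from thetaburst.synthetic import generate_lfp_session, pairs_from_ground_truth

FS = 1017.0


def burst(onset, offset, region="MS"):
    return BurstEvent(region, "theta", onset, offset, 1.0, 1.0)


class TestPlvIdentities:
    def test_identical_phases(self):
        phases = np.linspace(-np.pi, np.pi, 1000)
        assert plv(phases, phases) == pytest.approx(1.0)

    def test_constant_offset_preserves_locking(self):
        phases = np.linspace(-np.pi, np.pi, 1000)
        assert plv(phases + np.pi / 4, phases) == pytest.approx(1.0)

    def test_balanced_differences_cancel(self):
        diffs = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert plv(diffs, np.zeros(4)) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert plv(a, b) == pytest.approx(plv(a + 1.1, b + 1.1))
        assert plv(a, b) == pytest.approx(plv(a + 2.0, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            plv(np.array([]), np.array([]))


class TestWindowedPlv:
    def test_coupled_sinusoids_lock_every_window(self):
        t = np.arange(0.0, 64.0, 1.0 / FS)
        pa = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        pb = np.angle(np.exp(1j * (2 * np.pi * 8 * t - 0.7)))
        series = windowed_plv(pa, pb, FS)
        assert len(series.plv) == 8
        assert np.all(series.plv > 0.999)

    def test_independent_phases_match_rayleigh_expectation(self):
        """IID uniform phase differences: window PLV should average to the
        Rayleigh resultant expectation sqrt(pi)/2/sqrt(N) within 3 SE."""
        rng = np.random.default_rng(1)
        n_win, n = 75, int(8 * FS)
        pa = rng.uniform(-np.pi, np.pi, n_win * n)
        series = windowed_plv(pa, np.zeros(n_win * n), FS)
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        se = np.sqrt((4 - np.pi) / (4 * n * n_win))
        assert abs(series.session_mean - expected) <= 3 * se

    def test_partial_locking_ordered_in_time_bins(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 1200.0, 1.0 / FS)
        pa = 2 * np.pi * 8 * t
        pb = pa.copy()
        half = len(t) // 2
        pb[half:] = rng.uniform(-np.pi, np.pi, len(t) - half)  # unlock minutes 10-20
        series = windowed_plv(np.angle(np.exp(1j * pa)), np.angle(np.exp(1j * pb)), FS)
        starts, binned = series.binned(300.0)
        assert len(binned) == 4
        assert min(binned[:2]) > max(binned[2:])


class TestClassifyCoupling:
    def test_within_window_is_coupled(self):
        flags = classify_coupling([burst(10.0, 10.4, "CA1")], [burst(9.2, 9.7)], 0.4)
        assert flags.tolist() == [True]

    def test_beyond_window_is_uncoupled(self):
        flags = classify_coupling([burst(10.0, 10.4, "CA1")], [burst(9.0, 9.5)], 0.4)
        assert flags.tolist() == [False]

    def test_onset_mode_measures_from_ms_onset(self):
        ca1 = [burst(10.0, 10.4, "CA1")]
        ms = [burst(9.7, 10.5)]
        assert classify_coupling(ca1, ms, 0.4, mode="onset").tolist() == [True]
        assert classify_coupling(ca1, ms, 0.4, mode="offset").tolist() == [False]

    def test_coupled_fraction_recovers_generator_probability(self):
        cfg = SynthConfig(
            duration_s=1200.0, seed=19, coupling_prob=0.5,
            burst_rate_per_min=12.0, ca1_independent_rate_per_min=0.0,
            coupling_delay_mean_s=0.2, coupling_delay_sd_s=0.05,
            lock_tail_gain=0.0,
        )
        _, gt = generate_lfp_session(cfg)
        ms = [burst(a, b) for a, b, _ in gt.bursts_in("MS")]
        ca1 = [burst(a, b, "CA1") for a, b, _ in gt.bursts_in("CA1")]
        # CA1 bursts exist only through coupling here, so classify the MS
        # bursts' successors: fraction of MS bursts followed by a CA1 burst
        flags = classify_coupling(ca1, ms, window_s=1.0)
        assert len(ca1) / len(ms) == pytest.approx(0.5, abs=0.05)
        assert np.all(flags)  # every coupled CA1 burst is close to its parent


class TestPeriBurstPlv:
    def test_constant_lag_gives_unit_ratio(self):
        t = np.arange(0.0, 20.0, 1.0 / FS)
        pa = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        pb = np.angle(np.exp(1j * (2 * np.pi * 8 * t - 0.5)))
        pair = BurstPair(burst(8.0, 8.5), burst(8.7, 9.2, "CA1"), 0.2)
        res = peri_burst_plv(pair, pa, pb, FS)
        assert res.pre_plv == pytest.approx(1.0)
        assert res.post_plv == pytest.approx(1.0)
        assert res.ratio == pytest.approx(1.0)

    def test_edge_event_skipped(self):
        t = np.arange(0.0, 5.0, 1.0 / FS)
        phases = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        pair = BurstPair(burst(0.5, 1.0), burst(1.2, 1.7, "CA1"), 0.2)
        assert peri_burst_plv(pair, phases, phases, FS) is None

    def test_during_exceeds_post_exceeds_pre_on_coupled_bursts(
        self, coupled_session, coupled_theta_phases
    ):
        """Locking imposed only during/after coupled bursts reproduces the
        during > post > pre epoch ordering."""
        _, session, gt = coupled_session
        p_ms, p_ca1 = coupled_theta_phases
        pairs = pairs_from_ground_truth(gt)
        peri = [
            r for p in pairs
            if (r := peri_burst_plv(p, p_ms, p_ca1, session.fs)) is not None
        ]
        assert len(peri) > 100
        pre = np.mean([r.pre_plv for r in peri])
        during = np.mean([r.during_plv for r in peri])
        post = np.mean([r.post_plv for r in peri])
        assert during > post > pre

    def test_post_locking_raises_ratio_for_most_events(self):
        """A strong post-burst locked tail spanning the post window:
        post/pre ratio > 1 for >= 90% of events.  The event rate keeps
        events far enough apart that pre windows stay clean of the previous
        event's tail."""
        cfg = SynthConfig(
            duration_s=1200.0, seed=23, coupling_prob=1.0,
            burst_rate_per_min=6.0, ca1_independent_rate_per_min=0.0,
            lock_tail_gain=1.0, lock_tail_s=2.5,
        )
        session, gt = generate_lfp_session(cfg)
        _, p_ms = analytic_signal(bandpass_fir(session.signals["MS"], FS, "theta"))
        _, p_ca1 = analytic_signal(bandpass_fir(session.signals["CA1"], FS, "theta"))
        peri = [
            r for p in pairs_from_ground_truth(gt)
            if (r := peri_burst_plv(p, p_ms, p_ca1, FS)) is not None
        ]
        assert np.mean([r.ratio > 1 for r in peri]) >= 0.9

    def test_uncoupled_bursts_have_unit_mean_ratio(self):
        """No imposed locking: post/pre PLV ratio centers on 1."""
        cfg = SynthConfig(
            duration_s=1200.0, seed=29, coupling_prob=1.0,
            burst_rate_per_min=12.0, ca1_independent_rate_per_min=0.0,
            lock_tail_gain=0.0,
        )
        session, gt = generate_lfp_session(cfg)
        _, p_ms = analytic_signal(bandpass_fir(session.signals["MS"], FS, "theta"))
        _, p_ca1 = analytic_signal(bandpass_fir(session.signals["CA1"], FS, "theta"))
        ratios = [
            np.log(r.ratio) for p in pairs_from_ground_truth(gt)
            if (r := peri_burst_plv(p, p_ms, p_ca1, FS)) is not None
        ]
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios)) <= 3 * se + 0.05


class TestPostBurstPhaseOffsets:
    def test_identical_signals_give_zero_offsets(self):
        t = np.arange(0.0, 20.0, 1.0 / FS)
        phases = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        pairs = [BurstPair(burst(5.0, 5.4), burst(5.5, 6.0, "CA1"), 0.1)]
        offsets = post_burst_phase_offsets(pairs, phases, phases, FS)
        assert np.allclose(offsets, 0.0)

    def test_constant_shift_appears_as_constant_offset(self):
        t = np.arange(0.0, 20.0, 1.0 / FS)
        base = 2 * np.pi * 8 * t
        pa = np.angle(np.exp(1j * (base + 0.9)))
        pb = np.angle(np.exp(1j * base))
        pairs = [BurstPair(burst(5.0, 5.4), burst(5.5, 6.0, "CA1"), 0.1)]
        offsets = post_burst_phase_offsets(pairs, pa, pb, FS)
        assert offsets[0] == pytest.approx(0.9, abs=1e-6)

    def test_pairs_beyond_precede_window_excluded(self):
        t = np.arange(0.0, 20.0, 1.0 / FS)
        phases = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        pairs = [BurstPair(burst(5.0, 5.4), burst(5.8, 6.3, "CA1"), 0.4)]
        assert len(post_burst_phase_offsets(pairs, phases, phases, FS)) == 0

    @pytest.mark.parametrize("lag", [0.0, np.pi / 4, np.pi / 2])
    def test_imposed_phase_lag_recovered(self, lag):
        """Generator phase lags {0, pi/4, pi/2} recovered by the circular
        mean of post-burst offsets within +/- 0.05 rad."""
        cfg = SynthConfig(
            duration_s=1200.0, seed=5, coupling_prob=1.0,
            burst_rate_per_min=12.0, ca1_independent_rate_per_min=0.0,
            phase_lag_rad=lag,
        )
        session, gt = generate_lfp_session(cfg)
        _, p_ms = analytic_signal(bandpass_fir(session.signals["MS"], FS, "theta"))
        _, p_ca1 = analytic_signal(bandpass_fir(session.signals["CA1"], FS, "theta"))
        offsets = post_burst_phase_offsets(
            pairs_from_ground_truth(gt), p_ms, p_ca1, FS, precede_s=1.0
        )
        assert len(offsets) >= 200
        err = np.angle(np.exp(1j * (circ_mean(offsets) - lag)))
        assert abs(err) <= 0.05
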