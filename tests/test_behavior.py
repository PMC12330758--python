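"""Kinematics, rest/initiation detection, and burst-behavior alignment."""

import numpy as np
import pytest

from thetaburst import SynthConfig
from thetaburst.behavior import (
    bout_burst_precedence,
    burst_triggered_velocity,
    bursts_near_events,
    compute_kinematics,
    detect_movement_bouts,
    detect_movement_initiations,
    detect_rest_periods,
    theta_power_velocity_correlation,
)
from thetaburst.burst_detection import BurstEvent
from thetaburst.session import BehaviorTrack
from thetaburst.synthetic import generate_behavior_track, generate_lfp_session

FPS = 20.0


def burst(onset, dur=0.3):
    return BurstEvent("CA1", "theta", onset, onset + dur, 1.0, 1.0)


def track_from_velocity(v, fps=FPS):
    """Straight-line track realizing a given speed profile."""
    x = np.concatenate([[0.0], np.cumsum(v[:-1] / fps)])
    return compute_kinematics(x, np.zeros_like(x), fps=fps)


class TestKinematics:
    def test_straight_line_at_constant_speed(self):
        t = np.arange(0, 10, 1 / FPS)
        kin = compute_kinematics(2.0 * t, np.zeros_like(t), FPS)
        interior = slice(5, -5)
        assert np.allclose(kin.velocity_cms[interior], 2.0, atol=0.01)
        assert np.allclose(kin.heading_rad[interior], 0.0, atol=0.01)

    def test_stationary_track_flags_heading(self):
        x = np.full(100, 3.0)
        kin = compute_kinematics(x, x, FPS)
        assert np.allclose(kin.velocity_cms, 0.0)
        assert np.all(np.isnan(kin.heading_rad))

    def test_circular_path_speed_and_heading(self):
        """Radius-5 circle traversed in 20 s: speed 2*pi*r/T, heading
        advances 2*pi per lap."""
        r, period = 5.0, 20.0
        t = np.arange(0, 40, 1 / FPS)
        x = r * np.cos(2 * np.pi * t / period)
        y = r * np.sin(2 * np.pi * t / period)
        kin = compute_kinematics(x, y, FPS)
        interior = slice(10, -10)
        assert np.allclose(
            kin.velocity_cms[interior], 2 * np.pi * r / period, rtol=0.02
        )
        unwrapped = np.unwrap(kin.heading_rad)
        laps = (unwrapped[-1] - unwrapped[0]) / (2 * np.pi)
        assert laps == pytest.approx(2.0, abs=0.1)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal(200)) / FPS
        y = np.cumsum(rng.standard_normal(200)) / FPS
        a = compute_kinematics(x, y, FPS)
        b = compute_kinematics(x + 100.0, y - 50.0, FPS)
        assert np.allclose(a.velocity_cms, b.velocity_cms)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(np.zeros(2), np.zeros(2), FPS)


class TestRestDetection:
    def test_single_rest_before_movement(self):
        v = np.concatenate([np.zeros(100), np.full(100, 3.0)])
        rests = detect_rest_periods(track_from_velocity(v))
        assert len(rests) == 1
        assert rests[0].duration_s == pytest.approx(5.0, abs=0.3)

    def test_sub_duration_rest_ignored(self):
        v = np.concatenate([np.full(20, 3.0), np.zeros(38), np.full(60, 3.0)])
        # 1.9 s below threshold: no rest
        rests = detect_rest_periods(track_from_velocity(v))
        assert rests == []

    def test_generator_rest_count_recovered(self):
        cfg = SynthConfig(duration_s=600.0, seed=6)
        _, gt = generate_lfp_session(cfg.replace(burst_rate_per_min=0.0, snr=0.0))
        track = generate_behavior_track(cfg, gt)
        kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
        rests = detect_rest_periods(kin)
        true_rests = [e for e in gt.behavior_events if e[0] == "rest"]
        assert len(rests) >= 0.9 * len(true_rests)
        assert len(rests) <= 1.2 * len(true_rests)


class TestInitiations:
    def test_step_transition_detected_once(self):
        v = np.concatenate([np.zeros(60), np.full(100, 3.0)])
        inits = detect_movement_initiations(track_from_velocity(v))
        assert len(inits) == 1
        assert inits[0].start_s == pytest.approx(3.0, abs=0.3)

    def test_unsustained_spike_ignored(self):
        v = np.zeros(200)
        v[100:102] = 3.0  # 0.1 s blip
        inits = detect_movement_initiations(track_from_velocity(v))
        assert inits == []

    def test_generator_initiation_count_recovered(self):
        cfg = SynthConfig(duration_s=600.0, seed=16)
        track = generate_behavior_track(cfg)
        kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
        inits = detect_movement_initiations(kin)
        gt_moves = [
            e for e in _behavior_events(cfg) if e[0] == "move" and e[1] > 3.0
        ]
        assert abs(len(inits) - len(gt_moves)) <= max(2, 0.2 * len(gt_moves))


def _behavior_events(cfg):
    from thetaburst.session import GroundTruth

    gt = GroundTruth()
    generate_behavior_track(cfg, gt)
    return gt.behavior_events


def test_mean_velocity_recovered_from_track():
    """Kinematics recover the generator's realized mean speed within 5%."""
    cfg = SynthConfig(duration_s=600.0, seed=10)
    from thetaburst.session import GroundTruth

    gt = GroundTruth()
    track = generate_behavior_track(cfg, gt)
    kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
    assert np.mean(kin.velocity_cms) == pytest.approx(
        gt.target_mean_velocity_cms, rel=0.05
    )


class TestBurstEventAlignment:
    def test_burst_at_event_time_counted(self):
        from thetaburst.behavior import MovementEvent

        events = {"m1": [MovementEvent("initiation", 50.0, 50.0)]}
        bursts = {"m1": [burst(50.0)]}
        out = bursts_near_events(bursts, events)
        assert out["fraction_events_with_burst"] == 1.0
        peak_bin = out["bin_centers_s"][np.argmax(out["mean_density"])]
        assert abs(peak_bin) <= 0.25

    def test_burst_outside_window_not_counted(self):
        from thetaburst.behavior import MovementEvent

        events = {"m1": [MovementEvent("initiation", 50.0, 50.0)]}
        out = bursts_near_events({"m1": [burst(52.5)]}, events)
        assert out["fraction_events_with_burst"] == 0.0

    def test_locked_bursts_peak_before_movement_onset(self):
        """Generator locks movement 0.5 s after CA1 bursts: the aligned
        histogram peaks in [-1, 0] s, within one bin of -0.5 s."""
        cfg = SynthConfig(
            duration_s=1200.0, seed=26, lock_fraction=1.0, lock_delay_s=0.5
        )
        _, gt = generate_lfp_session(cfg)
        track = generate_behavior_track(cfg, gt)
        kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
        inits = detect_movement_initiations(kin)
        assert len(inits) >= 5
        ca1 = [burst(a, b - a) for a, b, _ in gt.bursts_in("CA1")]
        out = bursts_near_events({"m": ca1}, {"m": inits})
        peak = out["bin_centers_s"][np.argmax(out["mean_density"])]
        assert -1.0 <= peak <= 0.0
        assert abs(peak - (-0.5)) <= 0.25 + 1e-9


class TestBoutPrecedence:
    def test_burst_within_lookback_labels_bout(self):
        from thetaburst.behavior import MovementEvent

        bouts = [MovementEvent("bout", 10.0, 12.0, 3.0)]
        df = bout_burst_precedence(bouts, [burst(8.7)])  # ends 1 s before
        assert df["preceded_by_burst"].tolist() == [True]

    def test_burst_too_early_does_not_label(self):
        from thetaburst.behavior import MovementEvent

        bouts = [MovementEvent("bout", 10.0, 12.0, 3.0)]
        df = bout_burst_precedence(bouts, [burst(7.0)])
        assert df["preceded_by_burst"].tolist() == [False]

    def test_faster_post_burst_bouts_detected(self):
        """Bouts after bursts get +1 cm/s: group difference significant."""
        from scipy import stats as spstats

        from thetaburst.behavior import MovementEvent

        rng = np.random.default_rng(1)
        bouts, bursts = [], []
        t = 10.0
        for i in range(100):
            preceded = i % 2 == 0
            v = 3.0 + rng.normal(0, 0.3) + (1.0 if preceded else 0.0)
            if preceded:
                bursts.append(burst(t - 1.0))
            bouts.append(MovementEvent("bout", t, t + 2.0, v))
            t += 10.0
        df = bout_burst_precedence(bouts, bursts)
        a = df[df.preceded_by_burst]["mean_velocity_cms"]
        b = df[~df.preceded_by_burst]["mean_velocity_cms"]
        assert spstats.ttest_ind(a, b).pvalue < 0.01
        assert a.mean() > b.mean()


class TestBurstTriggeredVelocity:
    def make_subjects(self, effect, n_subj=6, seed=0):
        rng = np.random.default_rng(seed)
        bursts_by, tracks_by = {}, {}
        for s in range(n_subj):
            v = 2.0 + 0.4 * rng.standard_normal(int(300 * FPS))
            onsets = np.arange(20.0, 280.0, 15.0)
            for on in onsets:
                i = int(on * FPS)
                v[i : i + int(1.5 * FPS)] += effect
            x = np.concatenate([[0.0], np.cumsum(v[:-1] / FPS)])
            tracks_by[f"s{s}"] = compute_kinematics(x, np.zeros_like(x), FPS)
            bursts_by[f"s{s}"] = [burst(on) for on in onsets]
        return bursts_by, tracks_by

    def test_flat_velocity_has_no_significant_bins(self):
        bursts_by, tracks_by = self.make_subjects(effect=0.0)
        out = burst_triggered_velocity(bursts_by, tracks_by)
        assert len(out["significant_bins"]) == 0

    def test_post_burst_step_localized_in_time(self):
        """+2 cm/s for 1.5 s after each burst: significant bins cover
        ~0-1.5 s and little beyond."""
        bursts_by, tracks_by = self.make_subjects(effect=2.0)
        out = burst_triggered_velocity(bursts_by, tracks_by)
        sig = out["significant_bins"]
        assert len(sig) > 0
        assert sig.min() >= 0.0
        assert np.sum((sig >= 0) & (sig <= 1.5)) >= 0.8 * len(sig)

    def test_trace_length_matches_window(self):
        bursts_by, tracks_by = self.make_subjects(effect=0.0, n_subj=2)
        out = burst_triggered_velocity(bursts_by, tracks_by)
        assert len(out["mean_trace"]) == int(6 * FPS) + 1


class TestThetaVelocityCorrelation:
    def test_perfectly_coupled_series(self):
        rng = np.random.default_rng(2)
        env = rng.uniform(1, 2, 2000)
        out = theta_power_velocity_correlation(
            {"a": env}, {"a": 3.0 * env}, {"a": "saline"}
        )
        assert out["per_condition_r"]["saline"] == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(3)
        out = theta_power_velocity_correlation(
            {"a": rng.standard_normal(10000)},
            {"a": rng.standard_normal(10000)},
            {"a": "saline"},
        )
        assert abs(out["per_condition_r"]["saline"]) < 0.03

    def test_condition_specific_slopes_yield_interaction(self):
        """Coupling slope 0.1 vs 0.4 across conditions: interaction term
        significant."""
        rng = np.random.default_rng(4)
        env_a = rng.standard_normal(5000)
        env_b = rng.standard_normal(5000)
        out = theta_power_velocity_correlation(
            {"a": env_a, "b": env_b},
            {
                "a": 0.1 * env_a + rng.standard_normal(5000),
                "b": 0.4 * env_b + rng.standard_normal(5000),
            },
            {"a": "saline", "b": "etoh"},
        )
        assert out["interaction_p"] < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            theta_power_velocity_correlation(
                {"a": np.ones(10)}, {"a": np.ones(11)}, {"a": "saline"}
            )


def test_rest_and_bout_intervals_do_not_overlap():
    cfg = SynthConfig(duration_s=300.0, seed=20)
    track = generate_behavior_track(cfg)
    kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
    rests = detect_rest_periods(kin)
    bouts = detect_movement_bouts(kin)
    intervals = sorted(
        [(e.start_s, e.end_s) for e in rests] + [(e.start_s, e.end_s) for e in bouts]
    )
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        assert a1 <= b0 + 1e-9
    total = sum(b - a for a, b in intervals)
    assert total <= cfg.duration_s + 1e-6
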