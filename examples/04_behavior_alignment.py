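"""Align CA1 theta bursts to movement initiations on a synthetic track.

The generator time-locks movement onsets 0.5 s after CA1 burst onsets; the
analysis recovers that latency as the peak of the burst-aligned histogram.
"""

import numpy as np

from thetaburst import SynthConfig
from thetaburst.behavior import (
    bursts_near_events,
    compute_kinematics,
    detect_movement_initiations,
    detect_rest_periods,
)
from thetaburst.burst_detection import BurstEvent
from thetaburst.synthetic import generate_behavior_track, generate_lfp_session

cfg = SynthConfig(duration_s=600.0, seed=26, lock_fraction=1.0, lock_delay_s=0.5)
_, truth = generate_lfp_session(cfg)
track = generate_behavior_track(cfg, truth)

kin = compute_kinematics(track.x_cm, track.y_cm, cfg.fps)
rests = detect_rest_periods(kin)
inits = detect_movement_initiations(kin)
print(f"mean velocity      : {np.mean(kin.velocity_cms):.2f} cm/s "
      f"(generator target {truth.target_mean_velocity_cms:.2f})")
print(f"rest periods       : {len(rests)}")
print(f"movement onsets    : {len(inits)}")

ca1 = [BurstEvent("CA1", "theta", a, b, 1.0, 1.0) for a, b, _ in truth.bursts_in("CA1")]
aligned = bursts_near_events({"m0": ca1}, {"m0": inits})
peak = aligned["bin_centers_s"][np.argmax(aligned["mean_density"])]
print(f"burst fraction near onsets : {aligned['fraction_events_with_burst']:.2f}")
print(f"aligned histogram peak     : {peak:+.2f} s relative to movement onset")
# The peak near -0.5 s recovers the generator's imposed burst->movement
# latency: bursts precede locomotion.
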