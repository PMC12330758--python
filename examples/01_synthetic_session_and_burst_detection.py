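"""Generate a synthetic three-region LFP session and detect theta bursts.

Builds a 5-minute session (MS, CA1, mPFC; 1/f background with Hann-enveloped
8 Hz bursts at ~6/min), runs the dual-threshold detector on the CA1 theta
envelope, and scores the detections against the generator's ground truth.
"""

import numpy as np

from thetaburst import SynthConfig
from thetaburst.burst_detection import detect_theta_bursts, summarize_bursts
from thetaburst.synthetic import burst_match_score, generate_lfp_session

cfg = SynthConfig(duration_s=300.0, seed=42, snr=3.0, lock_tail_gain=0.0)
session, truth = generate_lfp_session(cfg)

bursts = detect_theta_bursts(
    session.signals["CA1"], cfg.fs, region="CA1", high_k=3.5, low_k=1.75
)
summary = summarize_bursts(bursts, session.duration_s)
score = burst_match_score(bursts, truth.bursts_in("CA1"), tol_s=0.1)

print(f"injected CA1 theta bursts : {len(truth.bursts_in('CA1'))}")
print(f"detected CA1 theta bursts : {summary.total_count}")
print(f"mean detected duration    : {summary.mean_duration_s:.3f} s")
print(f"onset-matched F1          : {score['f1']:.3f}")
print(f"median onset error        : {np.median(np.abs(score['onset_errors_s']))*1000:.1f} ms")
# F1 near 1 means the detector recovers the injected events; the onset error
# (tens of ms) reflects the time resolution of a 5-12 Hz envelope.
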