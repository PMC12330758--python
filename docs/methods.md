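# Methods

This note documents the models, estimators and numerical choices behind
`thetaburst`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Signal model and the synthetic generator

A session is modeled as three simultaneously recorded LFP channels (MS, CA1,
mPFC) sampled at 1017 Hz for 20 minutes.  The generator builds each channel
as

- **1/f background**: Gaussian noise spectrally shaped to
  PSD ∝ 1/f^α (default α = 1), produced by scaling the rFFT of white noise
  with an f^(−α/2) amplitude profile and normalizing to unit RMS.  This
  reproduces the aperiodic broadband context that burst detection must work
  against; it contains no line noise, movement artifacts, or non-stationary
  aperiodic slope changes, all of which real recordings have.
- **Theta bursts**: Hann-enveloped cosines at a fixed carrier (default 8 Hz)
  with peak amplitude `snr` × background RMS (default 3).  Counts are
  Poisson (default 6/min per region), onsets uniform, durations log-normal
  with arithmetic mean 0.35 s and SD 0.15 s.  The Hann envelope avoids the
  spectral splatter a rectangular gate would add.  The rate and duration
  parameters are free choices — no per-region burst-rate estimates exist to
  copy — set once to values that give realistic burst densities (bursts
  occupy a few percent of session time) and a duration spread consistent
  with the wide duration distributions real theta bursts show
  (coefficient of variation ≈ 0.43).
- **MS→CA1 propagation**: each MS burst spawns, with probability
  `coupling_prob` (default 0.6), a CA1 burst whose onset follows the MS
  burst's completion by a truncated-normal (≥ 0) delay (default
  0.25 ± 0.10 s).  The coupled burst copies the MS carrier frequency and is
  rendered against the same phase reference with a fixed lag, so the
  instantaneous phase difference φ_MS − φ_CA1 during co-activity equals
  `phase_lag_rad` exactly — making imposed phase offsets analytically known.
- **Post-burst locked tail**: during a coupled event both regions carry a
  lower-amplitude (default 0.4 × burst peak) phase-locked theta component
  spanning MS onset → CA1 offset and decaying linearly over `lock_tail_s`
  (default 1.5 s) afterwards.  This is the generator's explicit model of
  post-burst coherence elevation: it is what makes post-burst phase offsets
  and the peri-burst PLV epoch ordering (during > post > pre) recoverable
  quantities rather than noise.  Detector-recovery experiments disable it
  (`lock_tail_gain = 0`) because the tail deliberately blurs burst
  boundaries.
- **Behavior**: a two-state (rest/move) semi-Markov process at 20 fps with
  state-dependent Gaussian speed noise (rest ≈ 0.15 cm/s, move ≈ 4 cm/s), a
  slowly drifting heading, and reflection at the walls of a 20 × 33 cm
  arena.  Movement onsets can be time-locked a fixed delay after a chosen
  fraction of CA1 bursts so burst-triggered analyses have a recoverable
  effect.  The generator logs every epoch and the realized mean speed.

Identical configuration and seed give bit-identical signals and ground
truth.  Overlapping burst placements are re-drawn (up to a bounded number of
attempts) and the re-draws counted in the ground-truth log.

What passing tests on this generator show: the estimators recover known
rates, delays, lags and phase offsets from signals with realistic spectral
shape and event statistics.  What they do not show: robustness to artifacts,
electrode drift, cross-frequency structure, non-sinusoidal theta waveforms,
or behavioral confounds present in real data.

## Filtering and spectra

Band filters are Hamming windowed-sinc FIRs (transition width 20 % of the
lower band edge, ≥ 50 dB stopband) applied forward-backward (`filtfilt`)
with reflect padding of three kernel lengths, so all band-limited signals
are zero-phase.  The first/last second of envelope and phase should be
treated as unreliable.  PSDs use Welch's method with 6-second non-overlapping
Hann windows and `nfft = 8096` — the value is kept as printed even though it
is presumably a typo for 8192; a power-of-two grid is one argument away.
Relative band power divides the trapezoidal band integral by the 0–55 Hz
total, so the high-gamma band is excluded from this normalization by
construction.  A separate low/high-theta table (4–8 / 8–12 Hz) serves the
relative-power contrast, distinct from the 5–12 Hz burst-detection band.

## Burst detection

Detection runs on the Hilbert envelope of the band-filtered signal.  An
event is a maximal interval with envelope > low_k·baseline containing at
least one sample > high_k·baseline; baseline is a robust session statistic
(median by default; mean and MAD available).  Thresholds are ratios, so
detection is invariant to global gain.  Events must last
≥ n_cycles / ref_freq_hz; the default reference 7.5 Hz makes 1.5 cycles
equal the stated 200 ms theta minimum, while the literal band low-cutoff
reading (5 Hz → 300 ms) is available via `ref_freq_hz=5`.  The choice is an
explicit argument rather than a silent resolution because the two published
statements conflict.  Detection runs on the continuous envelope; the 5-s
segmentation exists for per-window baselining but is not used to cut events,
which would split bursts at window edges.

Defaults are 2.0/1.0 × median (the common dual-threshold convention).  For
recovery experiments against the generator, where the injected burst peak is
known (≈ 7 × the median theta envelope at snr = 3), the operating point
3.5/1.75 × median anchors event validity at half the known peak; with the
conventional 2.0/1.0 thresholds, sustained suprathreshold excursions of the
1/f background are also detected as events — they are genuine theta-envelope
elevations, indistinguishable in principle from injected bursts at that
threshold.  Onset accuracy is limited by the ~1/bandwidth (≈ 140 ms) time
resolution of a 5–12 Hz envelope; the median onset error on synthetic
sessions is ≈ 25 ms.

## Lagged coherence and envelope lags

Lagged coherence tiles the signal into consecutive epochs of `n_cycles`
(default 3) at each probe frequency, takes the Hann-tapered Fourier
coefficient at that frequency per epoch, and computes
|Σ F_t F*_{t+1}| / sqrt(Σ|F_t|² Σ|F_{t+1}|²), averaged over 5–12 Hz in 1-Hz
steps.  A stationary sinusoid scores ≈ 1; epoch-wise phase scrambling drops
the value to the random-phasor floor (≈ 1/√n_epochs).  The time course uses
2.5-minute bins.

Envelope lags are estimated per overlapping window (default 10 s, 50 %
overlap) as the argmax of the normalized cross-correlation of mean-subtracted
theta envelopes within ± 250 ms, refined by parabolic interpolation around
the integer-lag peak (sub-sample precision; imposed 20–100 ms delays are
recovered with median error ≈ 0.2 samples).  Positive lag means MS leads
CA1.  Window length, overlap and lag bound are package decisions — no
published values exist.  Lag dispersion is the SD over window lags;
per-subject centering subtracts the session median.

## Coupling, phase and circular statistics

Pairing is greedy first-match: each MS burst takes the first CA1 burst whose
onset falls within (MS offset, MS offset + 1 s], each CA1 burst used at most
once.  The latency split uses pooled 25th/75th percentiles; the degenerate
all-equal case is assigned to the mid group.  Delay KDEs use Gaussian
kernels with Silverman bandwidth.  Fisher's r-to-z compares duration
correlations; with the printed inputs it reproduces z = −4.01 (short-latency)
and z = 0.62 (long-latency).

Three distinct coupling windows appear in different analyses (200 ms for
post-burst phase offsets, 400 ms for coupled/uncoupled classification, 1 s
for pairing); each is its own configuration key.  Whether "preceded by an MS
burst within X ms" measures from MS onset or offset is ambiguous in the
source; both modes exist, offset being the default for consistency with the
1-s pairing rule.  PLV is computed between any named region pair with
MS–CA1 the pipeline default (the single sentence naming CA1–mPFC in the
source's PLV definition is treated as a typo, since every surrounding
analysis is MS–CA1).

Circular tests are implemented in-package: Rayleigh (Z = nR², p via the
standard small-sample-corrected exponential approximation), Watson–Williams
(F with the (1 + 3/8κ) concentration correction, κ estimated from the
within-group resultant; a warning fires below R̄ = 0.45 where the F
approximation degrades), Mardia–Watson–Wheeler (uniform scores, χ² with
2(k−1) df, sub-nanoradian tie jitter), and seeded label-shuffling
permutation tests with add-one smoothing.  All three parametric tests are
calibration-checked: at 2000 replicates under their nulls the empirical
type-I error lies within the binomial 95 % interval of α = 0.05 (group
size 50, where the Watson–Williams F approximation is in its valid regime).

## Behavior

Velocity comes from central differences of the 20 fps track with a 5-frame
moving average before thresholding (raw tracking noise would otherwise
trigger spurious crossings).  Rest is velocity < 0.5 cm/s for ≥ 2 s.  A
movement initiation is the first sample above 1.5 cm/s following ≥ 2 s of
rest, with up to 0.5 s of transition allowed between leaving the rest band
and crossing the movement threshold (the acceleration ramp), and velocity
required to stay above threshold for 0.5 s.  Bouts end after 0.5 s below the
rest threshold; both the sustain and bout-end durations are package choices.
Burst-aligned histograms use 0.25-s bins over ± 2 s, Gaussian-smoothed with
σ = 1 bin, unit-area normalized per subject, then averaged — the bin width
is chosen so σ = 1 bin is meaningful.  Burst-triggered velocity traces span
−3…+3 s at 20 fps (121 samples); each post-onset bin is tested across
subjects against the subject's pre-onset baseline mean with paired t-tests
under Benjamini–Hochberg FDR at 0.05.  The mixed-model comparison of aligned
traces is delegated to a standard mixed-effects routine; the module builds
the long-format design table (subject, condition, time, velocity).

## Classification

Each detected burst yields ten features: duration, peak/mean envelope,
envelope skewness (standardized third moment), rise/decay asymmetry
(argmax position / length), normalized Shannon spectral entropy over
4–20 Hz periodogram bins, peak frequency, cycle count, inter-burst interval,
and session time.  The classifier is a gradient-boosted tree ensemble
(depth 3, 200 rounds, learning rate 0.1; engine delegated to xgboost);
features are z-scored on the training fold only.  Evaluation uses
stratified session-grouped cross-validation — whole sessions are held out
and every fold keeps both classes, so no session contributes to training
and testing and pooled out-of-fold probabilities remain comparable.  A
deliberate leakage mode (pooled stratified splits) exists only to
demonstrate the inflation grouped splitting prevents.  ROC/PR/confusion
metrics are computed in-package; the trapezoidal AUROC equals the pairwise
ranking estimator (ties half-credit) to numerical precision.

Under the shifted-generator experiment (−40 % burst duration, doubled rate
in one condition), burst-level separability is intrinsically bounded: with
the generator's realistic duration spread, the Bayes-optimal AUROC from
duration and inter-burst interval is ≈ 0.80 (measured directly on
ground-truth features), and detected-feature AUROC is ≈ 0.65–0.70 because
threshold-crossing widths dilute the duration contrast.  This ceiling is a
property of the chosen study conditions, not of the classifier; tightening
the duration distribution until the shift became trivially separable would
make the generator unrealistic.  Null checks (label-shuffled bursts) score
at chance.

## Problem sizes

Synthetic experiments use 20-minute sessions at 1017 Hz for recovery
analyses (detection F1, phase-lag and envelope-lag recovery, peri-burst
ordering), 10-minute sessions for the multi-session classification
experiments (4 sessions per condition), and 2000 replicates for test
calibration — sizes at which every reported quantity's sampling error is
small relative to its acceptance margin while a full run of the test suite
and acceptance script completes in minutes on one CPU.

## Known limitations

- The generator's bursts share one carrier frequency per session; real theta
  bursts drift in frequency and waveform asymmetry.
- Background noise is stationary Gaussian 1/f; no artifacts, line noise
  (beyond what the notch would remove), or state-dependent spectral changes.
- The post-burst locked tail is a phenomenological device for making
  post-burst synchrony measurable, not a circuit model.
- Burst onset/offset estimates inherit the ~140 ms time resolution of the
  theta envelope; duration-based contrasts are correspondingly diluted.
- The Watson–Williams test assumes adequate concentration; it warns rather
  than refuses below R̄ = 0.45.
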