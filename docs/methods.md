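# Methods

`thetastim` tests whether the amplitude of a stimulation-evoked potential
(EP) recorded in a target structure depends on the phase of the local theta
(3–8 Hz) oscillation at the moment the stimulation pulse is delivered.  The
package implements the full chain from continuous multichannel LFP to
group-level inference, plus a synthetic-session generator with exact ground
truth.  This note documents the model, the estimators, the numerical
choices, and what the synthetic validation does and does not show.

## Phase convention

All angles are cosine-referenced analytic phase on [−180°, 180°):
0° = oscillation peak, ±180° = trough, +90° = falling flank, −90° = rising
flank.  The quarter-circle bins *peak/falling/trough/rising* are the
half-open arcs [center − 45°, center + 45°), which partition the circle.

## Preprocessing

Continuous recordings are re-referenced to the common average of the
ipsilateral depth-electrode group, low-passed (zero-phase FIR, 400 Hz
cutoff, ~80 Hz transition band) and decimated to 1 kHz, then epoched to the
half-open window [−750, 500) ms around each pulse (1250 samples; sample 750
is latency 0 ms) and baseline-corrected to the mean of [−750, −2] ms.
Trials are pruned by peak-to-peak range (> 800 μV) and then by Pearson
sample kurtosis exceeding the channel mean by more than 2 SD, where the
kurtosis statistics are computed within trial class (stimulation-free
trials are referenced only to stimulation-free trials of the same channel).
The comparison is strict, so a zero-SD reference prunes nothing.  Channels
retaining fewer than 200 trials are flagged excluded, never silently
dropped.

## Narrowband oscillation detection

Power is estimated by Welch's method (2 s Hann segments, 50% overlap — the
method is intended for rest segments longer than 90 s) and interpolated
onto 50 log-spaced frequencies from 1 to 50 Hz.  The aperiodic 1/f
background is a robust line on log–log axes (iteratively reweighted least
squares with Tukey bisquare weights, ≤ 50 iterations, tolerance 1e−8; an
exact zero-residual OLS fit is used directly since the robust scale
estimate degenerates there).  The background-corrected spectrum is smoothed
with a 4-point boxcar and oscillations are its positive interior local
maxima.  Two numerical choices matter:

- The even-length boxcar is implemented in its *centered* form (a 2×4
  moving average: five taps with half-weight ends, shrunk and renormalized
  at the edges).  A plain 4-sample window is necessarily off-center and
  turns a symmetric bump into two exactly tied smoothed values, which a
  strict local-maximum rule cannot rank.
- "Positive" means above 1e−8 rather than above 0: a perfectly fitted
  background leaves ±1e−16 rounding noise whose sign is meaningless,
  whereas genuine oscillatory bumps are ~0.1 log₁₀ units or more.

Peak reliability is a group property: a one-sample t-test of per-electrode
corrected power against zero at the peak frequency (with a documented
zero-variance convention: p = 0 if the common value is nonzero, else
t = 0, p = 1).

## Theta phase at stimulation onset

Each trial is truncated at +50 ms *before* filtering, so the evoked
response cannot leak into the estimate; the truncated segment is band-passed
3–8 Hz with a zero-phase (forward–backward) second-order Butterworth filter
and the analytic (Hilbert) phase is read at the 0 ms sample.

Reading the phase only 50 ms from the segment end sits well inside the
narrowband filter's edge transient (the 3–8 Hz band-pass rings for
hundreds of ms).  With scipy's default reflection padding this produces a
frequency-dependent bias of roughly ±25°; we therefore use Gustafsson's
method for the forward–backward initial conditions (`filtfilt(...,
method="gust")`), which approximately halves the bias mid-band (~12° at
5.5 Hz, near 0° at 5 Hz).  The residual error is *quantified rather than
assumed*: pseudotrials (below) put the mean absolute circular error at
about 15° under the default synthetic conditions.  Ground-truth phase for
validation comes from filtering an entire continuous stimulation-free
segment (steady-state, no truncation), with the first and last 5 s flagged
unusable.

Pseudotrial validation: stimulation-free trials are sampled every 100 ms
from a rest segment, a phase-balanced "model EP" (the unweighted mean of
the four 90°-bin mean stimulation trials) is added to each, the estimator
is run on these pseudotrials, and its output is scored against the
ground-truth phase of the untruncated recording at each mock onset.

One consequence worth knowing: because the estimator's error depends
slightly on the local oscillation trajectory, timecourses of the
phase–amplitude correlation computed against *estimated* phase carry a
small theta-periodic ripple that is absent when scored against true phase.

## Evoked components

A phase-balanced EP (mean of the four phase-bin means, so a non-uniform
onset-phase distribution cannot bias the average) is computed per
electrode; component windows are then detected once on the grand average
across electrodes and applied to every trial of every electrode.
Detection: the first two negative local minima in +20 to +500 ms, with
candidates closer than 50 ms merged keeping the deeper one; window edges
are the nearest curvature zero crossings (inflections of the raw trace)
within 150 ms of each peak, clamped to peak ± 150 ms when none exists;
overlapping windows split at the midpoint.  If a trace is so noisy that
more than 10 inflections fall within 150 ms of a peak, a moving average is
escalated (5, 11, 21 ms) until the count is sane — clean grand averages
are processed raw.  Curvature below 1e−9 of the trace maximum is treated
as zero so exactly-straight stretches do not generate rounding-noise
inflections.  Per-trial component amplitude is the *mean* signal over the
window (inclusive), chosen over peak picking for single-trial noise
robustness.

## Circular–linear phase–amplitude statistics

For onset phases φ and amplitudes x,

    r = sqrt((r_xc² + r_xs² − 2 r_xc r_xs r_cs) / (1 − r_cs²)),

with r_xc = corr(x, cos φ), r_xs = corr(x, sin φ), r_cs = corr(cos φ,
sin φ).  Significance is a permutation z-score: the amplitude vector is
shuffled against the fixed phase vector (default n = 500) and
z = (r_obs − mean r_perm)/sd r_perm.  Aggregation across electrodes is on
z, not p.

Calibration caveat: r is non-negative, so its permutation null is
right-skewed (Rayleigh-type, skewness ≈ 0.6).  The z-score is therefore
*not* exactly standard normal: the exact null tail beyond z = 1.645 is
≈ 6.9%, not 5%.  The permutation p-value itself is exactly calibrated by
construction; treat z thresholds as approximate.

The timecourse variant computes r at every epoch sample (undefined
timepoints, e.g. zero amplitude variance, are recorded as NaN) and scans
+20 to +500 ms for the first two local maxima under the same 50 ms
separation rule.  Candidates must have prominence ≥ 1/√n_trials — the null
scale of r — because every finite-trial r(t) carries sample-level wiggles
that a bare strict-local-maximum scan would report as peaks.

## Binned contrasts and sham isolation

Because phase at onset predicts future amplitude by definition, peak- vs
trough-binned EPs differ even without any effect of stimulation.  The
non-evoked component is estimated from stimulation-free trials sampled at
100 ms intervals (preprocessed and phase-estimated identically to
stimulation trials) and resampled with replacement, n matched to the
stimulation-trial count, with weights proportional to (stimulation count /
sham count) on an 18 × 20° phase histogram.  Waveforms are untouched —
matching is pure resampling.  The isolated response is the binned EP minus
the binned matched-sham mean (the identity isolated + sham = EP holds per
timepoint).  Abolishment of pre-stimulus (−100 to 0 ms) peak/trough and
falling/rising differences is reported as a quality metric (paired t
across electrodes), never silently enforced.  On synthetic sessions the
isolation removes a pre-stimulus contrast of t ≈ 11 down to chance level.

## Connectivity

Phase-locking between the stimulation site and target uses the resultant
length of the phase-difference distribution (PLV) and its circular mean
(offset).  Chance level: the continuous phase series are split into 500 ms
epochs, the statistic is the mean per-epoch PLV, and the null re-pairs the
two channels' epochs at random (n = 500), giving a permutation z.  The
Rayleigh test uses z = nR̄² with p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)),
which is well behaved over the whole range (the small-sample series
correction exp(−z)(1 + (2z − z²)/4n) goes negative for large z and is not
used); the approximation tracks a 100 000-draw Monte-Carlo null within
~10% wherever the Monte-Carlo has resolution.

## Group-level inference

Electrode z-scores are averaged within subject (unweighted) and tested
against zero across subjects.  The binned peak/trough contrast is tested
with a linear mixed-effects model, amplitude ~ phase +
(phase | subject/electrode): fixed effect of phase (coded ±0.5) with
random intercepts and slopes for subject and for electrode nested within
subject, fitted by maximum likelihood (REML is invalid for LR comparison
of fixed effects).  The likelihood-ratio statistic compares the full model
against the same random structure without the fixed effect; the one-sided
p is the χ²₁ upper tail by default (a halved-p convention is available via
`one_sided="halved"`).  Two robustness measures: each model is fitted with
both Powell and L-BFGS and the better likelihood kept (single-optimizer
likelihood noise near the variance boundary is large enough to corrupt a
1-df LR statistic), and on failure of the random-slope structure the model
falls back to random intercepts only, reported in the result.  Null
simulations (8 subjects × 3 electrodes) put the type-I rate at ~5–7%.

## Synthetic sessions

`generate_session` builds: 1/f^α Gaussian background noise (spectral
shaping; α = 1.5 by default) plus a theta oscillation, a pulse train
(0.5 Hz fixed or ~1 Hz with interpulse intervals uniform on 1–1.25 s), and
per pulse a brief biphasic artifact (±200 μV, 4 ms) plus two negative
Gaussian EP components (60 ms/σ15/30 μV and 140 ms/σ30/20 μV) whose
amplitudes are multiplied by 1 + m·cos(φ_true − φ*), with φ_true read from
the noiseless theta phase at pulse onset — ground truth is exact.  Rest
segments of ≥ 95 s precede and follow the train.  Optional epileptiform
outliers (brief high-kurtosis transients below the range threshold) support
pruning round-trips.  Generator choices:

- **Low-frequency knee.**  The noise spectrum is flat below 0.5 Hz.
  Without a knee, total 1/f^1.5 power is dominated by arbitrarily slow
  drift and grows with duration, which makes any in-band SNR definition
  depend on session length; real LFP aperiodic spectra flatten at low
  frequency.
- **Theta SNR.**  `theta_snr_db` (default 10 dB) sets the theta amplitude
  as theta power over the expected 3–8 Hz shaped-noise power (≈ 22 μV
  against 15 μV total noise RMS at the defaults).
- **Frequency jitter.**  The instantaneous theta frequency wanders slowly
  (smoothed Gaussian noise, ~0.5 s correlation, clipped to ±0.5 Hz,
  default on).  Real theta decoheres over a few hundred ms; a perfectly
  coherent sinusoid never does, which would make phase trivially
  predictive at all lags.  The integrated phase keeps ground truth exact.
- **Shared oscillation across channels.**  All channels of a session see
  the same theta trajectory at fixed per-channel phase offsets (noise is
  independent per channel), emulating a within-network oscillation; this
  is what makes stimulation-site/target phase-locking analyses meaningful.
- **Multiplicative modulation.**  Modulation acts on component amplitude
  as the minimal model of phase-dependent receptivity to input.

Two lighter generators serve calibration studies where waveforms add
nothing: a statistical-level channel (uniform phases; amplitude =
base·(1 + m cos(φ − φ*)) + Gaussian noise) and a hierarchical
subject/electrode amplitude generator for the mixed-model analyses.

### What the synthetic validation shows — and does not

Passing the synthetic suite shows the estimators recover known structure
under realistic noise, 1/f background, theta non-stationarity, artifact
transients, and estimator edge effects.  It does not emulate: epileptiform
background activity beyond simple transients, volume conduction or
reference-choice effects, laminar phase reversals and traveling-wave phase
gradients, theta power fluctuations correlated with behavior, or
non-sinusoidal theta waveform asymmetry.  Conclusions about clinical
recordings additionally depend on those factors.

A limitation surfaced by the synthetic studies: when the evoked response
is strongly phase-modulated, the estimator's contamination by the EP
becomes phase-dependent, and the sham-matching procedure (whose trials
carry no EP) can leave a μV-scale pre-stimulus residue.  At the default
conditions this residue is below the electrode-level noise, but it is the
reason the pre-stimulus abolishment check is reported rather than assumed.

## Problem sizes

Default validation sizes were chosen to make the statistical checks
informative at desk scale: 500 statistical channels × 300 trials for
type-I calibration, 20 full sessions × 1200 pulses for power and
preferred-phase recovery, 20 sessions × 300 pulses for sham isolation,
and 200 null simulations for mixed-model calibration.
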