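# Methods

`mibci` is a complete, self-contained replica of a closed-loop
motor-imagery (MI) brain-computer-interface experiment that compares two
timing strategies for kinesthetic robotic feedback.  Because no recorded
EEG ships with the package, every stage is exercised on synthetic data
whose generative structure matches what the analysis assumes.  This note
documents the models, the defaults and the reasoning behind the open
design choices.

## Trial and session model

A trial is laid out in trial-relative seconds: 4 s of rest (alerting beep
at 3 s), a 1.5-s right-arrow cue at 4 s, an MI period from 4 to 8 s, the
orthosis actuation resolving at 9 s, a 5-s stop screen, and a relax screen
of uniformly random 4-6 s (habituation control).  The MI period tiles into
four half-open 1-s decision windows ([4,5) ... [7,8)); the pre-cue rest
period tiles into four matching rest windows used as the negative class
for scoring.  The choice of the 0-4 s interval for rest scoring is a
design decision: it is the only interval labelled rest in the paradigm and
makes the confusion table balanced (4 + 4 windows per trial).  Windows are
non-overlapping and aligned to integer seconds; the "at most four flexion
movements per trial" property of the continuous feedback implies exactly
four decisions per MI period, so no sliding evaluation is modelled.  A
session phase holds 80 trials in 4 runs of 20; a full cohort of 18
participants therefore contributes 1,440 testing trials per condition.

## Synthetic EEG generator

Per channel the signal is Gaussian 1/f^alpha background noise (default
alpha = 1, spectrally shaped in the Fourier domain, unit-RMS scaled to
`noise_amplitude`) plus two band-limited rhythms: a mu oscillation
(~10 Hz) and a beta oscillation (~20 Hz).  Each rhythm originates from a
lateralized "source" whose electrode gains follow a Gaussian kernel in the
2-D head plane (`spatial_sigma`, default 0.25 head-radius units), with the
contralateral source over C3 for right-hand MI and a mirrored source over
C4.  ERD is planted multiplicatively: the oscillator envelope is scaled by
sqrt(1 + erd) during the MI period (250-ms raised-cosine ramps to avoid
spectral splatter), so band power scales by exactly (1 + erd) — the
quantity the ERD/ERS normalization estimates.  Oscillators carry a random
phase and ~20% slow amplitude jitter per trial so trials are not replicas.

Defaults: `rhythm_amplitude` 20 uV, `noise_amplitude` 4 uV RMS.  The SNR
is chosen so that a planted ERD survives the full analysis chain to within
the package's recovery tolerance (+-0.08): two mechanisms dilute the
estimate on the way — in-band background power at the wavelet bin, and
common-average referencing, which mixes a fraction (the mean source gain
over electrodes) of the *unmodulated* mirror source into the measuring
electrode.  With the default kernel width the CAR dilution is ~3-8% and
the residual noise dilution a few percent; the same CAR mixing produces
the small apparent ipsilateral "ERS" (~+0.05) visible opposite a
unilateral source, which is a property of re-referencing, not a generator
artifact.  The default condition effects used in validation scenarios are
continuous = bilateral alpha ERD -0.5 plus ipsilateral beta ERD -0.3,
discrete = contralateral-only alpha ERD -0.3; cohort generation jitters
every nonzero depth by N(0, 0.1) per participant (zero effects stay
exactly zero so null conditions remain null).

What the generator does *not* emulate: volume conduction beyond the
Gaussian gain kernel, eye-blink/EMG artifacts (only optional square
amplitude spikes for the rejection test), non-stationary rhythm frequency,
inter-trial dependence, and the heterogeneous participant phenotypes of
real cohorts.  Passing tests therefore demonstrate internal consistency
of the pipeline — planted effects are recovered, null effects are not
invented — not decoding performance on real EEG.

## Decoder (FBCSP + PSO + LDA)

Calibration filters each scored 1-s window with a notch filter and a
six-band FIR filter bank (8-12 ... 28-32 Hz, order 30, Hamming design),
fits CSP per band from the MI vs. rest window covariances (trace-
normalized per window, ridge 1e-6 fallback if singular), extracts
log-variance features of the 2m = 6 CSP projections per band (36 features;
m = 3 is common FBCSP practice), selects features with binary PSO and
trains an equal-prior LDA on the selection.  The notch is built as
identity-minus-narrowband-bandpass, which places an exact spectral null at
the mains frequency (default 60 Hz, the recording site's grid) while a
plain order-30 window-design band-stop cannot reach 20 dB.

The online contract is strict causality: a window is filtered in
isolation with forward-only FIR filters, so the decision depends only on
samples inside the window (verified by mutating future samples).
Calibration uses the same per-window causal filtering for train/test
consistency.

PSO hyperparameters (undisclosed upstream) follow standard binary-PSO
practice: swarm 20, 50 iterations, inertia 0.7, c1 = c2 = 1.49, sigmoid
velocity transfer with |v| <= 4, fitness = 5-fold CV accuracy minus
0.01 x selected fraction (parsimony pressure so "select everything" is not
a trivial optimum), all-zero masks repaired to the best univariate
feature, fixed seed.  LDA uses the pooled-covariance solution with
Ledoit-Wolf shrinkage engaged when the pooled covariance condition number
exceeds 1e6.  Feature selection operates at the feature level; the union
of bands with selected features is the band-selection this induces.

## Feedback controllers and kinematics

The orthosis moves 5.5 cm at 1.4 cm/s; the continuous rule commands a 25%
step (1.375 cm) at each MI-labelled window's end (5, 6, 7, 8 s — the
earliest time the window is fully acquired; processing latency is modelled
as zero) and an extension at 9 s if anything flexed; the discrete rule
commands a single full flexion plus extension at 9 s iff at least three of
the four MI windows were labelled MI (raw count, not consecutive).  The
trajectory simulator integrates commands at constant velocity; a command
arriving mid-motion is queued until the actuator is free, displacement is
clamped to [0, 5.5] cm.  Calibration-phase behaviour (feedback on every
trial regardless of the decoder) is a `force_trigger` flag.

## Performance metrics and paired comparison

TP/TN/FP/FN are counted at the window level and pooled over all testing
trials of a participant before computing Sens = 100 TP/(TP+FN) and
CA = 100 (TP+TN)/total — one value per participant and condition (with
constant window counts per trial, pooling and per-trial averaging agree up
to rounding; pooling is numerically cleaner).  Condition differences use a
Lilliefors-corrected Kolmogorov-Smirnov normality check and a two-sided
Wilcoxon signed-rank test, Pratt zero handling, exact enumeration of all
sign patterns for n <= 12 and the tie-corrected normal approximation with
continuity correction above.

## ERD/ERS mapping

Offline analysis is zero-phase (forward-backward) 8-30 Hz FIR filtering,
common average reference, and automated artifact rejection (a trial is
dropped iff any channel exceeds +-100 uV after filtering — a reproducible
surrogate for visual inspection).  Complex Morlet wavelets with
f0/sigma_f = 6 and normalization A = (1/(sigma_t sqrt(pi)))^(1/2) are
convolved with each channel; power is the squared modulus evaluated on a
0-8 s x 8-30 Hz grid at 0.1 s and 0.5 Hz resolution (trials are
reflection-padded by the wavelet support, truncated at +-5 sigma_t).
Power is averaged over trials first and then normalized per
(channel, frequency) bin to (P - P_R)/P_R against the average of a
baseline interval, default 1.0-3.5 s of the rest period (excluding wavelet
edge effects at t = 0 and most of the post-beep second).  Normalizing the
trial average rather than averaging single-trial ratios avoids the upward
Jensen bias a noisy per-trial baseline induces; band summaries average the
normalized bins, which preserves the per-bin fractional-change semantics.

## Cluster-based permutation test

Per bin, a paired t statistic over participant condition differences
(zero-variance bins are set to t = 0); bins beyond the 2.5th/97.5th
t-quantiles form candidates; maximal connected components under adjacency
in one dimension at a time (consecutive time bins, consecutive frequency
bins, or neighbouring channels — no diagonals) are scored by mass (sum of
t); the null is the maximum absolute cluster mass under random
within-participant condition exchange, equivalent to sign-flipping the
difference maps — the standard scheme for a paired design, chosen over a
literal between-group random partition which would contradict the paired t
statistic.  Channel neighbours are pairs closer than 1.3 x the minimal
inter-electrode distance in the head plane, which reproduces the
nearest-neighbour lattice of the 16-channel montage.  p-values use the
(1 + exceedances)/(1 + N) estimator so they are never zero; positive and
negative clusters are formed separately and tested against the max-|mass|
null (two-sided).  Both a full channel x frequency x time test and a
per-band topographic variant (channels only, after band/interval
averaging) are provided.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and `scripts/acceptance.py` are
deliberate package choices that keep a complete run on a single CPU short
while leaving every estimate's Monte-Carlo error well inside its assertion
band: parameter recovery uses 200 trials per depth with the wavelet grid
restricted to the alpha band at the electrode under test; family-wise
error calibration uses statistics-level participant maps on a
16 x 5 x 10 grid (300-500 null replicates at 500 permutations, n = 18);
the cohort replica in the acceptance script runs 8 participants with
20-trial phases on a 1 Hz x 0.2 s map grid.  Degenerate inputs are handled
explicitly: zero-variance CSP projections floor at 1e-12 before the log,
singular covariances warn and fall back to ridge/shrinkage, zero baseline
power and empty band selections raise, and all-zero PSO masks are
repaired.  All stochastic stages draw from `numpy` Generators seeded via
`SeedSequence` from explicit integers, so every artifact is reproducible
bit-for-bit.

## Known limitations

The EDF encoder writes 16-bit integer samples, so round trips are exact
only to the per-channel quantization step.  The decoder's unit-scaling
invariance is empirical, not exact: a global amplitude rescaling shifts
all log-variance features equally, which moves the LDA decision value
unless the selected-feature weights sum to zero.  The cluster test's
Monte-Carlo p-values carry the usual sqrt(p(1-p)/N) resolution.  Synthetic
performance numbers (Sens/CA of simulated cohorts) characterize the
pipeline under the generator's assumptions and are not predictions of
human BCI performance.
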