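# mibci

A reproducible, end-to-end replica of a closed-loop motor-imagery (MI)
brain-computer-interface experiment comparing two timing strategies for
kinesthetic robotic feedback: **continuous** (a 25% hand-orthosis flexion
step immediately after each 1-s EEG window classified as MI) versus
**discrete** (a single full 5.5-cm movement after the MI period, if at
least three of its four windows were classified as MI).

The package is for BCI and EEG-methods researchers who want to study,
stress-test or extend every computational stage of such an experiment
without access to recorded data:

* **Synthetic EEG** — 16-channel sensorimotor montage at 256 Hz, 1/f
  background noise plus lateralized mu (~10 Hz) and beta (~20 Hz) rhythms
  whose power is suppressed by a planted, participant-variable ERD during
  the MI period of a cue-based (Graz-style) trial.
* **Online decoder** — filter-bank CSP (six 4-Hz bands, 8-32 Hz),
  log-variance features, binary-PSO feature selection, LDA; strictly
  causal 1-s window classification.
* **Feedback** — both controllers plus a constant-velocity kinematic
  simulator of the orthosis (5.5 cm travel, 1.4 cm/s).
* **Metrics** — window-level sensitivity (Sens) and classification
  accuracy (CA) per participant; Lilliefors-corrected KS normality check
  and paired Wilcoxon signed-rank comparison.
* **ERD/ERS maps** — complex Morlet wavelets (f0/sigma_f = 6) on a
  0-8 s x 8-30 Hz grid; power P(t, f) = |w * S|^2 normalized to
  (P - P_R)/P_R against a rest baseline; band and grand-average summaries.
* **Cluster statistics** — paired t maps thresholded at the 2.5/97.5
  t-quantiles, spatio-spectral-temporal clustering, max-cluster-mass
  sign-flip permutation null with family-wise error control.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

`examples/01_protocol_and_feedback.py` — the same decoder output pattern
(`mi, mi, rest, mi`) driving both controllers:

```
continuous feedback -> 4 actuation events
  t= 5.0 s  flexion_step +1.38 cm
  t= 6.0 s  flexion_step +1.38 cm
  t= 8.0 s  flexion_step +1.38 cm
  t= 9.0 s  extension    -4.12 cm
  peak displacement 4.12 cm, final 0.00 cm

discrete feedback -> 2 actuation events
  t= 9.0 s  full_flexion +5.50 cm
  t= 9.0 s  extension    -5.50 cm
  peak displacement 5.50 cm, final 0.00 cm
```

Each correctly detected window earns an immediate 1.38-cm step under the
continuous rule; the discrete rule waits for the whole MI period and moves
once, because three or more windows were classified as MI.

`examples/02_synthesize_and_decode.py` — calibrating the decoder on a
synthetic participant with a strong (-0.6) bilateral alpha ERD and scoring
a fresh testing phase of 40 trials (320 scored windows):

```
calibrated: 15/36 features selected, PSO fitness 0.946
confusion: TP=156 TN=141 FP=19 FN=4
Sens = 97.5%   CA = 92.8%
```

Sens is the fraction of MI-period windows that would have driven the
orthosis; CA additionally penalizes false triggers during rest.

`examples/03_erds_maps.py` — the spectral chain recovering a planted
contralateral alpha ERD of -0.4 from 60 trials:

```
alpha ERD/ERS during MI  C3:-0.39  Cz:-0.07  C4:-0.09
beta  ERD/ERS during MI  C3:-0.03  Cz:-0.04  C4:-0.04
```

The remaining examples run the cluster permutation test on a planted
bilateral condition effect (`04`) and a scaled six-participant cohort
end-to-end (`05`).  A thin CLI (`mibci simulate|calibrate|classify|
simulate-feedback|score|compare|erds|cluster|run-experiment`) wraps the
same library calls for shell use; sessions persist as EDF + events TSV,
maps as HDF5, models as JSON.

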