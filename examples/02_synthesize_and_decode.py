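"""Generate a synthetic session, calibrate the decoder, score a test session.

A participant with a strong (-0.6) bilateral alpha ERD is simulated; the
FBCSP + PSO + LDA pipeline is trained on a calibration phase and evaluated
online (1-s causal windows) on a fresh testing phase.
"""

from mibci import (
    BandEffect,
    ConditionEffects,
    ParticipantProfile,
    PSOConfig,
    build_session_schedule,
    calibrate,
    classify_trial,
    generate_session,
    sensitivity,
    classification_accuracy,
    tally_confusion,
)

effects = {"continuous": ConditionEffects(
    alpha=BandEffect(contra=-0.6, ipsi=-0.6))}
profile = ParticipantProfile(participant_id="P01", effects=effects, seed=7)

cal_sched = build_session_schedule("P01", "continuous", "calibration", seed=1,
                                   n_runs=1, trials_per_run=40)
model = calibrate(generate_session(profile, cal_sched),
                  pso_config=PSOConfig(seed=0))
print(f"calibrated: {int(model.mask.sum())}/{model.n_features} features "
      f"selected, PSO fitness {model.pso_fitness:.3f}")

test_sched = build_session_schedule("P01", "continuous", "testing", seed=2,
                                    n_runs=1, trials_per_run=40)
preds, phases = [], []
for rec in generate_session(profile, test_sched):
    labels = classify_trial(rec, model)
    preds += labels["rest"] + labels["mi"]
    phases += ["rest"] * 4 + ["mi"] * 4

counts = tally_confusion(preds, phases)
print(f"confusion: TP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")
print(f"Sens = {sensitivity(counts):.1f}%   CA = {classification_accuracy(counts):.1f}%")
# Sens: fraction of MI-period windows driving the orthosis; CA: overall
# window accuracy including false triggers during rest.
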