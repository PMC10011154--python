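"""Scaled-down end-to-end cohort replica.

Six synthetic participants complete both feedback conditions (calibration
+ testing), the decoder is trained and scored per session, ERD/ERS maps
are built from the testing phases, and the paired statistics are run.
Scaled well below the full 18 x 80-trial design so it finishes in a few
minutes; see scripts/acceptance.py for the larger run.
"""

import json

from mibci import ExperimentConfig, PSOConfig, run_experiment

config = ExperimentConfig(
    n_participants=6,
    seed=0,
    n_runs=1,
    trials_per_run=12,
    pso=PSOConfig(swarm_size=10, iterations=10, seed=0),
    erds_freq_step=2.0,
    erds_time_step=0.5,
    n_permutations=500,
)
report = run_experiment(config, verbose=True)

print("\nmean Sens:", {k: round(v, 1) for k, v in report["mean_sens"].items()})
print("mean CA:  ", {k: round(v, 1) for k, v in report["mean_ca"].items()})
for metric, comp in report["comparisons"].items():
    print(f"Wilcoxon {metric}: p = {comp['p_value']:.4f}")
for band, rep in report["clusters"].items():
    print(f"{band}: {rep['n_significant']} significant clusters")
# The synthetic continuous condition plants deeper/bilateral ERD than the
# discrete one, so Sens/CA favor it and the alpha cluster test tends to
# flag central channels.
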