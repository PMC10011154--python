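"""End-to-end experiment replica on synthetic participants.

For every participant and feedback condition: generate a calibration
session, train the decoder, generate a testing session, classify its 1-s
windows online, drive the orthosis controller, and score Sens/CA; then
build per-condition ERD/ERS maps and run the paired statistics (Wilcoxon
on Sens/CA, cluster permutation test on the maps).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import erds as erds_mod
from .clusterstat import ClusterConfig, band_topography_test, channel_adjacency
from .feedback import OrthosisSpec, TrialDecision, run_controller
from .filters import FilterBankSpec
from .metrics import (
    ParticipantPerformance,
    compare_conditions,
    performance_table,
    tally_confusion,
)
from .montage import DEFAULT_MONTAGE
from .pipeline import PipelineModel, calibrate, classify_trial
from .protocol import build_session_schedule
from .pso import PSOConfig
from .synth import ParticipantProfile, cohort_profiles, generate_session

CONDITIONS = ("continuous", "discrete")


@dataclass
class ExperimentConfig:
    """Everything a full synthetic-cohort run needs, with one master seed."""

    n_participants: int = 18
    seed: int = 0
    n_runs: int = 4
    trials_per_run: int = 20
    bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    m_pairs: int = 3
    pso: PSOConfig = field(default_factory=PSOConfig)
    orthosis: OrthosisSpec = field(default_factory=OrthosisSpec)
    baseline: tuple[float, float] = erds_mod.BASELINE_DEFAULT
    wavelet_ratio: float = erds_mod.WAVELET_RATIO
    erds_freq_step: float = 0.5
    erds_time_step: float = 0.1
    erds_max_trials: int | None = None   # cap trials entering the maps
    mi_interval: tuple[float, float] = (4.0, 8.0)
    n_permutations: int = 5000
    participant_erd_sd: float = 0.1

    def freqs(self) -> np.ndarray:
        return np.arange(8.0, 30.0 + 1e-9, self.erds_freq_step)

    def times(self) -> np.ndarray:
        return np.arange(0.0, 8.0 + 1e-9, self.erds_time_step)

    def stage_seed(self, *tags: int) -> int:
        """Counter-based derivation of per-stage seeds from the master seed."""
        ss = np.random.SeedSequence([self.seed, *tags])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ParticipantResult:
    participant_id: str
    condition: str
    performance: ParticipantPerformance
    model: PipelineModel
    n_actuations: int


def run_participant_condition(
    profile: ParticipantProfile,
    condition: str,
    config: ExperimentConfig,
) -> tuple[ParticipantResult, list]:
    """Calibrate, test online, drive feedback and score one participant in
    one condition.  Returns the result plus the raw testing records (for
    the map stage)."""
    cal_sched = build_session_schedule(
        profile.participant_id, condition, "calibration",
        config.stage_seed(1), config.n_runs, config.trials_per_run,
    )
    test_sched = build_session_schedule(
        profile.participant_id, condition, "testing",
        config.stage_seed(2), config.n_runs, config.trials_per_run,
    )
    cal = generate_session(profile, cal_sched)
    model = calibrate(cal, config.bank, config.m_pairs, config.pso,
                      min_trials=min(20, len(cal)))

    test = generate_session(profile, test_sched)
    preds, phases = [], []
    n_act = 0
    for rec in test:
        labels = classify_trial(rec, model)
        preds += labels["rest"] + labels["mi"]
        phases += ["rest"] * len(labels["rest"]) + ["mi"] * len(labels["mi"])
        decision = TrialDecision(tuple(labels["mi"]), condition)
        events = run_controller(decision, config.orthosis, rec.timeline)
        n_act += sum(1 for e in events if e.displacement > 0)
    counts = tally_confusion(preds, phases)
    perf = ParticipantPerformance(profile.participant_id, condition, counts)
    return ParticipantResult(profile.participant_id, condition, perf, model,
                             n_act), test


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None,
                   verbose: bool = False) -> dict:
    """Full synthetic-cohort replica; returns the summary report dict."""
    t0 = time.time()
    profiles = cohort_profiles(
        config.n_participants, config.stage_seed(0),
        erd_sd=config.participant_erd_sd,
    )
    freqs, times = config.freqs(), config.times()

    perfs: list[ParticipantPerformance] = []
    maps = {c: [] for c in CONDITIONS}
    actuations = {c: 0 for c in CONDITIONS}
    for profile in profiles:
        for condition in CONDITIONS:
            res, test = run_participant_condition(profile, condition, config)
            perfs.append(res.performance)
            actuations[condition] += res.n_actuations
            if config.erds_max_trials is not None:
                test = test[: config.erds_max_trials]
            maps[condition].append(
                erds_mod.session_erds(
                    test, config.baseline, freqs, times,
                    ratio=config.wavelet_ratio,
                )
            )
            if verbose:
                print(
                    f"{profile.participant_id} {condition}: "
                    f"Sens {res.performance.sens:.1f}  CA {res.performance.ca:.1f}"
                )

    table = performance_table(perfs)
    comparisons = {}
    if config.n_participants >= 6:  # the paired test needs a real cohort
        for metric in ("sens", "ca"):
            a = table[table.condition == "continuous"].sort_values("participant")
            b = table[table.condition == "discrete"].sort_values("participant")
            comp = compare_conditions(a[metric].to_numpy(), b[metric].to_numpy())
            comp["differences"] = comp["differences"].tolist()
            comparisons[metric] = comp

    adj = channel_adjacency(DEFAULT_MONTAGE)
    cluster_cfg = ClusterConfig(
        n_permutations=config.n_permutations, seed=config.stage_seed(3)
    )
    cluster_reports = {}
    for band in ("alpha", "beta"):
        result = band_topography_test(
            maps["continuous"], maps["discrete"], band, config.mi_interval,
            adj, cluster_cfg,
        )
        cluster_reports[band] = {
            "n_clusters": len(result.clusters),
            "clusters": [
                {"size": c.size, "mass": c.mass, "sign": c.sign,
                 "p_value": c.p_value,
                 "channels": sorted({DEFAULT_MONTAGE.labels[i]
                                     for i in c.bins[:, 0]})}
                for c in result.clusters
            ],
            "n_significant": len(result.significant),
        }

    report = {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "trials_per_phase": config.n_runs * config.trials_per_run,
        "mean_sens": {
            c: float(table[table.condition == c].sens.mean()) for c in CONDITIONS
        },
        "mean_ca": {
            c: float(table[table.condition == c].ca.mean()) for c in CONDITIONS
        },
        "actuations": actuations,
        "comparisons": comparisons,
        "clusters": cluster_reports,
        "runtime_s": time.time() - t0,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "performance.csv", index=False)
        from .io import save_maps

        save_maps(outdir / "maps.h5", maps, {"seed": config.seed})
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        # append-only run log: one record per artifact with its content hash
        from .io import file_hash

        log = [
            {"stage": stage, "output": name, "sha256_16": file_hash(outdir / name),
             "seed": config.seed, "timestamp": time.time()}
            for stage, name in (("score", "performance.csv"),
                                ("erds", "maps.h5"),
                                ("report", "report.json"))
        ]
        log_path = outdir / "runlog.jsonl"
        with open(log_path, "a") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return report
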