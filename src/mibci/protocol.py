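"""Trial time structure and session design of the cue-based (Graz-style)
motor-imagery paradigm.

A trial runs, in trial-relative seconds with origin at rest onset:

====================  ========================================
0 - 4 s               rest (white cross); alerting beep at 3 s
4 - 5.5 s             right-pointing arrow cue (MI starts at 4 s)
4 - 8 s               motor-imagery period, four 1-s decision windows
9 s                   orthosis actuation resolves (extension / full flexion)
9 - 14 s              stop screen
14 s + 4-6 s          relax screen, random duration to prevent habituation
====================  ========================================

Every session phase holds 80 right-hand MI trials in 4 runs of 20.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from typing import Callable, Literal

import numpy as np
import pandas as pd

Condition = Literal["continuous", "discrete"]
Phase = Literal["calibration", "testing"]

WINDOW_LENGTH = 1.0  # seconds of EEG per decision window

RELAX_RANGE = (4.0, 6.0)


class ProtocolViolation(ValueError):
    """A sampled or supplied value breaks the trial time structure."""


@dataclass(frozen=True)
class TrialTimeline:
    """Event onsets of a single trial, trial-relative seconds."""

    rest_onset: float = 0.0
    beep_at: float = 3.0
    mi_onset: float = 4.0
    arrow_duration: float = 1.5
    mi_end: float = 8.0
    actuation_resolution_at: float = 9.0
    stop_screen_duration: float = 5.0
    relax_onset: float = 14.0
    relax_duration: float = 5.0

    def __post_init__(self) -> None:
        if not (
            self.rest_onset < self.beep_at < self.mi_onset
            < self.mi_end <= self.actuation_resolution_at < self.relax_onset
        ):
            raise ProtocolViolation("trial events out of order")
        n = (self.mi_end - self.mi_onset) / WINDOW_LENGTH
        if abs(n - round(n)) > 1e-9:
            raise ProtocolViolation("MI period must tile into 1-s windows")
        if not RELAX_RANGE[0] <= self.relax_duration <= RELAX_RANGE[1]:
            raise ProtocolViolation(
                f"relax duration {self.relax_duration} outside {RELAX_RANGE}"
            )

    @property
    def duration(self) -> float:
        """Total trial duration in seconds."""
        return self.relax_onset + self.relax_duration


@dataclass(frozen=True)
class WindowSpec:
    """Half-open 1-s scoring window [start, end)."""

    start: float
    end: float
    phase: Literal["rest", "mi", "other"]

    def __post_init__(self) -> None:
        if abs((self.end - self.start) - WINDOW_LENGTH) > 1e-9:
            raise ProtocolViolation("windows are exactly 1 s long")


def build_trial_timeline(
    relax_sampler: Callable[[], float] | None = None,
    rng: np.random.Generator | None = None,
) -> TrialTimeline:
    """Build a timeline with a sampled relax duration.

    ``relax_sampler`` overrides the default uniform(4, 6) draw; values
    outside [4, 6] raise :class:`ProtocolViolation`.
    """
    if relax_sampler is None:
        rng = rng if rng is not None else np.random.default_rng()
        relax = float(rng.uniform(*RELAX_RANGE))
    else:
        relax = float(relax_sampler())
    return TrialTimeline(relax_duration=relax)


def _tile(start: float, end: float, phase: str) -> list[WindowSpec]:
    n = int(round((end - start) / WINDOW_LENGTH))
    return [
        WindowSpec(start + i * WINDOW_LENGTH, start + (i + 1) * WINDOW_LENGTH, phase)
        for i in range(n)
    ]


def mi_windows(timeline: TrialTimeline) -> list[WindowSpec]:
    """Consecutive 1-s windows tiling the MI period [mi_onset, mi_end)."""
    return _tile(timeline.mi_onset, timeline.mi_end, "mi")


def rest_windows(timeline: TrialTimeline) -> list[WindowSpec]:
    """Consecutive 1-s windows tiling the pre-cue rest period."""
    return _tile(timeline.rest_onset, timeline.mi_onset, "rest")


def scoring_windows(timeline: TrialTimeline) -> list[WindowSpec]:
    """All scored windows of a trial: rest first, then MI."""
    return rest_windows(timeline) + mi_windows(timeline)


@dataclass(frozen=True)
class TrialDescriptor:
    trial_index: int
    relax_duration: float

    def timeline(self) -> TrialTimeline:
        return TrialTimeline(relax_duration=self.relax_duration)


@dataclass(frozen=True)
class SessionSchedule:
    """80 right-hand MI trials in 4 runs of 20, for one participant/phase."""

    participant_id: str
    condition: Condition
    phase: Phase
    runs: tuple[tuple[TrialDescriptor, ...], ...]
    seed: int

    @property
    def trials(self) -> list[TrialDescriptor]:
        return [t for run in self.runs for t in run]

    @property
    def n_trials(self) -> int:
        return sum(len(run) for run in self.runs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "participant": self.participant_id,
                "condition": self.condition,
                "phase": self.phase,
                "seed": self.seed,
                "runs": [
                    [asdict(t) for t in run] for run in self.runs
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionSchedule":
        obj = json.loads(text)
        runs = tuple(
            tuple(TrialDescriptor(**t) for t in run) for run in obj["runs"]
        )
        return cls(obj["participant"], obj["condition"], obj["phase"], runs, obj["seed"])


N_RUNS = 4
TRIALS_PER_RUN = 20


def build_session_schedule(
    participant_id: str,
    condition: Condition,
    phase: Phase,
    seed: int,
    n_runs: int = N_RUNS,
    trials_per_run: int = TRIALS_PER_RUN,
) -> SessionSchedule:
    """Deterministic session schedule; relax durations from a seeded generator."""
    if condition not in ("continuous", "discrete"):
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in ("calibration", "testing"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(participant_id.encode()),
                                0 if condition == "continuous" else 1,
                                0 if phase == "calibration" else 1])
    )
    runs = []
    idx = 0
    for _ in range(n_runs):
        run = []
        for _ in range(trials_per_run):
            run.append(TrialDescriptor(idx, float(rng.uniform(*RELAX_RANGE))))
            idx += 1
        runs.append(tuple(run))
    return SessionSchedule(participant_id, condition, phase, tuple(runs), seed)


def condition_order(participant_id: str, seed: int) -> tuple[Condition, Condition]:
    """Randomized per-participant order of the two session conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(participant_id.encode()), 99])
    )
    order: list[Condition] = ["continuous", "discrete"]
    if rng.integers(2):
        order.reverse()
    return tuple(order)  # type: ignore[return-value]


def events_table(schedule: SessionSchedule) -> pd.DataFrame:
    """Long-form event table: one row per event per trial.

    Columns onset (session-relative seconds), duration, label, trial_index.
    Trials are laid out back to back in schedule order.
    """
    rows = []
    t0 = 0.0
    for trial in schedule.trials:
        tl = trial.timeline()
        rows += [
            (t0 + tl.rest_onset, tl.mi_onset - tl.rest_onset, "rest", trial.trial_index),
            (t0 + tl.beep_at, 0.0, "beep", trial.trial_index),
            (t0 + tl.mi_onset, tl.arrow_duration, "cue", trial.trial_index),
            (t0 + tl.mi_onset, tl.mi_end - tl.mi_onset, "mi", trial.trial_index),
            (t0 + tl.actuation_resolution_at, tl.stop_screen_duration, "stop",
             trial.trial_index),
            (t0 + tl.relax_onset, tl.relax_duration, "relax", trial.trial_index),
        ]
        t0 += tl.duration
    return pd.DataFrame(rows, columns=["onset", "duration", "label", "trial_index"])


def write_events(schedule_or_table, path) -> None:
    table = (
        events_table(schedule_or_table)
        if isinstance(schedule_or_table, SessionSchedule)
        else schedule_or_table
    )
    table.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "label", "trial_index"}
    if not required.issubset(table.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    return table
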