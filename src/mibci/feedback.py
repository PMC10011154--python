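"""Robotic hand-orthosis feedback: continuous vs. discrete timing rules.

Continuous: each MI-classified 1-s window triggers, at the window's end, a
partial flexion of 25% of the maximum displacement (1.38 cm of 5.5 cm); an
extension returns the hand to the start position when the trial's
actuation window resolves (9 s).  Discrete: nothing moves until 9 s; if at
least three of the four MI-period windows were classified as MI, a single
full flexion to 5.5 cm is performed, followed by extension.

The kinematic simulator integrates the commanded targets at the constant
actuator velocity (1.4 cm/s); a command arriving mid-motion is queued until
the current motion completes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .pipeline import MI
from .protocol import TrialTimeline, mi_windows

DISCRETE_THRESHOLD = 3  # MI windows needed to trigger the single movement


@dataclass(frozen=True)
class OrthosisSpec:
    max_displacement: float = 5.5   # cm
    velocity: float = 1.4           # cm/s
    step_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must lie in (0, 1]")
        if self.velocity <= 0 or self.max_displacement <= 0:
            raise ValueError("velocity and displacement must be positive")

    @property
    def step_cm(self) -> float:
        return self.step_fraction * self.max_displacement


@dataclass(frozen=True)
class ActuationEvent:
    time: float  # trial-relative seconds at which the command is issued
    kind: Literal["flexion_step", "full_flexion", "extension"]
    displacement: float  # signed cm; flexion positive


@dataclass(frozen=True)
class TrialDecision:
    window_labels: tuple[str, ...]
    condition: Literal["continuous", "discrete"]

    @property
    def n_mi(self) -> int:
        return sum(1 for lb in self.window_labels if lb == MI)


def continuous_controller(
    decision: TrialDecision,
    spec: OrthosisSpec = OrthosisSpec(),
    timeline: TrialTimeline = TrialTimeline(),
    force_trigger: bool = False,
) -> list[ActuationEvent]:
    """One flexion step per MI-labeled window, extension at resolution time.

    ``force_trigger`` reproduces the calibration phase, in which feedback is
    delivered on every window regardless of the decoder output.
    """
    if decision.condition != "continuous":
        raise ValueError("decision is not for the continuous condition")
    windows = mi_windows(timeline)
    if len(decision.window_labels) != len(windows):
        raise ValueError("one label per MI-period window required")
    events: list[ActuationEvent] = []
    total = 0.0
    for w, label in zip(windows, decision.window_labels):
        if force_trigger or label == MI:
            step = min(spec.step_cm, spec.max_displacement - total)
            total += step
            events.append(ActuationEvent(w.end, "flexion_step", step))
    if events:
        events.append(
            ActuationEvent(timeline.actuation_resolution_at, "extension", -total)
        )
    return events


def discrete_controller(
    decision: TrialDecision,
    spec: OrthosisSpec = OrthosisSpec(),
    timeline: TrialTimeline = TrialTimeline(),
    force_trigger: bool = False,
) -> list[ActuationEvent]:
    """Single full flexion + extension at 9 s iff >= 3 windows were MI."""
    if decision.condition != "discrete":
        raise ValueError("decision is not for the discrete condition")
    if len(decision.window_labels) != len(mi_windows(timeline)):
        raise ValueError("one label per MI-period window required")
    if not (force_trigger or decision.n_mi >= DISCRETE_THRESHOLD):
        return []
    t = timeline.actuation_resolution_at
    return [
        ActuationEvent(t, "full_flexion", spec.max_displacement),
        ActuationEvent(t, "extension", -spec.max_displacement),
    ]


def run_controller(decision: TrialDecision, spec: OrthosisSpec = OrthosisSpec(),
                   timeline: TrialTimeline = TrialTimeline(),
                   force_trigger: bool = False) -> list[ActuationEvent]:
    fn = (continuous_controller if decision.condition == "continuous"
          else discrete_controller)
    return fn(decision, spec, timeline, force_trigger)


def orthosis_trajectory(
    events: list[ActuationEvent],
    spec: OrthosisSpec = OrthosisSpec(),
    duration: float = 19.0,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear displacement time series from an event list.

    Returns (times, displacement_cm).  Commands are served in order; a
    command issued before the previous motion finished starts when the
    actuator becomes free (the hardware cannot teleport).  Displacement is
    clamped to [0, max_displacement].
    """
    if any(b.time < a.time for a, b in zip(events, events[1:])):
        raise ValueError("events must be time-ordered")
    times = np.arange(0.0, duration + dt / 2, dt)
    pos = np.zeros_like(times)
    current = 0.0
    t_free = 0.0  # when the actuator finishes its current motion
    segments = []  # (t_start, t_end, from, to)
    for ev in events:
        start = max(ev.time, t_free)
        target = float(np.clip(current + ev.displacement, 0.0, spec.max_displacement))
        travel = abs(target - current) / spec.velocity
        segments.append((start, start + travel, current, target))
        current = target
        t_free = start + travel
    for t0, t1, p0, p1 in segments:
        if t1 > t0:
            ramp = (times >= t0) & (times < t1)
            pos[ramp] = p0 + (p1 - p0) * (times[ramp] - t0) / (t1 - t0)
        pos[times >= t1] = p1
    return times, pos
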