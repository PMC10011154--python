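"""Feedback controllers and orthosis kinematics, exhaustively over the
16 possible window-label patterns."""

from itertools import product

import numpy as np
import pytest

from mibci.feedback import (
    ActuationEvent,
    OrthosisSpec,
    TrialDecision,
    continuous_controller,
    discrete_controller,
    orthosis_trajectory,
    run_controller,
)
from mibci.protocol import TrialTimeline

SPEC = OrthosisSpec()
ALL_PATTERNS = [tuple("mi" if b else "rest" for b in bits)
                for bits in product([0, 1], repeat=4)]


def n_mi(pattern):
    return pattern.count("mi")


class TestContinuous:
    def test_all_mi_four_steps_to_max_then_extension(self, timeline):
        events = continuous_controller(
            TrialDecision(("mi",) * 4, "continuous"), SPEC, timeline)
        flex = [e for e in events if e.kind == "flexion_step"]
        assert len(flex) == 4
        assert all(e.displacement == pytest.approx(1.375) for e in flex)
        assert sum(e.displacement for e in flex) == pytest.approx(5.5)
        assert events[-1].kind == "extension"
        assert events[-1].time == 9.0

    def test_no_mi_no_events(self, timeline):
        events = continuous_controller(
            TrialDecision(("rest",) * 4, "continuous"), SPEC, timeline)
        assert events == []

    def test_alternating_pattern_times_and_total(self, timeline):
        events = continuous_controller(
            TrialDecision(("rest", "mi", "rest", "mi"), "continuous"),
            SPEC, timeline)
        flex = [e for e in events if e.kind == "flexion_step"]
        assert [e.time for e in flex] == [6.0, 8.0]
        assert sum(e.displacement for e in flex) == pytest.approx(2.75)

    def test_steps_at_window_ends(self, timeline):
        events = continuous_controller(
            TrialDecision(("mi", "mi", "mi", "mi"), "continuous"), SPEC,
            timeline)
        assert [e.time for e in events if e.kind == "flexion_step"] == [
            5.0, 6.0, 7.0, 8.0]

    def test_force_trigger_calibration_mode(self, timeline):
        events = continuous_controller(
            TrialDecision(("rest",) * 4, "continuous"), SPEC, timeline,
            force_trigger=True)
        assert sum(e.kind == "flexion_step" for e in events) == 4


class TestDiscrete:
    def test_three_mi_triggers_single_full_flexion(self, timeline):
        events = discrete_controller(
            TrialDecision(("mi", "mi", "mi", "rest"), "discrete"), SPEC,
            timeline)
        kinds = [e.kind for e in events]
        assert kinds == ["full_flexion", "extension"]
        assert events[0].displacement == pytest.approx(5.5)
        assert events[0].time == 9.0

    def test_two_mi_below_threshold_no_events(self, timeline):
        events = discrete_controller(
            TrialDecision(("mi", "mi", "rest", "rest"), "discrete"), SPEC,
            timeline)
        assert events == []

    def test_four_mi_still_single_flexion(self, timeline):
        events = discrete_controller(
            TrialDecision(("mi",) * 4, "discrete"), SPEC, timeline)
        assert sum(e.kind == "full_flexion" for e in events) == 1

    def test_condition_mismatch_rejected(self, timeline):
        with pytest.raises(ValueError):
            discrete_controller(TrialDecision(("mi",) * 4, "continuous"),
                                SPEC, timeline)


class TestExhaustivePatterns:
    @pytest.mark.parametrize("pattern", ALL_PATTERNS)
    def test_event_counts_match_rules(self, pattern, timeline):
        cont = continuous_controller(TrialDecision(pattern, "continuous"),
                                     SPEC, timeline)
        disc = discrete_controller(TrialDecision(pattern, "discrete"),
                                   SPEC, timeline)
        assert sum(e.kind == "flexion_step" for e in cont) == n_mi(pattern)
        assert sum(e.displacement > 0 for e in disc) in (0, 1)
        assert (len(disc) == 2) == (n_mi(pattern) >= 3)

    @pytest.mark.parametrize("pattern", ALL_PATTERNS)
    def test_trajectory_bounded_and_returns_to_zero(self, pattern, timeline):
        for condition in ("continuous", "discrete"):
            events = run_controller(TrialDecision(pattern, condition), SPEC,
                                    timeline)
            t, pos = orthosis_trajectory(events, SPEC, duration=19.0)
            assert pos.min() >= -1e-9
            assert pos.max() <= SPEC.max_displacement + 1e-9
            assert pos[-1] == pytest.approx(0.0, abs=1e-9)
            # continuity: bounded slope at the actuator velocity
            assert np.abs(np.diff(pos)).max() <= SPEC.velocity * 0.01 + 1e-9

    @pytest.mark.parametrize("pattern", ALL_PATTERNS)
    def test_peak_displacement(self, pattern, timeline):
        cont_events = continuous_controller(
            TrialDecision(pattern, "continuous"), SPEC, timeline)
        _, cont_pos = orthosis_trajectory(cont_events, SPEC)
        disc_events = discrete_controller(
            TrialDecision(pattern, "discrete"), SPEC, timeline)
        _, disc_pos = orthosis_trajectory(disc_events, SPEC)
        assert cont_pos.max() == pytest.approx(
            min(n_mi(pattern) * SPEC.step_cm, SPEC.max_displacement), abs=0.02)
        expected_disc = SPEC.max_displacement if n_mi(pattern) >= 3 else 0.0
        assert disc_pos.max() == pytest.approx(expected_disc, abs=0.02)


class TestTrajectory:
    def test_full_flexion_ramp_duration(self):
        events = [ActuationEvent(0.0, "full_flexion", 5.5)]
        t, pos = orthosis_trajectory(events, SPEC, duration=6.0)
        ramp_end = 5.5 / 1.4
        assert pos[np.searchsorted(t, ramp_end + 0.05)] == pytest.approx(5.5)
        assert pos[np.searchsorted(t, ramp_end / 2)] == pytest.approx(
            5.5 / 2, abs=0.05)

    def test_no_events_identically_zero(self):
        _, pos = orthosis_trajectory([], SPEC)
        assert not pos.any()

    def test_queued_commands_serialize(self):
        # two steps issued back-to-back: second starts after first completes
        events = [ActuationEvent(1.0, "flexion_step", 1.375),
                  ActuationEvent(1.1, "flexion_step", 1.375)]
        t, pos = orthosis_trajectory(events, SPEC, duration=5.0)
        t_done = 1.0 + 2 * 1.375 / 1.4
        assert pos[np.searchsorted(t, t_done + 0.05)] == pytest.approx(2.75)
        assert np.abs(np.diff(pos)).max() <= 1.4 * 0.01 + 1e-9

    def test_unordered_events_rejected(self):
        events = [ActuationEvent(2.0, "flexion_step", 1.0),
                  ActuationEvent(1.0, "flexion_step", 1.0)]
        with pytest.raises(ValueError):
            orthosis_trajectory(events, SPEC)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            OrthosisSpec(step_fraction=0.0)
        with pytest.raises(ValueError):
            OrthosisSpec(velocity=-1.0)
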