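"""Trial structure and the two feedback timing rules.

Builds the standard trial timeline, shows its 1-s scoring windows, and
feeds the same decoder output pattern to both orthosis controllers.
"""

from mibci import (
    OrthosisSpec,
    TrialDecision,
    build_trial_timeline,
    continuous_controller,
    discrete_controller,
    mi_windows,
    orthosis_trajectory,
    rest_windows,
)

timeline = build_trial_timeline(relax_sampler=lambda: 5.0)
print(f"MI period {timeline.mi_onset}-{timeline.mi_end} s, "
      f"actuation resolves at {timeline.actuation_resolution_at} s")
print("rest windows:", [(w.start, w.end) for w in rest_windows(timeline)])
print("MI windows:  ", [(w.start, w.end) for w in mi_windows(timeline)])

# the decoder called three of the four MI windows "mi"
labels = ("mi", "mi", "rest", "mi")
spec = OrthosisSpec()

for name, controller in (("continuous", continuous_controller),
                         ("discrete", discrete_controller)):
    events = controller(TrialDecision(labels, name), spec, timeline)
    print(f"\n{name} feedback -> {len(events)} actuation events")
    for e in events:
        print(f"  t={e.time:4.1f} s  {e.kind:12s} {e.displacement:+.2f} cm")
    t, pos = orthosis_trajectory(events, spec)
    print(f"  peak displacement {pos.max():.2f} cm, final {pos[-1]:.2f} cm")

# Continuous: each detected window earns one 25% flexion step immediately;
# discrete: one full 5.5 cm movement at 9 s because >= 3 windows were MI.
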