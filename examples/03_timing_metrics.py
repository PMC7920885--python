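"""Procedure-timing metrics from an annotated event timeline.

Builds the classic worked example — skin incision at t=0, vessel loop
passed at t=100 s, instruments out of the incision during [10,20) and
[50,55), hands otherwise active — computes the timing metrics, then shows
a censored (not-completed) procedure and a group summary.
"""

from handmotion import Event, ProcedureTimeline, compute_metrics, summarize_group
from handmotion import TimelineTargets, generate_timeline

toy = ProcedureTimeline(
    [
        Event(0.0, "milestone", "skin_incision"),
        Event(100.0, "milestone", "vessel_loop_passed"),
        Event(0.0, "instrument_in", "forceps"),
        Event(10.0, "instrument_out", "forceps"),
        Event(20.0, "instrument_in", "forceps"),
        Event(50.0, "instrument_out", "forceps"),
        Event(55.0, "instrument_in", "forceps"),
        Event(0.0, "contact_start", "hands"),
        Event(10.0, "contact_end", "hands"),
        Event(20.0, "contact_start", "hands"),
        Event(50.0, "contact_end", "hands"),
        Event(55.0, "contact_start", "hands"),
        Event(100.0, "contact_end", "hands"),
    ]
)
m = compute_metrics(toy)
print(f"total {m.total_time:g} s, idle {m.idle_time:g} s, active {m.active_time:g} s, "
      f"idle/active {m.idle_pct_of_active:.1f} %")

# A procedure that never reaches the vessel-loop milestone is censored at
# the 20-minute cap, reported as "> 1200", and excluded from group means.
censored = compute_metrics(
    ProcedureTimeline(
        [Event(0.0, "milestone", "skin_incision"),
         Event(30.0, "contact_start", "hands"),
         Event(400.0, "contact_end", "hands")]
    )
)
print(f"uncompleted procedure: total {censored.format_field('total_time')}, "
      f"completed={censored.completed}")

# Group summary over two synthetic expert-like procedures
records = [
    compute_metrics(
        generate_timeline(
            TimelineTargets.for_skill("expert", total_time=t, active_time=t - 8.0),
            seed=s,
        )
    )
    for s, t in ((1, 303.0), (2, 328.0))
]
total = summarize_group(records).fields["total_time"]
print(f"expert group total time: mean {total['mean']:g} s "
      f"(range {total['min']:g}-{total['max']:g})")
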