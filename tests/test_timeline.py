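"""Timeline validation, the eight timing metrics, and group summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from handmotion.timeline import (
    Event,
    ProcedureMetrics,
    ProcedureTimeline,
    TimelineValidationError,
    compute_metrics,
    summarize_group,
    validate_timeline,
)


def tl(events, **kw):
    return ProcedureTimeline(list(events), **kw)


BASE = [
    Event(0.0, "milestone", "skin_incision"),
    Event(100.0, "milestone", "vessel_loop_passed"),
]


def test_worked_interval_example(toy_timeline):
    m = compute_metrics(toy_timeline)
    assert m.total_time == 100.0
    assert m.idle_time == 15.0
    assert m.active_time == 85.0
    assert m.completed
    assert m.idle_pct_of_active == pytest.approx(100 * 15 / 85)  # ~17.6%
    assert m.active_idle_ratio == pytest.approx(85 / 15)


def test_validation_passes_on_wellformed_toy(toy_timeline):
    assert validate_timeline(toy_timeline) == []


@pytest.mark.parametrize(
    "events, fragment",
    [
        (BASE + [Event(10, "dissection_start", "blunt")], "unclosed"),
        ([Event(5, "milestone", "vessel_loop_passed"),
          Event(10, "milestone", "skin_incision")], "precedes skin_incision"),
        ([Event(0, "milestone", "skin_incision"),
          Event(10, "teleport", "x")], "unknown event kind"),
        (BASE + [Event(10, "instrument_out", "forceps")], "expected instrument_in"),
        (BASE + [Event(10, "dissection_start", "laser"),
                 Event(12, "dissection_end", "laser")], "unknown dissection mode"),
        (BASE + [Event(10, "dissection_start", "blunt"),
                 Event(12, "dissection_start", "sharp"),
                 Event(14, "dissection_end", "sharp"),
                 Event(20, "dissection_end", "blunt")], "overlapping dissection"),
        ([Event(3, "contact_start", "hands"), Event(5, "contact_end", "hands")],
         "missing skin_incision"),
    ],
)
def test_validation_catches_structural_violations(events, fragment):
    errs = validate_timeline(tl(events))
    assert any(fragment in e for e in errs), errs
    with pytest.raises(TimelineValidationError):
        compute_metrics(tl(events))


def test_instrument_changes_count_transitions_not_repickups():
    picks = ["scalpel", "forceps", "scalpel", "retractor"]
    events = BASE + [
        Event(10.0 + i, "instrument_pickup", p) for i, p in enumerate(picks)
    ]
    assert compute_metrics(tl(events)).instrument_changes == 3

    events = BASE + [
        Event(10.0, "instrument_pickup", "scalpel"),
        Event(20.0, "instrument_pickup", "scalpel"),
    ]
    assert compute_metrics(tl(events)).instrument_changes == 0


def test_missing_vessel_loop_is_censored_at_time_limit():
    events = [Event(0.0, "milestone", "skin_incision"),
              Event(30.0, "contact_start", "hands"),
              Event(400.0, "contact_end", "hands")]
    m = compute_metrics(tl(events, time_limit=1200.0))
    assert not m.completed
    assert m.total_time == 1200.0
    assert "total_time" in m.censored_fields
    assert m.format_field("total_time") == "> 1200"


def test_dissection_mode_times_and_ratio():
    events = BASE + [
        Event(10.0, "dissection_start", "blunt"),
        Event(30.0, "dissection_end", "blunt"),
        Event(40.0, "dissection_start", "sharp"),
        Event(88.0, "dissection_end", "sharp"),
    ]
    m = compute_metrics(tl(events))
    assert m.blunt_time == 20.0 and m.sharp_time == 48.0
    assert m.sharp_blunt_ratio == pytest.approx(2.4)
    assert m.active_time == 68.0  # dissection counts as activity


def test_zero_denominator_ratios_are_undefined():
    m = compute_metrics(tl(BASE))
    assert m.idle_time == 0.0 and m.active_time == 0.0
    assert m.active_idle_ratio is None
    assert m.sharp_blunt_ratio is None
    assert m.idle_pct_of_active is None


def test_instrument_durations_per_identity():
    events = BASE + [
        Event(0.0, "instrument_in", "retractor"),
        Event(60.0, "instrument_out", "retractor"),
        Event(20.0, "instrument_in", "scalpel"),
        Event(35.0, "instrument_out", "scalpel"),
    ]
    m = compute_metrics(tl(events))
    assert m.instrument_durations == {"retractor": 60.0, "scalpel": 15.0}
    # idle = union of the two out intervals [60,100) and [35,100) = 65
    assert m.idle_time == 65.0


def test_splitting_an_interval_leaves_accounting_unchanged(toy_timeline):
    """Interval accounting must be invariant to splitting any event
    interval into adjacent sub-intervals."""
    m0 = compute_metrics(toy_timeline)
    split = [e for e in toy_timeline.events] + [
        Event(15.0, "instrument_in", "forceps"),
        Event(15.0, "instrument_out", "forceps"),
        Event(70.0, "contact_end", "hands"),
        Event(70.0, "contact_start", "hands"),
    ]
    m1 = compute_metrics(tl(split))
    assert m1.idle_time == m0.idle_time
    assert m1.active_time == m0.active_time
    assert m1.total_time == m0.total_time


@given(st.integers(0, 2**31 - 1))
def test_adding_an_out_interval_never_decreases_idle(seed):
    rng = np.random.default_rng(seed)
    a, b = np.sort(rng.integers(0, 100_000, 2)).tolist()
    base_events = BASE + [
        Event(10.0, "instrument_in", "forceps"),
        Event(30.0, "instrument_out", "forceps"),
        Event(50.0, "instrument_in", "forceps"),
    ]
    m0 = compute_metrics(tl(base_events))
    extra = base_events + [
        Event(a / 1000.0, "instrument_in", "clamp"),
        Event(a / 1000.0, "instrument_out", "clamp"),
        Event(b / 1000.0, "instrument_in", "clamp"),
    ]
    m1 = compute_metrics(tl(extra))
    assert m1.idle_time >= m0.idle_time


def test_summarize_means_and_ranges():
    def metrics_with_total(total, completed=True):
        return ProcedureMetrics(
            total_time=total, idle_time=10.0, active_time=total - 10,
            time_to_pectoralis_minor=50.0, instrument_changes=5,
            blunt_time=10.0, sharp_time=20.0, instrument_durations={},
            active_idle_ratio=(total - 10) / 10, sharp_blunt_ratio=2.0,
            idle_pct_of_active=100 * 10 / (total - 10), completed=completed,
        )

    g = summarize_group([metrics_with_total(303.0), metrics_with_total(328.0)])
    assert g.fields["total_time"]["mean"] == 315.5
    assert g.fields["total_time"]["min"] == 303.0
    assert g.fields["total_time"]["max"] == 328.0

    single = summarize_group([metrics_with_total(400.0)])
    assert single.fields["total_time"] == {
        "mean": 400.0, "min": 400.0, "max": 400.0, "n": 1, "censored_n": 0,
    }

    censored = summarize_group(
        [metrics_with_total(303.0), metrics_with_total(1200.0, completed=False)]
    )
    assert censored.fields["total_time"]["mean"] == 303.0  # censored excluded
    assert censored.fields["total_time"]["censored_n"] == 1

    with pytest.raises(ValueError):
        summarize_group([])


def test_csv_round_trip(tmp_path, toy_timeline):
    p = tmp_path / "timeline.csv"
    toy_timeline.to_csv(p)
    back = ProcedureTimeline.from_csv(p)
    assert [(e.time, e.kind, e.detail) for e in back.events] == [
        (e.time, e.kind, e.detail) for e in toy_timeline.events
    ]
    assert compute_metrics(back).idle_time == 15.0
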