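"""Procedure-event timelines and observational timing metrics.

A procedure (axillary artery exposure and proximal control, in the study
this package grew out of) is annotated as a timestamped event stream:
milestones (skin incision, division of pectoralis minor, passage of the
vessel loop), hand/instrument contact intervals, instrument in/out-of-
incision intervals, instrument pickups, and blunt/sharp dissection-mode
intervals.  From such a timeline the eight observational metrics are
computed:

1. total time (skin incision to passage of the vessel loop),
2. total idle time,
3. total active time,
4. time from skin incision to division of pectoralis minor,
5. number of instrument changes,
6. blunt dissection time,
7. sharp dissection time,
8. per-instrument use durations,

plus the derived ratios (active/idle, sharp/blunt, idle as % of active).

Operational definitions:

* idle time is the union of the intervals instruments spend outside the
  incision (instrument_out to the next instrument_in), clipped to the
  procedure window;
* active time is the union of hand/instrument contact intervals and
  dissection intervals — bimanual simultaneous activity is not double
  counted;
* a procedure with no vessel-loop milestone is censored at the time limit
  (default 1200 s, i.e. 20 min): total time is reported as "> limit",
  excluded from group means, never silently averaged.

Active and idle derive from different event families and therefore need
not satisfy active + idle = total.

All event times are interpreted on a 1-millisecond grid (interval sums are
computed in integer milliseconds), so metrics on ms-resolution timelines
are exact.  Intervals are half-open [start, end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Event",
    "ProcedureTimeline",
    "ProcedureMetrics",
    "GroupSummary",
    "TimelineValidationError",
    "validate_timeline",
    "compute_metrics",
    "summarize_group",
    "MILESTONES",
    "DEFAULT_TIME_LIMIT",
]

DEFAULT_TIME_LIMIT = 1200.0  # s; the 20-minute procedure cap

EVENT_KINDS = {
    "milestone",
    "contact_start",
    "contact_end",
    "instrument_in",
    "instrument_out",
    "instrument_pickup",
    "dissection_start",
    "dissection_end",
}
MILESTONES = ("skin_incision", "pectoralis_minor_divided", "vessel_loop_passed")
DISSECTION_MODES = ("blunt", "sharp")


@dataclass(frozen=True)
class Event:
    time: float  # seconds from video start
    kind: str
    detail: str = ""


@dataclass
class ProcedureTimeline:
    """Ordered event stream of one procedure."""

    events: list[Event]
    time_limit: float = DEFAULT_TIME_LIMIT

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)

    def of_kind(self, kind: str, detail: str | None = None) -> list[Event]:
        return [
            e
            for e in self.events
            if e.kind == kind and (detail is None or e.detail == detail)
        ]

    def milestone_time(self, name: str) -> float | None:
        ev = self.of_kind("milestone", name)
        return ev[0].time if ev else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time for e in self.events],
                "kind": [e.kind for e in self.events],
                "detail": [e.detail for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, time_limit: float = DEFAULT_TIME_LIMIT) -> "ProcedureTimeline":
        df = pd.read_csv(path, keep_default_na=False)
        events = [
            Event(float(r.time_s), str(r.kind), str(r.detail))
            for r in df.itertuples(index=False)
        ]
        return cls(events, time_limit=time_limit)


class TimelineValidationError(ValueError):
    """A timeline violated its structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def _check_alternation(
    events: Sequence[Event], open_kind: str, close_kind: str, label: str, errs: list[str]
) -> None:
    """start/end (or in/out) events must alternate, starting open, ending closed."""
    expect_open = True
    for e in events:
        want = open_kind if expect_open else close_kind
        if e.kind != want:
            errs.append(
                f"{label}: expected {want} but found {e.kind} at t={e.time:g}"
            )
            return
        expect_open = not expect_open
    if not expect_open:
        errs.append(f"{label}: unclosed {open_kind} interval")


def validate_timeline(t: ProcedureTimeline) -> list[str]:
    """Collect all structural violations (empty list means valid).

    Checks: known event kinds; non-negative times; a single skin-incision
    milestone preceding all other events; milestone order; matched
    start/end pairs for contacts and dissection modes; matched in/out
    alternation per instrument; valid dissection-mode labels.
    """
    errs: list[str] = []
    for i, e in enumerate(t.events):
        if e.kind not in EVENT_KINDS:
            errs.append(f"row {i}: unknown event kind {e.kind!r}")
        if e.time < 0:
            errs.append(f"row {i}: negative time {e.time:g}")
        if e.kind == "milestone" and e.detail not in MILESTONES:
            errs.append(f"row {i}: unknown milestone {e.detail!r}")

    incision = t.milestone_time("skin_incision")
    if incision is None:
        errs.append("missing skin_incision milestone")
    else:
        if len(t.of_kind("milestone", "skin_incision")) > 1:
            errs.append("multiple skin_incision milestones")
        for e in t.events:
            if e.time < incision:
                errs.append(
                    f"event {e.kind}/{e.detail} at t={e.time:g} precedes skin_incision"
                )
        for name in ("pectoralis_minor_divided", "vessel_loop_passed"):
            mt = t.milestone_time(name)
            if mt is not None and mt < incision:
                errs.append(f"{name} precedes skin_incision")

    # contact intervals pair per contact label (hand or instrument)
    contacts = [e for e in t.events if e.kind in ("contact_start", "contact_end")]
    for detail in sorted({e.detail for e in contacts}):
        _check_alternation(
            [e for e in contacts if e.detail == detail],
            "contact_start",
            "contact_end",
            f"contact[{detail}]",
            errs,
        )

    # dissection intervals pair per mode; modes must not overlap each other
    dissect = [e for e in t.events if e.kind in ("dissection_start", "dissection_end")]
    for e in dissect:
        if e.detail not in DISSECTION_MODES:
            errs.append(f"unknown dissection mode {e.detail!r} at t={e.time:g}")
    for mode in DISSECTION_MODES:
        _check_alternation(
            [e for e in dissect if e.detail == mode],
            "dissection_start",
            "dissection_end",
            f"dissection[{mode}]",
            errs,
        )
    depth = 0
    for e in dissect:
        depth += 1 if e.kind == "dissection_start" else -1
        if depth > 1:
            errs.append(f"overlapping dissection modes at t={e.time:g}")
            break

    # instrument in/out alternation per instrument, starting with in
    inout = [e for e in t.events if e.kind in ("instrument_in", "instrument_out")]
    for detail in sorted({e.detail for e in inout}):
        seq = [e for e in inout if e.detail == detail]
        expect_in = True
        for e in seq:
            want = "instrument_in" if expect_in else "instrument_out"
            if e.kind != want:
                errs.append(
                    f"instrument[{detail}]: expected {want} but found {e.kind} "
                    f"at t={e.time:g}"
                )
                break
            expect_in = not expect_in
    return errs


# ---------------------------------------------------------------------------
# metric computation (integer-millisecond interval arithmetic)


def _ms(x: float) -> int:
    return int(round(x * 1000.0))


def _union_length_ms(intervals: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    """Total length of the union of half-open ms intervals clipped to [lo, hi)."""
    clipped = sorted(
        (max(a, lo), min(b, hi)) for a, b in intervals if min(b, hi) > max(a, lo)
    )
    total = 0
    cur_a = cur_b = None
    for a, b in clipped:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def _paired_intervals(
    events: Sequence[Event], open_kind: str, close_kind: str, end_ms: int
) -> list[tuple[int, int]]:
    """Turn an alternating open/close event sequence into ms intervals.

    An unclosed trailing interval is closed at ``end_ms``.
    """
    out: list[tuple[int, int]] = []
    open_t: int | None = None
    for e in events:
        if e.kind == open_kind:
            open_t = _ms(e.time)
        elif e.kind == close_kind and open_t is not None:
            out.append((open_t, _ms(e.time)))
            open_t = None
    if open_t is not None:
        out.append((open_t, end_ms))
    return out


@dataclass
class ProcedureMetrics:
    """The eight observational metrics plus derived ratios for one operator.

    Times in seconds.  ``completed`` is False when the vessel-loop milestone
    is absent; then ``total_time`` equals the time limit and is censored
    ("> limit").  Undefined ratios (zero denominator) are ``None``.
    """

    total_time: float
    idle_time: float
    active_time: float
    time_to_pectoralis_minor: float | None
    instrument_changes: int
    blunt_time: float
    sharp_time: float
    instrument_durations: dict[str, float]
    active_idle_ratio: float | None
    sharp_blunt_ratio: float | None
    idle_pct_of_active: float | None
    completed: bool
    time_limit: float = DEFAULT_TIME_LIMIT

    @property
    def censored_fields(self) -> set[str]:
        """Fields reported as '> limit' rather than measured values."""
        if self.completed:
            return set()
        out = {"total_time", "active_time"}
        if self.time_to_pectoralis_minor is None:
            out.add("time_to_pectoralis_minor")
        return out

    def format_field(self, name: str) -> str:
        if name in self.censored_fields:
            return f"> {self.time_limit:g}"
        v = getattr(self, name)
        return "NA" if v is None else f"{v:g}"

    def to_dict(self) -> dict:
        return {
            "total_time": self.total_time,
            "idle_time": self.idle_time,
            "active_time": self.active_time,
            "time_to_pectoralis_minor": self.time_to_pectoralis_minor,
            "instrument_changes": self.instrument_changes,
            "blunt_time": self.blunt_time,
            "sharp_time": self.sharp_time,
            "instrument_durations": dict(self.instrument_durations),
            "active_idle_ratio": self.active_idle_ratio,
            "sharp_blunt_ratio": self.sharp_blunt_ratio,
            "idle_pct_of_active": self.idle_pct_of_active,
            "completed": self.completed,
            "time_limit": self.time_limit,
            "censored_fields": sorted(self.censored_fields),
        }


def compute_metrics(t: ProcedureTimeline, validate: bool = True) -> ProcedureMetrics:
    """Compute the eight metrics and derived ratios from a timeline.

    Raises :class:`TimelineValidationError` when ``validate`` is on and the
    timeline is malformed.
    """
    if validate:
        errs = validate_timeline(t)
        if errs:
            raise TimelineValidationError(errs)

    incision = t.milestone_time("skin_incision")
    assert incision is not None  # guaranteed by validation
    loop = t.milestone_time("vessel_loop_passed")
    limit_ms = _ms(t.time_limit)
    inc_ms = _ms(incision)

    completed = loop is not None
    if completed:
        total_ms = _ms(loop) - inc_ms
        end_ms = _ms(loop)
    else:
        total_ms = limit_ms
        end_ms = inc_ms + limit_ms

    # idle: union of out-of-incision intervals across instruments
    inout = [e for e in t.events if e.kind in ("instrument_in", "instrument_out")]
    out_intervals: list[tuple[int, int]] = []
    in_intervals_by_instr: dict[str, list[tuple[int, int]]] = {}
    for detail in sorted({e.detail for e in inout}):
        seq = [e for e in inout if e.detail == detail]
        out_intervals += _paired_intervals(seq, "instrument_out", "instrument_in", end_ms)
        in_intervals_by_instr[detail] = _paired_intervals(
            seq, "instrument_in", "instrument_out", end_ms
        )
    idle_ms = _union_length_ms(out_intervals, inc_ms, end_ms)

    # active: union of contact intervals and dissection intervals
    contacts = [e for e in t.events if e.kind in ("contact_start", "contact_end")]
    activity: list[tuple[int, int]] = []
    for detail in sorted({e.detail for e in contacts}):
        seq = [e for e in contacts if e.detail == detail]
        activity += _paired_intervals(seq, "contact_start", "contact_end", end_ms)
    dissect = [e for e in t.events if e.kind in ("dissection_start", "dissection_end")]
    mode_ms: dict[str, int] = {}
    for mode in DISSECTION_MODES:
        seq = [e for e in dissect if e.detail == mode]
        ivs = _paired_intervals(seq, "dissection_start", "dissection_end", end_ms)
        mode_ms[mode] = _union_length_ms(ivs, inc_ms, end_ms)
        activity += ivs
    active_ms = _union_length_ms(activity, inc_ms, end_ms)

    pect = t.milestone_time("pectoralis_minor_divided")
    time_to_pect = None if pect is None else (_ms(pect) - inc_ms) / 1000.0

    # instrument changes: transitions between distinct instruments in pickup
    # order; re-picking the same instrument is not a change
    pickups = [e.detail for e in t.of_kind("instrument_pickup")]
    changes = sum(1 for a, b in zip(pickups, pickups[1:]) if a != b)

    instrument_durations = {
        instr: _union_length_ms(ivs, inc_ms, end_ms) / 1000.0
        for instr, ivs in in_intervals_by_instr.items()
    }

    idle = idle_ms / 1000.0
    active = active_ms / 1000.0
    blunt = mode_ms["blunt"] / 1000.0
    sharp = mode_ms["sharp"] / 1000.0
    return ProcedureMetrics(
        total_time=total_ms / 1000.0,
        idle_time=idle,
        active_time=active,
        time_to_pectoralis_minor=time_to_pect,
        instrument_changes=changes,
        blunt_time=blunt,
        sharp_time=sharp,
        instrument_durations=instrument_durations,
        active_idle_ratio=(active / idle) if idle_ms > 0 else None,
        sharp_blunt_ratio=(sharp / blunt) if mode_ms["blunt"] > 0 else None,
        idle_pct_of_active=(100.0 * idle / active) if active_ms > 0 else None,
        completed=completed,
        time_limit=t.time_limit,
    )


_SUMMARY_FIELDS = (
    "total_time",
    "idle_time",
    "active_time",
    "time_to_pectoralis_minor",
    "instrument_changes",
    "blunt_time",
    "sharp_time",
    "active_idle_ratio",
    "sharp_blunt_ratio",
    "idle_pct_of_active",
)


@dataclass
class GroupSummary:
    """Mean and range per metric over a group of operators.

    Censored records ("> limit") are excluded from means and counted in
    ``censored_n``; a field is flagged censored whenever any record in the
    group is censored for it.
    """

    n_operators: int
    fields: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.fields.items():
            rows.append(
                {
                    "metric": name,
                    "mean": s["mean"],
                    "min": s["min"],
                    "max": s["max"],
                    "n": s["n"],
                    "censored_n": s["censored_n"],
                }
            )
        return pd.DataFrame(rows)


def summarize_group(metrics: Sequence[ProcedureMetrics]) -> GroupSummary:
    """Aggregate operator metrics into per-field mean + (min, max)."""
    if len(metrics) == 0:
        raise ValueError("summarize_group requires at least one record")
    fields: dict[str, dict] = {}
    for name in _SUMMARY_FIELDS:
        values = []
        censored = 0
        for m in metrics:
            if name in m.censored_fields:
                censored += 1
                continue
            v = getattr(m, name)
            if v is not None:
                values.append(float(v))
        fields[name] = {
            "mean": (sum(values) / len(values)) if values else None,
            "min": min(values) if values else None,
            "max": max(values) if values else None,
            "n": len(values),
            "censored_n": censored,
        }
    return GroupSummary(n_operators=len(metrics), fields=fields)
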