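import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from handmotion.timeline import Event, ProcedureTimeline


@pytest.fixture
def toy_timeline() -> ProcedureTimeline:
    """Worked interval example: incision at 0, vessel loop at 100 s,
    instruments out of the incision during [10, 20) and [50, 55),
    hands otherwise continuously active."""
    ev = [
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
    return ProcedureTimeline(ev)


def random_timeline_targets(rng: np.random.Generator):
    """Draw an internally consistent TimelineTargets on the ms grid."""
    from handmotion.synthetic import TimelineTargets

    completed = rng.random() < 0.8
    limit = 1200.0
    total = float(rng.integers(60_000, 1_200_001)) / 1000.0
    end = total if completed else limit
    idle = float(rng.integers(0, int(end * 1000) - 10 + 1)) / 1000.0
    active = float(rng.integers(0, int(end * 1000) + 1)) / 1000.0
    blunt = float(rng.integers(0, int(active * 1000) + 1)) / 1000.0
    sharp = float(rng.integers(0, int(active * 1000) - int(blunt * 1000) + 1)) / 1000.0
    pect = (
        None
        if rng.random() < 0.3
        else float(rng.integers(0, int(end * 1000) + 1)) / 1000.0
    )
    return TimelineTargets(
        total_time=total,
        idle_time=idle,
        active_time=active,
        time_to_pectoralis_minor=pect,
        instrument_changes=int(rng.integers(0, 120)),
        blunt_time=blunt,
        sharp_time=sharp,
        completed=bool(completed),
        time_limit=limit,
    )
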