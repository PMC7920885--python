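"""End-to-end run: synthetic cohort -> per-operator reports -> group panel.

Builds a small cohort (one operator per skill level, each with 300 s of
simulated motion and a matching procedure timeline), runs the whole
pipeline through its config interface, and prints the group panel.
"""

import tempfile
from pathlib import Path

from handmotion import (
    MotionProfile,
    TimelineTargets,
    generate_timeline,
    generate_trajectory,
    run_pipeline,
)
from handmotion.tracking import write_tracks_csv

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    operators = []
    for i, level in enumerate(("expert", "resident", "novice")):
        tracks = generate_trajectory(
            MotionProfile.for_skill(level, seed=50 + i, duration=300.0)
        )
        tcsv = tmp / f"{level}_tracks.csv"
        write_tracks_csv([t.to_hand_track() for t in tracks.values()], tcsv)
        tlcsv = tmp / f"{level}_timeline.csv"
        generate_timeline(TimelineTargets.for_skill(level), seed=50 + i).to_csv(tlcsv)
        operators.append(
            {"id": f"{level}_0", "group": level, "tracks": str(tcsv),
             "timeline": str(tlcsv), "frame_rate": 50.0}
        )

    result = run_pipeline({"operators": operators}, out_dir=tmp / "reports")

print(f"{'group':>10s} {'speed H':>8s} {'total s':>8s} {'idle s':>7s} {'changes':>8s}")
for group in ("expert", "resident", "novice"):
    g = result["groups"][group]
    ms = g["metrics_summary"]
    print(
        f"{group:>10s} {g['entropy_mean']['speed']:8.2f} "
        f"{ms['total_time']['mean']:8.1f} {ms['idle_time']['mean']:7.1f} "
        f"{ms['instrument_changes']['mean']:8.0f}"
    )

# Experts show the lowest joint speed entropy, shortest total time, least
# idle time and fewest instrument changes; every report embeds input
# hashes and the binning policy so each number is auditable.
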