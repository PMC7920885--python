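"""Joint entropy separates smooth from rough bimanual motion.

Simulates 600 s of hand motion for an expert-like, a resident-like and a
novice-like operator (identical parameters except the velocity jitter:
2, 10 and 20 px/s) and prints each operator's joint entropy triplet.
Lower speed entropy = smoother, more predictable bimanual motion.
"""

from handmotion import MotionProfile, generate_trajectory, operator_entropy
from handmotion.kinematics import track_kinematics

print(f"{'operator':>10s} {'jitter':>7s} {'speed H':>8s} {'accel H':>8s} {'dir H':>6s}")
for level in ("expert", "resident", "novice"):
    profile = MotionProfile.for_skill(level, seed=7, duration=600.0)
    tracks = generate_trajectory(profile)
    triplet = operator_entropy(
        track_kinematics(tracks["dominant"].to_hand_track()),
        track_kinematics(tracks["nondominant"].to_hand_track()),
    )
    print(
        f"{level:>10s} {profile.jitter_sd:7.0f} "
        f"{triplet.speed.bits:8.2f} {triplet.acceleration.bits:8.2f} "
        f"{triplet.direction.bits:6.2f}"
    )

# Speed entropy rises with jitter (the skill knob): the expert's tight
# speed distribution occupies few histogram bins, the novice's noise
# spreads across many.  Values are in bits on the package's default
# binning (32 bins over the pooled 1st-99th percentile range per hand).
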