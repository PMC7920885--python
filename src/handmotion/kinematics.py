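"""1 Hz kinematic features from per-frame hand tracks.

The per-frame centroid track is first collapsed to a 1 Hz position series
(mean of the valid centroids inside each second), then differenced:

* speed(k)        = |p(k+1) - p(k)|            [pixels/s]
* acceleration(k) = speed(k+1) - speed(k)      [pixels/s per s]
* direction(k)    = angle between the displacement vectors
                    p(k)->p(k+1) and p(k+1)->p(k+2), unsigned, in
                    degrees on [0, 180]

Averaging within the second before differencing suppresses detector pixel
noise that frame-rate differencing would amplify.  No interpolation is
performed across detection gaps: a second with fewer than half its frames
validly detected is an invalid sample, and every derived sample touching
an invalid position is itself invalid.  Idle (out-of-frame) time is signal
in this domain, not noise to impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import HandTrack

__all__ = [
    "KinematicSeries",
    "resample_1hz",
    "compute_kinematics",
    "track_kinematics",
    "write_kinematics_csv",
]

# A 1 Hz sample is kept only if at least this fraction of its frames have a
# valid detection.
MIN_VALID_FRACTION = 0.5


@dataclass
class KinematicSeries:
    """Per-second kinematics for one hand, NaN-padded with validity masks.

    All arrays share length ``n = floor(track duration in seconds)``.
    ``speed[k]`` covers the displacement over [k, k+1) and has one fewer
    defined sample than there are positions; acceleration and direction
    have one fewer defined sample than speed.
    """

    hand: str
    times: np.ndarray  # second index, shape (n,)
    speed: np.ndarray
    speed_valid: np.ndarray
    acceleration: np.ndarray
    acceleration_valid: np.ndarray
    direction_change: np.ndarray  # degrees in [0, 180]
    direction_valid: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (
            self.speed,
            self.speed_valid,
            self.acceleration,
            self.acceleration_valid,
            self.direction_change,
            self.direction_valid,
        ):
            if len(arr) != n:
                raise ValueError("all series must share the 1 Hz grid length")

    def feature(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, valid_mask) for 'speed'|'acceleration'|'direction'."""
        if name == "speed":
            return self.speed, self.speed_valid
        if name == "acceleration":
            return self.acceleration, self.acceleration_valid
        if name == "direction":
            return self.direction_change, self.direction_valid
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "hand": self.hand,
                "speed": self.speed,
                "speed_valid": self.speed_valid.astype(int),
                "acceleration": self.acceleration,
                "acceleration_valid": self.acceleration_valid.astype(int),
                "direction_change": self.direction_change,
                "direction_valid": self.direction_valid.astype(int),
            }
        )


def resample_1hz(track: HandTrack) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a per-frame track to per-second positions.

    Returns
    -------
    positions : (n, 2) float array
        Mean of the valid centroids within each whole second; NaN rows
        where the second is invalid.
    valid : (n,) bool array
        A second is valid when at least half of its frames carry a valid
        detection.
    """
    fps = track.frame_rate
    n_sec = int(np.floor(track.n_frames / fps))
    if n_sec < 1:
        raise ValueError("track shorter than one second cannot be resampled")
    positions = np.full((n_sec, 2), np.nan)
    valid = np.zeros(n_sec, bool)
    for k in range(n_sec):
        lo = int(round(k * fps))
        hi = int(round((k + 1) * fps))
        sel = track.valid[lo:hi]
        n_frames = hi - lo
        if n_frames > 0 and sel.sum() >= MIN_VALID_FRACTION * n_frames:
            positions[k, 0] = np.mean(track.x[lo:hi][sel])
            positions[k, 1] = np.mean(track.y[lo:hi][sel])
            valid[k] = True
    return positions, valid


def compute_kinematics(
    positions: np.ndarray, valid: np.ndarray | None = None, hand: str = ""
) -> KinematicSeries:
    """Differentiate a 1 Hz position series into speed/acceleration/direction.

    ``positions`` is (n, 2); ``valid`` marks usable samples (defaults to
    all-finite rows).  A zero-length displacement has no direction, so the
    corresponding direction sample is invalid rather than 0 degrees —
    stillness must not masquerade as directional stability.
    """
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    n = len(positions)
    if valid is None:
        valid = np.isfinite(positions).all(axis=1)
    valid = np.asarray(valid, bool)

    times = np.arange(n)
    speed = np.full(n, np.nan)
    speed_valid = np.zeros(n, bool)
    acc = np.full(n, np.nan)
    acc_valid = np.zeros(n, bool)
    theta = np.full(n, np.nan)
    theta_valid = np.zeros(n, bool)

    disp = np.diff(positions, axis=0)  # disp[k] = p(k+1) - p(k)
    pair_ok = valid[:-1] & valid[1:]
    step = np.linalg.norm(disp, axis=1)
    speed[: n - 1][pair_ok] = step[pair_ok]
    speed_valid[: n - 1] = pair_ok

    for k in range(n - 2):
        if speed_valid[k] and speed_valid[k + 1]:
            acc[k] = speed[k + 1] - speed[k]
            acc_valid[k] = True
            u, v = disp[k], disp[k + 1]
            nu, nv = step[k], step[k + 1]
            if nu > 0 and nv > 0:
                cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
                theta[k] = np.degrees(np.arccos(cosang))
                theta_valid[k] = True

    return KinematicSeries(
        hand=hand,
        times=times,
        speed=speed,
        speed_valid=speed_valid,
        acceleration=acc,
        acceleration_valid=acc_valid,
        direction_change=theta,
        direction_valid=theta_valid,
    )


def track_kinematics(track: HandTrack) -> KinematicSeries:
    """Full pipeline for one hand: 1 Hz resampling then differencing."""
    positions, valid = resample_1hz(track)
    return compute_kinematics(positions, valid, hand=track.hand)


def write_kinematics_csv(series: list[KinematicSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
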