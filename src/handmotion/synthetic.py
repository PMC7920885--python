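"""Synthetic bimanual motion, rendered video, and procedure timelines.

Real glove-tracked surgical footage cannot be redistributed, so this
module fabricates the three kinds of input the pipeline consumes:

* ground-truth hand trajectories with controllable "skill" structure,
* rendered videos (two colored blobs plus optional distractor blobs) with
  a per-frame ground-truth sidecar, and
* procedure-event timelines that reproduce requested timing metrics
  exactly by construction.

The motion model is a smoothed random walk: each hand carries a velocity
that relaxes toward ``base_speed`` along a heading which is re-drawn at
Poisson-distributed direction-change events, while a per-frame Gaussian
kick of scale ``jitter_sd`` perturbs the velocity (an Ornstein-Uhlenbeck
style process).  Larger ``jitter_sd`` produces rougher, less predictable
motion — the knob that emulates decreasing operator skill.  Idle periods
are modeled as the hand leaving the frame entirely, the nearest observable
analogue of instruments resting outside the incision.

Every function takes all randomness from an explicit seed; the same seed
always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from skimage.draw import disk

from .colors import (
    ColorSpec,
    DEFAULT_DISTRACTOR_RGBS,
    GREEN_GLOVE,
    GREEN_GLOVE_RGB,
    ORANGE_GLOVE,
    ORANGE_GLOVE_RGB,
    check_separability,
)
from .timeline import DEFAULT_TIME_LIMIT, Event, ProcedureTimeline
from .tracking import HandTrack

__all__ = [
    "MotionProfile",
    "SyntheticScene",
    "GroundTruthTrack",
    "generate_trajectory",
    "render_video",
    "TimelineTargets",
    "generate_timeline",
]

SkillLevel = Literal["expert", "resident", "novice"]

# Mean-reversion rate of the velocity toward its target (1/s).  A 0.1 s
# relaxation time models rapid neuromuscular velocity correction; it keeps
# purposeful motion tightly concentrated around base_speed so that the
# jitter kick — the skill knob — is what broadens the speed distribution.
_VELOCITY_RELAXATION = 10.0
# Average idle bout length used to decide how many out-of-frame blocks to
# carve the idle budget into (s).
_IDLE_BOUT_S = 15.0

# Skill presets: only jitter differs between levels so that entropy
# contrasts are attributable to motion roughness alone.
_SKILL_JITTER = {"expert": 2.0, "resident": 10.0, "novice": 20.0}


@dataclass(frozen=True)
class MotionProfile:
    """Parameters of one operator's simulated hand motion.

    base_speed : pixels/s — target magnitude of the hand velocity.
    jitter_sd : pixels/s — standard deviation of the per-frame Gaussian
        velocity kick; the skill knob (expert 2, resident 10, novice 20).
    direction_change_rate : events/s — Poisson rate of heading re-draws.
    idle_fraction : fraction of frames the hand spends out of frame.
    """

    skill_level: SkillLevel = "expert"
    base_speed: float = 100.0
    jitter_sd: float = 2.0
    direction_change_rate: float = 0.2
    idle_fraction: float = 0.2
    duration: float = 600.0
    frame_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.idle_fraction <= 1.0):
            raise ValueError("idle_fraction must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.base_speed < 0:
            raise ValueError("base_speed must be >= 0")
        if self.direction_change_rate < 0:
            raise ValueError("direction_change_rate must be >= 0")

    @classmethod
    def for_skill(cls, level: SkillLevel, seed: int = 0, **overrides) -> "MotionProfile":
        """Preset profile for a skill level; only jitter differs by level."""
        if level not in _SKILL_JITTER:
            raise ValueError(f"unknown skill level {level!r}")
        kw = dict(skill_level=level, jitter_sd=_SKILL_JITTER[level], seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class SyntheticScene:
    """Geometry and colors of the rendered scene.

    Glove blobs are solid filled circles — detection is color-based, so
    shape carries no information.  Distractor blobs are rendered beneath
    the gloves (an operator's gloves are never occluded by bystanders) and
    use colors separable from both glove specs.
    """

    frame_size: tuple[int, int] = (640, 480)  # (width, height)
    glove_specs: tuple[ColorSpec, ColorSpec] = (GREEN_GLOVE, ORANGE_GLOVE)
    glove_rgbs: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        GREEN_GLOVE_RGB,
        ORANGE_GLOVE_RGB,
    )
    distractor_rgbs: tuple[tuple[int, int, int], ...] = ()
    blob_radius: int = 10
    background_rgb: tuple[int, int, int] = (70, 70, 70)

    def __post_init__(self) -> None:
        w, h = self.frame_size
        if w <= 4 * self.blob_radius or h <= 4 * self.blob_radius:
            raise ValueError("frame too small for the blob radius")
        check_separability(list(self.glove_specs))
        for spec, rgb in zip(self.glove_specs, self.glove_rgbs):
            if not spec.contains_rgb(rgb):
                raise ValueError(
                    f"render color {rgb} for {spec.name!r} falls outside its own HSV box"
                )
        for rgb in self.distractor_rgbs:
            for spec in self.glove_specs:
                if spec.contains_rgb(rgb):
                    raise ValueError(
                        f"distractor color {rgb} is not separable from glove {spec.name!r}"
                    )
        for spec in self.glove_specs:
            if spec.contains_rgb(self.background_rgb):
                raise ValueError("background color falls inside a glove HSV box")

    @property
    def margin(self) -> float:
        return self.blob_radius + 2.0

    def with_distractors(self, rgbs=None) -> "SyntheticScene":
        return replace(self, distractor_rgbs=tuple(rgbs or DEFAULT_DISTRACTOR_RGBS))


@dataclass
class GroundTruthTrack:
    """True per-frame blob positions for one hand."""

    hand: str
    frame_rate: float
    x: np.ndarray
    y: np.ndarray
    in_frame: np.ndarray  # bool per frame

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def to_hand_track(self) -> HandTrack:
        """View the ground truth as a HandTrack (for kinematics/entropy)."""
        x = np.where(self.in_frame, self.x, np.nan)
        y = np.where(self.in_frame, self.y, np.nan)
        return HandTrack(self.hand, self.frame_rate, self.in_frame.copy(), x, y)


def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [lo, hi] (billiard unfolding)."""
    span = hi - lo
    q = np.mod(p - lo, 2.0 * span)
    return lo + np.minimum(q, 2.0 * span - q)


def _idle_mask(n: int, idle_fraction: float, frame_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean out-of-frame mask with exactly round(idle_fraction*n) frames set.

    The idle budget is split into a few contiguous bouts placed between
    random-length active stretches, so the exact requested fraction is met
    while the bout structure stays plausible.
    """
    n_idle = int(round(idle_fraction * n))
    mask = np.zeros(n, bool)
    if n_idle == 0:
        return mask
    if n_idle >= n:
        mask[:] = True
        return mask
    k = max(1, int(round(n_idle / (_IDLE_BOUT_S * frame_rate))))
    k = min(k, n_idle)
    # sizes of the k idle bouts (each >= 1 frame)
    cuts = np.sort(rng.choice(np.arange(1, n_idle), size=k - 1, replace=False)) if k > 1 else np.array([], int)
    idle_sizes = np.diff(np.concatenate([[0], cuts, [n_idle]])).astype(int)
    # sizes of the k+1 active stretches (each >= 1 frame)
    n_active = n - n_idle
    acuts = np.sort(rng.choice(np.arange(1, n_active), size=k, replace=False))
    active_sizes = np.diff(np.concatenate([[0], acuts, [n_active]])).astype(int)
    pos = 0
    for i in range(k):
        pos += active_sizes[i]
        mask[pos : pos + idle_sizes[i]] = True
        pos += idle_sizes[i]
    return mask


def _simulate_hand(
    profile: MotionProfile,
    scene: SyntheticScene,
    hand: str,
    rng: np.random.Generator,
    x_bounds: tuple[float, float] | None = None,
) -> GroundTruthTrack:
    fps = profile.frame_rate
    dt = 1.0 / fps
    n = int(round(profile.duration * fps))
    if n < 1:
        raise ValueError("duration times frame_rate must give at least one frame")
    beta = min(1.0, _VELOCITY_RELAXATION * dt)

    # piecewise-constant heading, re-drawn at Poisson events
    change = rng.random(n) < profile.direction_change_rate * dt
    change[0] = True
    draws = rng.uniform(0.0, 2.0 * np.pi, int(change.sum()))
    idx = np.cumsum(change) - 1
    angle = draws[idx]
    target = profile.base_speed * np.stack([np.cos(angle), np.sin(angle)], axis=1)

    # OU-style velocity: v[t] = (1-beta) v[t-1] + beta*target[t] + kick[t]
    kick = profile.jitter_sd * rng.standard_normal((n, 2))
    drive = beta * target + kick
    drive[0] = target[0]  # v starts exactly on target
    v = lfilter([1.0], [1.0, -(1.0 - beta)], drive, axis=0)

    w, h = scene.frame_size
    m = scene.margin
    x_lo, x_hi = x_bounds if x_bounds is not None else (m, w - 1 - m)
    p0 = np.array(
        [
            rng.uniform(x_lo + 0.25 * (x_hi - x_lo), x_lo + 0.75 * (x_hi - x_lo)),
            rng.uniform(0.25 * h, 0.75 * h),
        ]
    )
    p = p0 + np.cumsum(v * dt, axis=0) - v[0] * dt  # position at frame 0 is p0
    x = _fold(p[:, 0], x_lo, x_hi)
    y = _fold(p[:, 1], m, h - 1 - m)

    in_frame = ~_idle_mask(n, profile.idle_fraction, fps, rng)
    return GroundTruthTrack(hand, fps, x, y, in_frame)


def generate_trajectory(
    profile: MotionProfile, scene: SyntheticScene | None = None
) -> dict[str, GroundTruthTrack]:
    """Simulate both hands; returns tracks keyed 'dominant'/'nondominant'.

    Positions always lie within frame bounds (reflecting walls keep the
    blob fully visible); the out-of-frame fraction equals
    ``profile.idle_fraction`` to within one frame by construction.  Each
    hand works its own half of the frame (dominant left, non-dominant
    right, separated by more than a blob diameter) so the two blobs never
    occlude one another.  A fixed seed yields bit-identical output.
    """
    scene = scene or SyntheticScene()
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(profile.seed).spawn(2)
    ]
    names = [spec.name for spec in scene.glove_specs]
    w = scene.frame_size[0]
    m = scene.margin
    half_gap = scene.blob_radius + 1.0
    bands = [(m, w / 2 - half_gap), (w / 2 + half_gap, w - 1 - m)]
    return {
        name: _simulate_hand(profile, scene, name, rng, x_bounds=band)
        for name, rng, band in zip(names, streams, bands)
    }


def tracks_to_sidecar(tracks: dict[str, GroundTruthTrack]) -> pd.DataFrame:
    rows = []
    for hand, tr in tracks.items():
        rows.append(
            pd.DataFrame(
                {
                    "frame_index": np.arange(tr.n_frames),
                    "hand": hand,
                    "x": tr.x,
                    "y": tr.y,
                    "in_frame": tr.in_frame.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _distractor_center(
    j: int, t: float, scene: SyntheticScene
) -> tuple[float, float]:
    """Deterministic circular path for distractor blob j at time t (s)."""
    w, h = scene.frame_size
    r = 0.30 * min(w, h)
    period = 8.0 + 3.0 * j
    phase = 2.0 * np.pi * j / 3.0
    cx = w / 2.0 + r * np.cos(2.0 * np.pi * t / period + phase)
    cy = h / 2.0 + r * np.sin(2.0 * np.pi * t / period + phase)
    return cx, cy


def render_video(
    tracks: dict[str, GroundTruthTrack],
    scene: SyntheticScene,
    path: str | Path,
    sidecar_path: str | Path | None = None,
) -> Path:
    """Render tracks as a multi-page TIFF video plus a ground-truth CSV.

    One solid circle per in-frame hand is drawn at its true position in
    that hand's glove color; distractor blobs (if the scene has any) are
    drawn beneath the gloves.  The sidecar CSV (default: video path with a
    ``.csv`` suffix) has one row per frame per hand.
    """
    import tifffile

    path = Path(path)
    n = max(tr.n_frames for tr in tracks.values())
    fps = next(iter(tracks.values())).frame_rate
    w, h = scene.frame_size
    base = np.empty((h, w, 3), np.uint8)
    base[:] = scene.background_rgb
    rgb_by_hand = {
        spec.name: rgb for spec, rgb in zip(scene.glove_specs, scene.glove_rgbs)
    }
    unknown = set(tracks) - set(rgb_by_hand)
    if unknown:
        raise ValueError(f"tracks for unknown hands {sorted(unknown)}")

    try:
        writer = tifffile.TiffWriter(path)
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write video to {path}: {exc}") from exc
    with writer:
        for i in range(n):
            frame = base.copy()
            for j, rgb in enumerate(scene.distractor_rgbs):
                cx, cy = _distractor_center(j, i / fps, scene)
                rr, cc = disk((cy, cx), scene.blob_radius, shape=(h, w))
                frame[rr, cc] = rgb
            for hand, tr in tracks.items():
                rgb = rgb_by_hand[hand]
                if i < tr.n_frames and tr.in_frame[i]:
                    rr, cc = disk((tr.y[i], tr.x[i]), scene.blob_radius, shape=(h, w))
                    frame[rr, cc] = rgb
            writer.write(frame, photometric="rgb", compression="zlib", contiguous=False)

    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".csv")
    tracks_to_sidecar(tracks).to_csv(sidecar, index=False)
    return path


# ---------------------------------------------------------------------------
# timeline synthesis


def _snap_ms(x: float | None) -> float | None:
    return None if x is None else round(x * 1000.0) / 1000.0


@dataclass(frozen=True)
class TimelineTargets:
    """Requested metric values for a synthetic procedure timeline.

    Times in seconds (snapped to the millisecond grid the metrics module
    works on).  ``active_time`` defaults to ``total_time - idle_time``.
    Recomputing metrics from the generated timeline reproduces these
    values exactly.
    """

    total_time: float = 600.0
    idle_time: float = 60.0
    active_time: float | None = None
    time_to_pectoralis_minor: float | None = None
    instrument_changes: int = 5
    blunt_time: float = 60.0
    sharp_time: float = 120.0
    completed: bool = True
    time_limit: float = DEFAULT_TIME_LIMIT

    def __post_init__(self) -> None:
        for name in (
            "total_time",
            "idle_time",
            "active_time",
            "time_to_pectoralis_minor",
            "blunt_time",
            "sharp_time",
            "time_limit",
        ):
            object.__setattr__(self, name, _snap_ms(getattr(self, name)))

    @property
    def end_time(self) -> float:
        """Procedure window length: total if completed, else the cap."""
        return self.total_time if self.completed else self.time_limit

    @property
    def resolved_active(self) -> float:
        if self.active_time is not None:
            return self.active_time
        return round((self.end_time - self.idle_time) * 1000.0) / 1000.0

    def validate(self) -> None:
        end = self.end_time
        active = self.resolved_active
        problems = []
        if self.total_time <= 0:
            problems.append("total_time must be positive")
        if self.completed and self.total_time > self.time_limit:
            problems.append("a completed procedure cannot exceed the time limit")
        if not 0 <= self.idle_time <= end - 0.01:
            problems.append("idle_time must lie in [0, end - 0.01]")
        if not 0 <= active <= end:
            problems.append("active_time must lie in [0, end]")
        if self.blunt_time < 0 or self.sharp_time < 0:
            problems.append("dissection times must be >= 0")
        if self.blunt_time + self.sharp_time > active:
            problems.append("blunt_time + sharp_time cannot exceed active_time")
        if self.instrument_changes < 0:
            problems.append("instrument_changes must be >= 0")
        tp = self.time_to_pectoralis_minor
        if tp is not None and not (0 <= tp <= end):
            problems.append("time_to_pectoralis_minor must lie in [0, end]")
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def for_skill(cls, level: SkillLevel, **overrides) -> "TimelineTargets":
        """Representative targets per operator group.

        The contrasts follow the qualitative pattern of the study: experts
        finish fastest with the least idle time and fewest instrument
        changes; novices (anatomically knowledgeable non-surgeons) are
        slowest with the most instrument changes; residents sit between.
        """
        presets: dict[str, dict] = {
            "expert": dict(
                total_time=315.0,
                active_time=307.0,
                idle_time=8.9,
                time_to_pectoralis_minor=96.0,
                instrument_changes=23,
                blunt_time=50.0,
                sharp_time=120.0,
            ),
            "resident": dict(
                total_time=619.0,
                active_time=589.0,
                idle_time=30.0,
                time_to_pectoralis_minor=212.0,
                instrument_changes=35,
                blunt_time=60.0,
                sharp_time=270.0,
            ),
            "novice": dict(
                total_time=1030.0,
                active_time=968.0,
                idle_time=54.2,
                time_to_pectoralis_minor=500.0,
                instrument_changes=67,
                blunt_time=200.0,
                sharp_time=320.0,
            ),
        }
        if level not in presets:
            raise ValueError(f"unknown skill level {level!r}")
        kw = presets[level]
        kw.update(overrides)
        return cls(**kw)


_INSTRUMENT_CYCLE = ("forceps", "scalpel", "retractor", "scissors")


def _random_partition_ms(total_ms: int, k: int, rng: np.random.Generator,
                         min_part: int = 0) -> np.ndarray:
    """Split total_ms into k integer parts (each >= min_part) at random."""
    free = total_ms - k * min_part
    if free < 0:
        raise ValueError("partition infeasible")
    if k == 1:
        return np.array([total_ms], int)
    cuts = np.sort(rng.integers(0, free + 1, size=k - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]]))
    return parts + min_part


def generate_timeline(
    targets: TimelineTargets, seed: int = 0
) -> ProcedureTimeline:
    """Build a valid procedure timeline whose metrics equal ``targets``.

    Skin incision is at t = 0.  Idle is realized as out-of-incision
    intervals of a primary instrument; active time as a single contact
    interval containing the blunt and sharp dissection intervals; pickups
    cycle through distinct instruments to hit the requested change count.
    Event times land on the millisecond grid, so the round trip through
    metric computation is exact.  Invalid (internally inconsistent)
    targets raise ``ValueError``.
    """
    targets.validate()
    rng = np.random.default_rng(seed)
    end_ms = int(round(targets.end_time * 1000))
    idle_ms = int(round(targets.idle_time * 1000))
    active_ms = int(round(targets.resolved_active * 1000))
    blunt_ms = int(round(targets.blunt_time * 1000))
    sharp_ms = int(round(targets.sharp_time * 1000))

    ev: list[Event] = [Event(0.0, "milestone", "skin_incision")]
    if targets.completed:
        ev.append(Event(end_ms / 1000.0, "milestone", "vessel_loop_passed"))
    if targets.time_to_pectoralis_minor is not None:
        ev.append(
            Event(targets.time_to_pectoralis_minor, "milestone", "pectoralis_minor_divided")
        )

    # idle: alternating in/out of the primary instrument
    if idle_ms > 0:
        free = end_ms - idle_ms
        k = 1 if free < 10_000 or idle_ms < 3 else int(rng.integers(1, 4))
        idle_parts = _random_partition_ms(idle_ms, k, rng, min_part=1)
        gaps = _random_partition_ms(free, k + 1, rng, min_part=1)
        ev.append(Event(0.0, "instrument_in", "forceps"))
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            ev.append(Event(pos / 1000.0, "instrument_out", "forceps"))
            pos += int(idle_parts[i])
            ev.append(Event(pos / 1000.0, "instrument_in", "forceps"))

    # active: one contact interval containing both dissection intervals
    if active_ms > 0:
        c0 = int(rng.integers(0, end_ms - active_ms + 1))
        ev.append(Event(c0 / 1000.0, "contact_start", "hands"))
        ev.append(Event((c0 + active_ms) / 1000.0, "contact_end", "hands"))
        slack = active_ms - blunt_ms - sharp_ms
        s1, s2, _ = _random_partition_ms(slack, 3, rng) if slack > 0 else (0, 0, 0)
        pos = c0 + int(s1)
        if blunt_ms > 0:
            ev.append(Event(pos / 1000.0, "dissection_start", "blunt"))
            ev.append(Event((pos + blunt_ms) / 1000.0, "dissection_end", "blunt"))
        pos += blunt_ms + int(s2)
        if sharp_ms > 0:
            ev.append(Event(pos / 1000.0, "dissection_start", "sharp"))
            ev.append(Event((pos + sharp_ms) / 1000.0, "dissection_end", "sharp"))

    # pickups: n_changes + 1 pickups cycling through distinct instruments
    n_pick = targets.instrument_changes + 1
    times = np.sort(rng.integers(0, end_ms + 1, size=n_pick))
    for i, t_ms in enumerate(times):
        ev.append(
            Event(int(t_ms) / 1000.0, "instrument_pickup",
                  _INSTRUMENT_CYCLE[i % len(_INSTRUMENT_CYCLE)])
        )

    return ProcedureTimeline(ev, time_limit=targets.time_limit)
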