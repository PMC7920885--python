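"""Synthetic motion, rendering, and timeline generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from handmotion.colors import ColorSpec, rgb_frame_to_hsv
from handmotion.synthetic import (
    MotionProfile,
    SyntheticScene,
    TimelineTargets,
    generate_timeline,
    generate_trajectory,
    render_video,
)
from handmotion.timeline import compute_metrics
from handmotion.tracking import read_frames, track_video

from conftest import random_timeline_targets

SMALL_SCENE = SyntheticScene(frame_size=(160, 120), blob_radius=8)


def short_profile(**kw):
    base = dict(duration=1.0, frame_rate=50.0, idle_fraction=0.0, seed=1)
    base.update(kw)
    return MotionProfile(**base)


def test_deterministic_limit_is_straight_constant_velocity():
    p = short_profile(jitter_sd=0.0, direction_change_rate=0.0, base_speed=100.0,
                      duration=0.2)
    tr = generate_trajectory(p, SMALL_SCENE)["dominant"]
    steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
    np.testing.assert_allclose(steps, 2.0, atol=1e-9)  # 100 px/s at 50 fps


def test_positions_stay_inside_frame_bounds():
    p = short_profile(jitter_sd=25.0, base_speed=200.0, duration=30.0, seed=9)
    for tr in generate_trajectory(p, SMALL_SCENE).values():
        w, h = SMALL_SCENE.frame_size
        assert (tr.x >= 0).all() and (tr.x <= w - 1).all()
        assert (tr.y >= 0).all() and (tr.y <= h - 1).all()


def test_idle_fraction_is_met():
    p = short_profile(idle_fraction=0.5, duration=100.0, seed=7)
    tr = generate_trajectory(p, SMALL_SCENE)["dominant"]
    out_s = (~tr.in_frame).sum() / p.frame_rate
    assert abs(out_s - 50.0) <= 5.0  # exact by construction, well within +-5 s


def test_same_seed_gives_identical_tracks():
    p = short_profile(seed=13, idle_fraction=0.3, duration=5.0)
    a = generate_trajectory(p, SMALL_SCENE)
    b = generate_trajectory(p, SMALL_SCENE)
    for hand in a:
        np.testing.assert_array_equal(a[hand].x, b[hand].x)
        np.testing.assert_array_equal(a[hand].in_frame, b[hand].in_frame)
    c = generate_trajectory(short_profile(seed=14, idle_fraction=0.3, duration=5.0),
                            SMALL_SCENE)
    assert not np.array_equal(a["dominant"].x, c["dominant"].x)


def test_invalid_profile_parameters_rejected():
    for kw in (
        dict(idle_fraction=1.5),
        dict(jitter_sd=-1.0),
        dict(frame_rate=0.0),
        dict(duration=-5.0),
        dict(base_speed=-1.0),
    ):
        with pytest.raises(ValueError):
            short_profile(**kw)


def test_render_and_reacquire_ground_truth(tmp_path):
    """Tracker recovers rendered blob centers within 2 px of the sidecar."""
    p = short_profile(duration=0.2, seed=3)  # 10 frames
    tracks = generate_trajectory(p, SMALL_SCENE)
    video = tmp_path / "clip.tif"
    render_video(tracks, SMALL_SCENE, video)
    assert video.with_suffix(".csv").exists()
    n_frames = sum(1 for _ in read_frames(video))
    assert n_frames == 10
    dom, nondom = track_video(video, SMALL_SCENE.glove_specs, p.frame_rate)
    for det, truth in ((dom, tracks["dominant"]), (nondom, tracks["nondominant"])):
        assert det.valid.all()
        err = np.hypot(det.x - truth.x, det.y - truth.y)
        assert err.max() <= 2.0


def test_out_of_frame_hand_leaves_no_glove_pixels(tmp_path):
    p = short_profile(duration=0.2, seed=3)
    tracks = generate_trajectory(p, SMALL_SCENE)
    tracks["dominant"].in_frame[3:6] = False
    video = tmp_path / "gap.tif"
    render_video(tracks, SMALL_SCENE, video)
    green = SMALL_SCENE.glove_specs[0]
    for i, frame in enumerate(read_frames(video)):
        n_green = green.mask(rgb_frame_to_hsv(frame)).sum()
        assert (n_green == 0) == (3 <= i <= 5)
    dom, _ = track_video(video, SMALL_SCENE.glove_specs, p.frame_rate)
    assert dom.gaps == [(3, 5)]


def test_distractor_blobs_do_not_perturb_tracking(tmp_path):
    p = short_profile(duration=0.4, seed=5)
    tracks = generate_trajectory(p, SMALL_SCENE)
    plain = tmp_path / "plain.tif"
    busy = tmp_path / "busy.tif"
    render_video(tracks, SMALL_SCENE, plain)
    render_video(tracks, SMALL_SCENE.with_distractors(), busy)
    a = track_video(plain, SMALL_SCENE.glove_specs, p.frame_rate)
    b = track_video(busy, SMALL_SCENE.glove_specs, p.frame_rate)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.x, tb.x)
        np.testing.assert_array_equal(ta.y, tb.y)
        np.testing.assert_array_equal(ta.valid, tb.valid)


def test_scene_rejects_inseparable_colors():
    with pytest.raises(ValueError, match="separable|overlap"):
        SyntheticScene(distractor_rgbs=((30, 200, 70),))  # the glove green itself
    near_green = ColorSpec("near", hue_range=(100.0, 170.0))
    with pytest.raises(ValueError, match="overlap"):
        SyntheticScene(glove_specs=(SMALL_SCENE.glove_specs[0], near_green))


def test_unwritable_video_path_raises(tmp_path):
    p = short_profile(duration=0.1, seed=2)
    tracks = generate_trajectory(p, SMALL_SCENE)
    with pytest.raises(OSError):
        render_video(tracks, SMALL_SCENE, tmp_path / "no_such_dir" / "x.tif")


# --- timeline generation ---------------------------------------------------


def test_requested_metrics_are_reproduced_exactly():
    targets = TimelineTargets(
        total_time=100.0, idle_time=15.0, instrument_changes=3,
        blunt_time=10.0, sharp_time=20.0,
    )
    m = compute_metrics(generate_timeline(targets, seed=0))
    assert (m.total_time, m.idle_time, m.active_time, m.instrument_changes) == (
        100.0, 15.0, 85.0, 3,
    )


def test_inconsistent_targets_rejected():
    with pytest.raises(ValueError):
        generate_timeline(TimelineTargets(total_time=100.0, idle_time=150.0), seed=0)
    with pytest.raises(ValueError):
        generate_timeline(
            TimelineTargets(total_time=100.0, idle_time=0.0, active_time=50.0,
                            blunt_time=40.0, sharp_time=30.0),
            seed=0,
        )


def test_same_seed_gives_identical_timeline():
    targets = TimelineTargets.for_skill("resident")
    a = generate_timeline(targets, seed=4)
    b = generate_timeline(targets, seed=4)
    assert [(e.time, e.kind, e.detail) for e in a.events] == [
        (e.time, e.kind, e.detail) for e in b.events
    ]


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60)
def test_metrics_roundtrip_on_random_valid_targets(seed):
    """compute_metrics(generate_timeline(m)) == m exactly, censored cases
    included."""
    rng = np.random.default_rng(seed)
    t = random_timeline_targets(rng)
    tl = generate_timeline(t, seed=int(rng.integers(0, 2**31)))
    m = compute_metrics(tl)
    assert m.completed == t.completed
    assert m.total_time == (t.total_time if t.completed else t.time_limit)
    assert m.idle_time == t.idle_time
    assert m.active_time == t.resolved_active
    assert m.instrument_changes == t.instrument_changes
    assert m.blunt_time == t.blunt_time
    assert m.sharp_time == t.sharp_time
    assert m.time_to_pectoralis_minor == t.time_to_pectoralis_minor


@pytest.mark.parametrize("level", ["expert", "resident", "novice"])
def test_skill_presets_are_valid_and_contrast(level):
    t = TimelineTargets.for_skill(level)
    t.validate()
    m = compute_metrics(generate_timeline(t, seed=1))
    assert m.total_time == t.total_time
    p = MotionProfile.for_skill(level)
    assert p.skill_level == level
    e, r, n = (MotionProfile.for_skill(l).jitter_sd
               for l in ("expert", "resident", "novice"))
    assert e < r < n
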