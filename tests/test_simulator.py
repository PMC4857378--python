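"""Turntable acquisition geometry: projection, rotation, frame
selection, foreshortening and the benefit of multi-frame averaging."""

import math

import numpy as np
import pytest

from posturekit import (
    CalibrationModel,
    ProjectionDomainError,
    TurntableScene,
    fit_calibration,
    generate_rectangle_fixture,
    measure_frame,
    point_distance,
    project_point,
    select_frames,
    simulate_rotation,
    summary_stats,
)
from posturekit.protocol import RECTANGLE_PROTOCOL


def scene(**kwargs):
    defaults = dict(
        landmarks3d={"axis": (0.0, 100.0, 0.0)},
        camera_distance=300.0,
        focal_px=300.0,
        image_size=(2048, 1536),
    )
    defaults.update(kwargs)
    return TurntableScene(**defaults)


def test_axis_point_projects_to_principal_column():
    sc = scene()
    cx, cy = sc.principal_point
    for angle in (0, 37.5, 90, 180, 271):
        u, v = project_point(sc, (0.0, 0.0, 0.0), angle)
        assert (u, v) == pytest.approx((cx, cy), abs=1e-9)


def test_projection_periodic_in_angle():
    sc = scene()
    p = (7.0, 40.0, 3.0)
    assert project_point(sc, p, 0.0) == pytest.approx(project_point(sc, p, 360.0), abs=1e-9)


def test_supplementary_angles_mirror_about_principal_line():
    """Closed-form pinhole oracle: for a point in the frontal plane of
    the axis, angles a and 180-a give mirrored u at identical v."""
    sc = scene()
    cx, _ = sc.principal_point
    x, y = 9.0, 55.0
    for a in (10.0, 33.0, 61.0):
        u1, v1 = project_point(sc, (x, y, 0.0), a)
        u2, v2 = project_point(sc, (x, y, 0.0), 180.0 - a)
        assert u2 - cx == pytest.approx(-(u1 - cx), abs=1e-9)
        assert v2 == pytest.approx(v1, abs=1e-9)
        # independent closed-form evaluation
        th = math.radians(a)
        depth = sc.camera_distance + x * math.sin(th)
        assert u1 == pytest.approx(cx + sc.focal_px * x * math.cos(th) / depth, abs=1e-9)


def test_point_behind_pinhole_rejected():
    sc = scene()
    with pytest.raises(ProjectionDomainError):
        project_point(sc, (0.0, 0.0, sc.camera_distance + 1.0), 0.0)


def test_frame_count_from_platform_speed_and_frame_rate():
    """0.7 rpm at 30 Hz: one revolution spans floor(30*60/0.7) = 2571 frames."""
    frames = simulate_rotation(scene(), n_revolutions=1)
    assert len(frames) == 2571
    assert frames[0].rotation_angle == 0.0
    assert all(0 <= f.rotation_angle < 360 for f in frames)


def test_axis_landmark_fixed_without_noise():
    frames = simulate_rotation(scene(noise_sd_px=0.0), 1)
    positions = {f.landmarks["axis"] for f in frames if "axis" in f.landmarks}
    assert len(positions) == 1


def test_simulation_seeding_contract():
    a = simulate_rotation(scene(noise_sd_px=1.0, seed=42), 1)
    b = simulate_rotation(scene(noise_sd_px=1.0, seed=42), 1)
    c = simulate_rotation(scene(noise_sd_px=1.0, seed=43), 1)
    assert [f.landmarks for f in a] == [f.landmarks for f in b]
    assert [f.landmarks for f in a] != [f.landmarks for f in c]


def test_far_side_landmarks_dropped():
    sc = scene(landmarks3d={"back": (0.0, 100.0, -10.0)})
    front = simulate_rotation(sc, 1)[0]  # angle 0: point behind the axis plane
    assert "back" not in front.landmarks
    u, v = project_point(sc, (0.0, 100.0, -10.0), 180.0)
    assert np.isfinite([u, v]).all()  # visible once rotated to the front


class _Frame:
    def __init__(self, idx, angle):
        self.frame_index = idx
        self.rotation_angle = angle


def test_select_frames_nearest_first_with_tie_break():
    frames = [_Frame(0, 88.0), _Frame(1, 90.0), _Frame(2, 92.0)]
    sel = select_frames(frames, target_angle=90.0, tolerance=2.0, max_frames=26)
    assert [f.rotation_angle for f in sel] == [90.0, 88.0, 92.0]
    assert not sel.empty_warning


def test_select_frames_empty_selection_warns_not_raises():
    frames = [_Frame(0, 92.0)]
    sel = select_frames(frames, target_angle=90.0, tolerance=0.5, max_frames=26)
    assert len(sel) == 0 and sel.empty_warning
    with pytest.raises(ValueError):
        select_frames(frames, 90.0, tolerance=0.0)


def test_select_frames_wraps_circularly():
    frames = [_Frame(0, 359.0), _Frame(1, 1.0), _Frame(2, 180.0)]
    sel = select_frames(frames, target_angle=0.0, tolerance=2.0, max_frames=26)
    assert {f.frame_index for f in sel} == {0, 1}


def test_full_revolution_yields_default_26_frame_window():
    frames = simulate_rotation(scene(), 1)
    sel = select_frames(frames, target_angle=90.0, tolerance=5.0, max_frames=26)
    assert len(sel) == 26


def _measure_fixture(fix):
    model = fit_calibration(fix.calibration_marks)
    measured = [measure_frame(f, model, RECTANGLE_PROTOCOL) for f in fix.frames]
    return (
        [m.values["width"] for m in measured],
        [m.values["height"] for m in measured],
        model,
    )


def test_noise_free_rectangle_recovered_exactly():
    fix = generate_rectangle_fixture(noise_sd_px=0.0, n_frames=5)
    widths, heights, model = _measure_fixture(fix)
    assert widths == pytest.approx([25.0] * 5, abs=1e-9)
    assert heights == pytest.approx([15.0] * 5, abs=1e-9)
    # default magnification is 1 px/cm, so identity calibration agrees
    identity = CalibrationModel.identity()
    m = measure_frame(fix.frames[0], identity, RECTANGLE_PROTOCOL)
    assert m.values["width"] == pytest.approx(25.0, abs=1e-9)
    assert m.values["height"] == pytest.approx(15.0, abs=1e-9)


def test_rectangle_fixture_seeding_contract():
    a = generate_rectangle_fixture(noise_sd_px=0.5, seed=9)
    b = generate_rectangle_fixture(noise_sd_px=0.5, seed=9)
    c = generate_rectangle_fixture(noise_sd_px=0.5, seed=10)
    assert a == b and a != c


def test_noisy_rectangle_mean_within_three_standard_errors():
    """0.2 px jitter at 1 px/cm magnification, n=30: sampling theory
    bounds the summary mean's distance from truth."""
    fix = generate_rectangle_fixture(noise_sd_px=0.2, n_frames=30, seed=3)
    widths, heights, _ = _measure_fixture(fix)
    for values, truth in ((widths, 25.0), (heights, 15.0)):
        s = summary_stats(values, rounding="exact")
        se = s.sd / math.sqrt(s.n)
        assert abs(s.mean - truth) <= 3 * se


def _chord_length_at_offset(phi_deg, distance, focal):
    """Projected length of a 20 cm antero-posterior chord at angular
    offset phi from profile (platform angle 90 + phi)."""
    sc = scene(camera_distance=distance, focal_px=focal,
               landmarks3d={"a": (0.0, 50.0, -10.0), "b": (0.0, 50.0, 10.0)})
    pa = project_point(sc, (0.0, 50.0, -10.0), 90.0 + phi_deg)
    pb = project_point(sc, (0.0, 50.0, 10.0), 90.0 + phi_deg)
    return point_distance(pa, pb) * distance / focal  # back to cm at unit mag


def test_orthographic_limit_matches_cosine_foreshortening():
    """Far camera: a chord of length L at offset phi projects to
    L|cos phi| within 0.1 %."""
    for phi in (0.0, 15.0, 30.0, 60.0, 85.0):
        projected = _chord_length_at_offset(phi, distance=1e6, focal=1e6)
        expected = 20.0 * abs(math.cos(math.radians(phi)))
        assert projected == pytest.approx(expected, rel=1e-3, abs=1e-6)


def test_projected_chord_non_increasing_away_from_profile():
    phis = np.linspace(0.0, 90.0, 31)
    lengths = [_chord_length_at_offset(p, distance=300.0, focal=300.0) for p in phis]
    assert all(l1 >= l2 - 1e-12 for l1, l2 in zip(lengths, lengths[1:]))


def test_window_average_beats_worst_single_frame():
    """Noise off: the mean over a symmetric window around profile is at
    least as accurate as the worst single frame in the window."""
    delta = 6.0
    phis = np.linspace(-delta, delta, 13)
    lengths = np.array([_chord_length_at_offset(p, 300.0, 300.0) for p in phis])
    errors = np.abs(lengths - 20.0)
    assert abs(lengths.mean() - 20.0) <= errors.max()


def test_window_mean_less_variable_than_single_frames():
    """Noise on: across seeded replicates the window mean is less
    variable than single-frame measurements."""
    means, singles = [], []
    for seed in range(12):
        fix = generate_rectangle_fixture(noise_sd_px=1.0, n_frames=26, seed=seed)
        widths, _, _ = _measure_fixture(fix)
        means.append(np.mean(widths))
        singles.extend(widths)
    assert np.std(means) < np.std(singles)
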