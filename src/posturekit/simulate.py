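"""Synthetic rotating-platform acquisition geometry.

Models the measurement set-up: a set of 3D body landmarks fixed to a
platform that rotates at constant angular speed, filmed by a stationary
pinhole camera.  The simulator produces the same per-frame landmark
tables that manual annotation of real video yields, which makes it the
test bed for two claims about the instrument:

* a chord that is not in the plane perpendicular to the optical axis is
  foreshortened (parallax error) — at angular offset φ from profile a
  chord of length L projects to ≈ L·|cos φ|;
* averaging measurements over a window of frames around the target
  orientation reduces that error compared with trusting a single frame.

Geometry conventions
--------------------
Body frame: origin on the rotation axis at the platform surface, Y up,
+Z toward the camera when the platform angle is 0° (subject facing the
camera); angles increase counter-clockwise seen from above, so 90° is
the right profile.  The camera pinhole sits on the +Z axis at
``camera_distance`` cm from the rotation axis, optical axis horizontal
through the origin, principal point at the image centre, square pixels.
Annotation error is modelled as isotropic Gaussian jitter in pixel
space.  Landmarks whose rotated position falls behind the axis-parallel
image plane (rotated Z < 0) are treated as self-occluded and dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .calibration import CalibrationMark, PixelPoint, WorldPoint
from .errors import ProjectionDomainError
from .metrics import LandmarkFrame

__all__ = [
    "TurntableScene",
    "SimulatedFrame",
    "project_point",
    "simulate_rotation",
    "select_frames",
    "FrameSelection",
    "generate_rectangle_fixture",
    "RectangleFixture",
]


@dataclass(frozen=True)
class TurntableScene:
    """Scene description: landmarks, platform, camera and noise.

    Defaults mirror the physical instrument: platform speed 0.7 rpm and
    a 30 Hz camera with a 2048x1536 px sensor.
    """

    landmarks3d: Mapping[str, tuple[float, float, float]]
    platform_rpm: float = 0.7
    camera_distance: float = 300.0  # axis-to-pinhole, cm
    focal_px: float = 300.0
    image_size: tuple[int, int] = (2048, 1536)
    frame_rate: float = 30.0
    noise_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform_rpm <= 0:
            raise ValueError("platform_rpm must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        pts = {k: tuple(float(c) for c in v) for k, v in self.landmarks3d.items()}
        extent = max((math.hypot(x, z) for x, _, z in pts.values()), default=0.0)
        if self.camera_distance <= extent:
            raise ValueError(
                "camera_distance must exceed the radial extent of the landmarks "
                f"({self.camera_distance} <= {extent})"
            )
        object.__setattr__(self, "landmarks3d", pts)

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.image_size[0] / 2.0, self.image_size[1] / 2.0)

    @property
    def degrees_per_frame(self) -> float:
        return self.platform_rpm * 360.0 / 60.0 / self.frame_rate


@dataclass(frozen=True)
class SimulatedFrame:
    """One synthetic video frame: platform angle + visible landmark pixels."""

    frame_index: int
    time_s: float
    rotation_angle: float  # degrees in [0, 360)
    landmarks: Mapping[str, PixelPoint]

    def as_landmark_frame(self) -> LandmarkFrame:
        return LandmarkFrame(
            frame_index=self.frame_index,
            landmarks=dict(self.landmarks),
            rotation_angle=self.rotation_angle,
        )


def _rotate_y(point3d: Sequence[float], angle_deg: float) -> np.ndarray:
    x, y, z = (float(c) for c in point3d)
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    # counter-clockwise seen from above (looking down -Y)
    return np.array([c * x + s * z, y, -s * x + c * z])


def project_point(
    scene: TurntableScene, point3d: Sequence[float], angle: float
) -> PixelPoint:
    """Pinhole projection of a body-frame point at a platform angle.

    Rotates the point about the vertical axis, translates into the
    camera frame and projects; no noise.  Raises
    :class:`ProjectionDomainError` if the rotated point lies at or
    behind the pinhole plane.
    """
    xr, yr, zr = _rotate_y(point3d, angle)
    depth = scene.camera_distance - zr
    if depth <= 0:
        raise ProjectionDomainError("point lies at or behind the pinhole plane")
    cx, cy = scene.principal_point
    u = cx + scene.focal_px * xr / depth
    v = cy - scene.focal_px * yr / depth  # image v grows downward
    return PixelPoint(u, v)


def _visible(point3d: Sequence[float], angle: float) -> bool:
    # self-occlusion stand-in: drop landmarks behind the axis plane
    return _rotate_y(point3d, angle)[2] >= 0


def simulate_rotation(scene: TurntableScene, n_revolutions: int = 1) -> list[SimulatedFrame]:
    """Simulate filming ``n_revolutions`` full platform turns.

    Frames are taken at 1/frame_rate intervals while the platform angle
    advances at ``platform_rpm``; the frame count is
    floor(frame_rate * 60 / rpm * n_revolutions).  Seeded Gaussian
    pixel jitter of SD ``noise_sd_px`` is added per landmark; landmarks
    on the far side of the platform are dropped.
    """
    if n_revolutions < 1:
        raise ValueError("n_revolutions must be >= 1")
    n_frames = int(math.floor(scene.frame_rate * 60.0 / scene.platform_rpm * n_revolutions))
    rng = np.random.default_rng(scene.seed)
    names = sorted(scene.landmarks3d)
    frames = []
    for i in range(n_frames):
        t = i / scene.frame_rate
        angle = (scene.degrees_per_frame * i) % 360.0
        landmarks = {}
        for name in names:
            p3 = scene.landmarks3d[name]
            if not _visible(p3, angle):
                continue
            u, v = project_point(scene, p3, angle)
            if scene.noise_sd_px > 0:
                du, dv = rng.normal(0.0, scene.noise_sd_px, size=2)
                u, v = u + du, v + dv
            landmarks[name] = PixelPoint(u, v)
        frames.append(SimulatedFrame(i, t, angle, landmarks))
    return frames


@dataclass(frozen=True)
class FrameSelection:
    """Frames near the target platform angle, nearest-first."""

    frames: tuple
    target_angle: float
    tolerance: float
    empty_warning: bool

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def select_frames(
    frames: Sequence,
    target_angle: float,
    tolerance: float,
    max_frames: int = 26,
) -> FrameSelection:
    """Pick up to ``max_frames`` frames closest to ``target_angle``.

    Eligible frames are those whose platform angle lies within
    ``tolerance`` degrees (circular distance) of the target; they are
    returned nearest-first, ties broken by earlier frame index.  An
    empty selection sets ``empty_warning`` rather than raising.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    eligible = [
        f for f in frames
        if f.rotation_angle is not None
        and _circular_distance(f.rotation_angle, target_angle) <= tolerance
    ]
    eligible.sort(key=lambda f: (_circular_distance(f.rotation_angle, target_angle), f.frame_index))
    chosen = tuple(eligible[:max_frames])
    return FrameSelection(
        frames=chosen,
        target_angle=target_angle,
        tolerance=tolerance,
        empty_warning=not chosen,
    )


@dataclass(frozen=True)
class RectangleFixture:
    """Synthetic frames of a flat rectangle facing the camera, plus truth."""

    frames: tuple[LandmarkFrame, ...]
    calibration_marks: tuple[CalibrationMark, ...]
    true_width: float
    true_height: float
    corner_names: tuple[str, str, str, str] = (
        "corner_bl", "corner_br", "corner_tr", "corner_tl",
    )


def generate_rectangle_fixture(
    width: float = 25.0,
    height: float = 15.0,
    distance: float = 300.0,
    noise_sd_px: float = 0.0,
    n_frames: int = 30,
    seed: int = 0,
    *,
    base_height: float = 150.0,
    focal_px: Optional[float] = None,
) -> RectangleFixture:
    """Frames of a known-dimension rectangle for criterion-validity tests.

    A planar ``width`` x ``height`` cm rectangle is centred on the
    rotation axis facing the camera (its plane parallel to the image
    plane), with its lower edge ``base_height`` cm above the platform
    base, and imaged ``n_frames`` times with seeded Gaussian annotation
    jitter of ``noise_sd_px``.  Because the rectangle is parallel to the
    image plane its projection is an exact uniform scaling, so with
    noise 0 any correct calibration recovers the true dimensions
    exactly.  The default ``focal_px = distance`` makes that scaling
    1 px/cm (identity calibration applies).

    Returns the frames, calibration marks taken from the rectangle's
    noise-free corner projections paired with their true world
    coordinates (playing the role of the calibration support in the
    object plane), and the ground-truth dimensions.
    """
    if width <= 0 or height <= 0:
        raise ValueError("rectangle dimensions must be positive")
    scene = TurntableScene(
        landmarks3d={},
        camera_distance=distance,
        focal_px=distance if focal_px is None else focal_px,
        noise_sd_px=noise_sd_px,
        seed=seed,
    )
    world = {
        "corner_bl": (-width / 2.0, base_height),
        "corner_br": (width / 2.0, base_height),
        "corner_tr": (width / 2.0, base_height + height),
        "corner_tl": (-width / 2.0, base_height + height),
    }
    exact = {
        name: project_point(scene, (x, y, 0.0), 0.0) for name, (x, y) in world.items()
    }
    marks = tuple(
        CalibrationMark(exact[name], WorldPoint(*world[name])) for name in sorted(world)
    )
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        landmarks = {}
        for name in sorted(exact):
            u, v = exact[name]
            if noise_sd_px > 0:
                du, dv = rng.normal(0.0, noise_sd_px, size=2)
                u, v = u + du, v + dv
            landmarks[name] = PixelPoint(u, v)
        frames.append(LandmarkFrame(frame_index=i, landmarks=landmarks, rotation_angle=0.0))
    return RectangleFixture(
        frames=tuple(frames),
        calibration_marks=marks,
        true_width=float(width),
        true_height=float(height),
    )
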