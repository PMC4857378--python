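"""Posture measurements from calibrated landmark coordinates.

The central quantity is the curvature index used for sagittal spinal
curves (cervical, thoracic, lumbar).  For a curve bounded by its upper
and lower limit vertebrae, let ``x`` (the "straight") be the chord
length between the limit vertebrae and ``f`` (the "arrow") the
perpendicular distance from the curve's apex to that chord.  Then

    CI = (f / x) * 100

is dimensionless and invariant under rigid motion and uniform scaling,
so it can be compared across subjects and camera set-ups.  Plain
Euclidean distances, interior angles and polygon areas of landmark
configurations are also provided, all in calibrated centimetre space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .calibration import CalibrationModel, PixelPoint, WorldPoint
from .errors import (
    DegenerateAngleError,
    DegenerateChordError,
    InsufficientDataError,
    ProtocolError,
)

__all__ = [
    "LandmarkFrame",
    "CurvatureRegion",
    "CurvatureResult",
    "curvature_index",
    "point_distance",
    "segment_angle",
    "polygon_area",
    "measure_frame",
    "MeasuredFrame",
]

_TINY = 1e-300


@dataclass(frozen=True)
class LandmarkFrame:
    """Named landmark pixel coordinates annotated on one video frame."""

    frame_index: int
    landmarks: Mapping[str, PixelPoint]
    rotation_angle: Optional[float] = None  # platform angle, degrees

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(
            self,
            "landmarks",
            {str(k): PixelPoint(*map(float, v)) for k, v in self.landmarks.items()},
        )


class CurvatureRegion(NamedTuple):
    """A spinal curve defined by three landmark names."""

    label: str
    upper_limit: str
    apex: str
    lower_limit: str


@dataclass(frozen=True)
class CurvatureResult:
    """Chord length x (cm), arrow f (cm) and curvature index CI = 100 f/x."""

    x: float
    f: float
    ci: float


def _pt(p: Sequence[float]) -> np.ndarray:
    return np.asarray(p, dtype=float).reshape(2)


def point_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two planar points (cm)."""
    return float(np.hypot(*(_pt(a) - _pt(b))))


def curvature_index(
    upper: Sequence[float],
    apex: Sequence[float],
    lower: Sequence[float],
    *,
    clamp_to_segment: bool = False,
) -> CurvatureResult:
    """Curvature index of a spinal curve from its three defining points.

    ``x`` is the chord between the limit vertebrae ``upper`` and
    ``lower``; ``f`` is the perpendicular distance from ``apex`` to the
    infinite line through them (the standard "arrow" of flexicurve-style
    indices).  With ``clamp_to_segment=True``, ``f`` is instead the
    distance from the apex to the closed chord segment, which differs
    only when the apex projects outside the chord.

    Raises
    ------
    DegenerateChordError
        If the limit points coincide.
    """
    u, a, l = _pt(upper), _pt(apex), _pt(lower)
    chord = l - u
    x = float(np.hypot(*chord))
    if x <= _TINY:
        raise DegenerateChordError("limit vertebrae coincide; chord length is zero")
    if clamp_to_segment:
        t = float(np.dot(a - u, chord)) / (x * x)
        t = min(1.0, max(0.0, t))
        f = float(np.hypot(*(a - (u + t * chord))))
    else:
        # twice the triangle area over the base
        d = a - u
        f = abs(float(chord[0] * d[1] - chord[1] * d[0])) / x
    return CurvatureResult(x=x, f=f, ci=100.0 * f / x)


def segment_angle(a: Sequence[float], vertex: Sequence[float], c: Sequence[float]) -> float:
    """Unsigned interior angle at ``vertex`` between rays to ``a`` and ``c``.

    Returned in degrees, in [0, 180].
    """
    ra = _pt(a) - _pt(vertex)
    rc = _pt(c) - _pt(vertex)
    na, nc = np.hypot(*ra), np.hypot(*rc)
    if na <= _TINY or nc <= _TINY:
        raise DegenerateAngleError("angle ray has zero length")
    cosang = float(np.dot(ra, rc) / (na * nc))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Absolute shoelace area of the closed polygon (cm^2)."""
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InsufficientDataError("a polygon needs at least 3 planar vertices")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


@dataclass(frozen=True)
class MeasuredFrame:
    """Metric values computed on one frame; metrics whose landmarks were
    absent from the frame are listed in ``missing`` rather than silently
    dropped."""

    frame_index: int
    values: Mapping[str, float]
    missing: tuple[str, ...] = ()
    rotation_angle: Optional[float] = None


def measure_frame(frame: LandmarkFrame, model: CalibrationModel, protocol) -> MeasuredFrame:
    """Evaluate every metric of ``protocol`` on one annotated frame.

    Landmarks are first mapped to world centimetres through ``model``;
    each configured metric (curvature index per region, distance pair,
    angle triple, area polygon) is then evaluated.  A metric whose
    landmarks are missing from this frame is flagged, not omitted.

    ``protocol`` is a :class:`posturekit.protocol.ProtocolConfig` (or any
    object exposing ``regions``, ``distances``, ``angles``, ``areas``).
    """
    world = {name: model.pixel_to_world(p) for name, p in frame.landmarks.items()}
    values: dict[str, float] = {}
    missing: list[str] = []

    def resolve(metric: str, names: Sequence[str]) -> Optional[list[WorldPoint]]:
        absent = [n for n in names if n not in world]
        if absent:
            missing.append(metric)
            return None
        return [world[n] for n in names]

    for region in protocol.regions:
        pts = resolve(region.label, (region.upper_limit, region.apex, region.lower_limit))
        if pts is not None:
            upper, apex, lower = pts
            values[region.label] = curvature_index(upper, apex, lower).ci
    for dist in protocol.distances:
        pts = resolve(dist.name, (dist.a, dist.b))
        if pts is not None:
            values[dist.name] = point_distance(*pts)
    for ang in protocol.angles:
        pts = resolve(ang.name, (ang.a, ang.vertex, ang.c))
        if pts is not None:
            a, vertex, c = pts
            values[ang.name] = segment_angle(a, vertex, c)
    for area in protocol.areas:
        pts = resolve(area.name, area.vertices)
        if pts is not None:
            values[area.name] = polygon_area(pts)

    return MeasuredFrame(
        frame_index=frame.frame_index,
        values=values,
        missing=tuple(missing),
        rotation_angle=frame.rotation_angle,
    )
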