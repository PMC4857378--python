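"""Measurement-protocol configuration.

A protocol names the metrics to evaluate on each frame (curvature
regions, distance pairs, angle triples, area polygons), how frames are
selected from the rotation (target platform angle, angular tolerance,
maximum number of frames to average — default 26), the rounding policy
for reported statistics and the stabilization rule.  Protocols are
plain data and round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import yaml

from .errors import ProtocolError
from .metrics import CurvatureRegion

__all__ = [
    "DistanceMetric",
    "AngleMetric",
    "AreaMetric",
    "FrameSelectionConfig",
    "StabilizationConfig",
    "ProtocolConfig",
    "RECTANGLE_PROTOCOL",
]


class DistanceMetric(NamedTuple):
    name: str
    a: str
    b: str


class AngleMetric(NamedTuple):
    name: str
    a: str
    vertex: str
    c: str


class AreaMetric(NamedTuple):
    name: str
    vertices: tuple[str, ...]


@dataclass(frozen=True)
class FrameSelectionConfig:
    """Window of platform angles from which frames are averaged."""

    target_angle: float = 90.0  # degrees; 90 = right profile
    tolerance: float = 5.0  # degrees
    max_frames: int = 26

    def __post_init__(self) -> None:
        if self.max_frames < 2:
            raise ProtocolError("frame_selection.max_frames must be >= 2")
        if self.tolerance <= 0:
            raise ProtocolError("frame_selection.tolerance must be > 0")


@dataclass(frozen=True)
class StabilizationConfig:
    rule: str = "terminal-plateau"
    decimals: int = 2
    epsilon: float = 0.05
    window: int = 5

    def __post_init__(self) -> None:
        if self.rule not in ("terminal-plateau", "delta-threshold"):
            raise ProtocolError(f"unknown stabilization rule {self.rule!r}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Full description of what to measure and how to aggregate it."""

    regions: tuple[CurvatureRegion, ...] = ()
    distances: tuple[DistanceMetric, ...] = ()
    angles: tuple[AngleMetric, ...] = ()
    areas: tuple[AreaMetric, ...] = ()
    frame_selection: FrameSelectionConfig = field(default_factory=FrameSelectionConfig)
    rounding: str = "printed-table"
    stabilization: StabilizationConfig = field(default_factory=StabilizationConfig)

    def __post_init__(self) -> None:
        if self.rounding not in ("printed-table", "exact"):
            raise ProtocolError(f"unknown rounding policy {self.rounding!r}")
        names = [m.name if hasattr(m, "name") else m.label for m in self.metrics]
        if len(names) != len(set(names)):
            raise ProtocolError("metric names must be unique within a protocol")
        for region in self.regions:
            if len({region.upper_limit, region.apex, region.lower_limit}) != 3:
                raise ProtocolError(
                    f"region {region.label!r} must use three distinct landmarks"
                )

    @property
    def metrics(self) -> tuple:
        return self.regions + self.distances + self.angles + self.areas

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(m.name if hasattr(m, "name") else m.label for m in self.metrics)

    def referenced_landmarks(self) -> set[str]:
        names: set[str] = set()
        for r in self.regions:
            names.update((r.upper_limit, r.apex, r.lower_limit))
        for d in self.distances:
            names.update((d.a, d.b))
        for a in self.angles:
            names.update((a.a, a.vertex, a.c))
        for ar in self.areas:
            names.update(ar.vertices)
        return names

    def check_landmarks(self, known: Sequence[str]) -> None:
        """Raise ProtocolError naming any referenced landmark absent from ``known``."""
        unknown = sorted(self.referenced_landmarks() - set(known))
        if unknown:
            raise ProtocolError(f"protocol references unknown landmarks: {', '.join(unknown)}")

    # -- serialisation -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metrics": {
                "regions": [
                    {"label": r.label, "upper_limit": r.upper_limit,
                     "apex": r.apex, "lower_limit": r.lower_limit}
                    for r in self.regions
                ],
                "distances": [{"name": d.name, "a": d.a, "b": d.b} for d in self.distances],
                "angles": [
                    {"name": a.name, "a": a.a, "vertex": a.vertex, "c": a.c}
                    for a in self.angles
                ],
                "areas": [
                    {"name": a.name, "vertices": list(a.vertices)} for a in self.areas
                ],
            },
            "frame_selection": {
                "target_angle": self.frame_selection.target_angle,
                "tolerance": self.frame_selection.tolerance,
                "max_frames": self.frame_selection.max_frames,
            },
            "rounding": self.rounding,
            "stabilization": {
                "rule": self.stabilization.rule,
                "decimals": self.stabilization.decimals,
                "epsilon": self.stabilization.epsilon,
                "window": self.stabilization.window,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        metrics = d.get("metrics", {})
        sel = d.get("frame_selection", {})
        stab = d.get("stabilization", {})
        return cls(
            regions=tuple(
                CurvatureRegion(r["label"], r["upper_limit"], r["apex"], r["lower_limit"])
                for r in metrics.get("regions", [])
            ),
            distances=tuple(
                DistanceMetric(m["name"], m["a"], m["b"])
                for m in metrics.get("distances", [])
            ),
            angles=tuple(
                AngleMetric(m["name"], m["a"], m["vertex"], m["c"])
                for m in metrics.get("angles", [])
            ),
            areas=tuple(
                AreaMetric(m["name"], tuple(m["vertices"]))
                for m in metrics.get("areas", [])
            ),
            frame_selection=FrameSelectionConfig(**sel),
            rounding=d.get("rounding", "printed-table"),
            stabilization=StabilizationConfig(**stab),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolConfig":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ProtocolError(f"could not parse protocol config: {exc}") from exc
        if not isinstance(data, dict):
            raise ProtocolError("protocol config must be a mapping")
        try:
            return cls.from_dict(data)
        except (KeyError, TypeError) as exc:
            raise ProtocolError(f"malformed protocol config: {exc}") from exc


#: protocol measuring the width and height of the four-corner rectangle
#: produced by the criterion-validity fixture and simulator
RECTANGLE_PROTOCOL = ProtocolConfig(
    distances=(
        DistanceMetric("width", "corner_bl", "corner_br"),
        DistanceMetric("height", "corner_bl", "corner_tl"),
    ),
    frame_selection=FrameSelectionConfig(target_angle=0.0, tolerance=5.0, max_frames=30),
)
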