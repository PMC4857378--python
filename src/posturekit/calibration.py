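"""Pixel-to-centimetre calibration from marked fiducial points.

A calibration support of known dimensions stands in the subject's plane;
the operator marks points on it whose real-world coordinates (in cm) are
known.  From these pixel/world correspondences we fit an invertible 2D
map so that every pixel in the image receives an (x, y) coordinate in
centimetres.

Two transform families are supported:

* ``affine`` (6 parameters, default with >= 3 non-collinear marks) —
  tolerates camera tilt, non-square pixels and independent axis scales;
* ``similarity`` (rotation + isotropic scale + translation, 4
  parameters) — the only family identifiable from exactly 2 marks.

Pixel convention: origin at the top-left corner, ``u`` grows rightward,
``v`` grows downward, continuous 0-based coordinates.  World ``y`` grows
upward; the fitted linear block absorbs the vertical flip (note that the
similarity family is orientation-preserving and cannot absorb a flip —
use affine with >= 3 marks when the world axes are mirrored).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import DegenerateConfigurationError, InsufficientDataError

__all__ = [
    "PixelPoint",
    "WorldPoint",
    "CalibrationMark",
    "CalibrationModel",
    "fit_calibration",
    "pixel_to_world",
    "world_to_pixel",
]

#: ratio of smallest to largest singular value below which marked pixel
#: points are declared collinear / coincident (scale-free test)
_COLLINEAR_RTOL = 1e-8


class PixelPoint(NamedTuple):
    """Continuous image coordinate, origin top-left, v downward (px)."""

    u: float
    v: float


class WorldPoint(NamedTuple):
    """Real-world planar coordinate, y upward (cm)."""

    x: float
    y: float


class CalibrationMark(NamedTuple):
    """One pixel/world correspondence marked on the calibration support."""

    pixel: PixelPoint
    world: WorldPoint


@dataclass(frozen=True)
class CalibrationModel:
    """Invertible planar map ``world = linear @ pixel + offset``.

    Attributes
    ----------
    linear : (2, 2) ndarray
        Coefficient block in cm/px.
    offset : (2,) ndarray
        Translation in cm.
    residual_rms : float
        Root-mean-square world-space fit residual in cm.
    n_marks : int
        Number of correspondences used in the fit.
    family : str
        Transform family that was fitted (``"affine"`` or ``"similarity"``).
    """

    linear: np.ndarray
    offset: np.ndarray
    residual_rms: float
    n_marks: int
    family: str = "affine"
    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        offset = np.asarray(self.offset, dtype=float).reshape(2)
        if not (np.isfinite(linear).all() and np.isfinite(offset).all()):
            raise DegenerateConfigurationError("calibration coefficients must be finite")
        det = float(np.linalg.det(linear))
        scale = float(np.abs(linear).max()) or 1.0
        if abs(det) <= (_COLLINEAR_RTOL * scale) ** 2:
            raise DegenerateConfigurationError(
                f"calibration linear block is singular (det={det:g}); "
                "the model is not invertible"
            )
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "_inverse", np.linalg.inv(linear))

    # -- application -------------------------------------------------

    def pixel_to_world(self, p: Sequence[float]) -> WorldPoint:
        u, v = float(p[0]), float(p[1])
        x, y = self.linear @ (u, v) + self.offset
        return WorldPoint(float(x), float(y))

    def world_to_pixel(self, w: Sequence[float]) -> PixelPoint:
        x, y = float(w[0]), float(w[1])
        u, v = self._inverse @ (np.array((x, y)) - self.offset)
        return PixelPoint(float(u), float(v))

    def transform(self, pixels: np.ndarray) -> np.ndarray:
        """Vectorised pixel→world for an (n, 2) array."""
        pixels = np.asarray(pixels, dtype=float)
        return pixels @ self.linear.T + self.offset

    # -- serialisation -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "offset": self.offset.tolist(),
            "residual_rms_cm": self.residual_rms,
            "n_marks": self.n_marks,
            "family": self.family,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            linear=np.asarray(d["linear"], dtype=float),
            offset=np.asarray(d["offset"], dtype=float),
            residual_rms=float(d["residual_rms_cm"]),
            n_marks=int(d["n_marks"]),
            family=str(d.get("family", "affine")),
        )

    @classmethod
    def from_json(cls, s: str) -> "CalibrationModel":
        return cls.from_dict(json.loads(s))

    @classmethod
    def identity(cls) -> "CalibrationModel":
        """Unit model: 1 px == 1 cm, no rotation or offset."""
        return cls(np.eye(2), np.zeros(2), 0.0, 0, family="similarity")


def _as_mark(m) -> CalibrationMark:
    if isinstance(m, CalibrationMark):
        return m
    pixel, world = m
    return CalibrationMark(PixelPoint(*map(float, pixel)), WorldPoint(*map(float, world)))


def fit_calibration(
    marks: Iterable[CalibrationMark | tuple],
    family: str | None = None,
) -> CalibrationModel:
    """Fit a pixel→world map by least squares on world-space residuals.

    Parameters
    ----------
    marks
        Pixel/world correspondences (``CalibrationMark`` or
        ``((u, v), (x, y))`` pairs).
    family
        ``"affine"``, ``"similarity"``, or None for automatic choice
        (affine with >= 3 marks, similarity with exactly 2).

    Raises
    ------
    InsufficientDataError
        Fewer than 2 marks, or affine requested with fewer than 3.
    DegenerateConfigurationError
        Duplicate pixel points, or 3+ collinear pixel points for an
        affine fit.
    """
    marks = [_as_mark(m) for m in marks]
    n = len(marks)
    if n < 2:
        raise InsufficientDataError(f"calibration needs at least 2 marks, got {n}")
    pix = np.array([m.pixel for m in marks], dtype=float)
    wor = np.array([m.world for m in marks], dtype=float)
    if not (np.isfinite(pix).all() and np.isfinite(wor).all()):
        raise DegenerateConfigurationError("calibration marks must be finite")

    if family is None:
        family = "affine" if n >= 3 else "similarity"
    if family not in ("affine", "similarity"):
        raise ValueError(f"unknown transform family {family!r}")

    _check_pixel_geometry(pix, family)

    if family == "affine":
        if n < 3:
            raise InsufficientDataError("an affine fit needs at least 3 marks")
        linear, offset = _fit_affine(pix, wor)
    else:
        linear, offset = _fit_similarity(pix, wor)

    residuals = pix @ linear.T + offset - wor
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return CalibrationModel(linear, offset, rms, n, family=family)


def _check_pixel_geometry(pix: np.ndarray, family: str) -> None:
    # pairwise duplicates: degenerate for every family
    diffs = pix[:, None, :] - pix[None, :, :]
    dist = np.sqrt(np.sum(diffs**2, axis=-1))
    span = float(dist.max()) or 1.0
    iu = np.triu_indices(len(pix), k=1)
    if np.any(dist[iu] <= _COLLINEAR_RTOL * span):
        raise DegenerateConfigurationError("duplicate pixel points among calibration marks")
    if family == "affine" and len(pix) >= 3:
        centered = pix - pix.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] < _COLLINEAR_RTOL * sv[0]:
            raise DegenerateConfigurationError(
                "pixel marks are collinear; an affine fit is not identifiable "
                "(add a mark off the line or force family='similarity')"
            )


def _fit_affine(pix: np.ndarray, wor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orthogonal-decomposition least squares on [u v 1] -> (x, y)
    design = np.column_stack([pix, np.ones(len(pix))])
    coef, *_ = np.linalg.lstsq(design, wor, rcond=None)
    linear = coef[:2].T
    offset = coef[2]
    return linear, offset


def _fit_similarity(pix: np.ndarray, wor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orientation-preserving similarity as a complex regression w = a z + b
    z = pix[:, 0] + 1j * pix[:, 1]
    w = wor[:, 0] + 1j * wor[:, 1]
    zc = z - z.mean()
    wc = w - w.mean()
    denom = float(np.sum(np.abs(zc) ** 2))
    a = complex(np.sum(np.conj(zc) * wc) / denom)
    b = complex(w.mean() - a * z.mean())
    linear = np.array([[a.real, -a.imag], [a.imag, a.real]])
    offset = np.array([b.real, b.imag])
    return linear, offset


def pixel_to_world(model: CalibrationModel, p: Sequence[float]) -> WorldPoint:
    """Map an image pixel to its real-world (x, y) coordinate in cm."""
    return model.pixel_to_world(p)


def world_to_pixel(model: CalibrationModel, w: Sequence[float]) -> PixelPoint:
    """Exact inverse of :func:`pixel_to_world`."""
    return model.world_to_pixel(w)
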