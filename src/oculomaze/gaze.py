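"""Landmark-based gaze estimation.

Converts per-frame eye landmark coordinates into pupil centers and
normalized gaze ratios.  The pupil is located as the center of the minimum
enclosing circle of the four iris landmarks (the face-mesh model exposes
iris points 469-472 for the right eye and 474-477 for the left).  Gaze is
then expressed as two dimensionless ratios per eye:

* **lateral ratio** — horizontal pupil offset from the external (outer)
  eye corner, normalized by the eye width (outer-to-inner corner
  distance); lies in [0, 1], 0.5 for a centered pupil.
* **anteroposterior ratio** — negated vertical pupil offset from the
  upper lid landmark, normalized by the eye height; lies in [-1, 0],
  -0.5 for a centered pupil.

Coordinates follow the landmark-stream convention: normalized image
coordinates with y increasing downward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Point2D",
    "EyeLandmarks",
    "LandmarkFrame",
    "Circle",
    "GazeSample",
    "TherapyMode",
    "DegenerateGeometryError",
    "min_enclosing_circle",
    "pupil_center",
    "lateral_ratio",
    "anteroposterior_ratio",
    "gaze_sample",
]


class DegenerateGeometryError(ValueError):
    """Raised when eye geometry has zero width or height."""


class TherapyMode(Enum):
    """Therapy session modality.

    String values match the session-table labels: binocular (``Bin``),
    left-eye monocular (``Mon-Izq``, healthy right eye covered) and
    right-eye monocular (``Mon-Der``).
    """

    BIN = "Bin"
    MON_IZQ = "Mon-Izq"
    MON_DER = "Mon-Der"

    @classmethod
    def parse(cls, label: str) -> "TherapyMode":
        """Parse a mode label; accepts the canonical Spanish-origin labels
        and common English aliases (case-insensitive)."""
        aliases = {
            "bin": cls.BIN,
            "binocular": cls.BIN,
            "mon-izq": cls.MON_IZQ,
            "mon-left": cls.MON_IZQ,
            "monocular-left": cls.MON_IZQ,
            "left": cls.MON_IZQ,
            "mon-der": cls.MON_DER,
            "mon-right": cls.MON_DER,
            "monocular-right": cls.MON_DER,
            "right": cls.MON_DER,
        }
        try:
            return aliases[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown therapy mode: {label!r}") from None


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate: ({self.x}, {self.y})")


@dataclass(frozen=True)
class Circle:
    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("negative radius")

    def contains(self, p: Point2D, tol: float = 1e-9) -> bool:
        return math.hypot(p.x - self.center.x, p.y - self.center.y) <= self.radius + tol


@dataclass(frozen=True)
class EyeLandmarks:
    """Eight landmarks of one eye: four iris points plus four contour
    points (outer/inner corners, upper/lower lids)."""

    iris: tuple[Point2D, Point2D, Point2D, Point2D]
    outer_corner: Point2D
    inner_corner: Point2D
    upper: Point2D
    lower: Point2D

    def __post_init__(self) -> None:
        if len(self.iris) != 4:
            raise ValueError(f"iris must have exactly 4 points, got {len(self.iris)}")
        object.__setattr__(self, "iris", tuple(self.iris))
        if self.outer_corner.x == self.inner_corner.x:
            raise DegenerateGeometryError("zero eye width (outer.x == inner.x)")
        if not self.upper.y < self.lower.y:
            raise DegenerateGeometryError(
                "upper lid must be above lower lid (y-down convention)"
            )

    @property
    def width(self) -> float:
        return abs(self.inner_corner.x - self.outer_corner.x)

    @property
    def height(self) -> float:
        return abs(self.lower.y - self.upper.y)


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped frame of binocular eye landmarks, optionally with a
    distance-sensor reading in millimetres."""

    timestamp_ms: int
    left: EyeLandmarks
    right: EyeLandmarks
    distance_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.distance_mm is not None and self.distance_mm < 0:
            raise ValueError("distance_mm must be >= 0")


@dataclass(frozen=True)
class GazeSample:
    """Per-timestamp gaze ratios.

    Lateral ratios live in [0, 1], anteroposterior in [-1, 0].  In
    binocular mode the ``*_bin`` fields hold the pointwise arithmetic
    means of the two eyes; in monocular modes only the therapy eye's
    fields are populated and the rest are ``None``.
    """

    timestamp_ms: int
    ratio_right: Optional[float] = None
    ratio_V_right: Optional[float] = None
    ratio_left: Optional[float] = None
    ratio_V_left: Optional[float] = None
    ratio_bin: Optional[float] = None
    ratio_V_bin: Optional[float] = None


# ---------------------------------------------------------------------------
# Minimum enclosing circle (Welzl's algorithm)
# ---------------------------------------------------------------------------

def _circle_from_2(a: Point2D, b: Point2D) -> Circle:
    cx, cy = (a.x + b.x) / 2.0, (a.y + b.y) / 2.0
    r = math.hypot(a.x - b.x, a.y - b.y) / 2.0
    return Circle(Point2D(cx, cy), r)


def _circle_from_3(a: Point2D, b: Point2D, c: Point2D) -> Optional[Circle]:
    # Circumcircle; None for (near-)collinear triples.
    ax, ay, bx, by, cx, cy = a.x, a.y, b.x, b.y, c.x, c.y
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    center = Point2D(ux, uy)
    return Circle(center, math.hypot(ax - ux, ay - uy))


def _trivial_circle(boundary: list[Point2D]) -> Circle:
    if not boundary:
        return Circle(Point2D(0.0, 0.0), 0.0)
    if len(boundary) == 1:
        return Circle(boundary[0], 0.0)
    if len(boundary) == 2:
        return _circle_from_2(boundary[0], boundary[1])
    c = _circle_from_3(boundary[0], boundary[1], boundary[2])
    if c is not None:
        return c
    # Collinear boundary: fall back to widest pair.
    best = None
    for i in range(3):
        for j in range(i + 1, 3):
            cand = _circle_from_2(boundary[i], boundary[j])
            if all(cand.contains(p) for p in boundary):
                if best is None or cand.radius < best.radius:
                    best = cand
    assert best is not None
    return best


def _welzl(points: list[Point2D], boundary: list[Point2D]) -> Circle:
    if not points or len(boundary) == 3:
        return _trivial_circle(boundary)
    p = points[-1]
    c = _welzl(points[:-1], boundary)
    if c.contains(p):
        return c
    return _welzl(points[:-1], boundary + [p])


def min_enclosing_circle(points: Sequence[Point2D]) -> Circle:
    """Smallest circle containing all ``points``.

    Welzl's recursive algorithm; inputs here are tiny (at most 16
    landmarks) so no randomized restructuring is needed.

    Raises
    ------
    ValueError
        If ``points`` is empty or larger than 16.
    """
    pts = [p if isinstance(p, Point2D) else Point2D(*p) for p in points]
    if not pts:
        raise ValueError("min_enclosing_circle requires at least one point")
    if len(pts) > 16:
        raise ValueError("min_enclosing_circle supports at most 16 points")
    # De-duplicate: repeated points add nothing and inflate recursion.
    seen: dict[tuple[float, float], Point2D] = {}
    for p in pts:
        seen.setdefault((p.x, p.y), p)
    return _welzl(list(seen.values()), [])


def pupil_center(eye: EyeLandmarks) -> Point2D:
    """Pupil position: center of the minimum circle enclosing the four
    iris landmarks."""
    return min_enclosing_circle(eye.iris).center


# ---------------------------------------------------------------------------
# Gaze ratios
# ---------------------------------------------------------------------------

def lateral_ratio(pupil: Point2D, eye: EyeLandmarks) -> float:
    """Horizontal pupil offset from the outer corner over the eye width.

    Clamped to [0, 1]; a pupil marginally outside the contour box (landmark
    jitter) is clamped with a warning rather than rejected.
    """
    width = eye.width
    if width == 0:
        raise DegenerateGeometryError("zero eye width")
    r = abs(pupil.x - eye.outer_corner.x) / width
    if r > 1.0:
        logger.warning("lateral ratio %.4f outside [0,1]; clamped", r)
        r = 1.0
    return r


def anteroposterior_ratio(pupil: Point2D, eye: EyeLandmarks) -> float:
    """Negated vertical pupil offset from the upper lid over the eye height.

    Returns a value in [-1, 0]: 0 at the upper lid, -1 at the lower lid,
    -0.5 at mid-height.  Clamped with a warning on overshoot.
    """
    height = eye.height
    if height == 0:
        raise DegenerateGeometryError("zero eye height")
    r = -(abs(pupil.y - eye.upper.y) / height)
    if r < -1.0:
        logger.warning("anteroposterior ratio %.4f outside [-1,0]; clamped", r)
        r = -1.0
    return r


def gaze_sample(frame: LandmarkFrame, mode: TherapyMode = TherapyMode.BIN) -> GazeSample:
    """Compute the gaze ratios of one landmark frame.

    In binocular mode all six fields are filled, the ``*_bin`` fields
    being pointwise means of the two eyes.  In a monocular mode only the
    therapy eye is evaluated (the occluded eye yields no signal) and the
    binocular fields stay ``None``.
    """
    def eye_ratios(eye: EyeLandmarks) -> tuple[float, float]:
        p = pupil_center(eye)
        return lateral_ratio(p, eye), anteroposterior_ratio(p, eye)

    if mode is TherapyMode.BIN:
        lat_r, ap_r = eye_ratios(frame.right)
        lat_l, ap_l = eye_ratios(frame.left)
        return GazeSample(
            timestamp_ms=frame.timestamp_ms,
            ratio_right=lat_r,
            ratio_V_right=ap_r,
            ratio_left=lat_l,
            ratio_V_left=ap_l,
            ratio_bin=(lat_r + lat_l) / 2.0,
            ratio_V_bin=(ap_r + ap_l) / 2.0,
        )
    if mode is TherapyMode.MON_IZQ:
        lat_l, ap_l = eye_ratios(frame.left)
        return GazeSample(timestamp_ms=frame.timestamp_ms,
                          ratio_left=lat_l, ratio_V_left=ap_l)
    if mode is TherapyMode.MON_DER:
        lat_r, ap_r = eye_ratios(frame.right)
        return GazeSample(timestamp_ms=frame.timestamp_ms,
                          ratio_right=lat_r, ratio_V_right=ap_r)
    raise ValueError(f"unsupported mode: {mode}")
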