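"""Exact 2D primitives: points, directed lines, closed contour polygons.

All templating measurements reduce to a handful of operations on these
types: projecting points onto an axis, finding the extreme contour point
along an axis, erecting perpendiculars, intersecting an infinite line with
a polygon, and measuring/applying angles.  Everything works in calibrated
millimetres with y increasing proximally (toward the patient's head).

Conventions
-----------
* ``DirectedLine`` directions are unit vectors; mechanical axes are always
  oriented *distally* (hip toward knee, knee toward ankle).
* Ties (co-extreme vertices, coincident crossings) break toward the lowest
  vertex index / most negative position along the line, so results are
  deterministic.
* Extremes of a linear functional over a polygon occur at vertices, so
  furthest-point searches scan vertices only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import TemplatingError

__all__ = [
    "Point2",
    "DirectedLine",
    "ContourPolygon",
    "project_offsets",
    "furthest_point_along",
    "perpendicular_line_at",
    "line_polygon_intersections",
    "angle_between_deg",
    "rotate_line_about",
]

_DEDUP_TOL = 1e-6  # mm, crossing deduplication
_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class Point2:
    """A point in the calibrated millimetre frame."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise TemplatingError(f"non-finite point ({self.x}, {self.y})")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Point2":
        return Point2(float(a[0]), float(a[1]))

    def distance_to(self, other: "Point2") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def _as_points_array(points: Iterable[Point2] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return points.reshape(-1, 2).astype(float)
    return np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class DirectedLine:
    """An infinite line with an anchor point and a unit direction."""

    origin: Point2
    direction: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = float(np.hypot(d[0], d[1]))
        if n == 0.0 or not np.isfinite(n):
            raise TemplatingError("line direction must be a nonzero vector")
        if abs(n - 1.0) > _UNIT_TOL:
            d = d / n
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))

    @staticmethod
    def through(p: Point2, q: Point2) -> "DirectedLine":
        """Line through two points, directed p -> q."""
        from .errors import DegenerateAxisError

        dx, dy = q.x - p.x, q.y - p.y
        if math.hypot(dx, dy) < 1e-12:
            raise DegenerateAxisError(
                f"cannot build axis through coincident points {p} and {q}")
        return DirectedLine(p, (dx, dy))

    @property
    def dir_array(self) -> np.ndarray:
        return np.array(self.direction, dtype=float)

    @property
    def normal(self) -> np.ndarray:
        """Left-hand unit normal (direction rotated +90 degrees)."""
        dx, dy = self.direction
        return np.array([-dy, dx], dtype=float)

    def point_at(self, t: float) -> Point2:
        return Point2(self.origin.x + t * self.direction[0],
                      self.origin.y + t * self.direction[1])

    def signed_distance(self, p: Point2) -> float:
        """Signed perpendicular distance of ``p`` (positive on normal side)."""
        return float(np.dot(p.array - self.origin.array, self.normal))

    def offset_of(self, p: Point2) -> float:
        """Signed position of the foot of ``p`` along the line."""
        return float(np.dot(p.array - self.origin.array, self.dir_array))

    def intersect_line(self, other: "DirectedLine") -> Point2:
        """Intersection point of two non-parallel infinite lines."""
        d1, d2 = self.dir_array, other.dir_array
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(denom) < 1e-12:
            raise TemplatingError("lines are parallel; no unique intersection")
        delta = other.origin.array - self.origin.array
        t = (delta[0] * d2[1] - delta[1] * d2[0]) / denom
        return self.point_at(float(t))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourPolygon:
    """A simple closed polygon (bone silhouette), vertices in CCW order.

    Vertices are stored as an ``(n, 2)`` float array; the closing edge from
    the last vertex back to the first is implicit.  Orientation is
    normalized to counter-clockwise on construction.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(v) < 3:
            raise TemplatingError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise TemplatingError("contour has non-finite vertices")
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def points(self) -> list[Point2]:
        return [Point2(float(x), float(y)) for x, y in self.vertices]

    def area(self) -> float:
        return abs(_signed_area(self.vertices))

    def is_simple(self) -> bool:
        """Non-self-intersection check (delegates to shapely)."""
        from shapely.geometry import Polygon

        return Polygon(self.vertices).is_valid

    def validate(self) -> "ContourPolygon":
        if not self.is_simple():
            raise TemplatingError("contour polygon is self-intersecting")
        return self

    def translated(self, dx: float, dy: float) -> "ContourPolygon":
        return ContourPolygon(self.vertices + np.array([dx, dy]))

    def transformed(self, matrix: np.ndarray, shift: np.ndarray) -> "ContourPolygon":
        return ContourPolygon(self.vertices @ np.asarray(matrix).T + np.asarray(shift))


# ---------------------------------------------------------------------------
# operations


def project_offsets(points: Iterable[Point2] | np.ndarray,
                    axis: DirectedLine) -> np.ndarray:
    """Signed offsets of each point along ``axis`` (order preserved)."""
    pts = _as_points_array(points)
    if len(pts) == 0:
        return np.empty(0)
    return (pts - axis.origin.array) @ axis.dir_array


def furthest_point_along(contour: ContourPolygon, axis: DirectedLine,
                         sense: int = +1) -> Point2:
    """Contour vertex with extreme signed offset along ``axis``.

    ``sense=+1`` takes the maximum offset, ``sense=-1`` the minimum; ties
    break toward the smallest vertex index.
    """
    offs = project_offsets(contour.vertices, axis)
    idx = int(np.argmax(offs)) if sense >= 0 else int(np.argmin(offs))
    return Point2.from_array(contour.vertices[idx])


def perpendicular_line_at(axis: DirectedLine, offset: float) -> DirectedLine:
    """Line perpendicular to ``axis`` through the point at signed ``offset``."""
    p = axis.point_at(offset)
    n = axis.normal
    return DirectedLine(p, (float(n[0]), float(n[1])))


def line_polygon_intersections(line: DirectedLine,
                               contour: ContourPolygon) -> list[Point2]:
    """All crossings of the infinite ``line`` with the polygon boundary.

    Returns points sorted by position along the line; crossings closer than
    1e-6 mm (vertex grazes) are deduplicated.  Edges collinear with the line
    contribute through their neighbouring edges' endpoint crossings.
    """
    v = contour.vertices
    a = v
    b = np.roll(v, -1, axis=0)
    e = b - a
    o = line.origin.array
    d = line.dir_array
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    ao = a - o
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]) / denom
        u = (ao[:, 0] * d[1] - ao[:, 1] * d[0]) / denom
    ok = (np.abs(denom) > 1e-15) & (u >= -1e-12) & (u <= 1.0 + 1e-12)
    ts = np.sort(t[ok])
    out: list[Point2] = []
    last_t = None
    for tv in ts:
        if last_t is not None and tv - last_t < _DEDUP_TOL:
            continue
        out.append(line.point_at(float(tv)))
        last_t = tv
    return out


def angle_between_deg(a: DirectedLine, b: DirectedLine) -> float:
    """Undirected acute angle between two lines, in degrees within [0, 90].

    Uses atan2 of |cross| / |dot|, which stays well-conditioned for nearly
    parallel and nearly perpendicular lines (acos loses ~1e-6 deg there).
    """
    ax, ay = a.direction
    bx, by = b.direction
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(abs(cross), abs(dot)))


def rotate_line_about(line: DirectedLine, pivot: Point2,
                      angle_deg: float) -> DirectedLine:
    """Rotate a line's direction by ``angle_deg`` (CCW), re-anchored at ``pivot``.

    The returned line always passes through the pivot; when the pivot lies
    on the input line (the only case the pipeline uses) this is the rigid
    rotation of the line about that point.
    """
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    dx, dy = line.direction
    return DirectedLine(pivot, (c * dx - s * dy, s * dx + c * dy))


def directed_angle_deg(a: DirectedLine, b: DirectedLine) -> float:
    """Signed CCW angle from direction ``a`` to direction ``b`` in (-180, 180]."""
    ax, ay = a.direction
    bx, by = b.direction
    return math.degrees(math.atan2(ax * by - ay * bx, ax * bx + ay * by))
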