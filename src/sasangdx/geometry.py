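"""Planar geometry primitives for landmark-based facial features.

Coordinates follow the image convention: x grows rightward, y grows
downward, units are pixels.  "Horizontal distance" is therefore |dx| and
"vertical distance" |dy|; the convention cancels in every ratio feature.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives coincident or collinear points
    that leave its result undefined."""


class Point2D(NamedTuple):
    x: float
    y: float

    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)


def _as_point(p) -> Point2D:
    q = Point2D(float(p[0]), float(p[1]))
    if not q.is_finite():
        raise ValueError(f"non-finite point {p!r}")
    return q


def point_distance(p, q, mode: str = "euclidean") -> float:
    """Distance between two points: ``euclidean``, ``horizontal`` (|dx|)
    or ``vertical`` (|dy|)."""
    p, q = _as_point(p), _as_point(q)
    dx, dy = q.x - p.x, q.y - p.y
    if mode == "euclidean":
        return math.hypot(dx, dy)
    if mode == "horizontal":
        return abs(dx)
    if mode == "vertical":
        return abs(dy)
    raise ValueError(f"unknown distance mode {mode!r}")


def angle_two_point(p, q, signed: bool = False, mirrored: bool = False) -> float:
    """Angle in degrees between the line through ``p``,``q`` and the
    horizontal axis.

    Unsigned (default): the acute angle in [0, 90].  ``signed``: the
    angle in (-90, 90] of the line oriented so dx >= 0; positive when
    the segment descends rightward in image coordinates.  ``mirrored``:
    the segment is first reflected left-right (x -> -x), which negates
    the signed angle and leaves the unsigned one unchanged.  These
    conventions are configurable because the source feature vocabulary
    leaves the suffixed variants undefined.
    """
    p, q = _as_point(p), _as_point(q)
    dx, dy = q.x - p.x, q.y - p.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("two-point angle of coincident points")
    if mirrored:
        dx = -dx
    # orient the line direction so dx >= 0 (lines, not rays)
    if dx < 0 or (dx == 0 and dy < 0):
        dx, dy = -dx, -dy
    ang = math.degrees(math.atan2(dy, dx))  # in (-90, 90]
    if dx == 0:
        ang = 90.0
    return ang if signed else abs(ang)


def angle_three_point(a, b, c) -> float:
    """Interior angle in degrees at vertex ``b`` of the path a-b-c, in
    [0, 180]."""
    a, b, c = _as_point(a), _as_point(b), _as_point(c)
    ux, uy = a.x - b.x, a.y - b.y
    vx, vy = c.x - b.x, c.y - b.y
    nu, nv = math.hypot(ux, uy), math.hypot(vx, vy)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("three-point angle with zero-length arm")
    cosang = (ux * vx + uy * vy) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def polygon_area(points: Iterable) -> float:
    """Shoelace area magnitude of a polygon given by its ordered
    vertices (pixels squared)."""
    pts = [_as_point(p) for p in points]
    if len(pts) < 3:
        raise ValueError(f"polygon needs >= 3 points, got {len(pts)}")
    s = 0.0
    for i in range(len(pts)):
        p, q = pts[i], pts[(i + 1) % len(pts)]
        s += p.x * q.y - q.x * p.y
    return abs(s) / 2.0


def point_line_distance(p, a, b) -> float:
    """Perpendicular distance from ``p`` to the infinite line through
    ``a`` and ``b``."""
    p, a, b = _as_point(p), _as_point(a), _as_point(b)
    dx, dy = b.x - a.x, b.y - a.y
    n = math.hypot(dx, dy)
    if n == 0.0:
        raise DegenerateGeometryError("point-line distance with coincident line points")
    return abs(dx * (p.y - a.y) - dy * (p.x - a.x)) / n
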