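"""Polygon primitives for region annotation and calibration.

Operator annotations are simple (non-self-intersecting) pixel-space
polygons.  Areas follow the shoelace convention (orientation
irrelevant); point membership is boundary-inclusive, so a detection
centre lying exactly on a region edge counts as inside the region.
Backed by shapely.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import InvalidGeometryError

__all__ = ["as_polygon", "polygon_area", "point_in_polygon", "points_in_polygon"]

PointLike = Sequence[float]


def as_polygon(vertices: Sequence[PointLike]) -> Polygon:
    """Validate a vertex list and return a shapely Polygon.

    Raises :class:`InvalidGeometryError` for fewer than three vertices,
    self-intersection, or zero area.
    """
    pts = np.asarray(vertices, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidGeometryError(
            f"polygon needs >= 3 (x, y) vertices, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise InvalidGeometryError("polygon has non-finite vertices")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise InvalidGeometryError("polygon is self-intersecting or degenerate")
    if poly.area <= 0.0:
        raise InvalidGeometryError("polygon has zero area")
    return poly


def polygon_area(vertices: Sequence[PointLike]) -> float:
    """Absolute (shoelace) area of a simple polygon in px^2."""
    return float(as_polygon(vertices).area)


def point_in_polygon(point: PointLike, vertices: Sequence[PointLike]) -> bool:
    """Boundary-inclusive point-in-polygon test for a simple polygon."""
    poly = as_polygon(vertices)
    return bool(poly.covers(Point(float(point[0]), float(point[1]))))


def points_in_polygon(points: np.ndarray, vertices: Sequence[PointLike]) -> np.ndarray:
    """Vectorised boundary-inclusive membership for an (N, 2) point array."""
    poly = prep(as_polygon(vertices))
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    return np.fromiter(
        (poly.covers(Point(x, y)) for x, y in pts), dtype=bool, count=len(pts)
    )
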