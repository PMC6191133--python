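"""Capped-area quantification from annotations plus cell detections.

The detector finds only uncapped cells; the operator outlines wide
regions of capped brood and capped honey (and the inner-frame
quadrilateral used for calibration).  The capped area of a region is
its gross polygon area minus one disc of the effective subtraction
radius per detected uncapped cell whose centre falls inside it:

    capped = max(0, polygon_area - n_inside * pi * r_eff**2)

Disc membership is decided by the centre alone (discs are not clipped
at region borders), which keeps the subtraction closed-form at the
cost of a small bias where uncapped cells straddle a region edge.
Physical areas come from the ratio of pixel areas to the inner-frame
quadrilateral of known physical size; the photograph is assumed
perpendicular to the lens, so no perspective rectification is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import CellDetectionSet
from .errors import InvalidAnnotationError, InvalidGeometryError
from .geometry import as_polygon, points_in_polygon, polygon_area

__all__ = [
    "CAPPED_LABELS",
    "FrameAnnotation",
    "RegionMeasurement",
    "FrameMeasurement",
    "count_cells_in_region",
    "capped_area",
    "scale_to_physical",
    "quantify_frame",
]

logger = logging.getLogger(__name__)

CAPPED_LABELS = frozenset({"capped_brood", "capped_honey"})

Point = tuple[float, float]


@dataclass(frozen=True)
class FrameAnnotation:
    """Operator annotation for one frame photograph.

    inner_corners: the four inner-frame corner points, ordered
    clockwise from top-left; regions: labelled capped polygons
    (labels restricted to capped_brood / capped_honey).
    """

    photo_id: str
    inner_corners: tuple[Point, Point, Point, Point]
    regions: tuple[tuple[str, tuple[Point, ...]], ...] = ()

    def __post_init__(self) -> None:
        corners = np.asarray(self.inner_corners, dtype=np.float64)
        if corners.shape != (4, 2):
            raise InvalidAnnotationError("inner_corners must be exactly 4 points")
        as_polygon(corners)  # simple quadrilateral with positive area
        for label, poly in self.regions:
            if label not in CAPPED_LABELS:
                raise InvalidAnnotationError(
                    f"unknown region label {label!r}; "
                    f"expected one of {sorted(CAPPED_LABELS)}"
                )
            as_polygon(poly)

    def polygons(self, label: str) -> list[tuple[Point, ...]]:
        return [poly for lab, poly in self.regions if lab == label]


@dataclass(frozen=True)
class RegionMeasurement:
    """Per-label quantification results for one photo."""

    gross_polygon_area_px2: float
    n_uncapped_inside: int
    subtracted_area_px2: float
    capped_area_px2: float
    capped_area_cm2: float
    capped_fraction_of_inner: float


@dataclass(frozen=True)
class FrameMeasurement:
    """All measured quantities for one frame photograph."""

    photo_id: str
    inner_area_px2: float
    inner_area_cm2: float
    per_label: dict[str, RegionMeasurement] = field(default_factory=dict)

    @property
    def total_capped_px2(self) -> float:
        return sum(m.capped_area_px2 for m in self.per_label.values())


def count_cells_in_region(
    detections: CellDetectionSet, polygon: Sequence[Point]
) -> int:
    """Number of detected centres inside a polygon (boundary inclusive).

    Membership is by centre only; discs are not clipped.
    """
    as_polygon(polygon)
    if len(detections) == 0:
        return 0
    return int(points_in_polygon(detections.centres, polygon).sum())


def capped_area(polygon: Sequence[Point], detections: CellDetectionSet) -> float:
    """Capped area (px^2) of one region polygon.

    Subtracts one effective-radius disc per detected centre inside the
    polygon, clamping at zero.  With fewer than two detections the
    effective radius is unavailable and nothing is subtracted.
    """
    gross = polygon_area(polygon)
    r = detections.effective_radius_px
    if r is None:
        return gross
    n = count_cells_in_region(detections, polygon)
    subtracted = n * np.pi * r * r
    net = gross - subtracted
    if net < 0:
        logger.warning(
            "subtracted disc area %.1f px^2 exceeds polygon area %.1f px^2; "
            "capped area clamped to 0",
            subtracted,
            gross,
        )
        return 0.0
    return float(net)


def scale_to_physical(
    area_px2: float,
    inner_corners: Sequence[Point],
    inner_frame_cm2: float,
) -> float:
    """Convert a pixel area to cm^2 via the inner-frame area ratio."""
    if area_px2 < 0:
        raise ValueError("area must be >= 0")
    if not inner_frame_cm2 > 0:
        raise ValueError("inner_frame_cm2 must be > 0")
    inner_px2 = polygon_area(inner_corners)
    if inner_px2 <= 0:
        raise InvalidGeometryError("degenerate inner quadrilateral")
    return float(area_px2) * float(inner_frame_cm2) / inner_px2


def quantify_frame(
    annotation: FrameAnnotation,
    detections: CellDetectionSet,
    inner_frame_cm2: float,
) -> FrameMeasurement:
    """Quantify capped brood and capped honey for one photograph.

    Multiple polygons sharing a label are summed (subtraction clamps
    per polygon).  Overlapping polygons of different labels are
    accepted but flagged with a warning, since their capped areas then
    double-count the overlap.
    """
    inner_px2 = polygon_area(annotation.inner_corners)
    inner_cm2 = float(inner_frame_cm2)

    polys = [(label, as_polygon(poly)) for label, poly in annotation.regions]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i][0] != polys[j][0] and polys[i][1].intersects(polys[j][1]):
                inter = polys[i][1].intersection(polys[j][1]).area
                if inter > 0:
                    warnings.warn(
                        f"photo {annotation.photo_id}: overlapping "
                        f"{polys[i][0]} and {polys[j][0]} polygons "
                        f"({inter:.1f} px^2 shared)",
                        stacklevel=2,
                    )

    per_label: dict[str, RegionMeasurement] = {}
    for label in sorted(CAPPED_LABELS):
        gross = 0.0
        n_inside = 0
        net = 0.0
        for poly in annotation.polygons(label):
            gross += polygon_area(poly)
            n_inside += count_cells_in_region(detections, poly)
            net += capped_area(poly, detections)
        per_label[label] = RegionMeasurement(
            gross_polygon_area_px2=gross,
            n_uncapped_inside=n_inside,
            subtracted_area_px2=gross - net,
            capped_area_px2=net,
            capped_area_cm2=scale_to_physical(
                net, annotation.inner_corners, inner_cm2
            ),
            capped_fraction_of_inner=net / inner_px2,
        )
        logger.info(
            "photo %s %s: gross=%.0f px2, n_uncapped=%d, capped=%.0f px2",
            annotation.photo_id,
            label,
            gross,
            n_inside,
            net,
        )

    return FrameMeasurement(
        photo_id=annotation.photo_id,
        inner_area_px2=inner_px2,
        inner_area_cm2=inner_cm2,
        per_label=per_label,
    )
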