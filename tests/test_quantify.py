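"""Capped-area quantification: subtraction arithmetic and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combquant import (
    CellDetectionSet,
    FrameAnnotation,
    InvalidAnnotationError,
    capped_area,
    count_cells_in_region,
    polygon_area,
    quantify_frame,
    scale_to_physical,
)

UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


def detections_at(centres, effective_radius=None, spacing=None):
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    return CellDetectionSet(
        centres=centres,
        detected_radii=np.full(len(centres), 6.0),
        accumulator_threshold_used=20,
        median_spacing_px=spacing,
        effective_radius_px=effective_radius,
    )


def square(x0, y0, side):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


class TestCountCellsInRegion:
    def test_no_detections(self):
        assert count_cells_in_region(detections_at([]), UNIT_SQUARE) == 0

    def test_centre_inside(self):
        det = detections_at([(0.5, 0.5)])
        assert count_cells_in_region(det, UNIT_SQUARE) == 1

    def test_membership_is_by_centre_only(self):
        # centre outside, disc would overlap: still not counted
        det = detections_at([(1.2, 0.5)], effective_radius=0.5)
        assert count_cells_in_region(det, UNIT_SQUARE) == 0

    def test_matches_per_point_membership(self):
        rng = np.random.default_rng(5)
        poly = square(10, 10, 50)
        pts = rng.uniform(0, 80, size=(500, 2))
        det = detections_at(pts)
        expected = int(
            np.sum((pts[:, 0] >= 10) & (pts[:, 0] <= 60)
                   & (pts[:, 1] >= 10) & (pts[:, 1] <= 60))
        )
        assert count_cells_in_region(det, poly) == expected


class TestCappedArea:
    def test_no_circles_returns_gross_area(self):
        poly = square(0, 0, 30)
        assert capped_area(poly, detections_at([])) == pytest.approx(900.0)

    def test_zero_detections_exact_to_1e9_relative(self):
        poly = [(0.0, 0.0), (123.4, 0.0), (123.4, 56.7), (0.0, 56.7)]
        assert capped_area(poly, detections_at([])) == pytest.approx(
            polygon_area(poly), rel=1e-9
        )

    def test_one_disc_subtracts_pi_r_squared(self):
        r = 3.0
        side = np.sqrt(2 * np.pi * r**2)  # polygon area = 2 pi r^2
        poly = square(0, 0, side)
        det = detections_at([(side / 2, side / 2)], effective_radius=r)
        assert capped_area(poly, det) == pytest.approx(np.pi * r**2, rel=1e-9)

    def test_over_subtraction_clamps_to_zero(self):
        poly = square(0, 0, 4)
        det = detections_at([(1, 1), (3, 1), (1, 3), (3, 3)], effective_radius=2.0)
        assert capped_area(poly, det) == 0.0

    def test_clamp_engages_exactly_at_area_balance(self):
        # n * pi * r^2 below, equal to, and above the polygon area
        r = 1.0
        disc = np.pi * r**2
        side = np.sqrt(2 * disc)
        poly = square(0, 0, side)
        inside = [(side / 2, side / 2), (side / 4, side / 4), (3 * side / 4, 3 * side / 4)]
        one = capped_area(poly, detections_at(inside[:1], effective_radius=r))
        two = capped_area(poly, detections_at(inside[:2], effective_radius=r))
        three = capped_area(poly, detections_at(inside, effective_radius=r))
        assert one == pytest.approx(disc, rel=1e-9)
        assert two == pytest.approx(0.0, abs=1e-9)
        assert three == 0.0

    def test_monotone_in_circle_count_and_radius(self):
        poly = square(0, 0, 100)
        pts = [(20, 20), (50, 50), (80, 80)]
        areas_by_n = [
            capped_area(poly, detections_at(pts[:n], effective_radius=5.0))
            for n in range(4)
        ]
        assert areas_by_n == sorted(areas_by_n, reverse=True)
        areas_by_r = [
            capped_area(poly, detections_at(pts, effective_radius=r))
            for r in (2.0, 5.0, 9.0)
        ]
        assert areas_by_r == sorted(areas_by_r, reverse=True)


class TestScaleToPhysical:
    def test_identity_case(self):
        corners = square(0, 0, 100)
        assert scale_to_physical(10000.0, corners, 880.0) == pytest.approx(880.0)

    def test_half_area(self):
        corners = square(0, 0, 100)
        assert scale_to_physical(5000.0, corners, 880.0) == pytest.approx(440.0)

    def test_zero(self):
        assert scale_to_physical(0.0, square(0, 0, 100), 880.0) == 0.0


class TestQuantifyFrame:
    def make_annotation(self, regions=()):
        return FrameAnnotation(
            photo_id="p1", inner_corners=tuple(square(0, 0, 200)), regions=regions
        )

    def test_no_regions(self):
        m = quantify_frame(self.make_annotation(), detections_at([]), 880.0)
        assert m.inner_area_px2 == pytest.approx(40000.0)
        assert m.inner_area_cm2 == 880.0
        assert all(r.capped_area_px2 == 0.0 for r in m.per_label.values())

    def test_region_without_detections_keeps_gross_area(self):
        ann = self.make_annotation(
            regions=(("capped_honey", tuple(square(10, 10, 50))),)
        )
        m = quantify_frame(ann, detections_at([]), 880.0)
        honey = m.per_label["capped_honey"]
        assert honey.capped_area_px2 == pytest.approx(2500.0)
        assert honey.capped_area_cm2 == pytest.approx(2500.0 / 40000.0 * 880.0)
        assert honey.capped_fraction_of_inner == pytest.approx(2500.0 / 40000.0)

    def test_same_label_polygons_are_summed(self):
        ann = self.make_annotation(
            regions=(
                ("capped_brood", tuple(square(0, 0, 20))),
                ("capped_brood", tuple(square(100, 100, 30))),
            )
        )
        m = quantify_frame(ann, detections_at([]), 880.0)
        assert m.per_label["capped_brood"].gross_polygon_area_px2 == pytest.approx(1300.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            self.make_annotation(regions=(("pollen", tuple(square(0, 0, 10))),))

    def test_overlapping_labels_flagged(self):
        ann = self.make_annotation(
            regions=(
                ("capped_brood", tuple(square(10, 10, 50))),
                ("capped_honey", tuple(square(30, 30, 50))),
            )
        )
        with pytest.warns(UserWarning, match="overlapping"):
            quantify_frame(ann, detections_at([]), 880.0)

    def test_translation_invariance(self):
        shift = np.array([37.0, -12.0])
        pts = [(30.0, 40.0), (60.0, 70.0)]
        region = square(20, 30, 60)
        ann_a = FrameAnnotation(
            "a", tuple(square(0, 0, 200)), (("capped_brood", tuple(region)),)
        )
        ann_b = FrameAnnotation(
            "b",
            tuple(tuple(np.asarray(p) + shift) for p in square(0, 0, 200)),
            (("capped_brood", tuple(tuple(np.asarray(p) + shift) for p in region)),),
        )
        det_a = detections_at(pts, effective_radius=4.0, spacing=8.0)
        det_b = detections_at(np.asarray(pts) + shift, effective_radius=4.0, spacing=8.0)
        m_a = quantify_frame(ann_a, det_a, 880.0)
        m_b = quantify_frame(ann_b, det_b, 880.0)
        for label in m_a.per_label:
            assert m_a.per_label[label].capped_area_px2 == pytest.approx(
                m_b.per_label[label].capped_area_px2, rel=1e-9
            )
        assert m_a.inner_area_px2 == pytest.approx(m_b.inner_area_px2, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_measurement_invariants_on_random_scenes(self, seed):
        """Areas are non-negative, capped <= gross, disjoint labels sum
        to at most the inner area."""
        rng = np.random.default_rng(seed)
        # two disjoint axis-aligned regions inside a 200 x 200 inner frame
        brood = square(5 + rng.uniform(0, 20), 5 + rng.uniform(0, 20), 60)
        honey = square(110 + rng.uniform(0, 20), 110 + rng.uniform(0, 20), 55)
        n = rng.integers(0, 40)
        det = detections_at(
            rng.uniform(0, 200, size=(n, 2)),
            effective_radius=float(rng.uniform(1, 6)) if n >= 2 else None,
        )
        ann = FrameAnnotation(
            "rand",
            tuple(square(0, 0, 200)),
            (("capped_brood", tuple(brood)), ("capped_honey", tuple(honey))),
        )
        m = quantify_frame(ann, det, 880.0)
        total = 0.0
        for reg in m.per_label.values():
            assert 0.0 <= reg.capped_area_px2 <= reg.gross_polygon_area_px2 + 1e-9
            assert reg.subtracted_area_px2 >= -1e-9
            assert 0.0 <= reg.capped_fraction_of_inner <= 1.0
            total += reg.capped_area_px2
        assert total <= m.inner_area_px2 + 1e-9
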