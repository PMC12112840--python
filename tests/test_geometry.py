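from __future__ import annotations

import math

import numpy as np
import pytest

from cervimorph.annotation_io import (
    Contour,
    Point2D,
    RadiographAnnotation,
    VertebraAnnotation,
)
from cervimorph.geometry import (
    LineSegment,
    MeasurementConfig,
    MeasurementError,
    band_extreme_point,
    cobb_angle,
    compute_curved_length,
    compute_sva,
    compute_vertical_length,
    endplate_line,
    measure_radiograph,
    polygon_centroid,
    posterosuperior_point,
)
from cervimorph.synthetic_data import SpineGeometryConfig, generate_spine_annotation
from conftest import rectangle

RASTER = MeasurementConfig(contour_source="raster")


def contour_of(points) -> Contour:
    return Contour(points=tuple(Point2D(float(x), float(y)) for x, y in points))


class TestPolygonCentroid:
    def test_unit_square(self):
        assert polygon_centroid(rectangle(0, 0, 1, 1)) == Point2D(0.5, 0.5)

    def test_right_triangle_closed_form(self):
        c = polygon_centroid([(0, 0), (3, 0), (0, 3)])
        assert c == pytest.approx((1.0, 1.0))

    def test_orientation_independent(self):
        ring = [(1.0, 2.0), (7.5, 1.0), (9.0, 6.0), (2.0, 8.0)]
        fwd = polygon_centroid(ring)
        rev = polygon_centroid(ring[::-1])
        assert fwd == pytest.approx(rev)

    def test_concave_l_shape_matches_monte_carlo(self, rng):
        # L-shape: 4x4 square minus its top-right 2x2 quadrant
        L = [(0, 0), (4, 0), (4, 2), (2, 2), (2, 4), (0, 4)]
        c = polygon_centroid(L)
        samples = rng.uniform(0, 4, size=(1_000_000, 2))
        inside = ~((samples[:, 0] > 2) & (samples[:, 1] > 2))
        mc = samples[inside].mean(axis=0)
        assert c == pytest.approx(tuple(mc), abs=1e-2)

    def test_zero_area_rejected(self):
        with pytest.raises(MeasurementError, match="zero"):
            polygon_centroid([(0, 0), (1, 1), (2, 2)])


class TestBandExtremePoint:
    def test_rectangle_corners(self):
        c = contour_of(rectangle(10, 20, 30, 40))
        assert band_extreme_point(c, "leftmost", "lowest") == Point2D(10, 60)
        assert band_extreme_point(c, "rightmost", "highest") == Point2D(40, 20)

    def test_rotated_rectangle_matches_exhaustive_scan(self, rng):
        theta = math.radians(10)
        base = np.asarray(rectangle(0, 0, 30, 20), dtype=float)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        pts = base @ rot.T + [100, 100]
        c = contour_of(pts)
        found = band_extreme_point(c, "rightmost", "highest", 0.25)
        x = pts[:, 0]
        band = x >= x.max() - 0.25 * (x.max() - x.min())
        brute = min(
            (pts[i] for i in np.nonzero(band)[0]), key=lambda p: (p[1], p[0])
        )
        assert found == pytest.approx(tuple(brute))

    def test_tie_break_smaller_x_then_index(self):
        # symmetric hexagon, band covering both bottom vertices at equal y
        hexagon = [(4, 0), (8, 2), (8, 6), (6, 8), (2, 8), (0, 4)]
        p = band_extreme_point(contour_of(hexagon), "leftmost", "lowest", 0.5)
        assert p == Point2D(2, 8)  # (6,8) ties in y; smaller x wins

    def test_too_few_points(self):
        with pytest.raises(MeasurementError):
            band_extreme_point(contour_of([(0, 0), (1, 1)]), "leftmost", "lowest")


class TestEndplateAndCobb:
    def test_level_rectangle_inferior_endplate_is_bottom_edge(self):
        seg = endplate_line(contour_of(rectangle(0, 0, 30, 20)), "c3_inferior")
        assert {seg.a, seg.b} == {Point2D(0, 20), Point2D(30, 20)}

    @pytest.mark.parametrize("theta_deg", [-20.0, -5.0, 5.0, 20.0])
    def test_rotated_rectangle_endplate_slope(self, theta_deg):
        theta = math.radians(theta_deg)
        base = np.asarray(rectangle(-15, -10, 30, 20), dtype=float)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        pts = base @ rot.T + [50, 50]
        seg = endplate_line(contour_of(pts), "c3_inferior")
        slope = (seg.b.y - seg.a.y) / (seg.b.x - seg.a.x)
        assert slope == pytest.approx(math.tan(theta), abs=1e-12)

    def test_degenerate_collinear_contour(self):
        with pytest.raises(MeasurementError, match="coincident"):
            endplate_line(contour_of([(0, 0), (0, 5), (0, 10)]), "c3_inferior")

    def test_parallel_lines_zero_angle(self):
        a = LineSegment(Point2D(0, 0), Point2D(10, 5))
        b = LineSegment(Point2D(3, 7), Point2D(13, 12))
        assert cobb_angle(a, b) == pytest.approx(0.0)

    def test_perpendicular_lines(self):
        a = LineSegment(Point2D(0, 0), Point2D(10, 0))
        b = LineSegment(Point2D(5, 0), Point2D(5, 10))
        assert abs(cobb_angle(a, b)) == pytest.approx(90.0)

    def test_published_normal_cluster_angle(self):
        # slope 0 vs slope tan(24.1 deg): the normal-cluster mean lordosis
        a = LineSegment(Point2D(0, 0), Point2D(10, 0))
        b = LineSegment(Point2D(0, 0), Point2D(10, 10 * math.tan(math.radians(24.1))))
        assert cobb_angle(a, b) == pytest.approx(24.1)


class TestPlumbLineLandmarks:
    def test_posterosuperior_corner_by_laterality(self):
        c = contour_of(rectangle(10, 20, 30, 40))
        right = posterosuperior_point(c, MeasurementConfig(anterior_side="right"))
        left = posterosuperior_point(c, MeasurementConfig(anterior_side="left"))
        assert right == Point2D(10, 20)  # posterior = image-left
        assert left == Point2D(40, 20)

    def test_sva_sign_and_zero(self):
        cfg = MeasurementConfig(anterior_side="right")
        assert compute_sva(Point2D(100, 0), Point2D(100, 50), cfg) == 0.0
        assert compute_sva(Point2D(110, 0), Point2D(100, 50), cfg) == pytest.approx(10.0)
        cfg_left = MeasurementConfig(anterior_side="left")
        assert compute_sva(Point2D(110, 0), Point2D(100, 50), cfg_left) == pytest.approx(-10.0)

    def test_vertical_length(self):
        assert compute_vertical_length(Point2D(0, 0), Point2D(0, 100)) == 100.0
        assert compute_vertical_length(Point2D(50, 10), Point2D(80, 10)) == 0.0

    def test_curved_length_collinear(self):
        pts = [Point2D(0, 25.0 * i) for i in range(5)]
        assert compute_curved_length(pts) == pytest.approx(100.0)

    def test_curved_length_needs_five_centroids(self):
        with pytest.raises(MeasurementError, match="5 centroids"):
            compute_curved_length([Point2D(0, 0)] * 4)

    def test_curved_at_least_straight_distance(self, rng):
        pts = [Point2D(*xy) for xy in rng.uniform(0, 100, size=(5, 2))]
        chord = math.dist(pts[0], pts[-1])
        assert compute_curved_length(pts) >= chord - 1e-12


class TestMeasureRadiograph:
    # grid spans the published per-cluster means of lordosis and SVA
    GRID = [(lo, sv) for lo in (0.0, 8.3, 13.9, 24.1) for sv in (0.0, 70.6, 95.9, 135.6)]

    @pytest.mark.parametrize("lordosis,sva", GRID)
    def test_polygon_direct_recovers_ground_truth(self, lordosis, sva):
        ann, truth = generate_spine_annotation(
            SpineGeometryConfig(lordosis_deg=lordosis, sva=sva)
        )
        _, params = measure_radiograph(ann)
        for got, want in zip(params.as_tuple(), truth.as_tuple()):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("lordosis,sva", [(8.3, 95.9), (24.1, 70.6), (13.9, 135.6)])
    def test_raster_mode_within_pixel_tolerance(self, lordosis, sva):
        cfg = SpineGeometryConfig(
            lordosis_deg=lordosis, sva=sva, segment_gap=260,
            body_width=140, body_height=90,
        )
        ann, truth = generate_spine_annotation(cfg)
        assert max(ann.image_width, ann.image_height) >= 1000
        _, params = measure_radiograph(ann, RASTER)
        assert params.lordosis_deg == pytest.approx(truth.lordosis_deg, abs=1.5)
        assert params.sva == pytest.approx(truth.sva, abs=1.5)
        assert params.vertical_length == pytest.approx(truth.vertical_length, abs=1.5)
        assert params.curved_length == pytest.approx(truth.curved_length, abs=1.5)

    def test_translation_invariance(self):
        ann, _ = generate_spine_annotation(SpineGeometryConfig(lordosis_deg=13.9, sva=70.6))
        _, base = measure_radiograph(ann)
        dx, dy = 17.0, 23.0
        moved = RadiographAnnotation(
            image_id=ann.image_id,
            image_width=ann.image_width + 100,
            image_height=ann.image_height + 100,
            vertebrae={
                label: VertebraAnnotation(
                    label, tuple(Point2D(p.x + dx, p.y + dy) for p in v.polygon)
                )
                for label, v in ann.vertebrae.items()
            },
        )
        _, shifted = measure_radiograph(moved)
        assert shifted.as_tuple() == pytest.approx(base.as_tuple())

    def test_rotation_consistency(self):
        """Rotating the whole radiograph leaves lordosis and curved length
        unchanged; SVA and vertical length follow the rotated landmarks."""
        ann, _ = generate_spine_annotation(SpineGeometryConfig(lordosis_deg=10.0, sva=40.0))
        lm, base = measure_radiograph(ann)
        phi = math.radians(4.0)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        pivot = np.array([ann.image_width / 2, ann.image_height / 2])

        def rotate(p: Point2D) -> np.ndarray:
            return (np.asarray(p) - pivot) @ rot.T + pivot

        rotated = RadiographAnnotation(
            image_id="rot",
            image_width=ann.image_width * 2,
            image_height=ann.image_height * 2,
            vertebrae={
                label: VertebraAnnotation(
                    label, tuple(Point2D(*rotate(p)) for p in v.polygon)
                )
                for label, v in ann.vertebrae.items()
            },
        )
        _, got = measure_radiograph(rotated)
        c3 = rotate(lm.centroids["C3"])
        c7 = rotate(lm.centroids["C7"])
        ps = rotate(lm.c7_posterosuperior)
        assert got.lordosis_deg == pytest.approx(base.lordosis_deg, abs=1e-9)
        assert got.curved_length == pytest.approx(base.curved_length, abs=1e-9)
        assert got.sva == pytest.approx(c3[0] - ps[0], abs=1e-9)
        assert got.vertical_length == pytest.approx(abs(c3[1] - c7[1]), abs=1e-9)

    def test_curved_never_below_vertical(self, rng):
        for _ in range(20):
            cfg = SpineGeometryConfig(
                lordosis_deg=float(rng.uniform(-25, 25)),
                sva=float(rng.uniform(-50, 150)),
                segment_gap=float(rng.uniform(80, 160)),
            )
            _, params = measure_radiograph(generate_spine_annotation(cfg)[0])
            assert params.curved_length >= params.vertical_length - 1e-9

    def test_raster_agrees_with_polygon_direct(self, rng):
        # lordotic range only: for kyphotic C7 tilts the band rule's
        # posterosuperior point slides along the superior endplate of a
        # dense contour, so the two contour sources legitimately differ
        for _ in range(25):
            cfg = SpineGeometryConfig(
                lordosis_deg=float(rng.uniform(0, 24)),
                sva=float(rng.uniform(0, 140)),
                segment_gap=float(rng.uniform(200, 300)),
                body_width=140.0,
                body_height=90.0,
            )
            ann, _ = generate_spine_annotation(cfg)
            _, direct = measure_radiograph(ann)
            _, raster = measure_radiograph(ann, RASTER)
            assert raster.lordosis_deg == pytest.approx(direct.lordosis_deg, abs=1.5)
            assert raster.sva == pytest.approx(direct.sva, abs=1.5)
            assert raster.vertical_length == pytest.approx(direct.vertical_length, abs=1.5)
            assert raster.curved_length == pytest.approx(direct.curved_length, abs=1.5)

    def test_invalid_record_reports_issue(self, stack_annotation):
        del stack_annotation.vertebrae["C5"]
        with pytest.raises(MeasurementError, match=r"MISSING_LABEL\(C5\)"):
            measure_radiograph(stack_annotation)

    def test_pixel_spacing_scales_lengths_not_angle(self):
        ann, _ = generate_spine_annotation(SpineGeometryConfig(lordosis_deg=8.3, sva=95.9))
        _, base = measure_radiograph(ann)
        _, scaled = measure_radiograph(ann, MeasurementConfig(pixel_spacing=0.2))
        assert scaled.lordosis_deg == pytest.approx(base.lordosis_deg)
        assert scaled.sva == pytest.approx(0.2 * base.sva)
        assert scaled.curved_length == pytest.approx(0.2 * base.curved_length)
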