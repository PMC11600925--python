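"""Geometry primitives against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneetemplate.errors import TemplatingError
from kneetemplate.geometry import (ContourPolygon, DirectedLine, Point2,
                                   angle_between_deg, furthest_point_along,
                                   line_polygon_intersections,
                                   perpendicular_line_at, project_offsets,
                                   rotate_line_about)


def star_polygon(rng, n=12, r_lo=5.0, r_hi=40.0, center=(0.0, 0.0)):
    """Random star-shaped (hence simple) polygon."""
    angles = np.sort(rng.uniform(0, 2 * math.pi, n))
    radii = rng.uniform(r_lo, r_hi, n)
    return ContourPolygon(np.column_stack([
        center[0] + radii * np.cos(angles),
        center[1] + radii * np.sin(angles)]))


def brute_force_crossings(line, contour):
    """Independent per-edge oracle: solve each edge's 2x2 linear system."""
    o, d = line.origin.array, line.dir_array
    v = contour.vertices
    ts = []
    for i in range(len(v)):
        a, b = v[i], v[(i + 1) % len(v)]
        A = np.column_stack([d, a - b])
        if abs(np.linalg.det(A)) < 1e-15:
            continue
        t, u = np.linalg.solve(A, a - o)
        if -1e-12 <= u <= 1 + 1e-12:
            ts.append(t)
    ts.sort()
    dedup = []
    for t in ts:
        if not dedup or t - dedup[-1] >= 1e-6:
            dedup.append(t)
    return [line.point_at(t) for t in dedup]


class TestProjectOffsets:
    def test_axis_aligned(self):
        axis = DirectedLine(Point2(0, 0), (0, 1))
        assert project_offsets([Point2(3, 5)], axis)[0] == pytest.approx(5.0)

    def test_origin_projects_to_zero(self):
        axis = DirectedLine(Point2(2, -1), (0.6, 0.8))
        assert project_offsets([Point2(2, -1)], axis)[0] == pytest.approx(0.0)

    def test_matches_per_point_dot_products(self):
        rng = np.random.default_rng(3)
        pts = [Point2(*xy) for xy in rng.normal(0, 10, (20, 2))]
        axis = DirectedLine(Point2(1.0, 2.0), (3.0, -4.0))
        offs = project_offsets(pts, axis)
        d = np.array([0.6, -0.8])
        for p, o in zip(pts, offs):
            expected = (p.array - np.array([1.0, 2.0])) @ d
            assert o == pytest.approx(expected, abs=1e-12)

    def test_empty_input(self):
        axis = DirectedLine(Point2(0, 0), (1, 0))
        assert len(project_offsets([], axis)) == 0


class TestFurthestPoint:
    def test_unit_square_top(self):
        sq = ContourPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])
        p = furthest_point_along(sq, DirectedLine(Point2(0, 0), (0, 1)), +1)
        assert p.y == pytest.approx(1.0)

    def test_matches_exhaustive_scan_on_17gon(self):
        rng = np.random.default_rng(11)
        th = np.linspace(0, 2 * math.pi, 18)[:-1]
        poly = ContourPolygon(np.column_stack([np.cos(th), np.sin(th)]) * 7)
        for _ in range(20):
            d = rng.normal(0, 1, 2)
            axis = DirectedLine(Point2(*rng.normal(0, 5, 2)), tuple(d))
            best = max(range(17),
                       key=lambda i: poly.vertices[i] @ axis.dir_array)
            p = furthest_point_along(poly, axis, +1)
            assert np.allclose(p.array, poly.vertices[best])

    def test_tie_breaks_to_lowest_index(self):
        # two co-extreme top vertices
        poly = ContourPolygon([[0, 0], [4, 0], [4, 2], [0, 2]])
        p = furthest_point_along(poly, DirectedLine(Point2(0, 0), (0, 1)), +1)
        assert (p.x, p.y) == (4.0, 2.0)  # first CCW vertex at y=2

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(5)
        poly = star_polygon(rng)
        axis = DirectedLine(Point2(1, 2), (0.6, 0.8))
        p0 = furthest_point_along(poly, axis, +1)
        th = math.radians(37.0)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        poly_r = ContourPolygon(poly.vertices @ R.T)
        axis_r = DirectedLine(Point2(*(R @ axis.origin.array)),
                              tuple(R @ axis.dir_array))
        p1 = furthest_point_along(poly_r, axis_r, +1)
        assert np.allclose(p1.array, R @ p0.array, atol=1e-9)


class TestPerpendicular:
    def test_vertical_axis_offset_nine(self):
        axis = DirectedLine(Point2(0, 0), (0, 1))
        perp = perpendicular_line_at(axis, 9.0)
        assert perp.origin.y == pytest.approx(9.0)
        assert abs(perp.direction[1]) < 1e-12

    def test_zero_offset_through_origin(self):
        axis = DirectedLine(Point2(3, 4), (1, 0))
        perp = perpendicular_line_at(axis, 0.0)
        assert (perp.origin.x, perp.origin.y) == (3.0, 4.0)

    def test_orthogonality_for_random_axes(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            axis = DirectedLine(Point2(*rng.normal(0, 10, 2)),
                                tuple(rng.normal(0, 1, 2)))
            perp = perpendicular_line_at(axis, float(rng.normal(0, 20)))
            assert abs(np.dot(perp.dir_array, axis.dir_array)) < 1e-9


class TestLinePolygonIntersections:
    def test_square_crossing(self):
        sq = ContourPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])
        pts = line_polygon_intersections(
            DirectedLine(Point2(-5, 0.5), (1, 0)), sq)
        assert len(pts) == 2
        assert sorted(round(p.x, 9) for p in pts) == [0.0, 1.0]

    def test_disjoint_line(self):
        sq = ContourPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])
        pts = line_polygon_intersections(
            DirectedLine(Point2(0, 5.0), (1, 0)), sq)
        assert pts == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_per_edge_oracle(self, seed):
        rng = np.random.default_rng(seed)
        poly = star_polygon(rng)
        line = DirectedLine(Point2(*rng.normal(0, 15, 2)),
                            tuple(rng.normal(0, 1, 2)))
        got = line_polygon_intersections(line, poly)
        expected = brute_force_crossings(line, poly)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g.distance_to(e) < 1e-9

    def test_vertex_graze_deduplicated(self):
        # horizontal line exactly through a vertex shared by two edges
        tri = ContourPolygon([[0, 0], [4, 0], [2, 3]])
        pts = line_polygon_intersections(
            DirectedLine(Point2(-1, 3.0), (1, 0)), tri)
        assert len(pts) == 1
        assert pts[0].x == pytest.approx(2.0)


class TestAngles:
    @pytest.mark.parametrize("d1,d2,expected", [
        ((1, 0), (1, 0), 0.0),
        ((1, 0), (0, 1), 90.0),
        ((1, 0), (1, 1), 45.0),
        ((1, 0), (-1, 1), 45.0),   # undirected: obtuse folds back
    ])
    def test_closed_forms(self, d1, d2, expected):
        a = DirectedLine(Point2(0, 0), d1)
        b = DirectedLine(Point2(5, 5), d2)
        assert angle_between_deg(a, b) == pytest.approx(expected, abs=1e-9)

    def test_rotate_zero_is_same_line_through_pivot(self):
        line = DirectedLine(Point2(0, 0), (1, 0))
        out = rotate_line_about(line, Point2(2, 0), 0.0)
        assert out.direction == line.direction
        assert (out.origin.x, out.origin.y) == (2.0, 0.0)

    def test_rotate_ninety(self):
        line = DirectedLine(Point2(0, 0), (1, 0))
        out = rotate_line_about(line, Point2(1, 1), 90.0)
        assert abs(out.direction[0]) < 1e-12
        assert angle_between_deg(line, out) == pytest.approx(90.0)

    def test_rotation_inverse_composition(self):
        line = DirectedLine(Point2(3, -2), (0.6, 0.8))
        pivot = Point2(3, -2)
        out = rotate_line_about(rotate_line_about(line, pivot, 2.0), pivot, -2.0)
        assert np.allclose(out.dir_array, line.dir_array, atol=1e-9)


class TestInvariants:
    @settings(max_examples=60, derandomize=True)
    @given(tx=st.floats(-100, 100), ty=st.floats(-100, 100),
           seed=st.integers(0, 50))
    def test_translation_equivariance(self, tx, ty, seed):
        """Shifting all inputs shifts point outputs and fixes scalars."""
        rng = np.random.default_rng(seed)
        poly = star_polygon(rng)
        line = DirectedLine(Point2(*rng.normal(0, 10, 2)),
                            tuple(rng.normal(0, 1, 2)))
        t = np.array([tx, ty])
        poly_t = ContourPolygon(poly.vertices + t)
        line_t = DirectedLine(Point2(*(line.origin.array + t)), line.direction)

        p0 = furthest_point_along(poly, line, +1)
        p1 = furthest_point_along(poly_t, line_t, +1)
        assert np.allclose(p1.array, p0.array + t, atol=1e-8)

        x0 = line_polygon_intersections(line, poly)
        x1 = line_polygon_intersections(line_t, poly_t)
        assert len(x0) == len(x1)
        for a, b in zip(x0, x1):
            assert np.allclose(b.array, a.array + t, atol=1e-8)

    def test_contour_rejects_degenerate(self):
        with pytest.raises(TemplatingError):
            ContourPolygon([[0, 0], [1, 1]])

    def test_contour_normalizes_orientation(self):
        cw = ContourPolygon([[0, 1], [1, 1], [1, 0], [0, 0]])
        from kneetemplate.geometry import _signed_area
        assert _signed_area(cw.vertices) > 0
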