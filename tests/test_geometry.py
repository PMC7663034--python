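"""Base measurements: axes, hull, boxes, reference shapes, invariances."""

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import Point, Polygon

from gmnodule import (
    GeometryConfig,
    NoduleContour,
    compute_geometry,
    ellipse_perimeter_ramanujan,
    minimum_area_rectangle,
    reference_shapes,
)
from gmnodule.errors import DegenerateContourError

from conftest import circle_contour, ellipse_contour, random_shape


def brute_force_major_axis(border):
    """Independent O(N^2) pairwise scan with the lexicographic tie policy."""
    best_d2 = -1.0
    best = None
    n = len(border)
    for i in range(n):
        xi, yi = border[i]
        for j in range(i + 1, n):
            xj, yj = border[j]
            d2 = (xi - xj) ** 2 + (yi - yj) ** 2
            p, q = ((xi, yi), (xj, yj))
            if q < p:
                p, q = q, p
            key = (p[0], p[1], q[0], q[1])
            if d2 > best_d2 or (d2 == best_d2 and key < best[1]):
                best_d2 = d2
                best = (np.sqrt(d2), key)
    return best


def exact_ellipse_perimeter(a, b):
    """Numeric arc-length integral of an ellipse (independent oracle)."""
    e2 = 1.0 - (b / a) ** 2
    val, _ = quad(lambda t: np.sqrt(1.0 - e2 * np.sin(t) ** 2), 0.0, np.pi / 2)
    return 4.0 * a * val


class TestComputeGeometry:
    def test_rectangle_axes(self, rectangle):
        g = compute_geometry(rectangle)
        assert g.major_axis_length == pytest.approx(np.hypot(40, 20), abs=1.5)
        # longest chord perpendicular to the diagonal: 20 / cos(26.57 deg)
        assert g.minor_axis_length == pytest.approx(20 / np.cos(np.arctan(0.5)), abs=1.5)
        assert g.bbox_area == g.major_axis_length * g.minor_axis_length

    def test_disk_measurements(self, disk):
        g = compute_geometry(disk)
        assert g.area_An == pytest.approx(np.pi * 50**2, rel=0.02)
        assert g.perimeter_Pn == pytest.approx(2 * np.pi * 50, rel=0.05)
        assert g.major_axis_length == pytest.approx(100.0, rel=0.02)

    def test_centroid_inside_hull(self, random_shapes_50):
        for contour in random_shapes_50[:20]:
            g = compute_geometry(contour)
            hull = Polygon(g.hull.points)
            assert hull.contains(Point(*g.centroid))

    def test_hull_bounds_area_and_perimeter(self):
        for seed in range(100):
            g = compute_geometry(random_shape(20_000 + seed))
            assert g.convex_perimeter_Pc <= g.perimeter_Pn * (1 + 1e-9)
            assert g.convex_area_Ac >= g.area_An * (1 - 1e-9)

    def test_major_axis_matches_brute_force(self):
        """Production farthest-pair search == independent O(N^2) oracle."""
        rng = np.random.default_rng(42)
        coarse = GeometryConfig(resample_spacing=2.0)  # keeps the oracle O(N^2) cheap
        for _ in range(25):
            contour = random_shape(int(rng.integers(0, 10_000)))
            g = compute_geometry(contour, coarse)
            border = g.boundary_points
            assert len(border) <= 400
            length, key = brute_force_major_axis(border)
            assert g.major_axis_length == length
            p1, p2 = g.major_axis_endpoints
            assert (p1[0], p1[1], p2[0], p2[1]) == key

    def test_minor_axis_perpendicular_within_tolerance(self, random_shapes_50):
        for contour in random_shapes_50[:10]:
            g = compute_geometry(contour)
            (x1, y1), (x2, y2) = g.major_axis_endpoints
            (u1, v1), (u2, v2) = g.minor_axis_endpoints
            major = np.array([x2 - x1, y2 - y1])
            minor = np.array([u2 - u1, v2 - v1])
            cosang = abs(major @ minor) / (
                np.linalg.norm(major) * np.linalg.norm(minor)
            )
            assert cosang <= np.sin(np.deg2rad(2.0)) + 1e-12
            assert g.minor_axis_length <= g.major_axis_length + 1e-9

    def test_projection_mode_agrees_on_ellipse(self, ellipse):
        chord = compute_geometry(ellipse, GeometryConfig(minor_axis_mode="chord"))
        proj = compute_geometry(ellipse, GeometryConfig(minor_axis_mode="projection"))
        assert chord.minor_axis_length == pytest.approx(60.0, rel=0.02)
        assert proj.minor_axis_length == pytest.approx(60.0, rel=0.02)

    def test_orientation_of_rotated_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        x, y_up = 60 * np.cos(t), 30 * np.sin(t)
        phi = np.deg2rad(30)
        xr = np.cos(phi) * x - np.sin(phi) * y_up
        yr = np.sin(phi) * x + np.cos(phi) * y_up
        c = NoduleContour(np.column_stack([200 + xr, 200 - yr]))
        g = compute_geometry(c)
        assert g.orientation_deg == pytest.approx(30.0, abs=2.0)


class TestMinimumAreaRectangle:
    def test_rectangle_is_its_own_minimum(self, rectangle):
        g = compute_geometry(rectangle)
        assert minimum_area_rectangle(g.hull) == pytest.approx(800.0, rel=0.03)

    def test_rotation_invariance(self):
        phi = np.deg2rad(37)
        base = np.array([(0, 0), (40, 0), (40, 20), (0, 20)], float)
        rot = base @ np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        g = compute_geometry(NoduleContour(rot + 100))
        assert minimum_area_rectangle(g.hull) == pytest.approx(800.0, rel=0.03)

    def test_disk_circumscribing_square(self, disk):
        g = compute_geometry(disk)
        assert minimum_area_rectangle(g.hull) == pytest.approx(100 * 100, rel=0.03)

    def test_contains_the_shape(self, random_shapes_50):
        for contour in random_shapes_50[:10]:
            g = compute_geometry(contour)
            assert minimum_area_rectangle(g.hull) >= g.area_An * (1 - 1e-9)


class TestReferenceShapes:
    def test_disk_references_are_the_circle(self, disk):
        refs = reference_shapes(compute_geometry(disk))
        assert refs.ellipse_perimeter_Pe == pytest.approx(2 * np.pi * 50, rel=0.02)
        assert refs.circle_perimeter == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_equal_area_circle_closed_form(self, disk):
        g = compute_geometry(disk)
        refs = reference_shapes(g)
        assert refs.circle_perimeter == pytest.approx(
            2 * np.sqrt(np.pi * g.area_An), rel=1e-9
        )

    def test_ramanujan_vs_integral_oracle(self):
        # frozen oracle value for the 2:1 ellipse, from the arc-length integral
        assert exact_ellipse_perimeter(60, 30) == pytest.approx(290.6534466, abs=1e-4)
        for a, b in [(50, 50), (60, 30), (80, 20), (45, 36), (100, 26)]:
            assert ellipse_perimeter_ramanujan(a, b) == pytest.approx(
                exact_ellipse_perimeter(a, b), rel=1e-3
            )

    def test_related_ellipse_of_ellipse_contour(self, ellipse):
        g = compute_geometry(ellipse)
        refs = reference_shapes(g)
        a, b = refs.ellipse_semi_axes
        assert a == pytest.approx(60, rel=0.02)
        assert b == pytest.approx(30, rel=0.03)
        assert a >= b > 0

    def test_major_diameter_circle_option(self, disk):
        g = compute_geometry(disk)
        refs = reference_shapes(g, GeometryConfig(tcp_reference="major_diameter"))
        assert refs.circle_radius == pytest.approx(g.major_axis_length / 2)

    def test_moments_ellipse_option(self, ellipse):
        g = compute_geometry(ellipse)
        refs = reference_shapes(g, GeometryConfig(tep_reference="moments_ellipse"))
        a, b = refs.ellipse_semi_axes
        assert a / b == pytest.approx(2.0, rel=0.15)


class TestInvariances:
    @staticmethod
    def _measure(points):
        g = compute_geometry(NoduleContour(points))
        return np.array(
            [g.area_An, g.perimeter_Pn, g.major_axis_length, g.minor_axis_length]
        )

    def test_rotation_and_mirror_invariance(self):
        for seed in [3, 17, 4242]:
            pts = random_shape(seed).points
            base = self._measure(pts)
            c = pts.mean(axis=0)
            for k in (1, 2, 3):
                phi = k * np.pi / 2
                rot = (pts - c) @ np.array(
                    [[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]]
                ) + c
                assert np.allclose(self._measure(rot), base, rtol=0.01)
            mirrored = np.column_stack([2 * c[0] - pts[:, 0], pts[:, 1]])[::-1]
            assert np.allclose(self._measure(mirrored), base, rtol=0.01)

    def test_scaling_covariance(self):
        for seed in [5, 99]:
            pts = random_shape(seed).points
            base = self._measure(pts)
            scaled = self._measure(pts * 2.0)
            assert scaled[0] == pytest.approx(4.0 * base[0], rel=0.01)
            assert np.allclose(scaled[1:], 2.0 * base[1:], rtol=0.01)

    def test_isoperimetric_maximum_for_disk(self):
        disk_q = None
        g = compute_geometry(circle_contour())
        disk_q = 4 * np.pi * g.area_An / g.perimeter_Pn**2
        for seed in range(20):
            g = compute_geometry(random_shape(31_000 + seed, spiculated=True))
            q = 4 * np.pi * g.area_An / g.perimeter_Pn**2
            assert q < disk_q

    def test_degenerate_contour_raises(self):
        # a collinear boundary cannot even be constructed
        with pytest.raises(DegenerateContourError):
            NoduleContour([(0, 0), (10, 0), (20, 0)])
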