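"""Contour construction, chain-code parsing and signature transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import masscontour as mc
from masscontour.exceptions import ChainCodeError, OpenPathError

from .oracles import brute_force_ray_ellipse


class TestChainCode:
    def test_square_trace(self):
        c = mc.parse_chain_code((0, 0), [0, 0, 2, 2, 4, 4, 6, 6])
        expected = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
        assert c.points.tolist() == [[x, y] for x, y in expected]
        assert mc.geometry.signed_area(c.points) > 0

    def test_empty_codes_is_format_error(self):
        with pytest.raises(ChainCodeError):
            mc.parse_chain_code((0, 0), [])

    def test_unknown_code_is_format_error(self):
        with pytest.raises(ChainCodeError):
            mc.parse_chain_code((0, 0), [0, 9, 2])

    def test_open_path_reports_gap(self):
        with pytest.raises(OpenPathError) as exc:
            mc.parse_chain_code((0, 0), [0, 0, 0])
        assert exc.value.terminal == (3, 0)
        assert exc.value.start == (0, 0)

    def test_open_path_permissive_mode_closes_and_warns(self):
        with pytest.warns(UserWarning, match="does not close"):
            c = mc.parse_chain_code((0, 0), [0, 0, 2, 2, 4, 4], on_open="close")
        assert tuple(c.points[0]) == (0.0, 0.0)
        # closure steps restore an 8-connected loop
        mc.encode_chain_code(c)

    def test_clockwise_input_is_reversed(self):
        # same square traced clockwise (negative-y first)
        c = mc.parse_chain_code((0, 0), [2, 2, 0, 0, 6, 6, 4, 4])
        assert mc.geometry.signed_area(c.points) > 0
        assert tuple(c.points[0]) == (0.0, 0.0)

    def test_round_trip(self):
        codes = [0, 0, 1, 2, 2, 3, 4, 4, 5, 6, 6, 7]
        c = mc.parse_chain_code((5, 5), codes)
        start, codes_out = mc.encode_chain_code(c)
        assert start == (5, 5)
        assert codes_out == codes


class TestCentroidAndDiameters:
    def test_centroid_square(self, unit_square):
        assert mc.centroid(unit_square) == (1.0, 1.0)

    def test_centroid_triangle(self):
        tri = mc.Contour(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]]))
        assert mc.centroid(tri) == (1.0, 1.0)

    def test_centroid_translation_equivariance(self, circle_contour):
        c = circle_contour(radius=20, n=100)
        shifted = mc.Contour(c.points + [5.0, 7.0])
        x0, y0 = mc.centroid(c)
        x1, y1 = mc.centroid(shifted)
        assert (x1, y1) == pytest.approx((x0 + 5, y0 + 7))

    def test_bounding_diameters(self, unit_square):
        assert mc.bounding_diameters(unit_square) == (2.0, 2.0)
        tri = mc.Contour(np.array([[0.0, 0.0], [4.0, 1.0], [2.0, 5.0]]))
        assert mc.bounding_diameters(tri) == (4.0, 5.0)

    def test_degenerate_contour_rejected(self):
        # collinear vertices give zero area, caught at construction
        with pytest.raises(ValueError):
            mc.Contour(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))


class TestReferenceEllipse:
    def test_circle_case(self, circle_contour):
        ell = mc.reference_ellipse(circle_contour(radius=50, center=(100, 100)))
        assert ell.center == pytest.approx((100, 100), abs=1e-9)
        assert ell.semi_axis_x == pytest.approx(50, abs=0.1)
        assert ell.semi_axis_y == pytest.approx(50, abs=0.1)

    def test_ellipse_case(self, ellipse_points):
        c = mc.Contour(ellipse_points(40, 20))
        ell = mc.reference_ellipse(c)
        assert ell.semi_axis_x == pytest.approx(40, abs=1e-9)
        assert ell.semi_axis_y == pytest.approx(20, abs=1e-9)

    def test_square_case(self, unit_square):
        ell = mc.reference_ellipse(unit_square)
        assert ell.center == (1.0, 1.0)
        assert (ell.semi_axis_x, ell.semi_axis_y) == (1.0, 1.0)


class TestAlignStart:
    def test_circle_starts_at_rightmost_crossover(self, circle_contour):
        c = circle_contour(radius=50, n=360)
        rolled = mc.Contour(np.roll(c.points, -97, axis=0))
        aligned = mc.align_start(rolled)
        assert tuple(aligned.points[0]) == pytest.approx((50.0, 0.0), abs=1e-9)

    def test_square_tie_break(self, unit_square):
        aligned = mc.align_start(unit_square)
        # candidates (2,0) and (2,2) tie on |y-1| and x; smaller index wins
        assert tuple(aligned.points[0]) == (2.0, 0.0)

    def test_idempotent(self, circle_contour):
        c = circle_contour(radius=30, n=123)
        once = mc.align_start(c)
        twice = mc.align_start(once)
        np.testing.assert_array_equal(once.points, twice.points)

    def test_vertex_multiset_unchanged(self, unit_square):
        aligned = mc.align_start(unit_square)
        assert sorted(map(tuple, aligned.points)) == sorted(
            map(tuple, unit_square.points)
        )


class TestSignatures:
    def test_radial_circle(self, circle_contour):
        sig = mc.radial_signature(mc.align_start(circle_contour(radius=50)))
        assert np.all(np.abs(sig.values - 50) < 0.5)

    def test_radial_square_oscillates(self):
        # side-2 square centered at origin, 8 boundary points
        pts = np.array(
            [[1, 0], [1, 1], [0, 1], [-1, 1], [-1, 0], [-1, -1], [0, -1], [1, -1]],
            dtype=float,
        )
        sig = mc.radial_signature(mc.Contour(pts))
        expected = [1, np.sqrt(2)] * 4
        np.testing.assert_allclose(sig.values, expected, atol=1e-12)

    def test_translation_invariance(self, ellipse_points):
        pts = ellipse_points(35, 22, n=200)
        s0 = mc.ellipse_signature(mc.align_start(mc.Contour(pts)))
        s1 = mc.ellipse_signature(mc.align_start(mc.Contour(pts + [11.0, -3.0])))
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-9)
        r0 = mc.radial_signature(mc.align_start(mc.Contour(pts)))
        r1 = mc.radial_signature(mc.align_start(mc.Contour(pts + [11.0, -3.0])))
        np.testing.assert_allclose(r1.values, r0.values, atol=1e-9)

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, k):
        theta = 2 * np.pi * np.arange(90) / 90
        pts = np.column_stack(
            ((30 + 2 * np.cos(3 * theta)) * np.cos(theta),
             (20 + 2 * np.cos(3 * theta)) * np.sin(theta))
        )
        base = mc.align_start(mc.Contour(pts))
        scaled = mc.align_start(mc.Contour(pts * k))
        for fn in (mc.radial_signature, mc.ellipse_signature):
            np.testing.assert_allclose(
                fn(scaled).values, k * fn(base).values, rtol=1e-9, atol=1e-9
            )

    def test_on_ellipse_residual_near_zero(self, ellipse_points):
        c = mc.align_start(mc.Contour(ellipse_points(40, 25, n=720)))
        sig = mc.ellipse_signature(c)
        assert np.max(sig.values) < 0.5

    def test_residual_nonnegative(self):
        rng = np.random.default_rng(3)
        theta = 2 * np.pi * np.arange(128) / 128
        r = 40 * (1 + 0.2 * np.cos(9 * theta) + 0.1 * np.sin(17 * theta))
        pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
        sig = mc.ellipse_signature(mc.align_start(mc.Contour(pts)))
        assert np.all(sig.values >= 0)

    def test_pushed_vertex_against_brute_force(self):
        # circle of radius 50 with the angle-0 vertex pushed to 55: the bump
        # changes D_x, so the expected residual comes from the oracle, not 5.
        n = 360
        theta = 2 * np.pi * np.arange(n) / n
        r = np.full(n, 50.0)
        r[0] = 55.0
        pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
        c = mc.align_start(mc.Contour(pts))
        sig = mc.ellipse_signature(c)
        ell = mc.reference_ellipse(c)
        x0, y0 = ell.center
        for i in range(0, n, 37):
            dx, dy = c.points[i, 0] - x0, c.points[i, 1] - y0
            th = np.arctan2(dy, dx)
            r_oracle = brute_force_ray_ellipse(ell.semi_axis_x, ell.semi_axis_y, th)
            h_oracle = abs(np.hypot(dx, dy) - r_oracle)
            assert sig.values[i] == pytest.approx(h_oracle, abs=1e-9)

    def test_signed_variant(self, ellipse_points):
        pts = ellipse_points(40, 25, n=180) * 1.0
        pts[10] *= 1.2  # push one vertex outward
        c = mc.align_start(mc.Contour(pts))
        signed = mc.ellipse_signature(c, signed=True)
        unsigned = mc.ellipse_signature(c)
        np.testing.assert_allclose(np.abs(signed.values), unsigned.values)
        assert np.any(signed.values < 0) or np.any(signed.values > 0)
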