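"""Ellipse mathematics: perimeter formulas, conic fit, rescale, mm conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ellipe

from fetalhc.errors import (
    DegenerateGeometryError,
    InvalidParameterError,
    TooFewPointsError,
)
from fetalhc.geometry import (
    EllipseParams,
    PixelSpacing,
    ellipse_boundary_points,
    exact_perimeter,
    fit_ellipse,
    hc_mm,
    ramanujan_circumference,
    rescale_ellipse,
)


def elliptic_perimeter(a, b):
    """Independent oracle: complete elliptic integral of the second kind."""
    hi, lo = max(a, b), min(a, b)
    return 4.0 * hi * ellipe(1.0 - (lo / hi) ** 2)


class TestRamanujan:
    def test_circle_reduces_to_2_pi_r(self):
        assert ramanujan_circumference(1.0, 1.0) == pytest.approx(2 * math.pi, abs=1e-15)
        assert ramanujan_circumference(3.5, 3.5) == pytest.approx(7 * math.pi, abs=1e-12)

    def test_two_to_one_ellipse_matches_quadrature(self):
        # frozen from the elliptic-integral oracle: P(2,1) = 9.68844822...
        assert ramanujan_circumference(2.0, 1.0) == pytest.approx(9.6884482, rel=1e-6)

    def test_symmetric_in_axes(self):
        assert ramanujan_circumference(1.0, 2.0) == ramanujan_circumference(2.0, 1.0)

    @pytest.mark.parametrize("a,b", [(0, 1), (-1, 2), (1, 0), (np.nan, 1)])
    def test_rejects_nonpositive_axes(self, a, b):
        with pytest.raises(InvalidParameterError):
            ramanujan_circumference(a, b)

    def test_relative_error_below_1e6_for_ratio_above_02(self):
        a_grid = np.linspace(1.0, 100.0, 50)
        ratio_grid = np.linspace(0.2, 1.0, 50)
        worst = 0.0
        for a in a_grid:
            for r in ratio_grid:
                b = a * r
                exact = elliptic_perimeter(a, b)
                worst = max(worst, abs(ramanujan_circumference(a, b) - exact) / exact)
        assert worst <= 1e-6

    @given(
        a=st.floats(0.1, 1e3), ratio=st.floats(0.2, 1.0), k=st.floats(1e-3, 1e3)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_scale_equivariance(self, a, ratio, k):
        b = a * ratio
        assert ramanujan_circumference(k * a, k * b) == pytest.approx(
            k * ramanujan_circumference(a, b), rel=1e-12
        )


class TestExactPerimeter:
    def test_circle(self):
        assert exact_perimeter(3.0, 3.0) == pytest.approx(6 * math.pi, rel=1e-12)

    def test_matches_elliptic_integral_series(self):
        assert exact_perimeter(2.0, 1.0) == pytest.approx(9.6884482, rel=1e-7)
        for a, b in [(5, 1), (10, 9), (1, 0.2)]:
            assert exact_perimeter(a, b) == pytest.approx(
                elliptic_perimeter(a, b), rel=1e-9
            )

    def test_degenerate_segment_limit(self):
        assert exact_perimeter(1.0, 1e-6) == pytest.approx(4.0, abs=1e-3)

    def test_rejects_nonpositive_axes(self):
        with pytest.raises(InvalidParameterError):
            exact_perimeter(-1.0, 1.0)


class TestEllipseParams:
    def test_canonicalizes_swapped_axes(self):
        e = EllipseParams(0, 0, 1.0, 2.0, 30.0)
        assert (e.a, e.b) == (2.0, 1.0)
        assert e.theta == pytest.approx(120.0)

    def test_theta_normalized_mod_180(self):
        assert EllipseParams(0, 0, 2, 1, 190.0).theta == pytest.approx(10.0)
        assert EllipseParams(0, 0, 2, 1, -10.0).theta == pytest.approx(170.0)

    def test_circle_theta_is_zero(self):
        assert EllipseParams(0, 0, 2, 2, 77.0).theta == 0.0

    def test_rejects_nonpositive_axes(self):
        with pytest.raises(InvalidParameterError):
            EllipseParams(0, 0, 0.0, 1.0)


class TestFitEllipse:
    def test_exact_roundtrip_single(self):
        truth = EllipseParams(5.0, -3.0, 4.0, 2.0, 30.0)
        fit = fit_ellipse(ellipse_boundary_points(truth, 100))
        assert fit.cx == pytest.approx(truth.cx, abs=1e-6)
        assert fit.cy == pytest.approx(truth.cy, abs=1e-6)
        assert fit.a == pytest.approx(truth.a, abs=1e-6)
        assert fit.b == pytest.approx(truth.b, abs=1e-6)
        assert fit.theta == pytest.approx(truth.theta, abs=1e-6)

    def test_roundtrip_100_random_ellipses(self, rng):
        worst = 0.0
        for _ in range(100):
            truth = EllipseParams(
                cx=rng.uniform(-50, 50),
                cy=rng.uniform(-50, 50),
                a=rng.uniform(5, 80),
                b=rng.uniform(2, 5) if rng.random() < 0.2 else rng.uniform(2, 80),
                theta=rng.uniform(0, 180),
            )
            fit = fit_ellipse(ellipse_boundary_points(truth, 120))
            dth = abs(fit.theta - truth.theta) % 180
            dth = min(dth, 180 - dth)
            err = max(
                abs(fit.cx - truth.cx), abs(fit.cy - truth.cy),
                abs(fit.a - truth.a), abs(fit.b - truth.b),
            )
            if truth.a - truth.b > 1e-3:
                err = max(err, dth)
            worst = max(worst, err)
        assert worst <= 1e-6

    def test_matches_independent_skimage_fit(self, rng):
        """Cross-check against scikit-image's ellipse model on noisy points."""
        from skimage.measure import EllipseModel

        truth = EllipseParams(10, 20, 30, 18, 40)
        pts = ellipse_boundary_points(truth, 200) + rng.normal(0, 0.05, (200, 2))
        ours = fit_ellipse(pts)
        try:
            sk = EllipseModel.from_estimate(pts)
            xc, yc, A, B, th = sk.params
        except AttributeError:  # older scikit-image
            sk = EllipseModel()
            sk.estimate(pts)
            xc, yc, A, B, th = sk.params
        a_sk, b_sk = max(A, B), min(A, B)
        assert ours.a == pytest.approx(a_sk, abs=0.05)
        assert ours.b == pytest.approx(b_sk, abs=0.05)
        assert ours.cx == pytest.approx(xc, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(TooFewPointsError):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    def test_collinear_points(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse(pts)

    def test_circle_any_theta(self):
        fit = fit_ellipse(ellipse_boundary_points(EllipseParams(0, 0, 7, 7), 50))
        assert fit.a == pytest.approx(7.0, abs=1e-6)
        assert fit.b == pytest.approx(7.0, abs=1e-6)


class TestRescale:
    def test_axis_aligned(self):
        e = rescale_ellipse(EllipseParams(0, 0, 2, 1, 0), 2.0, 1.0)
        assert (e.a, e.b, e.theta) == (pytest.approx(4.0), pytest.approx(1.0), pytest.approx(0.0))

    def test_identity(self):
        e = EllipseParams(3, 4, 5, 2, 25)
        r = rescale_ellipse(e, 1.0, 1.0)
        assert r.isoclose(e, 1e-12)

    def test_inverse_roundtrip(self, rng):
        for _ in range(20):
            e = EllipseParams(rng.uniform(-5, 5), rng.uniform(-5, 5),
                              rng.uniform(2, 9), rng.uniform(1, 2), rng.uniform(0, 180))
            fx, fy = rng.uniform(0.2, 5, 2)
            r = rescale_ellipse(rescale_ellipse(e, fx, fy), 1 / fx, 1 / fy)
            assert abs(r.cx - e.cx) <= 1e-9
            assert abs(r.cy - e.cy) <= 1e-9
            assert abs(r.a - e.a) <= 1e-9
            assert abs(r.b - e.b) <= 1e-9

    def test_rotated_matches_point_map_oracle(self):
        """Map 360 boundary samples through the diagonal transform and re-fit."""
        e = EllipseParams(0, 0, 3, 1, 45)
        fx, fy = 2.0, 0.5
        direct = rescale_ellipse(e, fx, fy)
        pts = ellipse_boundary_points(e, 360) * np.array([fx, fy])
        refit = fit_ellipse(pts)
        assert direct.a == pytest.approx(refit.a, abs=1e-8)
        assert direct.b == pytest.approx(refit.b, abs=1e-8)
        assert direct.theta == pytest.approx(refit.theta, abs=1e-6)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(InvalidParameterError):
            rescale_ellipse(EllipseParams(0, 0, 2, 1), 0.0, 1.0)


class TestHcMm:
    def test_circle_isotropic(self):
        v = hc_mm(EllipseParams(0, 0, 10, 10), PixelSpacing(0.1))
        assert v == pytest.approx(2 * math.pi, rel=1e-12)

    def test_isotropic_scaling(self):
        v = hc_mm(EllipseParams(0, 0, 20, 10), PixelSpacing(0.1))
        assert v == pytest.approx(ramanujan_circumference(2.0, 1.0), rel=1e-12)
        assert v == pytest.approx(9.68845, rel=1e-5)

    def test_anisotropic_circle_becomes_ellipse(self):
        v = hc_mm(EllipseParams(0, 0, 10, 10), PixelSpacing(0.2, 0.1))
        assert v == pytest.approx(ramanujan_circumference(2.0, 1.0), rel=1e-9)

    def test_invariant_to_axis_swap_with_rotation(self):
        s = PixelSpacing(0.07, 0.13)
        e1 = EllipseParams(1, 2, 8, 3, 25)
        e2 = EllipseParams(1, 2, 3, 8, 25 + 90)  # canonicalizes back to e1
        assert hc_mm(e1, s) == pytest.approx(hc_mm(e2, s), rel=1e-12)

    def test_spacing_validation(self):
        with pytest.raises(InvalidParameterError):
            PixelSpacing(0.0)
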