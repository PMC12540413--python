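"""Orthogonal centerline fitting, orientation angles, deviation statistics."""

import math

import numpy as np
import pytest

from rowturn.centerline_fit import (
    StandardLine,
    angle_between,
    fit_line,
    line_angle,
    line_endpoints,
    orientation_from_endpoints,
    summarize,
    vertical_endpoints,
)
from rowturn.errors import NearVerticalLineError, UnderdeterminedFitError

from .oracles import grid_search_angle, minimal_angle_between
from .reference_data import (
    ANGULAR_DEVIATIONS_DEG,
    DEVIATION_MAE,
    DEVIATION_MAX,
    DEVIATION_MEAN,
)


def line_from_angle(deg, x0=0.0, y0=0.0):
    """FittedLine-like helper through (x0, y0) at the given orientation."""
    return fit_line([(x0, y0), (x0 + math.cos(math.radians(deg)),
                                y0 + math.sin(math.radians(deg)))])


class TestFitLine:
    def test_collinear_diagonal(self):
        line = fit_line([(0, 0), (1, 1), (2, 2)])
        assert line_angle(line) == pytest.approx(45.0, abs=1e-9)

    def test_horizontal(self):
        line = fit_line([(0, 5), (10, 5), (20, 5)])
        assert line.vy == 0.0 and line.vx == 1.0
        assert line.y0 == 5.0

    def test_underdetermined_raises(self):
        with pytest.raises(UnderdeterminedFitError):
            fit_line([(3, 3), (3, 3)])

    def test_noisy_slope_two_recovered(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 2 * x + 1 + rng.normal(0, 0.5, 50)
        pts = np.column_stack([x, y])
        angle = line_angle(fit_line(pts))
        assert abs(angle - math.degrees(math.atan(2))) < 1.0

    def test_matches_grid_search_oracle(self, rng):
        """TLS direction agrees with the brute-force angular grid search."""
        for _ in range(5):
            true_deg = rng.uniform(-80, 80)
            t = rng.uniform(0, 100, 40)
            pts = np.column_stack([
                t * math.cos(math.radians(true_deg)),
                t * math.sin(math.radians(true_deg)),
            ]) + rng.normal(0, 1.0, (40, 2))
            fitted = line_angle(fit_line(pts))
            oracle = grid_search_angle(pts, step_deg=0.01)
            assert minimal_angle_between(fitted, oracle) < 0.02

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        a0 = line_angle(fit_line(pts))
        a1 = line_angle(fit_line(pts + [1234.5, -77.3]))
        assert a0 == pytest.approx(a1, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(0, 1, (30, 2)) * [10, 1]  # elongated cloud
        a0 = line_angle(fit_line(pts))
        phi = 25.0
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        rot = pts @ np.array([[c, s], [-s, c]])  # row-vector rotation by +phi
        a1 = line_angle(fit_line(rot))
        assert minimal_angle_between(a1, a0 + phi) < 1e-6

    def test_collinear_zero_residual(self):
        pts = np.column_stack([np.arange(10.0), 3 * np.arange(10.0) + 2])
        line = fit_line(pts)
        n = np.array([-line.vy, line.vx])
        res = (pts - [line.x0, line.y0]) @ n
        assert np.abs(res).max() < 1e-9


class TestEndpoints:
    def test_diagonal_through_origin(self):
        line = line_from_angle(45.0)
        p_start, p_end = line_endpoints(line, 100)
        assert p_start == pytest.approx((0.0, 0.0))
        assert p_end == pytest.approx((100.0, 100.0))

    def test_horizontal_line(self):
        line = fit_line([(0, 7), (10, 7)])
        p_start, p_end = line_endpoints(line, 50)
        assert p_start == (0.0, 7.0) and p_end == (50.0, 7.0)

    def test_vertical_raises_and_fallback_works(self):
        line = fit_line([(5, 0), (5, 10)])
        with pytest.raises(NearVerticalLineError):
            line_endpoints(line, 100)
        top, bottom = vertical_endpoints(line, 100)
        assert top == pytest.approx((5.0, 0.0))
        assert bottom == pytest.approx((5.0, 100.0))


class TestLineAngle:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(0, 0), (1, 0)], 0.0),
            ([(0, 0), (1, 1)], 45.0),
            ([(0, 0), (0, 1)], 90.0),
        ],
    )
    def test_cardinal_directions(self, pts, expected):
        assert line_angle(fit_line(pts)) == pytest.approx(expected, abs=1e-9)


class TestAngleBetween:
    def test_identical_lines_zero(self):
        line = line_from_angle(30.0)
        std = StandardLine(0, 0, math.cos(math.radians(30)), math.sin(math.radians(30)))
        dev = angle_between(line, std)
        assert dev.theta == pytest.approx(0.0, abs=1e-9)

    def test_slope_zero_vs_one(self):
        fitted = line_from_angle(45.0)
        std = StandardLine(0, 5, 10, 5)  # horizontal
        dev = angle_between(fitted, std)
        assert dev.abs_theta == pytest.approx(45.0, abs=1e-9)
        # matches the slope formula arctan(|m2-m1|/|1+m1*m2|)
        assert dev.abs_theta == pytest.approx(
            math.degrees(math.atan(abs((1 - 0) / (1 + 0)))), abs=1e-9
        )

    def test_wraparound_near_vertical(self):
        """80 deg vs -80 deg differ by 20 deg, not 160."""
        fitted = line_from_angle(80.0)
        std = StandardLine(0, 0, math.cos(math.radians(-80)), math.sin(math.radians(-80)))
        dev = angle_between(fitted, std)
        assert dev.abs_theta == pytest.approx(
            minimal_angle_between(80.0, -80.0), abs=1e-9
        )

    def test_symmetry_in_magnitude(self, rng):
        for _ in range(20):
            a, b = rng.uniform(-89, 89, 2)
            la, lb = line_from_angle(a), line_from_angle(b)
            sa = StandardLine(0, 0, math.cos(math.radians(a)), math.sin(math.radians(a)))
            sb = StandardLine(0, 0, math.cos(math.radians(b)), math.sin(math.radians(b)))
            assert angle_between(la, sb).abs_theta == pytest.approx(
                angle_between(lb, sa).abs_theta, abs=1e-9
            )

    def test_slope_formula_consistency(self, rng):
        """Signed wrap agrees with the arctan slope formula whenever the
        slopes are finite and non-perpendicular."""
        for _ in range(50):
            a, b = rng.uniform(-80, 80, 2)
            m1 = math.tan(math.radians(b))
            m2 = math.tan(math.radians(a))
            if abs(1 + m1 * m2) < 1e-6:
                continue
            fitted = line_from_angle(a)
            std = StandardLine(0, 0, 1, m1)
            expected = math.degrees(math.atan(abs((m2 - m1) / (1 + m1 * m2))))
            assert angle_between(fitted, std).abs_theta == pytest.approx(
                expected, abs=1e-9
            )

    def test_sign_convention_left_is_negative(self):
        """A fitted line whose upper end sits left of a vertical standard
        line has negative theta."""
        fitted = line_from_angle(85.0)  # top end (small v) at smaller u
        std = StandardLine(0, 0, 0, 1)  # vertical
        assert angle_between(fitted, std).theta == pytest.approx(-5.0, abs=1e-9)


class TestSummarize:
    def test_published_deviation_statistics(self):
        s = summarize(ANGULAR_DEVIATIONS_DEG)
        assert round(s.mean, 3) == DEVIATION_MEAN
        assert round(s.mae, 3) == DEVIATION_MAE
        assert s.max_abs == DEVIATION_MAX
        assert s.n == 11

    def test_all_zero(self):
        s = summarize([0.0, 0.0, 0.0])
        assert (s.mean, s.mae, s.max_abs) == (0.0, 0.0, 0.0)

    def test_symmetric_pair(self):
        s = summarize([3.0, -3.0])
        assert (s.mean, s.mae, s.max_abs) == (0.0, 3.0, 3.0)

    def test_empty_raises(self):
        with pytest.raises(UnderdeterminedFitError):
            summarize([])

    def test_ordering_invariants(self, rng):
        vals = rng.uniform(-10, 10, 25)
        s = summarize(list(vals))
        assert s.mae >= abs(s.mean)
        assert s.max_abs >= s.mae


def test_orientation_from_endpoints_wraps():
    assert orientation_from_endpoints(0, 0, -1, -1) == pytest.approx(45.0)
    assert orientation_from_endpoints(0, 0, 0, -2) == pytest.approx(90.0)
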