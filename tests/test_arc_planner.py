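"""Arc radius/center/angle rules, waypoint sampling, spline smoothing."""

import numpy as np
import pytest

from rowturn.arc_planner import (
    ArcSpec,
    PlannerInput,
    arc_angle,
    arc_center,
    arc_radius,
    plan_turn,
    sample_arc,
)
from rowturn.errors import DegenerateAzimuthError, InfeasibleTurnError

from .oracles import natural_spline_eval


class TestArcRadius:
    def test_lateral_limited(self):
        assert arc_radius(PlannerInput(Xw=2, Zw=5, beta_deg=90)) == 2.0

    def test_forward_limited(self):
        assert arc_radius(PlannerInput(Xw=-4, Zw=3, beta_deg=90)) == 3.0

    def test_below_minimum_raises(self):
        with pytest.raises(InfeasibleTurnError):
            arc_radius(PlannerInput(Xw=1, Zw=5, beta_deg=90, R_min=1.5))


class TestArcCenter:
    def test_lateral_case(self):
        inp = PlannerInput(Xw=2, Zw=5, beta_deg=90)
        np.testing.assert_allclose(arc_center(inp, 2.0), [2, 0, 3])

    def test_forward_case_negative_x(self):
        inp = PlannerInput(Xw=-6, Zw=3, beta_deg=90)
        np.testing.assert_allclose(arc_center(inp, 3.0), [-3, 0, 0])

    def test_equality_case(self):
        inp = PlannerInput(Xw=4, Zw=4, beta_deg=90)
        np.testing.assert_allclose(arc_center(inp, 4.0), [4, 0, 0])


class TestArcAngle:
    def test_positive_branch(self):
        assert arc_angle(90.0) == 90.0

    def test_negative_branch(self):
        assert arc_angle(-30.0) == 150.0

    def test_zero_raises(self):
        with pytest.raises(DegenerateAzimuthError):
            arc_angle(0.0)

    def test_branches_partition_half_turn(self):
        """alpha(b) + alpha(-b) = 180 for all b in (0, 180): the positive
        and negative azimuth branches split the half turn."""
        for b in np.linspace(1, 179, 89):
            assert arc_angle(b) + arc_angle(-b) == pytest.approx(180.0)


class TestSampleArc:
    def test_forward_case_starts_at_origin(self):
        spec = ArcSpec(R=3.0, O=(3.0, 0.0, 0.0), alpha_deg=90.0, turn_direction="left")
        pts = sample_arc(spec, 10)
        np.testing.assert_allclose(pts[0], [0, 0, 0], atol=1e-12)

    def test_lateral_quarter_arc_ends_at_target(self):
        spec = ArcSpec(R=2.0, O=(2.0, 0.0, 3.0), alpha_deg=90.0, turn_direction="left")
        pts = sample_arc(spec, 50)
        np.testing.assert_allclose(pts[-1], [2, 0, 5], atol=1e-12)

    def test_all_points_on_circle(self):
        spec = ArcSpec(R=2.5, O=(-2.5, 0.0, 1.0), alpha_deg=135.0, turn_direction="right")
        pts = sample_arc(spec, 200)
        radii = np.linalg.norm(pts - np.asarray(spec.O), axis=1)
        np.testing.assert_allclose(radii, spec.R, atol=1e-12)


class TestPlanTurn:
    def test_lead_in_then_quarter_arc(self):
        path = plan_turn(PlannerInput(Xw=2, Zw=5, beta_deg=90), n=50)
        np.testing.assert_allclose(path.waypoints[0], [0, 0, 0], atol=1e-12)
        # the lead-in runs along X=0 up to the arc start (0, 0, 3)
        lead = path.waypoints[path.waypoints[:, 2] <= 3.0 + 1e-9]
        np.testing.assert_allclose(lead[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(path.waypoints[-1], [2, 0, 5], atol=1e-12)
        assert path.terminal_offset == pytest.approx(0.0, abs=1e-12)

    def test_path_length_bounds_distance(self):
        path = plan_turn(PlannerInput(Xw=3, Zw=6, beta_deg=45), n=80)
        seglens = np.linalg.norm(np.diff(path.waypoints, axis=0), axis=1)
        assert seglens.sum() >= np.linalg.norm(path.waypoints[-1] - path.waypoints[0])

    def test_mirror_symmetry_across_forward_axis(self):
        p_left = plan_turn(PlannerInput(Xw=2.5, Zw=6, beta_deg=70), n=40)
        p_right = plan_turn(PlannerInput(Xw=-2.5, Zw=6, beta_deg=70), n=40)
        mirrored = p_left.waypoints * [-1, 1, 1]
        np.testing.assert_allclose(p_right.waypoints, mirrored, atol=1e-12)

    def test_spline_interpolates_waypoints(self):
        path = plan_turn(PlannerInput(Xw=2, Zw=5, beta_deg=90), n=30)
        # exact interpolation at the knots
        at_knots = np.column_stack([path._cs_x(path._knots), path._cs_z(path._knots)])
        np.testing.assert_allclose(at_knots, path.waypoints[:, [0, 2]], atol=1e-9)
        # resampling spans origin to terminal point
        dense = path.evaluate(300)
        np.testing.assert_allclose(dense[0], path.waypoints[0], atol=1e-9)
        np.testing.assert_allclose(dense[-1], path.waypoints[-1], atol=1e-9)

    def test_propagates_guard_errors(self):
        with pytest.raises(InfeasibleTurnError):
            plan_turn(PlannerInput(Xw=0.5, Zw=5, beta_deg=90))
        with pytest.raises(DegenerateAzimuthError):
            plan_turn(PlannerInput(Xw=2, Zw=5, beta_deg=0.0))


class TestSpline:
    def test_segments_are_c2_continuous(self):
        path = plan_turn(PlannerInput(Xw=2, Zw=5, beta_deg=90), n=25)
        for channel in ("x", "z"):
            segs = sorted([s for s in path.spline if s.channel == channel],
                          key=lambda s: s.x_lo)
            for a, b in zip(segs, segs[1:]):
                h = a.x_hi - a.x_lo
                val_a = a.a + a.b * h + a.c * h**2 + a.d * h**3
                d1_a = a.b + 2 * a.c * h + 3 * a.d * h**2
                d2_a = 2 * a.c + 6 * a.d * h
                assert val_a == pytest.approx(b.a, abs=1e-9)
                assert d1_a == pytest.approx(b.b, abs=1e-9)
                assert d2_a == pytest.approx(2 * b.c, abs=1e-9)

    def test_matches_tridiagonal_oracle(self, rng):
        """scipy-backed smoothing equals an independent natural-spline
        solve on random waypoint sets."""
        from scipy.interpolate import CubicSpline

        for _ in range(10):
            n = int(rng.integers(4, 12))
            x = np.sort(rng.uniform(0, 10, n))
            while np.any(np.diff(x) < 1e-3):
                x = np.sort(rng.uniform(0, 10, n))
            y = rng.uniform(-5, 5, n)
            cs = CubicSpline(x, y, bc_type="natural")
            xq = np.linspace(x[0], x[-1], 57)
            np.testing.assert_allclose(cs(xq), natural_spline_eval(x, y, xq),
                                       atol=1e-9)
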