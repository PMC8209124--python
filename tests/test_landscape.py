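"""Genus-line regression, collinearity, trajectories and path integrals."""

import math

import numpy as np
import pytest

from paceshape.cohorts import synthetic_genus_params
from paceshape.landscape import (
    GenusLine,
    PopulationPoint,
    SingularPathError,
    collinearity,
    fit_genus_line,
    parameter_trajectory,
    path_integral_change,
    perturbation_curve,
    rank_parameter_changes,
)
from paceshape.sensitivity import SensitivityVector, gradient_vector
from paceshape.siler import PARAM_NAMES, QuadratureConfig, SilerParams, pace_shape_summary

WIDE = QuadratureConfig(max_upper=2000.0)


@pytest.fixture(scope="module")
def genus():
    params = synthetic_genus_params()
    pts = [pace_shape_summary(p) for p in params]
    line = fit_genus_line([(s.e, s.epsilon) for s in pts], params_list=params)
    return params, pts, line


@pytest.fixture(scope="module")
def const_line():
    """Constant-hazard family c: 0.2 -> 0.1, i.e. e: 5 -> 10 along eps = 0.

    Sampled densely so the interpolated trajectory follows c(e) = 1/e.
    """
    plist = [SilerParams(-30.0, 1.0, 1.0 / e, -30.0, 0.0) for e in np.linspace(5.0, 10.0, 11)]
    pts = [pace_shape_summary(p, WIDE) for p in plist]
    return fit_genus_line([(s.e, s.epsilon) for s in pts], params_list=plist)


class TestFitGenusLine:
    def test_two_points_exact(self):
        line = fit_genus_line([(10.0, 1.0), (20.0, 2.0)], weights=[2.0, 5.0])
        assert line.beta0 == pytest.approx(0.0, abs=1e-10)
        assert line.beta1 == pytest.approx(0.1, rel=1e-10)

    def test_ols_hand_values(self):
        line = fit_genus_line([(0.0, 0.0), (1.0, 1.0), (2.0, 4.0)])
        assert line.beta1 == pytest.approx(2.0, rel=1e-10)
        assert line.beta0 == pytest.approx(-1.0 / 3.0, rel=1e-10)

    def test_weighted_normal_equations_oracle(self):
        pts = [(0.0, 0.0), (1.0, 1.0), (2.0, 4.0)]
        w = np.array([1.0, 1.0, 4.0])
        X = np.column_stack([np.ones(3), [p[0] for p in pts]])
        y = np.array([p[1] for p in pts])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        line = fit_genus_line(pts, weights=list(w))
        assert line.beta0 == pytest.approx(beta[0], rel=1e-10)
        assert line.beta1 == pytest.approx(beta[1], rel=1e-10)

    def test_equal_weights_is_ols(self):
        pts = [(0.0, 0.1), (1.0, 0.9), (2.0, 2.3), (3.0, 2.9)]
        a = fit_genus_line(pts)
        b = fit_genus_line(pts, weights=[7.0] * 4)
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-12)

    def test_slope_significance_fields(self, genus):
        _, _, line = genus
        assert line.slope_se > 0
        assert 0 <= line.p_value < 0.05
        assert line.beta1 > 0

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            fit_genus_line([(1.0, 0.0), (1.0, 1.0)])


class TestPerturbationCurve:
    def test_single_value_is_current_point(self, theta_star):
        (pt,) = perturbation_curve(theta_star, "c", [theta_star.c])
        s = pace_shape_summary(theta_star)
        assert pt == pytest.approx((s.e, s.epsilon), rel=1e-9)

    def test_background_curve_on_zero_equality(self):
        base = SilerParams(-30.0, 1.0, 0.2, -30.0, 0.0)
        curve = perturbation_curve(base, "c", [0.1, 0.2, 0.4], WIDE)
        for e, eps in curve:
            assert abs(eps) < 1e-6

    def test_ageing_chord_most_perpendicular(self, genus):
        # perturbing the rate of ageing cuts across the genus line; the
        # early-life parameters move populations along it
        params, _, line = genus
        mid = parameter_trajectory(line)(sum(line.e_range) / 2.0)
        cos = {}
        for name in ("a0", "a1", "c", "b1"):
            v = getattr(mid, name)
            lo, hi = pace_shape_summary(mid.replace(**{name: 0.5 * v})), \
                pace_shape_summary(mid.replace(**{name: 1.5 * v}))
            chord = np.array([hi.e - lo.e, hi.epsilon - lo.epsilon])
            chord /= np.linalg.norm(chord)
            d = line.direction
            cos[name] = abs(chord @ d)
        assert cos["b1"] < min(cos["a0"], cos["a1"], cos["c"])


class TestCollinearity:
    def test_parallel_and_perpendicular(self):
        line = GenusLine(0.0, 0.5, 0.0, 0.0, (0.0, 1.0), ())
        par = SensitivityVector("c", 2.0, 1.0)
        perp = SensitivityVector("c", -0.5, 1.0)
        assert collinearity(line, par) == pytest.approx(1.0, rel=1e-12)
        assert collinearity(line, perp) == pytest.approx(0.0, abs=1e-12)

    def test_forty_five_degrees(self):
        assert collinearity(0.0, SensitivityVector("c", 1.0, 1.0)) == pytest.approx(
            1.0 / math.sqrt(2.0), rel=1e-12
        )

    def test_scale_invariance(self, genus):
        _, _, line = genus
        v = SensitivityVector("c", -3.0, -0.4)
        v10 = SensitivityVector("c", -30.0, -4.0)
        assert collinearity(line, v) == pytest.approx(collinearity(line, v10), rel=1e-12)

    def test_zero_vector_rejected(self, genus):
        _, _, line = genus
        with pytest.raises(ValueError):
            collinearity(line, SensitivityVector("c", 0.0, 0.0))

    def test_genus_ordering_early_life_most_collinear(self, genus):
        params, _, line = genus
        med = {
            name: np.median([collinearity(line, gradient_vector(p)[name]) for p in params])
            for name in PARAM_NAMES
        }
        for early in ("a0", "a1", "c"):
            assert med[early] > med["b0"]
        assert med["b0"] > med["b1"]


class TestParameterTrajectory:
    def test_endpoints_exact(self, genus):
        params, pts, line = genus
        traj = parameter_trajectory(line)
        for p, s in ((params[0], pts[0]), (params[-1], pts[-1])):
            got = traj(s.e)
            for name in PARAM_NAMES:
                assert getattr(got, name) == pytest.approx(getattr(p, name), rel=1e-9)

    def test_only_varying_parameter_moves(self):
        plist = [SilerParams(-2.0, 1.0, c, -5.0, 0.15) for c in (0.05, 0.02, 0.008)]
        pts = [pace_shape_summary(p) for p in plist]
        line = fit_genus_line([(s.e, s.epsilon) for s in pts], params_list=plist)
        traj = parameter_trajectory(line)
        mid = traj(sum(line.e_range) / 2.0)
        assert mid.a0 == pytest.approx(-2.0, rel=1e-12)
        assert mid.b1 == pytest.approx(0.15, rel=1e-12)
        assert plist[2].c < mid.c < plist[0].c

    def test_clamped_to_range(self, genus):
        params, _, line = genus
        traj = parameter_trajectory(line)
        assert traj(line.e_range[0] - 5.0) == traj(line.e_range[0])

    def test_single_population_rejected(self):
        p = SilerParams(-2.0, 1.0, 0.01, -5.0, 0.15)
        s = pace_shape_summary(p)
        line = GenusLine(0.0, 0.1, 0.0, 0.5, (s.e, s.e + 1.0),
                         (PopulationPoint(s.e, s.epsilon, 1.0, p),))
        with pytest.raises(ValueError):
            parameter_trajectory(line)

    def test_interpolated_points_stay_near_line(self, genus):
        # diagnostic: the trajectory's own (e, eps) curve should hug the line
        _, _, line = genus
        traj = parameter_trajectory(line)
        for e in np.linspace(*line.e_range, 7):
            s = pace_shape_summary(traj(float(e)))
            assert abs(s.epsilon - line.predict(s.e)) < 0.25


class TestPathIntegral:
    def test_background_analytic_value(self, const_line):
        # halving c doubles e: unscaled Theta = -log 2, length 5, |Theta| = log2/5
        traj = parameter_trajectory(const_line)
        res = path_integral_change(const_line, traj, "c", n_segments=200, quad=WIDE)
        assert res.unscaled == pytest.approx(-math.log(2.0), abs=1e-3)
        assert abs(res.theta_total) == pytest.approx(math.log(2.0) / 5.0, abs=1e-3)

    def test_reversal_flips_sign(self, const_line):
        traj = parameter_trajectory(const_line)
        fwd = path_integral_change(const_line, traj, "c", n_segments=100, quad=WIDE)
        import dataclasses

        rev_line = dataclasses.replace(const_line, e_range=const_line.e_range[::-1])
        rev = path_integral_change(rev_line, traj, "c", n_segments=100, quad=WIDE)
        assert rev.theta_total == pytest.approx(-fwd.theta_total, rel=1e-9)

    def test_segment_refinement_converges(self, genus):
        params, _, line = genus
        traj = parameter_trajectory(line)
        r200 = path_integral_change(line, traj, "c", n_segments=200)
        r400 = path_integral_change(line, traj, "c", n_segments=400)
        assert abs(r400.theta_total - r200.theta_total) < 1e-3 * abs(r200.theta_total)

    def test_singular_path_reported(self, genus):
        # eps_b0 crosses zero along this genus line: a genuine improper integral
        params, _, line = genus
        traj = parameter_trajectory(line)
        with pytest.raises(SingularPathError, match="b0"):
            path_integral_change(line, traj, "b0", n_segments=50)

    def test_unknown_param_rejected(self, const_line):
        traj = parameter_trajectory(const_line)
        with pytest.raises(ValueError):
            path_integral_change(const_line, traj, "zz")


class TestRankParameterChanges:
    def test_single_varying_parameter_dominates_ageing(self):
        plist = [SilerParams(-2.0, 1.0, c, -5.0, 0.15) for c in (0.06, 0.025, 0.01)]
        pts = [pace_shape_summary(p) for p in plist]
        line = fit_genus_line([(s.e, s.epsilon) for s in pts], params_list=plist)
        traj = parameter_trajectory(line)
        rank, errors = rank_parameter_changes(line, traj, n_segments=60)
        d = dict(rank)
        assert d["c"] > d["b1"]

    def test_synthetic_genus_early_life_dominates(self, genus):
        params, _, line = genus
        traj = parameter_trajectory(line)
        rank, errors = rank_parameter_changes(line, traj, n_segments=60)
        d = dict(rank)
        for early in ("a0", "a1", "c"):
            assert early in d and d[early] > d["b1"]
        assert "b0" in errors  # reported singularity, not silently dropped
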