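"""Feedback-loop ODE model: nullclines, fixed points, phase structure."""

from dataclasses import replace

import numpy as np
import pytest

from mirswitch import (
    FeedbackParams,
    InvalidInputError,
    critical_beta,
    find_fixed_points,
    nullcline_X_of_Y,
    nullcline_Y_of_X,
    phase_diagram,
    rhs,
    saddle_node_alphas,
    simulate_trajectory,
    steady_state_curve,
)

# regression fixtures frozen from the scalar-reduction + bisection solver,
# cross-checked against a brute-force 2-D residual scan
REF_STABLE_LOW = (0.058520, 0.401100)    # low-miRNA / high-ERK point
REF_STABLE_HIGH = (0.995242, 0.006914)   # high-miRNA / low-ERK point
# saddle-node boundaries of the bistable window at beta=10, gamma=1
REF_ALPHA_ON = 5.2029
REF_ALPHA_OFF = 12.3184


def brute_force_fixed_points(params, n=3000):
    """Independent oracle: residual sign-scan of F on a dense linear Y grid."""
    Y = np.linspace(1e-9, 1 - 1e-9, n)
    X = nullcline_X_of_Y(params, Y)
    F = Y * (1 + params.gamma + (params.alpha * X) ** params.n_1) - params.gamma
    sign = np.signbit(F)
    brackets = np.nonzero(sign[:-1] != sign[1:])[0]
    out = []
    from scipy.optimize import brentq

    def f(y):
        x = nullcline_X_of_Y(params, y)
        return y * (1 + params.gamma + (params.alpha * x) ** params.n_1) - params.gamma

    for i in brackets:
        y = brentq(f, Y[i], Y[i + 1], xtol=1e-14)
        out.append((float(nullcline_X_of_Y(params, y)), float(y)))
    return sorted(out)


class TestRhs:
    def test_no_erk_repression_settles_at_dosage(self, feedback_params):
        dx, _ = rhs(feedback_params, X=1.0, Y=0.0)
        assert dx == pytest.approx(0.0, abs=1e-14)

    def test_no_mirna_repression_erk_settles_at_gamma_fraction(self):
        p = FeedbackParams(alpha=0.0, beta=10.0, gamma=1.0)
        _, dy = rhs(p, X=0.3, Y=p.gamma / (1 + p.gamma))
        assert dy == pytest.approx(0.0, abs=1e-14)

    def test_reference_fixed_point_annihilates_both_derivatives(self, feedback_params):
        dx, dy = rhs(feedback_params, *REF_STABLE_HIGH)
        assert abs(dx) < 1e-5 and abs(dy) < 1e-5  # rounded fixture coordinates


class TestNullclines:
    def test_y_nullcline_at_origin(self):
        p = FeedbackParams(alpha=12.0, beta=10.0, gamma=1.0)
        assert nullcline_Y_of_X(p, 0.0) == pytest.approx(0.5)

    def test_x_nullcline_at_zero_erk(self):
        p = FeedbackParams(alpha=12.0, beta=10.0, gamma=1.0)
        assert nullcline_X_of_Y(p, 0.0) == pytest.approx(1.0)

    def test_hand_evaluated_point(self):
        p = FeedbackParams(alpha=12.0, beta=10.0, gamma=1.0)
        assert nullcline_Y_of_X(p, 1.0) == pytest.approx(1.0 / 146.0, rel=1e-12)

    def test_each_nullcline_zeroes_its_own_equation(self, feedback_params):
        X = np.linspace(0.0, 1.0, 17)
        Y = nullcline_Y_of_X(feedback_params, X)
        _, dy = rhs(feedback_params, X, Y)
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)
        Yq = np.linspace(0.0, 1.0, 17)
        Xq = nullcline_X_of_Y(feedback_params, Yq)
        dx, _ = rhs(feedback_params, Xq, Yq)
        np.testing.assert_allclose(dx, 0.0, atol=1e-12)


class TestFindFixedPoints:
    def test_decoupled_system_has_one_stable_point(self):
        p = FeedbackParams(alpha=0.0, beta=10.0, gamma=1.0)
        fps = find_fixed_points(p)
        assert len(fps) == 1 and fps[0].stable

    def test_reference_set_is_bistable_with_saddle(self, feedback_params):
        fps = find_fixed_points(feedback_params)
        assert [fp.stability for fp in fps] == ["stable", "saddle", "stable"]
        assert fps[0].X == pytest.approx(REF_STABLE_LOW[0], abs=1e-4)
        assert fps[0].Y == pytest.approx(REF_STABLE_LOW[1], abs=1e-4)
        assert fps[2].X == pytest.approx(REF_STABLE_HIGH[0], abs=1e-4)
        assert fps[2].Y == pytest.approx(REF_STABLE_HIGH[1], abs=1e-4)

    def test_heterozygote_dosage_remains_bistable(self, feedback_params):
        fps = find_fixed_points(replace(feedback_params, dosage=0.5))
        assert sum(fp.stable for fp in fps) == 2

    def test_residuals_below_tolerance(self, feedback_params):
        for fp in find_fixed_points(feedback_params):
            dx, dy = rhs(feedback_params, fp.X, fp.Y)
            assert abs(dx) < 1e-9 and abs(dy) < 1e-9

    @pytest.mark.parametrize("alpha,beta,gamma", [
        (12.0, 10.0, 1.0), (3.0, 10.0, 1.0), (20.0, 10.0, 1.0),
        (12.0, 10.0, 0.2), (8.0, 5.0, 2.0), (0.5, 2.0, 1.0),
    ])
    def test_matches_brute_force_oracle(self, alpha, beta, gamma):
        p = FeedbackParams(alpha=alpha, beta=beta, gamma=gamma)
        got = find_fixed_points(p)
        expected = brute_force_fixed_points(p)
        assert len(got) == len(expected)
        for fp, (x, y) in zip(got, expected):
            assert fp.X == pytest.approx(x, abs=1e-9)
            assert fp.Y == pytest.approx(y, abs=1e-9)

    def test_count_is_odd_and_stability_alternates(self, feedback_params):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = FeedbackParams(alpha=float(rng.uniform(0, 30)), beta=10.0,
                               gamma=float(np.exp(rng.uniform(-2, 2))))
            fps = find_fixed_points(p)
            assert len(fps) in (1, 3)
            if len(fps) == 3:
                assert [fp.stability for fp in fps] == ["stable", "saddle", "stable"]

    def test_dosage_monotonicity(self, feedback_params):
        wt = [fp.X for fp in find_fixed_points(feedback_params) if fp.stable]
        het = [fp.X for fp in find_fixed_points(replace(feedback_params, dosage=0.5))
               if fp.stable]
        assert all(h <= w for h, w in zip(het, wt))


class TestStability:
    def test_perturbations_decay_around_stable_points(self, feedback_params):
        for fp in find_fixed_points(feedback_params):
            if not fp.stable:
                continue
            out = simulate_trajectory(feedback_params, fp.X + 1e-3,
                                      min(fp.Y + 1e-3, 1.0), 60.0, 0.5)
            assert out["terminal"][0] == pytest.approx(fp.X, abs=1e-6)
            assert out["terminal"][1] == pytest.approx(fp.Y, abs=1e-6)

    def test_saddle_perturbation_escapes(self, feedback_params):
        saddle = [fp for fp in find_fixed_points(feedback_params)
                  if fp.stability == "saddle"][0]
        out = simulate_trajectory(feedback_params, saddle.X + 1e-3, saddle.Y,
                                  80.0, 0.5)
        dist = np.hypot(out["terminal"][0] - saddle.X, out["terminal"][1] - saddle.Y)
        assert dist > 0.05


class TestPhaseDiagram:
    def test_no_feedback_beta_zero_monostable(self):
        pd_ = phase_diagram(np.linspace(0, 20, 12), np.geomspace(0.05, 20, 12), 0.0)
        assert np.all(pd_.n_stable == 1)

    def test_beta_ten_has_bistable_region(self):
        alphas = np.concatenate([[0.0], np.geomspace(0.1, 20, 30)])
        gammas = np.geomspace(0.05, 20, 30)
        pd_ = phase_diagram(alphas, gammas, 10.0)
        assert pd_.bistable_mask.any()
        assert set(np.unique(pd_.n_stable)) <= {1, 2}
        # the zero-alpha column is always monostable
        assert np.all(pd_.n_stable[0] == 1)

    def test_reference_point_inside_bistable_region(self):
        pd_ = phase_diagram(np.array([12.0]), np.array([1.0]), 10.0)
        assert pd_.n_stable[0, 0] == 2


class TestSteadyStateCurve:
    def test_alpha_zero_single_zero_level(self):
        df = steady_state_curve(np.array([0.0]), 10.0, 1.0)
        assert df["n_stable"].iloc[0] == 1
        assert df["M_low"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_regimes_in_order(self):
        df = steady_state_curve(np.linspace(0, 20, 81), 10.0, 1.0)
        regimes = df["regime"].tolist()
        # contiguous blocks: low, bistable, high
        assert regimes[0] == "low" and regimes[-1] == "high"
        first_b = regimes.index("bistable")
        last_b = len(regimes) - 1 - regimes[::-1].index("bistable")
        assert all(r == "low" for r in regimes[:first_b])
        assert all(r == "bistable" for r in regimes[first_b:last_b + 1])
        assert all(r == "high" for r in regimes[last_b + 1:])

    def test_saddle_node_regression_values(self):
        a_on, a_off = saddle_node_alphas(10.0, 1.0, tol=1e-4)
        assert a_on == pytest.approx(REF_ALPHA_ON, abs=5e-4)
        assert a_off == pytest.approx(REF_ALPHA_OFF, abs=5e-4)


class TestCriticalBeta:
    def test_no_bistability_below_two(self):
        assert critical_beta(beta_grid=np.arange(1.0, 1.95, 0.05)) is None

    def test_small_scan_finds_onset_just_above_two(self):
        b = critical_beta(beta_grid=np.arange(2.0, 2.5, 0.05))
        assert b is not None and 2.0 < b <= 2.2

    def test_non_cooperative_arms_cannot_be_bistable(self):
        b = critical_beta(
            beta_grid=np.arange(1.0, 20.0, 0.5),
            alpha_grid=np.concatenate([[0.0], np.logspace(-2, 3, 120)]),
            gamma_grid=np.logspace(-2, 2, 60),
            n_E=1.0, n_1=1.0)
        assert b is None


class TestTrajectory:
    def test_start_at_stable_point_stays(self, feedback_params):
        fp = [p for p in find_fixed_points(feedback_params) if p.stable][0]
        out = simulate_trajectory(feedback_params, fp.X, fp.Y, 20.0, 0.5)
        assert out["distance_to_fixed_point"] < 1e-9

    def test_converges_to_a_stable_point_and_stays_in_domain(self, feedback_params):
        out = simulate_trajectory(feedback_params, 1.0, 1.0, 100.0, 0.1)
        assert out["basin_index"] is not None
        assert out["distance_to_fixed_point"] < 1e-6
        assert np.all(out["X"] >= -1e-12)
        assert np.all((out["Y"] >= -1e-12) & (out["Y"] <= 1.0 + 1e-12))

    def test_zero_dt_rejected(self, feedback_params):
        with pytest.raises(InvalidInputError):
            simulate_trajectory(feedback_params, 0.5, 0.5, 10.0, 0.0)
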