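"""Tests for flow-pair generation and the RK4-templated RHS learner."""

import numpy as np
import pytest
from scipy.stats import kstest

from emergent.rhs_learning import (
    FlowPairSet,
    RK4NetConfig,
    _rk4_loss_and_grads,
    _MLP,
    baseline_euler_gh,
    generate_flow_pairs,
    integrate_learned,
    oa_fixed_point,
    oa_flow,
    oa_time_to_reach,
    ott_antonsen_rhs,
    rk4_step,
    train_rhs_net,
)


class TestOttAntonsen:
    def test_reference_values(self):
        assert ott_antonsen_rhs(0.0) == 0.0
        assert ott_antonsen_rhs(1.0, K=2.0, gamma=0.5) == pytest.approx(-0.5)
        assert oa_fixed_point(2.0, 0.5) == pytest.approx(np.sqrt(0.5))
        assert ott_antonsen_rhs(oa_fixed_point(2.0, 0.5)) == pytest.approx(0.0, abs=1e-15)
        assert oa_fixed_point(1.0, 0.5) == 0.0  # subcritical

    def test_closed_form_flow_matches_quadrature(self):
        from scipy.integrate import solve_ivp

        for r0 in (0.05, 0.4, 0.95):
            sol = solve_ivp(
                lambda _t, y: ott_antonsen_rhs(y),
                (0, 4.0),
                [r0],
                rtol=1e-12,
                atol=1e-12,
            )
            assert oa_flow(r0, 4.0) == pytest.approx(sol.y[0, -1], abs=1e-9)

    def test_time_inversion_round_trips(self):
        t = oa_time_to_reach(0.05, 0.6)
        assert oa_flow(0.05, t) == pytest.approx(0.6, abs=1e-12)
        t = oa_time_to_reach(1.0, 0.75)
        assert oa_flow(1.0, t) == pytest.approx(0.75, abs=1e-12)

    def test_crossing_the_fixed_point_is_unreachable(self):
        with pytest.raises(ValueError, match="attainable"):
            oa_time_to_reach(0.2, 0.9)


class TestRk4Step:
    def test_zero_rhs_is_identity(self):
        y = np.array([[0.3]])
        assert rk4_step(lambda z: np.zeros_like(z), y, 0.1) == pytest.approx(y)

    def test_linear_rhs_reproduces_degree_four_taylor(self):
        lam, dt, y0 = -0.7, 0.2, 1.3
        stepped = rk4_step(lambda y: lam * y, y0, dt)
        x = lam * dt
        taylor = y0 * (1 + x + x**2 / 2 + x**3 / 6 + x**4 / 24)
        assert stepped == pytest.approx(taylor, rel=1e-15)

    def test_fixed_point_is_exactly_stationary(self):
        r = oa_fixed_point()
        assert rk4_step(lambda y: ott_antonsen_rhs(y), r, 0.05) == pytest.approx(
            r, abs=1e-14
        )

    def test_single_step_error_scales_as_dt_to_the_fifth(self):
        lam, y0 = -1.0, 1.0
        dts = np.array([0.1, 0.05, 0.025])
        errs = np.array(
            [abs(rk4_step(lambda y: lam * y, y0, dt) - np.exp(lam * dt)) for dt in dts]
        )
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert abs(slope - 5.0) < 0.3


class TestBackprop:
    def test_rk4_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = _MLP([1, 5, 5, 1], rng)
        y = rng.uniform(0, 1, (12, 1))
        target = rng.uniform(0, 1, (12, 1))
        dt = 0.05
        loss, gw, gb = _rk4_loss_and_grads(net, y, target, dt)
        eps = 1e-6
        for arr, grad in [(net.weights[1], gw[1]), (net.biases[0], gb[0])]:
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(3):
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = _rk4_loss_and_grads(net, y, target, dt)
                arr[idx] = orig - eps
                lm, _, _ = _rk4_loss_and_grads(net, y, target, dt)
                arr[idx] = orig
                assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-10)
                it.iternext()


class TestFlowPairs:
    def test_generated_pairs_cover_coherence_range_uniformly(self, flow_pairs_by_dt):
        for dt, pairs in flow_pairs_by_dt.items():
            assert pairs.dt == dt
            assert len(pairs) == 500
            assert kstest(pairs.y_start, "uniform").statistic < 0.08

    def test_branches_stay_on_their_side_of_the_fixed_point(self, flow_pairs_by_dt):
        pairs = flow_pairs_by_dt[0.01]
        r_star = oa_fixed_point()
        # allow slack for finite-size fluctuation of the effective fixed point
        assert np.all(pairs.y_start[pairs.branch == 0] < r_star + 0.05)
        assert np.all(pairs.y_start[pairs.branch == 1] > r_star - 0.05)

    def test_same_seed_is_bit_identical(self):
        a = generate_flow_pairs(n_pairs=20, dt=0.01, n_oscillators=300, seed=9)
        b = generate_flow_pairs(n_pairs=20, dt=0.01, n_oscillators=300, seed=9)
        assert np.array_equal(a.y_start, b.y_start)
        assert np.array_equal(a.y_end, b.y_end)

    def test_end_values_follow_the_flow_direction(self, flow_pairs_by_dt):
        pairs = flow_pairs_by_dt[0.05]
        drift = pairs.y_end - pairs.y_start
        expected = ott_antonsen_rhs(pairs.y_start) * pairs.dt
        # correlation, not equality: individual pairs carry ensemble noise
        assert np.corrcoef(drift, expected)[0, 1] > 0.9

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            generate_flow_pairs(n_pairs=10, dt=-0.01)
        with pytest.raises(ValueError):
            generate_flow_pairs(n_pairs=10, dt=0.015, step=0.01)
        with pytest.raises(ValueError, match="attainable"):
            generate_flow_pairs(n_pairs=10, dt=0.01, r_lo=0.9)


class TestTraining:
    def test_recovers_known_cubic_rhs_from_exact_pairs(self):
        # closed-loop identifiability: pairs generated by rk4_step on a
        # known cubic; the trained sub-network must recover it.
        rng = np.random.default_rng(5)
        f = lambda y: 0.5 * y - y**3
        y0 = rng.uniform(0, 1, 400)
        y1 = rk4_step(f, y0, 0.05)
        pairs = FlowPairSet(y_start=y0, y_end=y1, dt=0.05)
        model = train_rhs_net(
            pairs, RK4NetConfig(epochs=40000, seed=1, lr_schedule="cosine")
        )
        grid = np.linspace(y0.min(), y0.max(), 200)
        assert np.max(np.abs(model.rhs(grid) - f(grid))) < 5e-3
        assert model.train_loss[-1] < model.train_loss[0]

    def test_training_is_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        y0 = rng.uniform(0, 1, 100)
        pairs = FlowPairSet(y_start=y0, y_end=rk4_step(lambda y: -y, y0, 0.01), dt=0.01)
        m1 = train_rhs_net(pairs, RK4NetConfig(epochs=50, seed=3))
        m2 = train_rhs_net(pairs, RK4NetConfig(epochs=50, seed=3))
        assert np.array_equal(m1.train_loss, m2.train_loss)
        for w1, w2 in zip(m1.net.weights, m2.net.weights):
            assert np.array_equal(w1, w2)

    def test_too_few_pairs_rejected(self):
        pairs = FlowPairSet(y_start=np.linspace(0, 1, 10), y_end=np.linspace(0, 1, 10), dt=0.1)
        with pytest.raises(ValueError):
            train_rhs_net(pairs)

    def test_model_json_round_trip(self):
        rng = np.random.default_rng(7)
        from emergent.rhs_learning import RHSModel

        y0 = rng.uniform(0, 1, 100)
        pairs = FlowPairSet(y_start=y0, y_end=rk4_step(lambda y: -y, y0, 0.01), dt=0.01)
        model = train_rhs_net(pairs, RK4NetConfig(epochs=20, seed=0))
        clone = RHSModel.from_json(model.to_json())
        grid = np.linspace(0, 1, 17)
        assert clone.rhs(grid) == pytest.approx(model.rhs(grid), abs=1e-12)


@pytest.fixture(scope="module")
def phi_result():
    """Scaled discovered-coordinate pipeline: 300 pairs of N = 2000
    oscillators at dt = 0.05, coherence targets capped at 0.97 — the
    density featurization degenerates at the fully synchronized end (all
    mass in one bin), and at reduced sampling the few near-delta
    snapshots disconnect the kernel graph."""
    from emergent.rhs_learning import learn_phi_dynamics

    pairs = generate_flow_pairs(
        n_pairs=300,
        dt=0.05,
        n_oscillators=2000,
        seed=201,
        retain_phases=True,
        r_hi=0.97,
    )
    result = learn_phi_dynamics(pairs, net_config=RK4NetConfig(epochs=20000, seed=7))
    return pairs, result


class TestPhiDynamics:
    """Learning the evolution law of the discovered coordinate phi_1."""

    def test_joint_embedding_has_one_significant_eigenfunction(self, phi_result):
        _, result = phi_result
        assert result.embedding.significant == [1]

    def test_phi1_is_one_to_one_with_coherence(self, phi_result):
        _, result = phi_result
        assert abs(result.diagnostics["spearman_phi_vs_R"]) > 0.99

    def test_learned_phi_fixed_point_maps_to_coherence_fixed_point(self, phi_result):
        pairs, result = phi_result
        phi_all = result.embedding.phi(1)
        traj = integrate_learned(
            result.model, float(np.median(phi_all)), np.linspace(0.0, 40.0, 81)
        )
        # invert the monotone phi(R) correspondence by a smoothed
        # interpolant of the joint-embedding scatter
        r_all = np.concatenate([pairs.y_start, pairs.y_end])
        order = np.argsort(phi_all)
        r_smooth = np.convolve(r_all[order], np.ones(25) / 25, mode="same")
        r_star_learned = np.interp(traj[-1], phi_all[order], r_smooth)
        assert abs(r_star_learned - oa_fixed_point()) < 0.03

    def test_pairs_without_phases_rejected(self):
        from emergent.rhs_learning import learn_phi_dynamics

        pairs = FlowPairSet(
            y_start=np.linspace(0, 1, 60), y_end=np.linspace(0, 1, 60), dt=0.05
        )
        with pytest.raises(ValueError, match="retain"):
            learn_phi_dynamics(pairs)


class TestIntegrateLearned:
    def test_zero_rhs_gives_constant_trajectory(self):
        out = integrate_learned(lambda y: 0.0 * y, 0.4, np.linspace(0, 1, 5))
        assert out == pytest.approx(np.full(5, 0.4))

    def test_analytic_rhs_matches_closed_form(self):
        t = np.linspace(0, 6, 61)
        out = integrate_learned(
            lambda y: ott_antonsen_rhs(y), 0.1, t, max_step=0.01
        )
        assert np.max(np.abs(out - oa_flow(0.1, t))) < 1e-6


class TestEulerGHBaseline:
    def test_constant_rhs_estimated_exactly(self):
        y0 = np.linspace(0, 0.9, 60)
        c = 0.37
        pairs = FlowPairSet(y_start=y0, y_end=y0 + c * 0.05, dt=0.05)
        baseline = baseline_euler_gh(pairs)
        assert baseline.raw_estimates == pytest.approx(np.full(60, c), abs=1e-9)

    def test_smoothing_beats_raw_euler_scatter(self, flow_pairs_by_dt):
        pairs = flow_pairs_by_dt[0.01]
        baseline = baseline_euler_gh(pairs, n_gh=10)
        truth_at_samples = ott_antonsen_rhs(pairs.y_start)
        rmse_raw = np.sqrt(np.mean((baseline.raw_estimates - truth_at_samples) ** 2))
        grid = np.linspace(0.05, 0.95, 200)
        rmse_gh = np.sqrt(np.mean((baseline(grid) - ott_antonsen_rhs(grid)) ** 2))
        assert rmse_gh < rmse_raw

    def test_default_harmonic_count_is_ten(self, flow_pairs_by_dt):
        baseline = baseline_euler_gh(flow_pairs_by_dt[0.05])
        assert len(baseline.gh_model.eigenvalues) == 10
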