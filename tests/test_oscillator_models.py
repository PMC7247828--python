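"""Unit and property tests for the Kuramoto-family simulators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emergent.oscillator_models import (
    OscillatorEnsemble,
    save_chung_lu_network,
    integrate_to_sync,
    kuramoto_rhs,
    kuramoto_rhs_pairwise,
    make_chung_lu_network,
    chung_lu_weights,
    order_parameter,
    order_parameter_series,
    phase_density,
    sample_cauchy_frequencies,
    simulate,
    to_rotating_frame,
    wrap_phases,
    Trajectory,
)


class TestCauchyFrequencies:
    def test_quartile_values_match_quantile_function(self):
        # gamma tan(pi (u - 1/2)) at u = 1/4, 1/2, 3/4
        omega = sample_cauchy_frequencies(0.5, 3, tail_cap=0.25)
        assert omega == pytest.approx([-0.5, 0.0, 0.5], abs=1e-12)

    @pytest.mark.parametrize("n", [3, 11, 8001])
    def test_symmetric_with_zero_median_for_odd_n(self, n):
        omega = sample_cauchy_frequencies(1.3, n)
        assert np.median(omega) == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(omega, -omega[::-1])

    def test_tail_cap_bounds_extreme_frequency(self):
        omega = sample_cauchy_frequencies(0.5, 8000, tail_cap=2.5e-4)
        expected = 0.5 * np.tan(np.pi * (0.5 - 2.5e-4))
        assert np.max(np.abs(omega)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "gamma,cap", [(-1.0, 0.1), (0.0, 0.1), (0.5, 0.5), (0.5, 0.7)]
    )
    def test_invalid_parameters_raise(self, gamma, cap):
        with pytest.raises(ValueError):
            sample_cauchy_frequencies(gamma, 10, tail_cap=cap)


class TestChungLu:
    def test_first_weight_is_n_times_p(self):
        w = chung_lu_weights(4000, 0.5, 0.9, 0.5)
        assert w[0] == pytest.approx(4000 * 0.5)
        # last weight from direct substitution of i = N
        expected_last = 4000 * 0.5 * (1 - 0.9 * 3999 / 4000) ** 0.5
        assert w[-1] == pytest.approx(expected_last)

    def test_adjacency_invariants(self):
        net = make_chung_lu_network(300, 0.5, 0.9, 0.5, seed=0)
        a = net.adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)
        assert set(np.unique(a)) <= {0, 1}
        assert np.allclose(net.probabilities, net.probabilities.T)
        assert net.probabilities.max() <= 1.0
        assert np.array_equal(net.degrees, a.sum(axis=1))

    def test_realized_degree_concentrates_on_expected_degree(self):
        # Monte-Carlo over adjacency draws: mean degree of each node within
        # 3 standard errors of the row sum of the edge probabilities.
        n, draws = 60, 300
        w = chung_lu_weights(n, 0.5, 0.9, 0.5)
        prob = np.minimum(np.outer(w, w) / w.sum(), 1.0)
        np.fill_diagonal(prob, 0.0)
        expected = prob.sum(axis=1)
        degs = np.array(
            [
                make_chung_lu_network(n, 0.5, 0.9, 0.5, seed=s).degrees
                for s in range(draws)
            ]
        )
        se = np.sqrt((prob * (1 - prob)).sum(axis=1) / draws)
        assert np.all(np.abs(degs.mean(axis=0) - expected) <= 3.0 * se + 1e-9)

    def test_negative_base_with_fractional_exponent_raises(self):
        with pytest.raises(ValueError):
            chung_lu_weights(100, 0.5, 1.5, 0.5)

    def test_network_persists_to_edge_list_and_metadata(self, tmp_path):
        import json
        import pandas as pd

        net = make_chung_lu_network(50, 0.5, 0.9, 0.5, seed=4)
        save_chung_lu_network(net, tmp_path / "edges.csv", tmp_path / "meta.json")
        edges = pd.read_csv(tmp_path / "edges.csv")
        assert len(edges) == net.adjacency.sum() // 2
        meta = json.loads((tmp_path / "meta.json").read_text())
        assert meta["p"] == 0.5 and meta["seed"] == 4
        assert meta["weights"]["first"] == pytest.approx(50 * 0.5)

    def test_alternate_weight_grouping_available(self):
        w = chung_lu_weights(100, 0.5, 0.9, 2.0, variant="exponent-inside")
        i = np.arange(1, 101)
        assert np.allclose(w, 100 * 0.5 * (1 - 0.9 * ((i - 1) / 100) ** 2))


class TestRhs:
    def test_identical_phases_give_natural_frequencies(self):
        omega = np.array([0.3, -1.2, 2.0])
        for coupling in (1.5, np.array([1.0, 2.0, 3.0])):
            ens = OscillatorEnsemble(
                phases=np.full(3, 0.7), frequencies=omega, coupling=coupling
            )
            assert kuramoto_rhs(ens) == pytest.approx(omega)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(2, 200),
        seed=st.integers(0, 2**31 - 1),
        hetero=st.booleans(),
    )
    def test_mean_field_identity_matches_pairwise_sum(self, n, seed, hetero):
        rng = np.random.default_rng(seed)
        coupling = rng.uniform(0.5, 5.0, n) if hetero else float(rng.uniform(0.5, 5.0))
        ens = OscillatorEnsemble(
            phases=rng.uniform(0, 2 * np.pi, n),
            frequencies=rng.standard_cauchy(n),
            coupling=coupling,
        )
        assert np.max(np.abs(kuramoto_rhs(ens) - kuramoto_rhs_pairwise(ens))) <= 1e-12

    def test_network_variant_matches_pairwise_sum(self):
        rng = np.random.default_rng(5)
        net = make_chung_lu_network(40, 0.5, 0.9, 0.5, seed=1)
        ens = OscillatorEnsemble(
            phases=rng.uniform(0, 2 * np.pi, 40),
            frequencies=rng.normal(size=40),
            coupling=3.0,
            adjacency=net.adjacency.astype(float),
        )
        assert kuramoto_rhs(ens) == pytest.approx(kuramoto_rhs_pairwise(ens), abs=1e-12)

    def test_firing_fixed_point_is_stationary(self):
        rng = np.random.default_rng(2)
        omega = rng.uniform(-0.5, 0.5, 20)
        alpha = np.where(rng.random(20) < 0.5, -1.0, 1.0) * rng.uniform(0.8, 2.0, 20)
        theta = -np.arcsin(omega / alpha)
        ens = OscillatorEnsemble(
            phases=theta, frequencies=omega, coupling=np.zeros(20), alpha=alpha
        )
        assert kuramoto_rhs(ens) == pytest.approx(np.zeros(20), abs=1e-12)

    def test_adjacency_with_per_oscillator_coupling_is_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous"):
            OscillatorEnsemble(
                phases=np.zeros(3),
                frequencies=np.zeros(3),
                coupling=np.ones(3),
                adjacency=np.zeros((3, 3)),
            )


class TestSimulate:
    def test_uncoupled_oscillator_grows_linearly(self):
        ens = OscillatorEnsemble(
            phases=np.zeros(1), frequencies=np.array([1.7]), coupling=0.0
        )
        traj = simulate(ens, np.array([0.3]), np.linspace(0, 5, 11))
        assert traj.phases[:, 0] == pytest.approx(0.3 + 1.7 * traj.times, abs=1e-4)

    def test_two_identical_oscillators_synchronize(self):
        ens = OscillatorEnsemble(
            phases=np.zeros(2), frequencies=np.array([1.0, 1.0]), coupling=2.0
        )
        traj = simulate(
            ens, np.array([0.0, 2.5]), np.linspace(0, 30, 31), atol=1e-10, rtol=1e-8
        )
        gap = wrap_phases(traj.phases[-1, 0] - traj.phases[-1, 1])
        assert abs(gap) < 1e-3

    def test_sync_integrator_reaches_steady_state(self):
        rng = np.random.default_rng(3)
        ens = OscillatorEnsemble(
            phases=np.zeros(50),
            frequencies=rng.uniform(-1, 1, 50),
            coupling=rng.uniform(10, 100, 50),
        )
        theta, t = integrate_to_sync(ens, rng.uniform(0, 2 * np.pi, 50))
        from emergent.oscillator_models import rotating_frame_velocities

        assert np.max(np.abs(rotating_frame_velocities(ens, theta))) < 1e-4


class TestObservables:
    def test_order_parameter_reference_values(self):
        r, psi = order_parameter(np.full(5, np.pi))
        assert (r, psi) == pytest.approx((1.0, np.pi))
        r, _ = order_parameter(np.linspace(0, 2 * np.pi, 8, endpoint=False))
        assert r == pytest.approx(0.0, abs=1e-12)
        r, psi = order_parameter(np.array([0.0, np.pi / 2]))
        assert (r, psi) == pytest.approx((np.sqrt(2) / 2, np.pi / 4))

    def test_order_parameter_empty_input_raises(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n=st.integers(1, 300), seed=st.integers(0, 2**31 - 1))
    def test_permutation_invariance_is_bit_identical(self, n, seed):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-10, 10, n)
        perm = rng.permutation(n)
        # R and psi are sums over oscillators; summation order changes, so
        # compare the sorted summands instead for bitwise invariance of the
        # density, and to tight tolerance for R/psi.
        assert order_parameter(phases) == pytest.approx(
            order_parameter(phases[perm]), abs=1e-12
        )
        d1 = phase_density(phases)
        d2 = phase_density(phases[perm])
        assert np.array_equal(d1.counts, d2.counts)

    def test_rotating_frame_zeroes_mean_phase_and_preserves_r(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(0, 2 * np.pi, (20, 100)) + rng.normal(0, 0.2, (20, 1))
        traj = Trajectory(times=np.arange(20.0), phases=phases)
        rot = to_rotating_frame(traj)
        series = order_parameter_series(rot)
        assert np.max(np.abs(series.psi)) < 1e-10
        orig = order_parameter_series(traj)
        assert series.R == pytest.approx(orig.R, abs=1e-12)

    def test_rigid_rotation_becomes_stationary(self):
        c = np.array([0.1, 0.5, -0.4, 0.2])
        t = np.linspace(0, 3, 7)
        phases = c[None, :] + 2.0 * t[:, None]
        rot = to_rotating_frame(Trajectory(times=t, phases=phases))
        assert np.ptp(rot.phases, axis=0) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_phase_density_mass_and_wrapping(self):
        d = phase_density(np.zeros(37))
        assert d.counts.sum() == 37
        assert d.counts.max() == 37
        assert d.normalized.sum() == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, 500)
        assert np.array_equal(
            phase_density(phases).counts, phase_density(phases + 2 * np.pi).counts
        )

    def test_uniform_phases_fill_bins_binomially(self):
        rng = np.random.default_rng(4)
        n = 100_000
        d = phase_density(rng.uniform(-np.pi, np.pi, n))
        expect = n / 200
        sigma = np.sqrt(n * (1 / 200) * (1 - 1 / 200))
        assert np.all(np.abs(d.counts - expect) < 5 * sigma)
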