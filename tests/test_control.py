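import numpy as np
import pytest
from scipy.linalg import expm

from conftest import random_stable_system
from oracles import lsq_min_energy

from fosnet.control import (
    ControlSpec,
    ControlSystem,
    minimum_control_energy,
    normalize_system,
    pairwise_transition_energies,
    persistence_energy,
    receptor_weighted_energy,
    suppress_set,
    suppression_profile,
)
from fosnet.regions import RegionSet
from fosnet.synthio import ReceptorMap


class TestNormalizeSystem:
    def test_zero_matrix_gives_negative_identity(self):
        assert np.allclose(normalize_system(np.zeros((2, 2))), -np.eye(2))

    def test_known_spectral_radius(self):
        A = np.array([[0.0, 3.0], [3.0, 0.0]])  # lambda_max = 3
        assert np.allclose(normalize_system(A, c=1.0), A / 4.0 - np.eye(2))

    def test_random_matrices_stabilized(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(2, 8)
            A = rng.uniform(0, 2, size=(n, n))
            np.fill_diagonal(A, 0)
            Astar = normalize_system(A)
            assert np.max(np.linalg.eigvals(Astar).real) < 0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_system(np.array([[0.0, -1.0], [0.0, 0.0]]))


class TestMinimumControlEnergy:
    def test_zero_transition_zero_energy(self):
        rng = np.random.default_rng(1)
        Astar, _, _ = random_stable_system(rng, n=3)
        res = minimum_control_energy(Astar, ControlSpec(), np.zeros(3), np.zeros(3))
        assert res.energy == 0.0
        assert res.residual == 0.0

    def test_scalar_closed_form(self):
        """A* = -1, T = 1: W = (1 - e^-2)/2, E = 2/(1 - e^-2)."""
        res = minimum_control_energy(np.array([[-1.0]]), ControlSpec(), np.array([0.0]), np.array([1.0]))
        assert res.energy == pytest.approx(2.0 / (1.0 - np.exp(-2.0)), abs=1e-9)

    def test_agrees_with_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Astar, x0, xf = random_stable_system(rng, n=3)
            res = minimum_control_energy(Astar, ControlSpec(), x0, xf)
            oracle = lsq_min_energy(Astar, np.eye(3), x0, xf)
            assert res.energy == pytest.approx(oracle, rel=0.01)

    def test_gramian_symmetric_psd(self):
        rng = np.random.default_rng(2)
        Astar, _, _ = random_stable_system(rng, n=4)
        W = ControlSystem(Astar, ControlSpec()).gramian()
        assert np.allclose(W, W.T)
        assert np.min(np.linalg.eigvalsh(W)) > -1e-12

    def test_energy_quadratic_in_displacement(self):
        rng = np.random.default_rng(3)
        Astar, _, xf = random_stable_system(rng, n=4)
        sys_ = ControlSystem(Astar, ControlSpec())
        e1 = sys_.energy(np.zeros(4), xf).energy
        e3 = sys_.energy(np.zeros(4), 3.0 * xf).energy
        assert e3 == pytest.approx(9.0 * e1, rel=1e-10)

    def test_integration_converged(self):
        """Doubling the grid changes the energy by < 0.01%."""
        rng = np.random.default_rng(4)
        Astar, x0, xf = random_stable_system(rng, n=4)
        e1 = minimum_control_energy(Astar, ControlSpec(n_steps=1001), x0, xf).energy
        e2 = minimum_control_energy(Astar, ControlSpec(n_steps=2001), x0, xf).energy
        assert abs(e2 - e1) / e1 < 1e-4

    def test_optimal_input_reaches_target(self):
        """The returned trajectories integrate to xf."""
        rng = np.random.default_rng(5)
        Astar, x0, xf = random_stable_system(rng, n=3)
        res = minimum_control_energy(Astar, ControlSpec(), x0, xf, return_trajectories=True)
        assert np.allclose(res.x[0], x0)
        assert np.allclose(res.x[-1], xf, atol=1e-6 * max(1, np.linalg.norm(xf)))
        # and the input energy integrates (trapezoid) to the reported energy
        h = res.t[1] - res.t[0]
        e_num = np.trapezoid((res.u**2).sum(axis=1), dx=h)
        assert e_num == pytest.approx(res.energy, rel=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ControlSpec(T=0)
        with pytest.raises(ValueError):
            ControlSpec(n_steps=100)  # even
        with pytest.raises(ValueError):
            ControlSpec(B_weights=np.zeros(3))


class TestSuppression:
    def _gramian_direct(self, Astar, w, T=1.0, K=801):
        """Independent Gramian: Simpson on explicit expm calls with B=diag(w)."""
        ts = np.linspace(0, T, K)
        B = np.diag(w)
        vals = np.array([expm(Astar * t) @ B @ B.T @ expm(Astar.T * t) for t in ts])
        s = np.ones(K)
        s[1:-1:2], s[2:-1:2] = 4.0, 2.0
        s *= (T / (K - 1)) / 3.0
        return np.einsum("k,kij->ij", s, vals)

    def test_no_suppression_zero_percent(self):
        rng = np.random.default_rng(6)
        Astar, x0, xf = random_stable_system(rng, n=4)
        sys_ = ControlSystem(Astar, ControlSpec())
        e = sys_.energy(x0, xf, weights=np.ones(4)).energy
        assert e == pytest.approx(sys_.energy(x0, xf).energy)

    def test_profile_nonnegative(self):
        rng = np.random.default_rng(7)
        Astar, x0, xf = random_stable_system(rng, n=4)
        prof = suppression_profile(Astar, ControlSpec(), x0, xf)
        assert np.all(prof.percent_increase >= -1e-7)

    def test_profile_matches_direct_recomputation(self):
        """4-node toy system: each entry equals an independent Gramian rebuild."""
        rng = np.random.default_rng(8)
        Astar, x0, xf = random_stable_system(rng, n=4)
        spec = ControlSpec(n_steps=801)
        prof = suppression_profile(Astar, spec, x0, xf)
        W_full = self._gramian_direct(Astar, np.ones(4))
        v = xf - expm(Astar) @ x0
        e_full = v @ np.linalg.pinv(W_full, rcond=1e-10) @ v
        for k in range(4):
            w = np.ones(4)
            w[k] = 0.0
            Wk = self._gramian_direct(Astar, w)
            ek = v @ np.linalg.pinv(Wk, rcond=1e-10) @ v
            assert prof.percent_increase[k] == pytest.approx(100.0 * (ek / e_full - 1.0), rel=1e-4, abs=1e-6)

    def test_set_suppression_monotone_in_set_size(self):
        rng = np.random.default_rng(9)
        Astar, x0, xf = random_stable_system(rng, n=5)
        sys_ = ControlSystem(Astar, ControlSpec())

        def energy_without(idx):
            w = np.ones(5)
            w[list(idx)] = 0.0
            return sys_.energy(x0, xf, weights=w).energy

        assert energy_without([0, 2]) >= energy_without([0]) - 1e-9 * energy_without([0])

    def test_empty_target_rejected(self):
        rng = np.random.default_rng(10)
        Astar, x0, xf = random_stable_system(rng, n=4)
        with pytest.raises(ValueError):
            suppress_set(Astar, ControlSpec(), x0, xf, [])
        with pytest.raises(ValueError):
            suppress_set(Astar, ControlSpec(), x0, xf, list(range(4)))

    def test_high_influence_set_beats_random_subsets(self):
        """A target set engineered as high-influence yields a positive t."""
        rng = np.random.default_rng(11)
        n = 10
        A = rng.uniform(0.5, 1.5, size=(n, n))
        # the first three regions receive almost no projections, so their
        # state is nearly unreachable without direct control input
        A[:3, :] *= 0.01
        np.fill_diagonal(A, 0.0)
        Astar = normalize_system(A)
        x0 = np.zeros(n)
        xf = rng.normal(size=n)
        res = suppress_set(Astar, ControlSpec(), x0, xf, [0, 1, 2], n_random_sets=50, seed=1)
        assert res.t_stat > 0
        assert res.null_percent_increase.mean() < res.percent_increase


class TestReceptorWeighting:
    def _map(self, n, mu):
        regions = RegionSet([f"r{i}" for i in range(n)], {f"r{i}": "cortex" for i in range(n)})
        dens = {"mu": np.asarray(mu, float), "delta": np.ones(n), "kappa": np.ones(n)}
        return ReceptorMap(regions=regions, density=dens)

    def test_uniform_density_equals_full_control(self):
        rng = np.random.default_rng(12)
        Astar, x0, xf = random_stable_system(rng, n=4)
        rmap = self._map(4, [7.0, 7.0, 7.0, 7.0])
        e_mu = receptor_weighted_energy(Astar, rmap, x0, xf, "mu", ControlSpec())
        e_full = minimum_control_energy(Astar, ControlSpec(), x0, xf)
        assert e_mu.energy == pytest.approx(e_full.energy, rel=1e-10)

    def test_inverse_square_scaling_in_weights(self):
        rng = np.random.default_rng(13)
        Astar, x0, xf = random_stable_system(rng, n=4)
        sys_ = ControlSystem(Astar, ControlSpec())
        w = rng.uniform(0.5, 2.0, size=4)
        for c in (0.5, 2.0, 10.0):
            e1 = sys_.energy(x0, xf, weights=w).energy
            e2 = sys_.energy(x0, xf, weights=c * w).energy
            assert e2 == pytest.approx(e1 / c**2, rel=1e-8)

    def test_zero_weight_equals_suppression(self):
        rng = np.random.default_rng(14)
        Astar, x0, xf = random_stable_system(rng, n=4)
        sys_ = ControlSystem(Astar, ControlSpec())
        w = np.ones(4)
        w[2] = 0.0
        e_w = sys_.energy(x0, xf, weights=w).energy
        prof = suppression_profile(Astar, ControlSpec(), x0, xf)
        e_full = prof.full_energy
        assert e_w == pytest.approx(e_full * (1 + prof.percent_increase[2] / 100.0), rel=1e-9)


class TestPersistence:
    def test_zero_state_free(self):
        rng = np.random.default_rng(15)
        Astar, _, _ = random_stable_system(rng, n=3)
        assert persistence_energy(Astar, ControlSpec(), np.zeros(3)).energy == 0.0

    def test_nonzero_state_costs_energy(self):
        rng = np.random.default_rng(16)
        Astar, x0, _ = random_stable_system(rng, n=3)
        assert persistence_energy(Astar, ControlSpec(), x0 + 1.0).energy > 0

    def test_scalar_closed_form(self):
        """A* = -1, x = 1, T = 1: v = 1 - e^-1, E = v^2 / W ~= 0.9242."""
        e = persistence_energy(np.array([[-1.0]]), ControlSpec(), np.array([1.0]))
        v = 1.0 - np.exp(-1.0)
        W = (1.0 - np.exp(-2.0)) / 2.0
        assert e.energy == pytest.approx(v**2 / W, abs=1e-9)


class TestPairwiseEnergies:
    def test_single_pair_equals_point_energy(self):
        rng = np.random.default_rng(17)
        Astar, x0, xf = random_stable_system(rng, n=4)
        E = pairwise_transition_energies(Astar, ControlSpec(), x0[None, :], xf[None, :])
        point = minimum_control_energy(Astar, ControlSpec(), x0, xf)
        assert E.shape == (1, 1)
        assert E[0, 0] == pytest.approx(point.energy, rel=1e-10)

    def test_three_by_three_grid(self):
        rng = np.random.default_rng(18)
        Astar, _, _ = random_stable_system(rng, n=4)
        X0 = rng.normal(size=(3, 4))
        Xf = rng.normal(size=(3, 4))
        E = pairwise_transition_energies(Astar, ControlSpec(), X0, Xf)
        assert E.shape == (3, 3)
        for i in range(3):
            for j in range(3):
                ref = minimum_control_energy(Astar, ControlSpec(), X0[i], Xf[j]).energy
                assert E[i, j] == pytest.approx(ref, rel=1e-9)

    def test_identical_states_diagonal_is_persistence(self):
        rng = np.random.default_rng(19)
        Astar, _, _ = random_stable_system(rng, n=4)
        X = rng.normal(size=(3, 4))
        E = pairwise_transition_energies(Astar, ControlSpec(), X, X)
        for i in range(3):
            p = persistence_energy(Astar, ControlSpec(), X[i]).energy
            assert E[i, i] == pytest.approx(p, rel=1e-9)
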