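"""Slow-manifold analysis: degenerate solutions, Morse index, escape
times, ecomode preconditioning, linearized drift, PCA embedding."""

import numpy as np
import pytest

from illcond_eco import (
    Ecosystem,
    EnsembleParams,
    degenerate_solutions,
    ecomode_projections,
    embed_trajectories,
    escape_time,
    integrate,
    linearized_drift,
    morse_index,
    preconditioning_ratio,
    rhs,
    sample_ecosystem,
)
from illcond_eco.dynamics import Trajectory

from conftest import perturbed_pair_eco


class TestDegenerateSolutions:
    def test_identity_P_single_cluster(self):
        eco = sample_ecosystem(EnsembleParams(N=10, epsilon=0.0, seed=2,
                                              rho=0.5))
        rng = np.random.default_rng(0)
        sols = degenerate_solutions(eco, [rng.uniform(0, 1, 10)
                                          for _ in range(5)])
        assert len(sols) == 1
        assert sols[0].n_members == 5

    def test_duplicate_pair_degenerate_line(self, duplicate_pair_eco):
        """Two mixtures of an exact redundant pair end at two distinct
        points on the same degenerate line n1 + n2 = 1."""
        sols = degenerate_solutions(
            duplicate_pair_eco,
            [np.array([0.8, 0.1]), np.array([0.1, 0.8])],
            with_morse=False)
        assert len(sols) == 2
        for s in sols:
            assert s.point.sum() == pytest.approx(1.0, abs=1e-8)

    def test_endpoints_satisfy_degenerate_complementarity(self):
        """Every deduplicated endpoint of the eps=0 dynamics satisfies the
        degenerate complementarity conditions (oracle residual check)."""
        eco = sample_ecosystem(EnsembleParams(
            N=40, M=5, epsilon=1e-3, assignment_mode="random-groups",
            seed=6))
        A0 = eco.epsilon_zero().A
        rng = np.random.default_rng(1)
        sols = degenerate_solutions(
            eco, [rng.uniform(0, 1, 40) for _ in range(8)],
            with_morse=False)
        assert len(sols) >= 1
        for s in sols:
            growth = eco.r + A0 @ s.point
            support = s.point > 1e-6 * s.point[s.point > 0].mean()
            assert np.max(np.abs(growth[support])) < 1e-6
            if np.any(~support):
                assert np.max(growth[~support]) < 1e-6


class TestMorseIndex:
    def test_stable_equilibrium_is_zero(self, stable20):
        from illcond_eco import find_equilibrium

        res = find_equilibrium(stable20,
                               np.random.default_rng(0).uniform(0, 1, 20))
        assert morse_index(stable20, res.n_star) == 0.0

    def test_half_unstable(self):
        # J = diag(n) A = diag(1, -1) at n = (1,1), r = -A n
        eco = Ecosystem(A=np.diag([1.0, -1.0]), r=np.array([-1.0, 1.0]))
        assert morse_index(eco, np.ones(2)) == 0.5

    def test_matches_eigenvalue_count_oracle(self):
        from scipy.linalg import eig

        from illcond_eco import jacobian

        eco = sample_ecosystem(EnsembleParams(
            N=15, M=3, epsilon=1e-3, assignment_mode="random-groups",
            seed=3))
        point = np.random.default_rng(4).uniform(0, 1, 15)
        lam = eig(jacobian(point, eco), right=False)
        expected = np.sum(lam.real > 1e-10 * np.abs(lam).max()) / 15
        assert morse_index(eco, point) == pytest.approx(expected)


class TestEscapeTime:
    def _linear_path(self):
        # 1-D path x(t) = 3 - t on t in [0, 6]; ball |x| <= 1 entered at
        # t=2, left at t=4
        times = np.linspace(0, 6, 121)
        return Trajectory(times=times, states=(3.0 - times)[:, None],
                          terminal_reason="t-max")

    def test_constructed_crossings(self):
        traj = self._linear_path()
        assert escape_time(traj, np.zeros(1), radius=1.0) == \
            pytest.approx(2.0, abs=1e-6)

    def test_never_enters(self):
        traj = self._linear_path()
        assert escape_time(traj, np.array([100.0]), radius=1.0) is None

    def test_constant_at_point_counts_full_duration(self):
        times = np.linspace(0, 5, 11)
        traj = Trajectory(times=times, states=np.zeros((11, 2)),
                          terminal_reason="derivative-floor")
        assert escape_time(traj, np.zeros(2), radius=0.5) == \
            pytest.approx(5.0)

    def test_per_visit_episodes(self):
        # |x(t)| dips below 1 twice: x = 2 cos(t) on [0, 2 pi]
        times = np.linspace(0, 2 * np.pi, 401)
        traj = Trajectory(times=times,
                          states=(2 * np.cos(times))[:, None],
                          terminal_reason="t-max")
        episodes = escape_time(traj, np.zeros(1), radius=1.0,
                               per_visit=True)
        assert len(episodes) == 2
        # each dwell: cos(t) in [-1/2, 1/2] lasts 2 pi/3 - ... = pi/3 * 2
        assert np.allclose(episodes, 2 * np.pi / 3 - np.pi / 3, atol=0.05)


class TestEcomodes:
    def test_full_K_preserves_kappa(self):
        from illcond_eco import condition_number

        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 8)) + 2 * np.eye(8)
        proj = ecomode_projections(A, 8)
        assert preconditioning_ratio(A, proj.W_fast) == pytest.approx(
            1.0, rel=1e-8)
        assert condition_number(proj.W_fast @ A) == pytest.approx(
            condition_number(A), rel=1e-8)

    def test_diagonal_two_scale(self):
        A = np.diag([1.0, 1e-6])
        proj = ecomode_projections(A, 1)
        assert np.allclose(np.abs(proj.W_fast), [[1.0, 0.0]])
        assert preconditioning_ratio(A, proj.W_fast) == pytest.approx(
            1e-6, rel=1e-6)

    def test_fast_slow_orthogonal(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((12, 12))
        proj = ecomode_projections(A, 4)
        assert np.allclose(proj.W_fast @ proj.W_slow.T, 0.0, atol=1e-10)
        assert np.allclose(proj.W_fast @ proj.W_fast.T, np.eye(4),
                           atol=1e-10)

    def test_K_validation(self):
        with pytest.raises(ValueError):
            ecomode_projections(np.eye(3), 4)

    def test_nonorthonormal_W_rejected(self):
        with pytest.raises(ValueError):
            preconditioning_ratio(np.eye(3), np.array([[1.0, 1.0, 0.0]]))

    def test_redundant_instance_preconditions(self):
        """Desk-scale preconditioning: K=M projections cut kappa by at
        least 100x on an ill-conditioned instance."""
        eco = sample_ecosystem(EnsembleParams(
            N=100, M=10, epsilon=1e-4, assignment_mode="random-groups",
            seed=0))
        proj = ecomode_projections(eco.A, 10)
        assert preconditioning_ratio(eco.A, proj.W_fast) < 1e-2
        assert preconditioning_ratio(eco.A, proj.W_slow) < 1e-2


class TestLinearizedDrift:
    def test_zero_at_eps_zero(self, duplicate_pair_eco):
        _, drift = linearized_drift(duplicate_pair_eco,
                                    np.array([0.5, 0.5]))
        assert np.all(drift == 0.0)

    def test_linear_in_eps(self):
        point = np.array([0.4, 0.6])
        _, d1 = linearized_drift(perturbed_pair_eco(1e-4), point)
        _, d2 = linearized_drift(perturbed_pair_eco(2e-4), point)
        assert np.allclose(d2, 2 * d1)

    def test_taylor_remainder(self):
        """community @ delta + drift approximates rhs near a point on the
        degenerate solution set, to order eps*|delta| + |delta|^2."""
        eco = perturbed_pair_eco(1e-4, seed=2)
        point = np.array([0.3, 0.7])  # on the eps=0 line n1+n2=1
        community, drift = linearized_drift(eco, point)
        rng = np.random.default_rng(0)
        for scale in (1e-3, 1e-4):
            delta = scale * rng.standard_normal(2)
            exact = rhs(point + delta, eco)
            approx = community @ delta + drift
            err = np.linalg.norm(exact - approx)
            bound = 20 * (np.linalg.norm(delta) ** 2
                          + eco.epsilon * np.linalg.norm(delta))
            assert err <= bound


class TestEmbedding:
    def _pair_trajs(self, eco, n=4, t_max=30.0):
        rng = np.random.default_rng(5)
        return [integrate(eco, rng.uniform(0.05, 1.0, eco.N), t_max=t_max,
                          rtol=1e-10, atol=1e-10) for _ in range(n)]

    def test_full_rank_embedding_is_isometry(self, duplicate_pair_eco):
        trajs = self._pair_trajs(duplicate_pair_eco)
        bundle = embed_trajectories(trajs, duplicate_pair_eco, K=2,
                                    mesh_resolution=(5, 5))
        X = np.vstack([t.states for t in trajs])
        Y = np.vstack([e for e in bundle.embeddings])
        dx = np.linalg.norm(X[None] - X[:, None], axis=-1)
        dy = np.linalg.norm(Y[None] - Y[:, None], axis=-1)
        assert np.allclose(dx, dy, atol=1e-10)

    def test_inverse_transform_of_mean(self, duplicate_pair_eco):
        trajs = self._pair_trajs(duplicate_pair_eco)
        bundle = embed_trajectories(trajs, duplicate_pair_eco, K=2,
                                    mesh_resolution=(4, 4))
        X = np.vstack([t.states for t in trajs])
        mean_emb = bundle.pca.transform(X).mean(axis=0)
        back = bundle.pca.inverse_transform(mean_emb[None])[0]
        assert np.allclose(back, X.mean(axis=0), atol=1e-10)

    def test_mesh_velocity_matches_finite_differences(self,
                                                      duplicate_pair_eco):
        """At a point on a trajectory (in a smooth region), the projected
        mesh vector field aligns with the trajectory's finite-difference
        velocity (cosine > 0.99)."""
        trajs = self._pair_trajs(duplicate_pair_eco, n=3, t_max=3.0)
        bundle = embed_trajectories(trajs, duplicate_pair_eco, K=2,
                                    mesh_resolution=(40, 40))
        traj = trajs[0]
        k = len(traj.times) // 3
        state = traj.states[k]
        emb = bundle.pca.transform(state[None])[0, :2]
        # finite-difference velocity, projected
        h = 1e-4 * max(1.0, traj.times[-1])
        v_fd = (traj(traj.times[k] + h) - traj(traj.times[k] - h)) / (2 * h)
        v_fd2 = bundle.pca.components_[:2] @ v_fd
        # nearest mesh cell's velocity
        idx = np.argmin(np.linalg.norm(bundle.mesh - emb, axis=1))
        v_mesh = bundle.mesh_velocity[idx]
        cos = (v_fd2 @ v_mesh) / (np.linalg.norm(v_fd2)
                                  * np.linalg.norm(v_mesh))
        assert cos > 0.99

    def test_too_few_trajectories_rejected(self, duplicate_pair_eco):
        with pytest.raises(ValueError):
            embed_trajectories([], duplicate_pair_eco, K=2)

    def test_K_exceeding_N_rejected(self, duplicate_pair_eco):
        trajs = self._pair_trajs(duplicate_pair_eco, n=2)
        with pytest.raises(ValueError):
            embed_trajectories(trajs, duplicate_pair_eco, K=3)
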