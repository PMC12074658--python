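"""Ensemble samplers: assignment matrices, sparsification, reconstruction,
the scaled-interaction ensemble, and diagonal stability."""

import numpy as np
import pytest

from illcond_eco import (
    BuninParams,
    EnsembleParams,
    check_diagonal_stability,
    sample_assignment_matrix,
    sample_bunin_ecosystem,
    sample_ecosystem,
)
from illcond_eco.ensembles import PercolationWarning


def svd_rank(A, tol=1e-10):
    s = np.linalg.svd(A, compute_uv=False)
    return int(np.sum(s > tol * s[0]))


class TestAssignmentMatrix:
    def test_identity(self):
        P = sample_assignment_matrix(3, 3, "identity")
        assert np.array_equal(P, np.eye(3))
        assert svd_rank(P) == 3

    def test_duplicate_explicit_pair(self):
        # column 0 duplicated at position 2: species 2 clones species 0
        P = sample_assignment_matrix(3, 2, "duplicate-columns",
                                     np.random.default_rng(0),
                                     duplicates=[(0, 2)])
        expected = np.eye(3)
        expected[:, 2] = expected[:, 0]
        assert np.array_equal(P, expected)
        assert svd_rank(P) == 2

    @pytest.mark.parametrize("mode,N,M", [
        ("duplicate-columns", 20, 5),
        ("random-groups", 20, 5),
        ("random-low-rank", 15, 4),
    ])
    def test_rank_exactly_M(self, mode, N, M):
        P = sample_assignment_matrix(N, M, mode, np.random.default_rng(42))
        assert svd_rank(P) == M

    def test_random_groups_all_nonempty(self):
        P = sample_assignment_matrix(12, 11, "random-groups",
                                     np.random.default_rng(1))
        # every group row used at least once
        assert np.all(P[:11].sum(axis=1) >= 1)

    def test_errors(self):
        with pytest.raises(ValueError):
            sample_assignment_matrix(3, 4, "identity")
        with pytest.raises(ValueError):
            sample_assignment_matrix(3, 2, "identity")
        with pytest.raises(ValueError):
            sample_assignment_matrix(3, 3, "duplicate-columns",
                                     np.random.default_rng(0))


class TestSampling:
    def test_sparsification_exact_count(self):
        eco = sample_ecosystem(EnsembleParams(N=100, seed=0, rho=0.05))
        off = ~np.eye(100, dtype=bool)
        n_zero = int(np.sum(eco.A[off] == 0.0))
        assert n_zero == int(np.floor(0.95 * 100 * 99))
        assert np.all(eco.A[np.diag_indices(100)] != 0.0)

    def test_reconstructibility_bit_identical(self):
        p = EnsembleParams(N=40, M=8, epsilon=1e-3,
                           assignment_mode="random-groups", seed=5)
        a, b = sample_ecosystem(p), sample_ecosystem(p)
        assert np.array_equal(a.A, b.A)
        assert np.array_equal(a.r, b.r)
        assert np.array_equal(a.mask, b.mask)

    @pytest.mark.parametrize("sparsify", ["group-level", "post-hoc"])
    def test_epsilon_counterpart_difference(self, sparsify):
        p = EnsembleParams(N=50, M=10, epsilon=1e-3,
                           assignment_mode="random-groups",
                           sparsify_mode=sparsify, seed=3)
        eco = sample_ecosystem(p)
        diff = eco.A - eco.epsilon_zero().A
        assert np.allclose(diff, 1e-3 * eco.masked_E(), atol=1e-15)

    def test_group_level_rank_deficiency(self):
        p = EnsembleParams(N=30, M=6, epsilon=0.0,
                           assignment_mode="random-groups", seed=2)
        eco = sample_ecosystem(p)
        assert svd_rank(eco.A) <= 6

    def test_posthoc_mask_applied_to_A(self):
        p = EnsembleParams(N=30, M=6, epsilon=1e-3,
                           assignment_mode="random-groups",
                           sparsify_mode="post-hoc", seed=2)
        eco = sample_ecosystem(p)
        assert np.all(eco.A[~eco.mask] == 0.0)

    def test_identity_reduces_to_masked_baseline(self):
        p = EnsembleParams(N=25, epsilon=0.0, seed=9)
        eco = sample_ecosystem(p)
        expected = np.where(eco.mask, eco.A0, 0.0) - eco.d * np.eye(25)
        assert np.allclose(eco.A, expected)

    def test_redundant_r_lift(self):
        p = EnsembleParams(N=30, M=5, epsilon=1e-3,
                           assignment_mode="duplicate-columns", seed=4)
        eco = sample_ecosystem(p)
        # clones share growth rates: r determined by representative column
        reps = np.argmax(eco.P, axis=0)
        assert np.allclose(eco.r, eco.r[reps])
        p2 = EnsembleParams(N=30, M=5, epsilon=1e-3,
                            assignment_mode="duplicate-columns",
                            redundant_r=False, seed=4)
        eco2 = sample_ecosystem(p2)
        assert np.unique(eco2.r).size == 30

    def test_percolation_warning(self):
        with pytest.warns(PercolationWarning):
            EnsembleParams(N=20, rho=0.05)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            EnsembleParams(N=10, M=11)
        with pytest.raises(ValueError):
            EnsembleParams(N=10, epsilon=-1.0)
        with pytest.raises(ValueError):
            EnsembleParams(N=10, rho=0.0)


class TestBuninEnsemble:
    def test_gamma_one_symmetric(self):
        eco = sample_bunin_ecosystem(BuninParams(N=50, gamma=1.0, seed=0))
        assert np.allclose(eco.A, eco.A.T)

    def test_gamma_zero_uncorrelated(self):
        # Monte-Carlo estimate of corr(A'_ij, A'_ji) over 20 draws at N=200
        xs, ys = [], []
        for s in range(20):
            p = BuninParams(N=200, mu=0.0, sigma=np.sqrt(200), gamma=0.0,
                            seed=s)
            eco = sample_bunin_ecosystem(p)
            Ap = -(eco.A + np.eye(200))  # sigma/sqrt(N) = 1, mu = 0
            iu = np.triu_indices(200, k=1)
            xs.append(Ap[iu])
            ys.append(Ap.T[iu])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
        assert abs(x.var() - 1.0) < 0.05

    def test_mean_offdiagonal_matches_mu(self):
        p = BuninParams(N=100, mu=2.0, sigma=1.0, gamma=0.0, seed=1)
        eco = sample_bunin_ecosystem(p)
        off = ~np.eye(100, dtype=bool)
        # mean off-diagonal entry is -mu/N up to sigma/sqrt(N) fluctuations
        assert np.isclose(eco.A[off].mean(), -0.02,
                          atol=5 * 1.0 / np.sqrt(100) / np.sqrt(9900))

    def test_sigma_c(self):
        assert BuninParams(N=10, gamma=0.0).sigma_c == 2.0
        assert BuninParams(N=10, gamma=1.0).sigma_c == 1.0

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            BuninParams(N=10, gamma=1.5)


class TestDiagonalStability:
    def test_trivial_cases(self):
        assert check_diagonal_stability(-np.eye(3))
        assert not check_diagonal_stability(np.array([[1.0, 0.0],
                                                      [0.0, -1.0]]))
        with pytest.raises(ValueError):
            check_diagonal_stability(np.ones((2, 3)))

    def test_flips_at_bisected_d(self):
        """Sweeping d upward flips stability exactly where the eigenvalue
        oracle says the symmetric part becomes negative definite."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 30)) * (rng.random((30, 30)) < 0.2)
        # oracle: critical d is half the top eigenvalue of X + X^T
        d_star = np.linalg.eigvalsh(X + X.T)[-1] / 2.0
        lo, hi = 0.0, 10 * abs(d_star) + 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if check_diagonal_stability(X - mid * np.eye(30)):
                hi = mid
            else:
                lo = mid
        assert np.isclose(0.5 * (lo + hi), d_star, atol=1e-8)

    def test_sampled_ecosystems_are_stabilized(self):
        for seed in range(3):
            eco = sample_ecosystem(EnsembleParams(N=40, seed=seed))
            assert check_diagonal_stability(eco.A)


def test_ecosystem_roundtrip(tmp_path, stable20):
    stable20.save(tmp_path / "eco")
    loaded = type(stable20).load(tmp_path / "eco")
    assert np.array_equal(loaded.A, stable20.A)
    assert np.array_equal(loaded.r, stable20.r)
    assert loaded.params == stable20.params
    stable20.export_csv(tmp_path / "csv")
    header = (tmp_path / "csv" / "A.csv").read_text().splitlines()[0]
    assert header.split(",")[1] == "s0001"
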