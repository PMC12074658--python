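import numpy as np
import pytest

from illcond_eco import (
    Ecosystem,
    EnsembleParams,
    sample_ecosystem,
)


@pytest.fixture
def logistic_eco():
    """Single-species logistic growth: r = 1, self-limitation 1."""
    return Ecosystem(A=np.array([[-1.0]]), r=np.array([1.0]))


@pytest.fixture
def stable20():
    """Diagonally stable N=20 dense-metadata instance (identity P)."""
    return sample_ecosystem(EnsembleParams(N=20, seed=7))


@pytest.fixture
def redundant30():
    """Small ill-conditioned instance: N=30, M=5, eps=1e-3."""
    return sample_ecosystem(EnsembleParams(
        N=30, M=5, epsilon=1e-3, assignment_mode="random-groups", seed=11))


@pytest.fixture
def duplicate_pair_eco():
    """Exact two-species redundant pair at eps=0.

    A = -ones(2,2) arises from lifting X = -I through P = [[1,1],[0,0]]
    (species 2 duplicates species 1); with shared growth rate r = (1, 1)
    the equilibrium set is the whole line n1 + n2 = 1 and the ratio
    n1/n2 is conserved along trajectories.
    """
    params = EnsembleParams(N=2, M=1, epsilon=0.0,
                            assignment_mode="duplicate-columns", d=1.0)
    P = np.array([[1.0, 1.0], [0.0, 0.0]])
    return Ecosystem(A=-np.ones((2, 2)), r=np.ones(2), params=params,
                     P=P, A0=np.zeros((2, 2)), E=np.zeros((2, 2)),
                     mask=np.ones((2, 2), dtype=bool), d=1.0)


def perturbed_pair_eco(epsilon=1e-4, seed=0):
    """The duplicate-pair system with an eps E symmetry-breaking term."""
    from dataclasses import replace

    from illcond_eco.ensembles import _assemble

    rng = np.random.default_rng(seed)
    E = rng.standard_normal((2, 2))
    P = np.array([[1.0, 1.0], [0.0, 0.0]])
    A0 = np.zeros((2, 2))
    mask = np.ones((2, 2), dtype=bool)
    params = EnsembleParams(N=2, M=1, epsilon=epsilon,
                            assignment_mode="duplicate-columns", d=1.0)
    A = _assemble(A0, E, P, mask, 1.0, epsilon, "group-level")
    return Ecosystem(A=A, r=np.ones(2), params=params, P=P, A0=A0, E=E,
                     mask=mask, d=1.0)
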