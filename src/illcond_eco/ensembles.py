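"""Random ecosystem ensembles.

Interaction matrices are drawn from a family of low-rank random matrices

    A = P^T (A0 - d I) P + eps * E,

where ``A0`` (group-level interactions), ``E`` (small differences among
redundant species) and the growth rates ``r`` have unit-normal entries, the
assignment matrix ``P`` has rank ``M <= N`` and encodes exact functional
redundancies, ``d > 0`` is intraspecific density limitation, and
``0 <= eps << 1`` breaks the exact redundancy.  With ``P = I`` and
``eps = 0`` the family reduces to the classical dense random-community
ensemble ``A = A0 - d I``.  A fraction ``1 - rho`` of interspecific
interactions is set to zero to mimic the low connectance of real foodwebs.

A second, independently parameterized family of scaled random interactions
(``sample_bunin_ecosystem``) exhibits a transition between a unique
globally stable equilibrium and multistability as the interaction
heterogeneity ``sigma`` grows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

ASSIGNMENT_MODES = ("identity", "duplicate-columns", "random-groups", "random-low-rank")
SPARSIFY_MODES = ("group-level", "post-hoc")

#: order of the named RNG substreams derived from the root seed
_STREAMS = ("A0", "E", "r", "mask", "P")


class PercolationWarning(UserWarning):
    """Connectance at or below the percolation threshold 1/N."""


@dataclass(frozen=True)
class EnsembleParams:
    """Parameters of the low-rank redundant ensemble.

    Parameters
    ----------
    N : int
        Number of species.
    M : int, optional
        Number of functional groups (numerical rank of the assignment
        matrix).  Defaults to ``N`` (no redundancy).
    epsilon : float
        Amplitude of the redundancy-breaking perturbation, dimensionless.
    d : float, optional
        Intraspecific density limitation.  ``None`` selects a heuristic
        ``3 * sqrt(rho * N)`` that is doubled (up to 10 times) until the
        sampled ecosystem passes the diagonal-stability check.
    rho : float
        Connectance: fraction of interspecific interactions that are
        retained (nonzero).
    assignment_mode : str
        One of ``identity``, ``duplicate-columns``, ``random-groups``,
        ``random-low-rank``.
    sparsify_mode : str
        ``group-level`` masks A0 and E with a shared pattern before lifting
        through P (preserves the rank-M degeneracy at eps=0);
        ``post-hoc`` masks the assembled A.
    redundant_r : bool
        When True (default), growth rates are lifted through the
        assignment matrix, ``r = P^T r0`` with ``r0`` unit normal, so that
        exactly redundant species are identical in growth rate as well as
        in interactions.  This is what makes the eps=0 solution set a
        *continuum* (only group totals are determined) and the eps > 0
        relaxation slow (~1/eps): if redundant species kept independent
        growth rates, within-group exclusion would proceed at the O(1)
        rate of their growth-rate gap and no slow manifold would exist.
        With ``P = I`` the lift is the identity and r is plain unit
        normal either way.
    seed : int
        Root seed; all draws derive from named substreams.
    """

    N: int
    M: Optional[int] = None
    epsilon: float = 0.0
    d: Optional[float] = None
    rho: float = 0.05
    assignment_mode: str = "identity"
    sparsify_mode: str = "group-level"
    redundant_r: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.M is None:
            object.__setattr__(self, "M", self.N)
        if not 1 <= self.M <= self.N:
            raise ValueError(f"require 1 <= M <= N, got M={self.M}, N={self.N}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if self.d is not None and self.d <= 0:
            raise ValueError("d must be positive")
        if self.assignment_mode not in ASSIGNMENT_MODES:
            raise ValueError(f"unknown assignment_mode {self.assignment_mode!r}")
        if self.sparsify_mode not in SPARSIFY_MODES:
            raise ValueError(f"unknown sparsify_mode {self.sparsify_mode!r}")
        if self.rho <= 1.0 / self.N:
            warnings.warn(
                f"connectance rho={self.rho} is at or below the percolation "
                f"threshold 1/N={1.0 / self.N:.3g}",
                PercolationWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class BuninParams:
    """Parameters of the scaled random-interaction ensemble.

    ``A = -I - (mu/N) * ones - (sigma/sqrt(N)) * A'`` with ``A'`` drawn from
    a bivariate Gaussian with unit off-diagonal variance and reciprocity
    correlation ``<A'_ij A'_ji> = gamma``.  The ensemble transitions from a
    unique globally stable equilibrium to multistability at the critical
    heterogeneity ``sigma_c = 2 / (1 + gamma)``.
    """

    N: int
    mu: float = 2.0
    sigma: float = 1.0
    gamma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if abs(self.gamma) > 1:
            raise ValueError("|gamma| must not exceed 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def sigma_c(self) -> float:
        """Predicted multistability threshold 2/(1+gamma)."""
        return 2.0 / (1.0 + self.gamma)


@dataclass
class Ecosystem:
    """A sampled ecosystem: interaction matrix, growth rates, provenance.

    The generative metadata (``P``, ``A0``, ``E``, ``mask``, ``d``) is
    retained so the eps=0 counterpart can be reconstructed from the exact
    same draws, and so single components can be replayed or perturbed.
    """

    A: np.ndarray
    r: np.ndarray
    params: Union[EnsembleParams, BuninParams, None] = None
    P: Optional[np.ndarray] = None
    A0: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    d: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def epsilon(self) -> float:
        if isinstance(self.params, EnsembleParams):
            return self.params.epsilon
        return 0.0

    def masked_E(self) -> np.ndarray:
        """The perturbation matrix after sparsification (both modes)."""
        if self.E is None or self.mask is None:
            raise ValueError("ecosystem carries no perturbation metadata")
        return np.where(self.mask, self.E, 0.0)

    def epsilon_zero(self) -> "Ecosystem":
        """The eps=0 counterpart assembled from the same draws and mask."""
        if not isinstance(self.params, EnsembleParams):
            raise ValueError("eps=0 counterpart requires ensemble metadata")
        if self.A0 is None or self.P is None or self.mask is None:
            raise ValueError("ecosystem carries no generative metadata")
        params0 = replace(self.params, epsilon=0.0)
        A = _assemble(self.A0, self.E, self.P, self.mask, self.d, 0.0,
                      self.params.sparsify_mode)
        return Ecosystem(A=A, r=self.r, params=params0, P=self.P, A0=self.A0,
                         E=self.E, mask=self.mask, d=self.d,
                         meta=dict(self.meta))

    # -- serialization -----------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        """Write matrices (npz) and parameters (JSON) to a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {"A": self.A, "r": self.r}
        for name in ("P", "A0", "E", "mask"):
            val = getattr(self, name)
            if val is not None:
                arrays[name] = val
        np.savez(path / "arrays.npz", **arrays)
        meta = {"d": self.d, "meta": self.meta,
                "params_kind": type(self.params).__name__ if self.params else None,
                "params": self.params.__dict__ if self.params else None}
        (path / "params.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Ecosystem":
        path = Path(path)
        data = np.load(path / "arrays.npz")
        meta = json.loads((path / "params.json").read_text())
        params = None
        if meta["params_kind"] == "EnsembleParams":
            params = EnsembleParams(**meta["params"])
        elif meta["params_kind"] == "BuninParams":
            params = BuninParams(**meta["params"])
        kwargs = {k: data[k] for k in ("P", "A0", "E", "mask") if k in data}
        return cls(A=data["A"], r=data["r"], params=params, d=meta["d"],
                   meta=meta.get("meta", {}), **kwargs)

    def export_csv(self, path: Union[str, Path]) -> None:
        """CSV export of A and r with species-id header row s0001..sNNNN."""
        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ids = [f"s{i + 1:04d}" for i in range(self.N)]
        pd.DataFrame(self.A, index=ids, columns=ids).to_csv(path / "A.csv")
        pd.DataFrame({"species": ids, "r": self.r}).to_csv(
            path / "r.csv", index=False)


def _rng_streams(seed: int) -> dict:
    children = SeedSequence(seed).spawn(len(_STREAMS))
    return {name: default_rng(ss) for name, ss in zip(_STREAMS, children)}


def sample_assignment_matrix(
    N: int,
    M: int,
    mode: str = "identity",
    rng: Optional[Generator] = None,
    duplicates: Optional[Sequence[tuple]] = None,
) -> np.ndarray:
    """Sample an N x N assignment matrix of numerical rank exactly M.

    Modes
    -----
    identity
        The identity (requires ``M == N``).
    duplicate-columns
        Identity with columns duplicated: each non-representative species k
        copies the column of a representative species j (``P[:, k] = e_j``),
        i.e. species j and k serve exactly indistinguishable functions.
        Explicit ``duplicates=[(j, k), ...]`` pairs may be given; otherwise
        representatives and sources are drawn from ``rng``.
    random-groups
        Each species is assigned uniformly to one of M groups (every group
        guaranteed nonempty by reassignment); ``P[g, s] = 1``.
    random-low-rank
        Product of N x M and M x N unit-normal factors.
    """
    if not 1 <= M <= N:
        raise ValueError(f"require 1 <= M <= N, got M={M}, N={N}")
    if mode == "identity":
        if M != N:
            raise ValueError("identity assignment requires M == N")
        return np.eye(N)
    if rng is None:
        rng = default_rng()
    if mode == "duplicate-columns":
        if M == N:
            raise ValueError("duplicate-columns requires M < N (no column to "
                             "duplicate when M == N)")
        P = np.eye(N)
        if duplicates is not None:
            for j, k in duplicates:
                P[:, k] = 0.0
                P[j, k] = 1.0
        else:
            reps = np.sort(rng.choice(N, size=M, replace=False))
            others = np.setdiff1d(np.arange(N), reps)
            sources = rng.choice(reps, size=others.size, replace=True)
            for j, k in zip(sources, others):
                P[:, k] = 0.0
                P[j, k] = 1.0
        return P
    if mode == "random-groups":
        groups = rng.integers(0, M, size=N)
        # guarantee every group nonempty: move members out of crowded groups
        counts = np.bincount(groups, minlength=M)
        for g in np.flatnonzero(counts == 0):
            donor = int(np.argmax(np.bincount(groups, minlength=M)))
            idx = np.flatnonzero(groups == donor)[0]
            groups[idx] = g
        P = np.zeros((N, N))
        P[groups, np.arange(N)] = 1.0
        return P
    if mode == "random-low-rank":
        return rng.standard_normal((N, M)) @ rng.standard_normal((M, N))
    raise ValueError(f"unknown assignment mode {mode!r}")


def _sample_mask(N: int, rho: float, rng: Generator) -> np.ndarray:
    """Boolean keep-mask: diagonal always kept; exactly
    ``N(N-1) - floor((1-rho) N(N-1))`` interspecific entries kept,
    chosen without replacement (deterministic count given the seed)."""
    n_off = N * (N - 1)
    n_zero = int(np.floor((1.0 - rho) * n_off))
    mask = np.ones((N, N), dtype=bool)
    if n_zero > 0:
        rows, cols = np.where(~np.eye(N, dtype=bool))
        kill = rng.choice(n_off, size=n_zero, replace=False)
        mask[rows[kill], cols[kill]] = False
    return mask


def _assemble(A0, E, P, mask, d, eps, sparsify_mode):
    N = A0.shape[0]
    eye = np.eye(N)
    if sparsify_mode == "group-level":
        A0m = np.where(mask, A0, 0.0)
        Em = np.where(mask, E, 0.0)
        return P.T @ (A0m - d * eye) @ P + eps * Em
    # post-hoc: mask the assembled matrix, diagonal preserved
    A_full = P.T @ (A0 - d * eye) @ P + eps * E
    return np.where(mask, A_full, 0.0)


def check_diagonal_stability(A: np.ndarray, tol: float = 0.0) -> bool:
    """Lyapunov diagonal stability via the sufficient condition that
    ``A + A^T`` is negative definite (largest eigenvalue < ``tol``).

    ``tol=0`` is the strict criterion guaranteeing a unique, globally
    stable, non-invasible equilibrium.  A small positive ``tol`` admits the
    rank-deficient ensembles, whose symmetric part is negative
    *semi*-definite at eps=0 (exact zero modes on the redundant subspace).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    lam_max = np.linalg.eigvalsh(A + A.T)[-1]
    return bool(lam_max < tol)


def sample_ecosystem(
    params: EnsembleParams,
    rng: Union[int, SeedSequence, None] = None,
) -> Ecosystem:
    """Sample one ecosystem from the low-rank redundant ensemble.

    All draws (A0, E, r, mask, P) come from named substreams of the root
    seed so that the eps=0 counterpart -- and any single component -- can be
    replayed exactly.  When ``params.d`` is ``None`` the density limitation
    starts at ``3 sqrt(rho N)`` and doubles (up to 10 times) until the eps=0
    part of the sampled matrix passes the diagonal-stability check; this
    makes every returned ecosystem globally stable up to the eps-scale
    perturbation.
    """
    if rng is None:
        rng = params.seed
    if isinstance(rng, (int, np.integer)):
        streams = _rng_streams(int(rng))
    elif isinstance(rng, SeedSequence):
        streams = {name: default_rng(ss)
                   for name, ss in zip(_STREAMS, rng.spawn(len(_STREAMS)))}
    else:
        # single generator: draws still reproducible, but not per-component
        streams = {name: rng for name in _STREAMS}

    N, M = params.N, params.M
    A0 = streams["A0"].standard_normal((N, N))
    E = streams["E"].standard_normal((N, N))
    r0 = streams["r"].standard_normal(N)
    mask = _sample_mask(N, params.rho, streams["mask"])
    P = sample_assignment_matrix(N, M, params.assignment_mode, streams["P"])
    r = P.T @ r0 if params.redundant_r else r0

    if params.d is not None:
        d = params.d
        A = _assemble(A0, E, P, mask, d, params.epsilon, params.sparsify_mode)
    else:
        d = 3.0 * np.sqrt(params.rho * N)
        for _ in range(10):
            A = _assemble(A0, E, P, mask, d, params.epsilon,
                          params.sparsify_mode)
            A_struct = _assemble(A0, E, P, mask, d, 0.0, params.sparsify_mode)
            # semidefinite tolerance admits the exact zero modes of
            # rank-deficient P (scaled to the matrix magnitude)
            tol = 1e-8 * max(1.0, float(np.abs(A_struct).max()))
            if check_diagonal_stability(A_struct, tol=tol):
                break
            d *= 2.0
    return Ecosystem(A=A, r=r, params=params, P=P, A0=A0, E=E, mask=mask, d=d)


def sample_bunin_ecosystem(
    params: BuninParams,
    rng: Union[int, SeedSequence, Generator, None] = None,
    r: Optional[np.ndarray] = None,
) -> Ecosystem:
    """Sample one ecosystem from the scaled random-interaction ensemble.

    ``A = -I - (mu/N) * ones - (sigma/sqrt(N)) * A'`` where the off-diagonal
    pairs ``(A'_ij, A'_ji)`` are bivariate Gaussian with unit variance and
    correlation ``gamma``; the diagonal of ``A'`` is zero (self-limitation
    lives in the ``-I`` term).  Growth rates default to ``r_i = 1``.
    """
    N = params.N
    if rng is None:
        rng = params.seed
    if isinstance(rng, (int, np.integer)):
        rng = default_rng(int(rng))
    elif isinstance(rng, SeedSequence):
        rng = default_rng(rng)
    g = params.gamma
    iu = np.triu_indices(N, k=1)
    z1 = rng.standard_normal(iu[0].size)
    z2 = rng.standard_normal(iu[0].size)
    Ap = np.zeros((N, N))
    Ap[iu] = z1
    Ap.T[iu] = g * z1 + np.sqrt(max(0.0, 1.0 - g * g)) * z2
    A = (-np.eye(N) - (params.mu / N) * np.ones((N, N))
         - (params.sigma / np.sqrt(N)) * Ap)
    if r is None:
        r = np.ones(N)
    return Ecosystem(A=A, r=np.asarray(r, dtype=float), params=params,
                     meta={"A_prime": "bivariate-gaussian"})
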