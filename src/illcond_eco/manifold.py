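"""Slow-manifold analysis.

At eps=0 the rank-deficient ensemble has a continuum of degenerate
equilibria (mixtures of substitutable species).  For eps > 0 these become
*pseudosolutions*: weakly unstable saddle regions that trap trajectories
and produce long transients.  This module locates degenerate solutions,
scores their instability (Morse index), measures trajectory dwell times
near them, builds the linearized drift along the manifold, constructs
ecomode projections from the right singular vectors of A (which
precondition the dynamics, kappa(W A) << kappa(A)), and embeds trajectory
bundles with PCA including a mesh-based pullback of the vector field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq
from sklearn.decomposition import PCA

from .conditioning import cluster_endpoints, condition_number
from .dynamics import Trajectory, integrate, jacobian, rhs
from .ensembles import Ecosystem


@dataclass
class PseudoSolution:
    """A point on the eps=0 degenerate solution set."""

    point: np.ndarray
    morse_alpha: Optional[float] = None  # N_minus / N in [0, 1]
    escape_time: Optional[float] = None
    n_members: int = 1  # endpoints merged into this cluster


@dataclass
class EcomodeProjection:
    """Row-orthonormal projections onto leading/trailing right singular
    vectors of A (W_fast = V[:, :K]^T, W_slow = V[:, N-K:]^T)."""

    K: int
    W_fast: np.ndarray  # (K, N)
    W_slow: np.ndarray  # (K, N)
    singular_values: np.ndarray


@dataclass
class EmbeddingBundle:
    """PCA embedding of pooled trajectories plus vector-field pullback."""

    pca: PCA
    K: int
    embeddings: List[np.ndarray]  # per-trajectory (T_i, K)
    mesh: np.ndarray  # (n_mesh, 2) embedded mesh points
    mesh_velocity: np.ndarray  # (n_mesh, 2) projected velocity field
    eps0_embedded: Optional[np.ndarray] = None  # projected eps=0 endpoints
    meta: dict = field(default_factory=dict)

    def transform(self, states: np.ndarray) -> np.ndarray:
        return self.pca.transform(np.atleast_2d(states))[:, :self.K]


def degenerate_solutions(
    eco: Ecosystem,
    initials: Sequence[np.ndarray],
    cluster_tol: float = 1e-4,
    t_max: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deriv_floor: float = 1e-13,
    with_morse: bool = True,
) -> List[PseudoSolution]:
    """Fixed points of the eps=0 counterpart reached from ``initials``.

    Each initial condition is integrated under the degenerate (eps=0)
    dynamics; endpoints are deduplicated by single-linkage clustering at
    ``cluster_tol``.  When ``with_morse`` is set, each representative point
    is scored with the Morse index of the *perturbed* (eps > 0) system, in
    which the former solutions are saddles.
    """
    eco0 = eco.epsilon_zero()
    endpoints = []
    for n0 in initials:
        traj = integrate(eco0, n0, t_max=t_max, rtol=rtol, atol=atol,
                         deriv_floor=deriv_floor, dense_output=False)
        if traj.terminal_reason != "blow-up":
            endpoints.append(np.maximum(traj.endpoint, 0.0))
    if not endpoints:
        return []
    pts = np.array(endpoints)
    labels = cluster_endpoints(pts, cluster_tol)
    out = []
    for lab in np.unique(labels):
        members = pts[labels == lab]
        point = members.mean(axis=0)
        alpha = morse_index(eco, point) if with_morse else None
        out.append(PseudoSolution(point=point, morse_alpha=alpha,
                                  n_members=int(members.shape[0])))
    return out


def morse_index(eco: Ecosystem, point: np.ndarray,
                tol: Optional[float] = None) -> float:
    """Scaled Morse instability index alpha = N_minus / N.

    N_minus counts eigenvalues of the Jacobian at ``point`` with real part
    above ``tol`` (unstable escape directions of the saddle).  ``tol``
    defaults to a machine-relative floor on the spectral magnitude.
    """
    point = np.asarray(point, dtype=float)
    if np.any(point < -1e-8):
        raise ValueError("point must be nonnegative")
    lam = np.linalg.eigvals(jacobian(np.maximum(point, 0.0), eco))
    if tol is None:
        tol = 1e-10 * max(1.0, float(np.abs(lam).max()))
    return float(np.sum(lam.real > tol)) / eco.N


def escape_time(
    traj: Trajectory,
    point: np.ndarray,
    radius: Optional[float] = None,
    per_visit: bool = False,
    refine: int = 8,
) -> Union[float, List[float], None]:
    """Dwell time of a trajectory inside the ball around ``point``.

    Total time (summed over entry/exit episodes) that the trajectory
    spends within ``radius`` of the point; ``per_visit`` returns the list
    of episode durations instead.  ``radius`` defaults to
    ``1e-2 * (1 + ||point||)``.  Returns ``None`` when the trajectory
    never enters the ball.
    """
    point = np.asarray(point, dtype=float)
    if radius is None:
        radius = 1e-2 * (1.0 + float(np.linalg.norm(point)))
    if radius <= 0:
        raise ValueError("radius must be positive")

    ts = traj.times
    if len(ts) < 2:
        inside = np.linalg.norm(traj.states[-1] - point) <= radius
        if not inside:
            return None
        return [0.0] if per_visit else 0.0
    sub = refine if traj.sol is not None else 1
    grid = np.concatenate([np.linspace(ts[i], ts[i + 1], sub + 1)[:-1]
                           for i in range(len(ts) - 1)] + [ts[-1:]])
    d = np.linalg.norm(traj(grid) - point, axis=-1) - radius

    def dist(t):
        return float(np.linalg.norm(traj(t) - point)) - radius

    inside = d <= 0
    if not inside.any():
        return None
    episodes = []
    i = 0
    while i < len(grid):
        if inside[i]:
            # refine the entry time
            if i == 0:
                t_in = grid[0]
            else:
                t_in = brentq(dist, grid[i - 1], grid[i])
            j = i
            while j + 1 < len(grid) and inside[j + 1]:
                j += 1
            if j + 1 < len(grid):
                t_out = brentq(dist, grid[j], grid[j + 1])
            else:
                t_out = grid[-1]
            episodes.append(float(t_out - t_in))
            i = j + 1
        i += 1
    return episodes if per_visit else float(sum(episodes))


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: first nonzero component of each
    column positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def ecomode_projections(A: np.ndarray, K: int) -> EcomodeProjection:
    """Fast/slow ecomode projections from the SVD of A.

    W_fast projects onto the K leading right singular vectors (fast
    relaxation directions); W_slow onto the K trailing ones (the slow
    'solving' directions along the redundant subspace).
    """
    A = np.asarray(A, dtype=float)
    N = A.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"require 1 <= K <= N, got K={K}")
    _, s, Vt = np.linalg.svd(A)
    V = _fix_signs(Vt.T)
    return EcomodeProjection(K=K, W_fast=V[:, :K].T, W_slow=V[:, N - K:].T,
                             singular_values=s)


def preconditioning_ratio(A: np.ndarray, W: np.ndarray) -> float:
    """kappa(W A) / kappa(A) for a row-orthonormal projection W.

    Values << 1 mean W preconditions the linear problem -W A n = W r.
    Returns ``inf`` when W A is numerically rank-deficient.
    """
    A = np.asarray(A, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    WWt = W @ W.T
    if not np.allclose(WWt, np.eye(W.shape[0]), atol=1e-8):
        raise ValueError("W must have orthonormal rows")
    kA = condition_number(A)
    kWA = condition_number(W @ A)
    if not np.isfinite(kWA):
        return np.inf
    return kWA / kA


def linearized_drift(eco: Ecosystem,
                     point: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linearization of the dynamics around a point on the eps=0 solution
    set: returns (community matrix of the unperturbed system,
    eps-induced drift vector).

    The community matrix is diag(n*) A_eps0; the drift
    eps * n*_i * (E_masked n*)_i is the order-eps term that pushes the
    trajectory along the slow manifold, preventing equilibration at the
    former solution.
    """
    point = np.asarray(point, dtype=float)
    A0 = eco.epsilon_zero().A
    community = point[:, None] * A0
    drift = eco.epsilon * point * (eco.masked_E() @ point)
    return community, drift


def embed_trajectories(
    trajs: Sequence[Trajectory],
    eco: Ecosystem,
    K: int,
    mesh_resolution: Tuple[int, int] = (20, 20),
    eps0_endpoints: Optional[np.ndarray] = None,
    mesh_margin: float = 0.05,
) -> EmbeddingBundle:
    """PCA embedding of a trajectory bundle with vector-field pullback.

    All trajectory states are pooled and PCA-transformed (feature-mean
    centering, no variance scaling).  The returned bundle carries the
    truncated per-trajectory embeddings, the projected eps=0 endpoints
    (when given), and a velocity field on a uniform mesh over the first
    two embedding coordinates: each 2-D mesh point is promoted to the full
    PCA space with the mean of the remaining coordinates, pulled back to
    ambient abundance space by inverting the (linear) PCA map, the
    right-hand side is evaluated there, and the resulting velocity is
    projected back onto the two leading components.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories to embed")
    N = eco.N
    if K > N:
        raise ValueError("K must not exceed the number of species")
    X = np.vstack([t.states for t in trajs])
    n_comp = min(X.shape[0], N)
    pca = PCA(n_components=n_comp)
    Y = pca.fit_transform(X)
    embeddings = [pca.transform(t.states)[:, :K] for t in trajs]
    tail_mean = Y[:, 2:].mean(axis=0) if n_comp > 2 else np.empty(0)

    lo = Y[:, :2].min(axis=0)
    hi = Y[:, :2].max(axis=0)
    pad = mesh_margin * (hi - lo)
    g1 = np.linspace(lo[0] - pad[0], hi[0] + pad[0], mesh_resolution[0])
    g2 = np.linspace(lo[1] - pad[1], hi[1] + pad[1], mesh_resolution[1])
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    mesh2 = np.column_stack([G1.ravel(), G2.ravel()])
    mesh_full = np.hstack([mesh2,
                           np.broadcast_to(tail_mean,
                                           (mesh2.shape[0],
                                            tail_mean.size))])
    ambient = pca.inverse_transform(mesh_full)
    vel = np.array([rhs(x, eco) for x in ambient])
    vel2 = vel @ pca.components_[:2].T
    eps0_emb = None
    if eps0_endpoints is not None:
        eps0_emb = pca.transform(np.atleast_2d(eps0_endpoints))[:, :2]
    return EmbeddingBundle(pca=pca, K=K, embeddings=embeddings, mesh=mesh2,
                           mesh_velocity=vel2, eps0_embedded=eps0_emb,
                           meta={"mesh_shape": mesh_resolution,
                                 "tail_mean": tail_mean})
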