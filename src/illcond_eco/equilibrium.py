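"""Equilibrium location, verification, settling times, and diversity.

The globally stable equilibrium of the Lotka-Volterra dynamics is the
solution of the linear complementarity problem

    n* >= 0,   w = -(r + A n*) >= 0,   n*^T w = 0,

i.e. surviving species have zero net per-capita growth while extinct
species have non-positive invasion growth rate (non-invasibility).  When
``A + A^T`` is negative definite, ``-A`` is a P-matrix and the solution is
unique; ``equilibrium_lcp`` computes it directly by principal pivoting and
serves as an integration-free cross-check of the dynamical endpoint.

The settling time tau is the first time the trajectory comes within the
convergence floor xi of n* -- by default with *persistent* semantics (the
trajectory also stays within xi afterwards), guarding against transient
grazes of the xi-ball; the plain first-crossing infimum is available via
``mode='first'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, nnls

from .dynamics import Trajectory, integrate, jacobian
from .ensembles import Ecosystem

DEFAULT_XI = 1e-7


class UnstableEcosystemError(RuntimeError):
    """Integration blew up: the ecosystem admits unbounded growth."""


@dataclass
class EquilibriumResult:
    """Verified equilibrium of one ecosystem."""

    n_star: np.ndarray
    support: np.ndarray  # indices of surviving species
    ncoex: int
    tau: Optional[float]  # settling time; None if never settled within xi
    xi: float
    residual: float  # max |r_i + (A n*)_i| over the support
    invasion_margin: float  # max off-support growth rate (<= 0 when stable)
    stable: bool  # from the Jacobian spectrum at n*
    nnls_residual: float  # support-row residual of the Lawson-Hanson solve
    verified: bool
    trajectory: Optional[Trajectory] = None

    def to_json(self, path=None) -> str:
        """Serialize the result (without the trajectory) to JSON."""
        import json

        payload = {
            "n_star": self.n_star.tolist(),
            "support": self.support.tolist(),
            "ncoex": self.ncoex,
            "tau": self.tau,
            "xi": self.xi,
            "residual": self.residual,
            "invasion_margin": self.invasion_margin,
            "stable": self.stable,
            "nnls_residual": self.nnls_residual,
            "verified": self.verified,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def coexistence_count(n_star: np.ndarray,
                      threshold: Optional[float] = None) -> int:
    """Number of surviving species: entries of n* above ``threshold``.

    The zero-norm of a numerically integrated equilibrium is ill-defined,
    so the default threshold is 1e-6 times the mean positive abundance.
    """
    return int(support_indices(n_star, threshold).size)


def support_indices(n_star: np.ndarray,
                    threshold: Optional[float] = None) -> np.ndarray:
    n_star = np.asarray(n_star, dtype=float)
    if np.any(n_star < -10 * np.finfo(float).eps * max(1, np.abs(n_star).max())):
        # tolerate solver-scale negatives only
        if np.any(n_star < -1e-8):
            raise ValueError("n_star must be nonnegative")
    if threshold is None:
        pos = n_star[n_star > 0]
        threshold = 1e-6 * pos.mean() if pos.size else np.inf
    return np.flatnonzero(n_star > threshold)


def settling_time(
    traj: Trajectory,
    n_star: np.ndarray,
    xi: float = DEFAULT_XI,
    mode: str = "persistent",
    refine: int = 8,
) -> Optional[float]:
    """Settling time tau = first time ||n(t) - n*||_2 <= xi.

    Uses dense-output evaluation (refined between solver steps), so tau is
    invariant to the solver's step grid.  ``mode='persistent'`` (default)
    requires the distance to remain below xi for the rest of the recorded
    path; ``mode='first'`` returns the plain infimum.  Returns ``None``
    when the trajectory never (persistently) enters the xi-ball.
    """
    if mode not in ("persistent", "first"):
        raise ValueError("mode must be 'persistent' or 'first'")
    n_star = np.asarray(n_star, dtype=float)

    def dist(t):
        return float(np.linalg.norm(traj(t) - n_star))

    if len(traj.times) < 2:
        return 0.0 if dist(traj.times[-1]) <= xi else None
    # refined time grid: `refine` samples inside every recorded step
    ts = traj.times
    sub = refine if traj.sol is not None else 1
    grid = np.concatenate([np.linspace(ts[i], ts[i + 1], sub + 1)[:-1]
                           for i in range(len(ts) - 1)] + [ts[-1:]])
    d = np.linalg.norm(traj(grid) - n_star, axis=-1)
    below = d <= xi
    if mode == "first":
        if not below.any():
            return None
        k = int(np.argmax(below))
    else:
        if not below[-1]:
            return None
        above = np.flatnonzero(~below)
        if above.size == 0:
            return 0.0
        k = int(above[-1]) + 1
    if k == 0:
        return 0.0
    t_lo, t_hi = grid[k - 1], grid[k]
    if t_hi == t_lo:
        return float(t_lo)
    return float(brentq(lambda t: dist(t) - xi, t_lo, t_hi, xtol=1e-12,
                        rtol=1e-12))


def polish_equilibrium(A: np.ndarray, r: np.ndarray, y: np.ndarray,
                       threshold: Optional[float] = None,
                       noninvasible: bool = True,
                       max_iter: int = 200) -> np.ndarray:
    """Project a near-equilibrium state onto the exact fixed point of its
    support.

    Reads the survivor set off ``y``, solves the interior balance
    ``A[S, S] n_S = -r_S`` exactly, drops any species the solve drives
    negative, and (with ``noninvasible``, the default) re-admits the
    species with the largest positive invasion growth rate until the
    complementarity conditions hold -- i.e. warm-started principal
    pivoting from the integrated support.  Used to sharpen integration
    endpoints before clustering: a trajectory that has committed to a
    basin polishes to that basin's (non-invasible) equilibrium, making
    endpoint comparisons insensitive to leftover integration transients
    such as marginal species that have not finished dying out.
    """
    A = np.asarray(A, dtype=float)
    r = np.asarray(r, dtype=float)
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    S = support_indices(y, threshold)
    in_basis = np.zeros(y.size, dtype=bool)
    in_basis[S] = True
    n = np.zeros_like(y)
    best = y
    for _ in range(max_iter):
        S = np.flatnonzero(in_basis)
        n[:] = 0.0
        if S.size:
            sol = np.linalg.solve(A[np.ix_(S, S)], -r[S])
            if np.any(sol <= 0):
                in_basis[S[sol <= 0]] = False
                continue
            n[S] = sol
        best = n.copy()
        if not noninvasible:
            return best
        growth = r + A @ n
        off = np.flatnonzero(~in_basis)
        if off.size == 0 or np.max(growth[off]) <= 1e-10:
            return best
        in_basis[off[np.argmax(growth[off])]] = True
    # cycling (possible off the P-matrix class): return the last feasible
    # interior solve rather than failing
    return best


def equilibrium_lcp(A: np.ndarray, r: np.ndarray,
                    max_iter: Optional[int] = None) -> np.ndarray:
    """Solve the equilibrium linear complementarity problem directly.

    Murty's least-index principal pivoting on LCP(M, q) with M = -A,
    q = -r; finite termination is guaranteed when M is a P-matrix (in
    particular when A + A^T is negative definite).  Independent of the ODE
    integration path.
    """
    A = np.asarray(A, dtype=float)
    r = np.asarray(r, dtype=float)
    N = r.size
    if max_iter is None:
        max_iter = 100 * N + 1000
    M = -A
    q = -r
    in_basis = np.zeros(N, dtype=bool)
    for _ in range(max_iter):
        n = np.zeros(N)
        S = np.flatnonzero(in_basis)
        if S.size:
            n[S] = np.linalg.solve(M[np.ix_(S, S)], -q[S])
        w = M @ n + q
        viol_n = np.flatnonzero(in_basis & (n < -1e-12))
        viol_w = np.flatnonzero(~in_basis & (w < -1e-12))
        if viol_n.size == 0 and viol_w.size == 0:
            return np.maximum(n, 0.0)
        # least-index rule
        i = min(viol_n[0] if viol_n.size else N,
                viol_w[0] if viol_w.size else N)
        in_basis[i] = ~in_basis[i]
    raise RuntimeError("principal pivoting did not converge; is -A a "
                       "P-matrix (A + A^T negative definite)?")


def find_equilibrium(
    eco: Ecosystem,
    n0: np.ndarray,
    xi: float = DEFAULT_XI,
    threshold: Optional[float] = None,
    t_max: float = 1e6,
    rtol: float = 1e-12,
    atol: float = 1e-12,
    deriv_floor: float = 1e-14,
    keep_trajectory: bool = False,
    verify_tol: float = 1e-6,
) -> EquilibriumResult:
    """Integrate to the derivative floor and verify the equilibrium.

    Verification: (i) local stability from the analytic Jacobian spectrum,
    (ii) complementarity -- on-support growth rates vanish and off-support
    invasion rates are non-positive, (iii) a Lawson-Hanson nonnegative
    least-squares solve of -A n = r as a direct residual check.  A
    failed verification is flagged (``verified=False``), not raised;
    blow-up raises :class:`UnstableEcosystemError`.
    """
    traj = integrate(eco, n0, t_max=t_max, rtol=rtol, atol=atol,
                     deriv_floor=deriv_floor)
    if traj.terminal_reason == "blow-up":
        raise UnstableEcosystemError(
            "trajectory blew up; A is not diagonally stable")
    n_star = np.maximum(traj.endpoint, 0.0)
    support = support_indices(n_star, threshold)
    growth = eco.r + eco.A @ n_star
    residual = float(np.max(np.abs(growth[support]))) if support.size else 0.0
    off = np.setdiff1d(np.arange(eco.N), support)
    invasion = float(np.max(growth[off])) if off.size else -np.inf
    lam = np.linalg.eigvals(jacobian(n_star, eco))
    stable = bool(np.max(lam.real) < 1e-7 * max(1.0, np.abs(lam).max()))
    x_nnls, _ = nnls(-eco.A, eco.r)
    nnls_res = (float(np.max(np.abs((-eco.A @ x_nnls - eco.r)[support])))
                if support.size else 0.0)
    scale = max(1.0, float(np.linalg.norm(eco.r)))
    verified = (residual <= verify_tol * scale
                and invasion <= verify_tol * scale
                and traj.terminal_reason == "derivative-floor")
    tau = settling_time(traj, n_star, xi=xi)
    return EquilibriumResult(
        n_star=n_star, support=support, ncoex=int(support.size), tau=tau,
        xi=xi, residual=residual, invasion_margin=invasion, stable=stable,
        nnls_residual=nnls_res, verified=verified,
        trajectory=traj if keep_trajectory else None)
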