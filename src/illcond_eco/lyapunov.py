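"""Fast Lyapunov Indicator (FLI) via the matrix variational equation.

For a trajectory n(t), the fundamental matrix obeys

    dw/dt = J[n(t)] w,   w(0) = I,

and the FLI is lambda_F = max_t log ||w(t)||_2 (natural log): the fastest
exponential divergence observed at any time along any initial direction.
Unlike the asymptotic Lyapunov exponent -- which is non-positive for
systems approaching a global fixed point -- lambda_F records transient
stretching, and so detects transient chaos.  The norm of w can overflow
long before the trajectory settles; whenever it exceeds an overflow guard
the matrix is rescaled and the log of the scale factor accumulated, so
that log ||w(t)|| is reconstructed exactly as
log ||w_stored(t)|| + rescale_log_sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.integrate import solve_ivp

from .dynamics import DEFAULT_BLOWUP, DEFAULT_DERIV_FLOOR
from .ensembles import Ecosystem


@dataclass
class FLIResult:
    lambda_F: float  # max over time of reconstructed log norm
    peak_time: float
    rescale_log_sum: float  # accumulated log scale factors at the end
    times: np.ndarray
    log_norms: np.ndarray  # reconstructed log ||w(t)|| at sampled times
    terminal_reason: str
    n_rescales: int = 0


@dataclass
class FLIGrid:
    lambda_F: np.ndarray  # (res1, res2)
    base: np.ndarray
    dir1: np.ndarray
    dir2: np.ndarray
    offsets1: np.ndarray
    offsets2: np.ndarray
    clamped: np.ndarray  # per-cell count of clamped (negative) coordinates
    t_max: float
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)


def _matnorm(W: np.ndarray, kind: str) -> float:
    if kind == "spectral":
        return float(np.linalg.norm(W, 2))
    if kind == "fro":
        return float(np.linalg.norm(W))
    raise ValueError("norm must be 'spectral' or 'fro'")


def variational_fli(
    f: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    n0: np.ndarray,
    t_max: float,
    W0: Optional[np.ndarray] = None,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    deriv_floor: float = DEFAULT_DERIV_FLOOR,
    blowup_guard: float = DEFAULT_BLOWUP,
    renorm_threshold: float = 1e100,
    norm: str = "spectral",
    method: str = "Radau",
    stop_on_floor: bool = True,
) -> FLIResult:
    """Generic FLI core: co-integrate state and fundamental matrix.

    ``f``/``jac`` map a state vector to its rate / Jacobian; the combined
    system is integrated with timestep control driven jointly, terminating
    on the derivative floor of the state, the horizon, or blow-up.  The
    fundamental matrix restarts (rescaled to unit Frobenius norm) whenever
    its norm crosses ``renorm_threshold``.
    """
    n0 = np.asarray(n0, dtype=float)
    N = n0.size
    W = np.eye(N) if W0 is None else np.asarray(W0, dtype=float).copy()
    K = W.shape[1]
    log_thr = np.log(renorm_threshold)

    def rhs_aug(t, y):
        n = y[:N]
        Wm = y[N:].reshape(N, K)
        J = jac(n)
        return np.concatenate([f(n), (J @ Wm).ravel()])

    def ev_floor(t, y):
        m = np.max(np.abs(f(y[:N])))
        return (np.log10(m) if m > 0 else -300.0) - np.log10(deriv_floor)

    ev_floor.terminal = stop_on_floor
    ev_floor.direction = -1

    def ev_blow(t, y):
        return np.max(y[:N]) - blowup_guard

    ev_blow.terminal = True
    ev_blow.direction = 1

    def ev_renorm(t, y):
        # Frobenius norm for the guard (cheap, upper-bounds spectral decay)
        return np.log(np.linalg.norm(y[N:]) + 1e-300) - log_thr

    ev_renorm.terminal = True
    ev_renorm.direction = 1

    t = 0.0
    n = n0.copy()
    log_sum = 0.0
    n_rescales = 0
    times = [0.0]
    lognorms = [np.log(_matnorm(W, norm))]
    reason = "t-max"
    while t < t_max:
        y0 = np.concatenate([n, W.ravel()])
        res = solve_ivp(rhs_aug, (t, t_max), y0, method=method, rtol=rtol,
                        atol=atol, events=(ev_floor, ev_blow, ev_renorm),
                        dense_output=False)
        Wt = res.y[N:, :].reshape(N, K, -1)
        for j, tj in enumerate(res.t):
            if tj == t and len(times) > 0:
                continue
            times.append(tj)
            lognorms.append(np.log(_matnorm(Wt[:, :, j], norm)) + log_sum)
        t = res.t[-1]
        n = res.y[:N, -1]
        W = Wt[:, :, -1]
        if res.status == 1:
            if len(res.t_events[2]):  # renormalize and continue
                scale = np.linalg.norm(W)
                W = W / scale
                log_sum += np.log(scale)
                n_rescales += 1
                continue
            reason = ("derivative-floor" if len(res.t_events[0])
                      else "blow-up")
            break
        if res.status == 0:
            reason = "t-max"
            break
        raise RuntimeError(f"variational integration failed: {res.message}")
    times = np.asarray(times)
    lognorms = np.asarray(lognorms)
    k = int(np.argmax(lognorms))
    return FLIResult(lambda_F=float(lognorms[k]), peak_time=float(times[k]),
                     rescale_log_sum=log_sum, times=times,
                     log_norms=lognorms, terminal_reason=reason,
                     n_rescales=n_rescales)


def integrate_variational(
    eco: Ecosystem,
    n0: np.ndarray,
    t_max: float = 500.0,
    n_columns: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> FLIResult:
    """FLI of one Lotka-Volterra trajectory with w(0) = I.

    ``n_columns`` evolves only K random orthonormal columns of w instead of
    the full identity -- a cheaper approximation for large N (each column
    is an independently evolving tangent direction; the max-norm over a
    K-column subset lower-bounds the full-matrix value).
    """
    A, r = eco.A, eco.r

    def f(n):
        return n * (r + A @ n)

    def jac(n):
        J = n[:, None] * A
        J[np.diag_indices_from(J)] += r + A @ n
        return J

    W0 = None
    if n_columns is not None and n_columns < eco.N:
        if rng is None:
            rng = default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((eco.N, n_columns)))
        W0 = Q
    return variational_fli(f, jac, n0, t_max, W0=W0, **kwargs)


def fli_slice(
    eco: Ecosystem,
    base: np.ndarray,
    dir1: Optional[np.ndarray] = None,
    dir2: Optional[np.ndarray] = None,
    extents: Tuple[float, float] = (0.5, 0.5),
    resolution: Tuple[int, int] = (20, 20),
    t_max: float = 500.0,
    seed: Optional[int] = None,
    clamp_floor: float = 1e-9,
    **kwargs,
) -> FLIGrid:
    """lambda_F over a 2-D slice of initial conditions (a caustic map).

    Grid points are ``base + u * dir1 + v * dir2`` with u, v spanning
    ``(-extents, +extents)`` at the given resolution.  Directions default
    to a random orthonormal pair from the seeded stream.  Coordinates
    driven negative are clamped to ``clamp_floor`` (abundances are
    physical); the per-cell count of clamped coordinates is recorded.
    """
    if resolution[0] < 1 or resolution[1] < 1:
        raise ValueError("resolution must be at least 1x1")
    base = np.asarray(base, dtype=float)
    N = base.size
    if dir1 is None or dir2 is None:
        rng = default_rng(SeedSequence(0 if seed is None else seed))
        Q, _ = np.linalg.qr(rng.standard_normal((N, 2)))
        dir1, dir2 = Q[:, 0], Q[:, 1]
    dir1 = np.asarray(dir1, dtype=float)
    dir2 = np.asarray(dir2, dtype=float)
    if np.linalg.matrix_rank(np.stack([dir1, dir2])) < 2:
        raise ValueError("slice directions must be linearly independent")
    u = (np.linspace(-extents[0], extents[0], resolution[0])
         if resolution[0] > 1 else np.array([0.0]))
    v = (np.linspace(-extents[1], extents[1], resolution[1])
         if resolution[1] > 1 else np.array([0.0]))
    lam = np.zeros((u.size, v.size))
    clamped = np.zeros((u.size, v.size), dtype=int)
    for i, ui in enumerate(u):
        for j, vj in enumerate(v):
            point = base + ui * dir1 + vj * dir2
            neg = point < 0
            clamped[i, j] = int(neg.sum())
            point = np.where(neg, clamp_floor, point)
            lam[i, j] = integrate_variational(eco, point, t_max=t_max,
                                              **kwargs).lambda_F
    return FLIGrid(lambda_F=lam, base=base, dir1=dir1, dir2=dir2,
                   offsets1=u, offsets2=v, clamped=clamped, t_max=t_max,
                   seed=seed)
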