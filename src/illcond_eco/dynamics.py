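"""Generalized Lotka-Volterra dynamics and stiff numerical integration.

The model is

    dn_i/dt = n_i * (r_i + sum_j A_ij n_j),

integrated with an implicit Runge-Kutta scheme (Radau) that uses the
analytic Jacobian

    J_ij = delta_ij * (r_i + (A n)_i) + n_i * A_ij.

Integration terminates on one of three events: the derivative floor
(max |dn/dt| below a threshold, i.e. the trajectory has reached the global
equilibrium to solver precision), the time horizon, or a blow-up guard for
non-diagonally-stable matrices.  Negative abundances are never clipped;
accuracy near zero is delegated to the stiff solver so that settling times
and Lyapunov indicators are not corrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .ensembles import Ecosystem

log = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-12
DEFAULT_ATOL = 1e-12
DEFAULT_DERIV_FLOOR = 1e-14
DEFAULT_BLOWUP = 1e12
DEFAULT_T_MAX = 1e6


@dataclass
class Trajectory:
    """One integration of the Lotka-Volterra dynamics.

    ``sol`` (when present) is the solver's dense-output interpolant;
    calling the trajectory evaluates states at arbitrary times.
    """

    times: np.ndarray
    states: np.ndarray  # (T, N)
    terminal_reason: str  # derivative-floor | t-max | blow-up
    solver_stats: dict = field(default_factory=dict)
    sol: Optional[object] = None  # scipy OdeSolution

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def __call__(self, t):
        """Dense evaluation of the state at time(s) ``t``, shape (..., N).

        Uses the solver interpolant when available, otherwise linear
        interpolation between the recorded samples.
        """
        if self.sol is None:
            t = np.asarray(t, dtype=float)
            if len(self.times) < 2:
                return np.broadcast_to(self.states[-1],
                                       t.shape + (self.n_species,)).copy()
            out = np.stack([np.interp(t, self.times, self.states[:, i])
                            for i in range(self.n_species)], axis=-1)
            return out
        return np.atleast_2d(np.asarray(self.sol(t)).T).reshape(
            np.shape(t) + (self.n_species,))

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        cols = [f"s{i + 1:04d}" for i in range(self.n_species)]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def rhs(n: np.ndarray, eco: Ecosystem) -> np.ndarray:
    """Right-hand side n_i (r_i + (A n)_i)."""
    n = np.asarray(n, dtype=float)
    if n.shape != eco.r.shape:
        raise ValueError(f"state length {n.shape} does not match N={eco.N}")
    return n * (eco.r + eco.A @ n)


def jacobian(n: np.ndarray, eco: Ecosystem) -> np.ndarray:
    """Analytic Jacobian.

    At an interior equilibrium the growth term vanishes and J reduces to
    the community matrix diag(n*) A.
    """
    n = np.asarray(n, dtype=float)
    if n.shape != eco.r.shape:
        raise ValueError(f"state length {n.shape} does not match N={eco.N}")
    J = n[:, None] * eco.A
    J[np.diag_indices_from(J)] += eco.r + eco.A @ n
    return J


def community_matrix(n_star: np.ndarray, eco: Ecosystem) -> np.ndarray:
    """diag(n*) A, the Jacobian restricted to its equilibrium form."""
    return np.asarray(n_star, dtype=float)[:, None] * eco.A


def integrate(
    eco: Ecosystem,
    n0: np.ndarray,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    deriv_floor: float = DEFAULT_DERIV_FLOOR,
    blowup_guard: float = DEFAULT_BLOWUP,
    dense_output: bool = True,
    t_eval: Optional[np.ndarray] = None,
    method: str = "Radau",
) -> Trajectory:
    """Integrate the dynamics from ``n0`` until equilibrium or ``t_max``.

    The derivative-floor event fires when ``max |dn/dt| < deriv_floor``
    (evaluated in log scale to avoid overshoot); the blow-up guard fires
    when any abundance exceeds ``blowup_guard``, which is reported as
    ``terminal_reason='blow-up'`` rather than raised.
    """
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != eco.r.shape:
        raise ValueError(f"n0 length {n0.shape} does not match N={eco.N}")
    if np.any(n0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    A, r = eco.A, eco.r
    log_floor = np.log10(deriv_floor)

    def f(t, y):
        return y * (r + A @ y)

    def jac(t, y):
        J = y[:, None] * A
        J[np.diag_indices_from(J)] += r + A @ y
        return J

    # already at equilibrium: no integration needed
    if float(np.max(np.abs(f(0.0, n0)))) < deriv_floor:
        return Trajectory(times=np.array([0.0]), states=n0[None, :].copy(),
                          terminal_reason="derivative-floor",
                          solver_stats={"nfev": 1, "njev": 0, "n_steps": 0,
                                        "rtol": rtol, "atol": atol})

    def ev_floor(t, y):
        m = np.max(np.abs(y * (r + A @ y)))
        return np.log10(m) - log_floor if m > 0 else -300.0

    ev_floor.terminal = True
    ev_floor.direction = -1

    def ev_blowup(t, y):
        return np.max(y) - blowup_guard

    ev_blowup.terminal = True
    ev_blowup.direction = 1

    res = solve_ivp(f, (0.0, t_max), n0, method=method, jac=jac, rtol=rtol,
                    atol=atol, dense_output=dense_output, t_eval=t_eval,
                    events=(ev_floor, ev_blowup))
    if res.status == 1:
        if len(res.t_events[1]):
            reason = "blow-up"
        else:
            reason = "derivative-floor"
    else:
        reason = "t-max"
        log.warning("integration reached t_max=%g without hitting the "
                    "derivative floor", t_max)
    stats = {"nfev": res.nfev, "njev": res.njev, "nlu": res.nlu,
             "n_steps": len(res.t) - 1, "rtol": rtol, "atol": atol,
             "method": method}
    return Trajectory(times=res.t, states=res.y.T, terminal_reason=reason,
                      solver_stats=stats, sol=res.sol)
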