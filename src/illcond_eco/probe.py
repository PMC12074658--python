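"""Pulse-perturbation probes of equilibrated ecosystems.

A multifactorial pulse -- a small random Gaussian kick applied
simultaneously to all surviving species -- plays the role of the random
start vector in Krylov iteration: the directions of fastest and slowest
return to equilibrium reveal the extremal singular vectors of A, and
hence the conditioning, without measuring A itself.  Responses are
projected onto the first and last right singular vectors, and a
single-time-series diagnostic tracks the alignment of the
finite-difference velocity with the fast/slow directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .dynamics import Trajectory, integrate
from .ensembles import Ecosystem
from .equilibrium import DEFAULT_XI, find_equilibrium, settling_time


@dataclass
class AlignmentSeries:
    """|cos| alignment of the finite-difference velocity with directions."""

    times: np.ndarray
    alignment: np.ndarray  # (n_directions, T), NaN where masked
    mask: np.ndarray  # True where velocity was well-defined
    method: str = "inner"


@dataclass
class PerturbationExperiment:
    n_star: np.ndarray
    support: np.ndarray
    w_first: np.ndarray  # leading right singular vector of A (fast)
    w_last: np.ndarray  # trailing right singular vector of A (slow)
    pulses: np.ndarray  # (R, N) applied perturbations
    times: np.ndarray  # shared evaluation grid
    proj_fast: np.ndarray  # (R, T) n(t) . w_first
    proj_slow: np.ndarray  # (R, T) n(t) . w_last
    align_fast: np.ndarray  # (R, T) velocity alignment, NaN-masked
    align_slow: np.ndarray
    return_times: np.ndarray  # (R,) settling times back to n*
    returned: np.ndarray  # (R,) bool flags
    amplitude: float
    meta: dict = field(default_factory=dict)

    def alignment_mean_se(self) -> dict:
        """Across-replicate mean and standard error of the alignments."""
        out = {}
        for name, arr in (("fast", self.align_fast),
                          ("slow", self.align_slow)):
            n = np.sum(~np.isnan(arr), axis=0)
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = sd / np.sqrt(n)
            out[name] = {"mean": mean, "se": se, "n": n}
        return out


def apply_pulse(
    eco: Ecosystem,
    n_star: np.ndarray,
    amplitude: float,
    rng: Union[int, Generator, None] = None,
    support: Optional[np.ndarray] = None,
    threshold: Optional[float] = None,
) -> np.ndarray:
    """n* plus a Gaussian pulse of standard deviation ``amplitude``.

    Perturbation entries of species extinct at steady state are set to
    exactly zero; the perturbed state is clipped to be nonnegative
    (abundances are physical).
    """
    from .equilibrium import support_indices

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = default_rng(rng)
    n_star = np.asarray(n_star, dtype=float)
    if support is None:
        support = support_indices(n_star, threshold)
    delta = np.zeros_like(n_star)
    delta[support] = rng.normal(0.0, amplitude, size=len(support))
    return np.maximum(n_star + delta, 0.0)


def velocity_alignment(
    traj: Union[Trajectory, Tuple[np.ndarray, np.ndarray]],
    directions: Sequence[np.ndarray],
    method: str = "inner",
) -> AlignmentSeries:
    """Per-time alignment of the trajectory velocity with unit directions.

    Velocities are central finite differences of the sampled states.  The
    primary ``method='inner'`` reports the absolute normalized inner
    product |v . d| / ||v|| (sign-folded: singular vectors are
    sign-ambiguous); ``method='pearson'`` reports the absolute Pearson
    correlation of the components.  A direction may also be a matrix of
    orthonormal rows, in which case the alignment is the fraction of the
    velocity norm inside that subspace, ||D v|| / ||v||.  Times where the
    velocity is numerically zero (stationary segments) are masked as NaN.
    """
    if method not in ("inner", "pearson"):
        raise ValueError("method must be 'inner' or 'pearson'")
    if isinstance(traj, Trajectory):
        times, states = traj.times, traj.states
    else:
        times, states = traj
    times = np.asarray(times, dtype=float)
    states = np.asarray(states, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples for central differences")
    vel = np.gradient(states, times, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    floor = 1e-14 * max(1.0, float(np.abs(states).max()))
    ok = speed > floor
    align = np.full((len(directions), len(times)), np.nan)
    for k, d in enumerate(directions):
        d = np.asarray(d, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if d.ndim == 2:  # orthonormal-row subspace
                a = np.linalg.norm(vel @ d.T, axis=1) / speed
            elif method == "inner":
                a = np.abs(vel @ (d / np.linalg.norm(d))) / speed
            else:
                vc = vel - vel.mean(axis=1, keepdims=True)
                dc = d - d.mean()
                denom = np.linalg.norm(vc, axis=1) * np.linalg.norm(dc)
                a = np.abs(vc @ dc) / denom
        align[k, ok] = a[ok]
    return AlignmentSeries(times=times, alignment=align, mask=ok,
                           method=method)


def probe_ensemble(
    eco: Ecosystem,
    n_pulses: int = 100,
    amplitude: float = 1e-3,
    n_star: Optional[np.ndarray] = None,
    seed: Union[int, SeedSequence] = 0,
    xi: float = DEFAULT_XI,
    n_grid: int = 201,
    t_max: float = 1e8,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deriv_floor: float = 1e-14,
    method: str = "inner",
    grid: str = "geometric",
) -> PerturbationExperiment:
    """Ensemble of pulse-response experiments at the global steady state.

    Each pulse is integrated back to equilibrium; responses are evaluated
    on a shared time grid, projected onto the extremal right singular
    vectors of A, and the velocity-alignment series is computed per pulse.
    Trajectories that do not return to within ``xi`` of n* are flagged.

    The shared grid is geometric by default (relaxation after a pulse
    spans the decades between the fast interaction timescale and the slow
    eps-scale sorting; a linear grid would put the whole fast epoch in
    its first cell); pass ``grid='linear'`` for uniformly spaced times.
    The derivative floor must resolve distances below ``xi`` -- the
    default ``1e-14`` stops integration only once the slow-mode residual
    is far inside the xi-ball.
    """
    from .equilibrium import support_indices

    root = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    kids = root.spawn(n_pulses + 1)
    if n_star is None:
        ic = default_rng(kids[-1]).uniform(0.0, 1.0, size=eco.N)
        eq = find_equilibrium(eco, ic, xi=xi, rtol=rtol, atol=atol)
        n_star = eq.n_star
    n_star = np.asarray(n_star, dtype=float)
    support = support_indices(n_star)
    _, _, Vt = np.linalg.svd(eco.A)
    w_first, w_last = Vt[0], Vt[-1]
    # fast / slow subspaces for the alignment series: the leading M right
    # singular vectors span the group-level (fast) dynamics, the trailing
    # N - M span the eps-scale redundant (slow) directions
    from .ensembles import EnsembleParams as _EP

    if isinstance(eco.params, _EP) and eco.params.M < eco.N:
        k_fast = eco.params.M
    else:
        k_fast = max(1, eco.N // 2)
    V_fast, V_slow = Vt[:k_fast], Vt[k_fast:]

    pulses, trajs, ret_times, returned = [], [], [], []
    for k in range(n_pulses):
        state0 = apply_pulse(eco, n_star, amplitude,
                             rng=default_rng(kids[k]), support=support)
        pulses.append(state0 - n_star)
        traj = integrate(eco, state0, t_max=t_max, rtol=rtol, atol=atol,
                         deriv_floor=deriv_floor)
        trajs.append(traj)
        # the return time is measured against the pulse's own settled
        # state; "returned" additionally demands that this state is the
        # base steady state up to the pulse scale -- near-marginal
        # species keep creeping on timescales far beyond xi, so replicate
        # endpoints agree to ~pulse amplitude rather than to xi
        end = np.maximum(traj.endpoint, 0.0)
        tau = settling_time(traj, end, xi=xi)
        back = float(np.linalg.norm(end - n_star)) <= max(
            10 * xi, 3.0 * amplitude * np.sqrt(max(1, support.size)))
        ok = (tau is not None
              and traj.terminal_reason == "derivative-floor"
              and back)
        ret_times.append(np.nan if tau is None else tau)
        returned.append(ok)
    ret_times = np.asarray(ret_times)
    t_end = np.nanmax(ret_times) if np.any(np.isfinite(ret_times)) else \
        max(t.times[-1] for t in trajs)
    if grid == "geometric":
        t_grid = np.concatenate([[0.0],
                                 np.geomspace(max(t_end * 1e-6, 1e-9),
                                              float(t_end), n_grid - 1)])
    elif grid == "linear":
        t_grid = np.linspace(0.0, float(t_end), n_grid)
    else:
        raise ValueError("grid must be 'geometric' or 'linear'")

    R = n_pulses
    proj_fast = np.zeros((R, n_grid))
    proj_slow = np.zeros((R, n_grid))
    align_fast = np.full((R, n_grid), np.nan)
    align_slow = np.full((R, n_grid), np.nan)
    for k, traj in enumerate(trajs):
        # clamp evaluation to the trajectory span (constant past settling),
        # but differentiate on the shared grid so spacings stay positive
        states = traj(np.minimum(t_grid, traj.times[-1]))
        proj_fast[k] = states @ w_first
        proj_slow[k] = states @ w_last
        series = velocity_alignment((t_grid, states), (V_fast, V_slow),
                                    method=method)
        align_fast[k] = series.alignment[0]
        align_slow[k] = series.alignment[1]
        # past the pulse's own return time the velocity is numerical
        # noise, not response dynamics: mask it
        if np.isfinite(ret_times[k]):
            post = t_grid > ret_times[k]
            align_fast[k, post] = np.nan
            align_slow[k, post] = np.nan
    return PerturbationExperiment(
        n_star=n_star, support=support, w_first=w_first, w_last=w_last,
        pulses=np.asarray(pulses), times=t_grid, proj_fast=proj_fast,
        proj_slow=proj_slow, align_fast=align_fast, align_slow=align_slow,
        return_times=ret_times, returned=np.asarray(returned),
        amplitude=amplitude, meta={"xi": xi, "method": method})
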