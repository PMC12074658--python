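"""Condition-number analytics.

The condition number kappa(A) = sigma_max / sigma_min (equivalently
||A||_2 ||A^-1||_2) measures both the difficulty of solving -A n = r and
the timescale separation of the ecosystem: redundancy (eps -> 0) drives
N - M singular values to the eps scale and kappa towards infinity.  This
module also provides the restricted condition number of the survivor
column-minor, the iterative-solver convergence-time bound, the
rectangular-random-matrix scaling law, Weyl singular-value gaps against
the eps=0 counterpart, and the numerical multistability-transition scan
for the scaled-interaction ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .dynamics import integrate
from .ensembles import BuninParams, Ecosystem, sample_bunin_ecosystem

log = logging.getLogger(__name__)


@dataclass
class ConditioningReport:
    kappa: float
    singular_values: np.ndarray  # descending
    kappa_restricted: Optional[float] = None
    weyl_max_gap: Optional[float] = None


def _svdvals(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a matrix")
    if not np.any(A):
        raise ValueError("condition number of the zero matrix is undefined")
    return np.linalg.svd(A, compute_uv=False)


def condition_number(A: np.ndarray) -> float:
    """kappa = sigma_max / sigma_min from a full SVD.

    Returns ``inf`` when sigma_min is below the machine-relative floor
    (numerically rank-deficient matrix).
    """
    s = _svdvals(A)
    floor = max(A.shape) * np.finfo(float).eps * s[0]
    if s[-1] <= floor:
        return np.inf
    return float(s[0] / s[-1])


def restricted_condition_number(A: np.ndarray,
                                support: Sequence[int]) -> float:
    """kappa of the N x |support| minor of the columns of surviving species."""
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("support must be nonempty")
    return condition_number(np.asarray(A, dtype=float)[:, support])


def kappa_scaling_law(N: int, Ncoex: int) -> float:
    """Expected condition number of a random N x Ncoex Gaussian matrix:
    9.563 N / (N - Ncoex + 1)."""
    if not 1 <= Ncoex <= N:
        raise ValueError(f"require 1 <= Ncoex <= N, got Ncoex={Ncoex}, N={N}")
    return 9.563 * N / (N - Ncoex + 1)


def iterative_time_bound(kappa: float, xi: float) -> float:
    """Convergence-time bound of an iterative linear solver:
    tau = log(xi) / log((kappa - 1)/(kappa + 1)), natural logarithms."""
    if kappa <= 1:
        raise ValueError("bound degenerates for kappa <= 1")
    if not 0 < xi <= 1:
        raise ValueError("xi must lie in (0, 1]")
    return float(np.log(xi) / np.log((kappa - 1.0) / (kappa + 1.0)))


@dataclass
class WeylGapReport:
    gaps: np.ndarray  # |sigma_i(A) - sigma_i(A - eps E_masked)| per index
    max_gap: float
    bound: float  # the loose bound eps * rho * N
    n_eps_scale: int  # singular values of A at scale ~eps


def weyl_gap(eco: Ecosystem) -> WeylGapReport:
    """Per-index singular-value shifts between A and its eps=0 counterpart.

    Weyl's inequality bounds every shift by the spectral norm of the
    perturbation eps * E (after masking); the reported ``bound`` is the
    looser analytic form eps * rho * N.  ``n_eps_scale`` counts singular
    values of A below 10 eps, the degenerate set that the perturbation
    lifted from zero.
    """
    from .ensembles import EnsembleParams

    if not isinstance(eco.params, EnsembleParams) or eco.A0 is None:
        raise ValueError("weyl_gap requires the generative metadata of the "
                         "low-rank ensemble")
    eps = eco.params.epsilon
    s = np.linalg.svd(eco.A, compute_uv=False)
    s0 = np.linalg.svd(eco.epsilon_zero().A, compute_uv=False)
    gaps = np.abs(s - s0)
    bound = eps * eco.params.rho * eco.N
    n_eps = int(np.sum(s < 10.0 * eps)) if eps > 0 else 0
    return WeylGapReport(gaps=gaps, max_gap=float(gaps.max()), bound=bound,
                         n_eps_scale=n_eps)


def conditioning_report(eco: Ecosystem,
                        support: Optional[Sequence[int]] = None
                        ) -> ConditioningReport:
    s = _svdvals(eco.A)
    kappa = condition_number(eco.A)
    kr = (restricted_condition_number(eco.A, support)
          if support is not None and len(support) else None)
    try:
        wmax: Optional[float] = weyl_gap(eco).max_gap
    except ValueError:
        wmax = None
    return ConditioningReport(kappa=kappa, singular_values=s,
                              kappa_restricted=kr, weyl_max_gap=wmax)


def cluster_endpoints(points: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    """Agglomerative (single-linkage) clustering of trajectory endpoints at
    an absolute Euclidean distance tolerance; returns integer labels."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(pdist(points), method="single")
    return fcluster(Z, t=tol, criterion="distance") - 1


@dataclass
class BuninTransitionReport:
    """Numerical multistability scan of the scaled-interaction ensemble."""

    sigmas: np.ndarray
    frac_multistable: np.ndarray  # fraction of replicates with >= 2 endpoints
    mean_kappa: np.ndarray
    sigma_c: Optional[float]  # 50%-crossing by linear interpolation
    gamma: float
    mu: float
    N: int
    replicates: int
    n_initials: int
    n_blowups: int = 0
    details: dict = field(default_factory=dict)


def bunin_transition_scan(
    sigmas: Sequence[float],
    gamma: float = 0.0,
    mu: float = 2.0,
    N: int = 150,
    replicates: int = 20,
    n_initials: int = 10,
    seed: Union[int, SeedSequence] = 0,
    cluster_tol: float = 1e-4,
    t_max: float = 250.0,
    rtol: float = 1e-5,
    atol: float = 1e-8,
    deriv_floor: float = 1e-7,
    blowup_guard: float = 1e4,
    polish: bool = True,
) -> BuninTransitionReport:
    """Scan sigma for the onset of multistability at fixed gamma.

    For each sigma, ``replicates`` random ecosystems are each integrated
    from ``n_initials`` uniform(0,1) initial conditions; endpoints are
    clustered at ``cluster_tol`` and a replicate counts as multistable when
    it shows >= 2 distinct endpoints.  The onset sigma_c is the first
    upward crossing of the 50% multistable fraction, linearly interpolated
    on the sigma grid; ``None`` when the grid never crosses.  Blown-up
    trajectories are excluded from clustering and counted.

    With ``polish`` (default) each endpoint is projected onto the exact
    equilibrium of its survivor support before clustering, so the
    comparison tests basin identity rather than leftover integration
    transients; this permits a short horizon and coarse solver tolerances
    (committing to a basin is much faster than converging within the
    clustering tolerance, which matters near the critical point where
    relaxation suffers critical slowing)."""
    sigmas = np.asarray(sigmas, dtype=float)
    root = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    frac = np.zeros(sigmas.size)
    mean_kappa = np.zeros(sigmas.size)
    n_blow = 0
    n_clusters_detail = []
    for si, sigma in enumerate(sigmas):
        multi = 0
        kappas = []
        ncl_row = []
        for rep in range(replicates):
            ss = SeedSequence(entropy=root.entropy, spawn_key=(si, rep))
            kids = ss.spawn(2)
            eco_rng, ic_rng = default_rng(kids[0]), default_rng(kids[1])
            params = BuninParams(N=N, mu=mu, sigma=float(sigma), gamma=gamma)
            eco = sample_bunin_ecosystem(params, rng=eco_rng)
            kappas.append(condition_number(eco.A))
            endpoints = []
            for _ in range(n_initials):
                n0 = ic_rng.uniform(0.0, 1.0, size=N)
                traj = integrate(eco, n0, t_max=t_max, rtol=rtol, atol=atol,
                                 deriv_floor=deriv_floor,
                                 blowup_guard=blowup_guard,
                                 dense_output=False)
                if traj.terminal_reason == "blow-up":
                    n_blow += 1
                    continue
                end = traj.endpoint
                if polish:
                    from .equilibrium import polish_equilibrium

                    try:
                        end = polish_equilibrium(eco.A, eco.r, end)
                    except RuntimeError:
                        pass  # keep the raw endpoint
                endpoints.append(end)
            ncl = 0
            if endpoints:
                labels = cluster_endpoints(np.array(endpoints), cluster_tol)
                ncl = int(labels.max()) + 1
                if ncl >= 2:
                    multi += 1
            ncl_row.append(ncl)
        frac[si] = multi / replicates
        mean_kappa[si] = float(np.mean(kappas))
        n_clusters_detail.append(ncl_row)
        log.info("sigma=%.3g frac_multistable=%.2f mean_kappa=%.3g",
                 sigma, frac[si], mean_kappa[si])
    sigma_c = _interpolate_crossing(sigmas, frac, level=0.5)
    return BuninTransitionReport(
        sigmas=sigmas, frac_multistable=frac, mean_kappa=mean_kappa,
        sigma_c=sigma_c, gamma=gamma, mu=mu, N=N, replicates=replicates,
        n_initials=n_initials, n_blowups=n_blow,
        details={"n_clusters": n_clusters_detail})


def _interpolate_crossing(x: np.ndarray, y: np.ndarray,
                          level: float = 0.5) -> Optional[float]:
    """First upward linear-interpolated crossing of ``level``; None if the
    curve never crosses from below."""
    if y[0] >= level:
        return float(x[0])
    for i in range(1, len(x)):
        if y[i] >= level > y[i - 1]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(x[i - 1] + f * (x[i] - x[i - 1]))
    return None
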