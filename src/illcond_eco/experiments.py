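"""Configuration-driven reproduction of the in-silico experiments.

Each experiment is a pure function returning tidy tabular results; the
``run_experiment`` dispatcher adds deterministic seeding, output files
(CSV/JSON only) and a manifest sufficient for bit-identical replay.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import __version__
from .conditioning import bunin_transition_scan, condition_number
from .dynamics import integrate
from .ensembles import Ecosystem, EnsembleParams, sample_ecosystem
from .equilibrium import settling_time, support_indices
from .evolution import GAConfig, run_evolution
from .lyapunov import fli_slice
from .manifold import embed_trajectories
from .probe import probe_ensemble

log = logging.getLogger(__name__)

EXPERIMENTS = ("simulate", "scan-kappa", "fli-map", "embed", "evolve",
               "perturb", "bunin-sweep", "connectance-sweep", "mn-sweep")


@dataclass
class ExperimentConfig:
    """One experiment run: name, parameters, scale overrides, seed, output."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; choose one "
                             f"of {EXPERIMENTS}")


def scan_kappa(
    n_ecosystems: int = 300,
    N: int = 100,
    M: int = 10,
    eps_min: float = 1e-5,
    eps_max: float = 1e-1,
    rho: float = 0.05,
    assignment_mode: str = "random-groups",
    seed: int = 0,
    xi: float = 1e-7,
    t_max: float = 1e12,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    deriv_floor: float = 1e-12,
) -> pd.DataFrame:
    """Settling time tau versus condition number kappa over an ensemble.

    Each replicate draws epsilon log-uniformly from [eps_min, eps_max],
    samples a fresh redundant ecosystem, integrates one uniform(0,1)
    initial condition to equilibrium, and records
    (epsilon, seed, kappa, tau, ncoex).
    """
    root = SeedSequence(seed)
    rows = []
    for i in range(n_ecosystems):
        ss = SeedSequence(entropy=root.entropy, spawn_key=(i,))
        kids = ss.spawn(3)
        eps = float(np.exp(default_rng(kids[0]).uniform(
            np.log(eps_min), np.log(eps_max))))
        params = EnsembleParams(N=N, M=M, epsilon=eps, rho=rho,
                                assignment_mode=assignment_mode)
        eco = sample_ecosystem(params, rng=kids[1])
        n0 = default_rng(kids[2]).uniform(0.0, 1.0, size=N)
        traj = integrate(eco, n0, t_max=t_max, rtol=rtol, atol=atol,
                         deriv_floor=deriv_floor)
        if traj.terminal_reason == "blow-up":
            log.warning("replicate %d blew up; skipped", i)
            continue
        n_star = np.maximum(traj.endpoint, 0.0)
        tau = settling_time(traj, n_star, xi=xi)
        rows.append({"epsilon": eps, "seed": i,
                     "kappa": condition_number(eco.A),
                     "tau": np.nan if tau is None else tau,
                     "ncoex": int(support_indices(n_star).size)})
    return pd.DataFrame(rows)


def _experiment_scan_kappa(cfg, out):
    df = scan_kappa(seed=cfg.seed, **cfg.params)
    df.to_csv(out / "scan_kappa.csv", index=False)
    return {"rows": len(df)}


def _experiment_bunin_sweep(cfg, out):
    p = dict(cfg.params)
    sigmas = p.pop("sigmas", np.arange(1.0, 3.01, 0.2))
    report = bunin_transition_scan(sigmas, seed=cfg.seed, **p)
    df = pd.DataFrame({"sigma": report.sigmas,
                       "gamma": report.gamma,
                       "frac_multistable": report.frac_multistable,
                       "mean_kappa": report.mean_kappa})
    df.to_csv(out / "bunin_sweep.csv", index=False)
    return {"sigma_c": report.sigma_c, "n_blowups": report.n_blowups}


def _experiment_fli_map(cfg, out):
    p = dict(cfg.params)
    ens = {k: p.pop(k) for k in
           ("N", "M", "epsilon", "rho", "assignment_mode", "d") if k in p}
    base = p.pop("base", None)
    eco = sample_ecosystem(EnsembleParams(**ens), rng=cfg.seed)
    if base is None:
        base = default_rng(SeedSequence(cfg.seed).spawn(1)[0]).uniform(
            0.0, 1.0, size=eco.N)
    grid = fli_slice(eco, np.asarray(base, dtype=float), seed=cfg.seed, **p)
    np.savetxt(out / "fli_grid.csv", grid.lambda_F, delimiter=",")
    sidecar = {"base": grid.base.tolist(), "dir1": grid.dir1.tolist(),
               "dir2": grid.dir2.tolist(),
               "offsets1": grid.offsets1.tolist(),
               "offsets2": grid.offsets2.tolist(),
               "t_max": grid.t_max, "seed": cfg.seed,
               "clamped_cells": int((grid.clamped > 0).sum())}
    (out / "fli_grid.json").write_text(json.dumps(sidecar, indent=2))
    return {"grid_shape": list(grid.lambda_F.shape),
            "lambda_range": [float(grid.lambda_F.min()),
                             float(grid.lambda_F.max())]}


def _experiment_embed(cfg, out):
    p = dict(cfg.params)
    ens = {k: p.pop(k) for k in
           ("N", "M", "epsilon", "rho", "assignment_mode", "d") if k in p}
    n_traj = p.pop("n_trajectories", 10)
    K = p.pop("K", None)
    t_kw = {k: p.pop(k) for k in ("t_max", "rtol", "atol", "deriv_floor")
            if k in p}
    params = EnsembleParams(**ens)
    eco = sample_ecosystem(params, rng=cfg.seed)
    if K is None:
        K = params.M
    rng = default_rng(SeedSequence(cfg.seed).spawn(1)[0])
    trajs = [integrate(eco, rng.uniform(0.0, 1.0, size=eco.N), **t_kw)
             for _ in range(n_traj)]
    bundle = embed_trajectories(trajs, eco, K=K, **p)
    emb = pd.concat([pd.DataFrame(e[:, :2], columns=["pc1", "pc2"])
                     .assign(trajectory=i)
                     for i, e in enumerate(bundle.embeddings)])
    emb.to_csv(out / "embeddings.csv", index=False)
    mesh = pd.DataFrame(np.hstack([bundle.mesh, bundle.mesh_velocity]),
                        columns=["pc1", "pc2", "v1", "v2"])
    mesh.to_csv(out / "mesh_velocity.csv", index=False)
    np.savetxt(out / "pca_components.csv", bundle.pca.components_,
               delimiter=",")
    return {"n_trajectories": n_traj, "K": K}


def _experiment_evolve(cfg, out):
    ga = GAConfig(seed=cfg.seed, **cfg.params)
    history = run_evolution(ga)
    history.to_csv(out / "evolution.csv")
    (out / "ga_settings.json").write_text(
        json.dumps(asdict(ga), indent=2, default=str))
    return {"generations": int(history.table["generation"].max()),
            "final_mean_ncoex": float(history.table["mean_ncoex"].iloc[-1])}


def _experiment_perturb(cfg, out):
    p = dict(cfg.params)
    ens = {k: p.pop(k) for k in
           ("N", "M", "epsilon", "rho", "assignment_mode", "d") if k in p}
    eco = sample_ecosystem(EnsembleParams(**ens), rng=cfg.seed)
    exp = probe_ensemble(eco, seed=cfg.seed, **p)
    proj = pd.DataFrame({"time": np.tile(exp.times, len(exp.pulses)),
                         "pulse": np.repeat(np.arange(len(exp.pulses)),
                                            len(exp.times)),
                         "proj_fast": exp.proj_fast.ravel(),
                         "proj_slow": exp.proj_slow.ravel()})
    proj.to_csv(out / "projections.csv", index=False)
    stats = exp.alignment_mean_se()
    align = pd.DataFrame({"time": exp.times,
                          "align_fast_mean": stats["fast"]["mean"],
                          "align_fast_se": stats["fast"]["se"],
                          "align_slow_mean": stats["slow"]["mean"],
                          "align_slow_se": stats["slow"]["se"]})
    align.to_csv(out / "alignment.csv", index=False)
    return {"n_pulses": len(exp.pulses),
            "all_returned": bool(exp.returned.all())}


def _experiment_simulate(cfg, out):
    p = dict(cfg.params)
    archive = p.pop("ecosystem", None)
    t_kw = {k: p.pop(k) for k in ("t_max", "rtol", "atol", "deriv_floor")
            if k in p}
    if archive is not None:
        eco = Ecosystem.load(archive)
    else:
        ens = {k: p.pop(k) for k in
               ("N", "M", "epsilon", "rho", "assignment_mode", "d")
               if k in p}
        eco = sample_ecosystem(EnsembleParams(**ens), rng=cfg.seed)
    n0 = p.pop("n0", None)
    if n0 is None:
        n0 = default_rng(SeedSequence(cfg.seed).spawn(1)[0]).uniform(
            0.0, 1.0, size=eco.N)
    traj = integrate(eco, np.asarray(n0, dtype=float), **t_kw)
    traj.to_csv(out / "trajectory.csv")
    return {"terminal_reason": traj.terminal_reason,
            "t_end": float(traj.times[-1])}


def _experiment_connectance_sweep(cfg, out):
    p = dict(cfg.params)
    rhos = p.pop("rhos", (0.05, 0.2, 1.0))
    frames = []
    for rho in rhos:
        df = scan_kappa(rho=float(rho), seed=cfg.seed, **p)
        frames.append(df.assign(rho=float(rho)))
    full = pd.concat(frames, ignore_index=True)
    full.to_csv(out / "connectance_sweep.csv", index=False)
    return {"rhos": list(rhos), "rows": len(full)}


def _experiment_mn_sweep(cfg, out):
    p = dict(cfg.params)
    Ms = p.pop("Ms", (5, 10, 20))
    frames = []
    for M in Ms:
        df = scan_kappa(M=int(M), seed=cfg.seed, **p)
        frames.append(df.assign(M=int(M)))
    full = pd.concat(frames, ignore_index=True)
    full.to_csv(out / "mn_sweep.csv", index=False)
    return {"Ms": list(Ms), "rows": len(full)}


_DISPATCH = {
    "simulate": _experiment_simulate,
    "scan-kappa": _experiment_scan_kappa,
    "fli-map": _experiment_fli_map,
    "embed": _experiment_embed,
    "evolve": _experiment_evolve,
    "perturb": _experiment_perturb,
    "bunin-sweep": _experiment_bunin_sweep,
    "connectance-sweep": _experiment_connectance_sweep,
    "mn-sweep": _experiment_mn_sweep,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Dispatch an experiment, write outputs plus a JSON manifest.

    The manifest echoes the full configuration (sufficient for replay),
    the package version, and wall-clock runtime.  Exit status reflects
    completion, not the scientific outcome.
    """
    out = Path(config.out or f"results_{config.name}")
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary = _DISPATCH[config.name](config, out)
    manifest = {
        "experiment": config.name,
        "seed": config.seed,
        "params": _jsonable(config.params),
        "version": __version__,
        "runtime_s": round(time.time() - t0, 3),
        "summary": _jsonable(summary),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
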