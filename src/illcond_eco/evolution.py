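"""Genetic-algorithm meta-optimization of foodwebs.

Populations of interaction matrices are evolved under selection for
steady-state diversity: each individual is integrated to its equilibrium,
fitness is the number of coexisting species Ncoex, the top elite fraction
survives unchanged, and the rest are rebuilt from random blocks of
row-column pairs copied from elite parents.  The growth-rate vector r is
held constant across all individuals and generations -- growth rates are
the only trait distinguishing niches, and letting them evolve collapses
the population onto identical species.  Selection for diversity drives
the condition number kappa upward: packed communities inevitably contain
nearly substitutable species.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .conditioning import condition_number
from .dynamics import integrate
from .ensembles import Ecosystem, EnsembleParams, sample_ecosystem
from .equilibrium import support_indices

log = logging.getLogger(__name__)


@dataclass
class GAConfig:
    """Settings of the evolutionary simulation.

    ``block_size`` defaults to max(1, N // 10) contiguous species indices;
    block size 1 recombines per-species row-column pairs.  Fitness
    integrations use their own (looser) solver settings: survivor counting
    only requires the equilibrium support, not high-precision timing.
    """

    N: int = 40
    pop_size: int = 100
    generations: int = 60
    elite_frac: float = 0.1
    block_size: Optional[int] = None
    mutation_rate: float = 0.0
    mutation_scale: float = 0.1
    single_parent: bool = False
    rho: float = 0.05
    seed: int = 0
    # fitness-evaluation integrator settings
    t_max: float = 1e4
    rtol: float = 1e-8
    atol: float = 1e-10
    deriv_floor: float = 1e-8
    record_kappa: bool = True
    checkpoint_every: int = 0  # 0 disables population checkpoints

    def resolved_block_size(self) -> int:
        return self.block_size or max(1, self.N // 10)


@dataclass
class EvolutionHistory:
    """Per-generation population statistics of one GA run."""

    table: pd.DataFrame  # generation, mean/q10/q90 ncoex and kappa
    settings: GAConfig
    r: np.ndarray
    final_population: List[np.ndarray]
    checkpoints: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _matrix_key(A: np.ndarray) -> bytes:
    return hashlib.sha1(np.ascontiguousarray(A).tobytes()).digest()


def evaluate_fitness(
    population: Sequence[np.ndarray],
    r: np.ndarray,
    n0: np.ndarray,
    config: GAConfig,
    cache: Optional[dict] = None,
) -> np.ndarray:
    """Diversity fitness: Ncoex of the equilibrium of each individual.

    Individuals whose trajectory blows up or fails to reach the
    derivative floor are assigned fitness 0 and logged.  Results are
    cached by matrix hash so elite survivors are not re-integrated.
    """
    scores = np.zeros(len(population), dtype=float)
    for i, A in enumerate(population):
        key = _matrix_key(A)
        if cache is not None and key in cache:
            scores[i] = cache[key]
            continue
        eco = Ecosystem(A=A, r=r)
        traj = integrate(eco, n0, t_max=config.t_max, rtol=config.rtol,
                         atol=config.atol, deriv_floor=config.deriv_floor,
                         dense_output=False)
        if traj.terminal_reason != "derivative-floor":
            log.warning("individual %d did not equilibrate (%s); fitness 0",
                        i, traj.terminal_reason)
            score = 0.0
        else:
            score = float(support_indices(
                np.maximum(traj.endpoint, 0.0)).size)
        scores[i] = score
        if cache is not None:
            cache[key] = score
    return scores


def _contiguous_blocks(N: int, block_size: int) -> List[np.ndarray]:
    edges = list(range(0, N, block_size)) + [N]
    return [np.arange(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def select_and_recombine(
    population: Sequence[np.ndarray],
    scores: np.ndarray,
    rng: Generator,
    config: GAConfig,
) -> List[np.ndarray]:
    """Elitist selection plus block row-column recombination.

    The top ``elite_frac`` of individuals (ties broken by a seeded
    shuffle) are copied unchanged.  Each replacement child partitions the
    species indices into contiguous blocks; for every block one elite
    parent is chosen uniformly (a single parent for all blocks when
    ``single_parent``) and both the rows and the columns of that block are
    copied from it, preserving row-column pairing.  Optional elementwise
    Gaussian mutation perturbs existing nonzero off-diagonal entries.
    """
    pop = list(population)
    n = len(pop)
    if n == 0:
        raise ValueError("population must be nonempty")
    n_elite = max(1, int(np.floor(config.elite_frac * n)))
    order = rng.permutation(n)  # seeded tie-break
    order = order[np.argsort(-scores[order], kind="stable")]
    elites = [pop[i] for i in order[:n_elite]]
    N = pop[0].shape[0]
    blocks = _contiguous_blocks(N, config.resolved_block_size())
    children = []
    for _ in range(n - n_elite):
        child = np.zeros((N, N))
        if config.single_parent:
            parents = [elites[rng.integers(len(elites))]] * len(blocks)
        else:
            parents = [elites[rng.integers(len(elites))] for _ in blocks]
        for blk, parent in zip(blocks, parents):
            child[blk, :] = parent[blk, :]
            child[:, blk] = parent[:, blk]
        if config.mutation_rate > 0:
            mut = ((rng.random((N, N)) < config.mutation_rate)
                   & (child != 0) & ~np.eye(N, dtype=bool))
            child = child + mut * rng.normal(0.0, config.mutation_scale,
                                             size=(N, N))
        children.append(child)
    return [A.copy() for A in elites] + children


def run_evolution(config: GAConfig,
                  rng: Optional[SeedSequence] = None) -> EvolutionHistory:
    """Full GA loop with per-generation Ncoex and kappa statistics.

    Generation 0 statistics describe the initial random population
    (identity assignment, eps=0), so ``generations=0`` returns only the
    initial-population row.  Deterministic given the seed.
    """
    root = rng if rng is not None else SeedSequence(config.seed)
    k_init, k_ga, k_ic = root.spawn(3)
    ga_rng = default_rng(k_ga)
    ic_rng = default_rng(k_ic)

    # shared growth rates across all individuals and generations
    init_streams = k_init.spawn(config.pop_size + 1)
    r = default_rng(init_streams[-1]).standard_normal(config.N)
    population = []
    for i in range(config.pop_size):
        params = EnsembleParams(N=config.N, M=config.N, epsilon=0.0,
                                rho=config.rho, assignment_mode="identity")
        eco = sample_ecosystem(params, rng=init_streams[i])
        population.append(eco.A)
    n0 = ic_rng.uniform(0.0, 1.0, size=config.N)

    cache: dict = {}
    rows = []
    checkpoints = {}
    for gen in range(config.generations + 1):
        scores = evaluate_fitness(population, r, n0, config, cache)
        row = {"generation": gen,
               "mean_ncoex": float(np.mean(scores)),
               "q10_ncoex": float(np.quantile(scores, 0.1)),
               "q90_ncoex": float(np.quantile(scores, 0.9)),
               "max_ncoex": float(np.max(scores))}
        if config.record_kappa:
            kappas = np.array([condition_number(A) for A in population])
            finite = kappas[np.isfinite(kappas)]
            row.update({
                "mean_kappa": float(np.mean(finite)) if finite.size else np.nan,
                "q10_kappa": float(np.quantile(finite, 0.1)) if finite.size else np.nan,
                "q90_kappa": float(np.quantile(finite, 0.9)) if finite.size else np.nan,
            })
        rows.append(row)
        if config.checkpoint_every and gen % config.checkpoint_every == 0:
            checkpoints[gen] = [A.copy() for A in population]
        if gen == config.generations:
            break
        population = select_and_recombine(population, scores, ga_rng, config)
    return EvolutionHistory(table=pd.DataFrame(rows), settings=config, r=r,
                            final_population=population,
                            checkpoints=checkpoints)
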