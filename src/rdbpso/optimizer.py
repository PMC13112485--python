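"""Retrospection-dropout bare-bones particle swarm optimization (RDBPSO).

Bare-bones PSO replaces the velocity update of classical PSO with direct
Gaussian sampling: a new candidate for a pair of guiding positions
``(p1, p2)`` is drawn coordinate-wise from ``N((p1+p2)/2, |p1-p2|)``.

RDBPSO adds two mechanisms on top of this:

* **Retrospection** — each particle keeps a dual-layer memory: its best
  historical solution ``y`` and its second-best ``y_second``, updated
  hierarchically so that ``f(y) <= f(y_second)`` always holds. A global
  pool of all ``2N`` memories supplies the global best/second-best.
* **Dropout** — particles are randomly paired each iteration; the member
  with the better memory fitness leads the pair. Each particle has four
  admissible memory combinations to sample from, of which only two are
  drawn uniformly at random, halving the per-iteration evaluation budget
  from ``4N`` to ``2N``.

All optimizers here minimize; negate the objective to maximize.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Objective",
    "ParticleState",
    "GlobalMemory",
    "OptimizerConfig",
    "OptimizationTrace",
    "initialize_swarm",
    "update_memory",
    "generate_candidate",
    "pair_particles",
    "candidate_combinations",
    "dropout_select",
    "consolidate_global_memory",
    "optimize",
    "optimize_standard_pso",
]


class Objective:
    """Box-bounded minimization objective with evaluation counting.

    Parameters
    ----------
    fn:
        Callable mapping a length-``d`` vector to a scalar (smaller is
        better).
    lower, upper:
        Box bounds; ``lower[j] < upper[j]`` is required for every
        coordinate.
    """

    def __init__(
        self,
        fn: Callable[[np.ndarray], float],
        lower: Sequence[float],
        upper: Sequence[float],
    ) -> None:
        self.fn = fn
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not np.all(self.lower <= self.upper):
            raise ValueError("every lower bound must not exceed its upper bound")
        self.dimension = self.lower.size
        self.n_evaluations = 0

    def evaluate(self, x: np.ndarray) -> float:
        self.n_evaluations += 1
        return float(self.fn(np.asarray(x, dtype=float)))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class ParticleState:
    """Position plus the dual-layer (best / second-best) memory."""

    index: int
    x: np.ndarray
    y: np.ndarray
    f_y: float
    y_second: np.ndarray
    f_y_second: float


@dataclass
class GlobalMemory:
    """Two lowest-fitness entries of the pooled particle memories."""

    gbest: np.ndarray
    gbest_fitness: float
    gsecond: np.ndarray
    gsecond_fitness: float


@dataclass
class OptimizerConfig:
    """Swarm configuration; defaults are the canonical study settings."""

    n_particles: int = 30
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class OptimizationTrace:
    """Per-iteration record of an optimizer run."""

    best_fitness_per_iteration: np.ndarray
    evaluations_per_iteration: np.ndarray
    global_memory: GlobalMemory
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "best_fitness_per_iteration": self.best_fitness_per_iteration.tolist(),
                "evaluations_per_iteration": self.evaluations_per_iteration.tolist(),
                "gbest": self.global_memory.gbest.tolist(),
                "gbest_fitness": self.global_memory.gbest_fitness,
                "gsecond_fitness": self.global_memory.gsecond_fitness,
            }
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, self.best_fitness_per_iteration.size + 1),
                "best_fitness": self.best_fitness_per_iteration,
                "evaluations": self.evaluations_per_iteration,
            }
        ).to_csv(path, index=False)


def _check_finite(fitness: float, index: int, position: np.ndarray) -> None:
    if not np.isfinite(fitness):
        raise ValueError(
            f"objective returned non-finite fitness {fitness!r} for particle "
            f"{index} at position {np.array2string(position, precision=4)}"
        )


def initialize_swarm(
    objective: Objective, config: OptimizerConfig, rng: np.random.Generator
) -> tuple[list[ParticleState], GlobalMemory]:
    """Draw two uniform positions per particle and rank them into memory.

    The lower-fitness draw becomes ``y``, the other ``y_second``; ties keep
    the first draw as ``y``. The current position ``x`` starts at ``y``.
    Consumes exactly ``2N`` objective evaluations.
    """
    particles: list[ParticleState] = []
    for i in range(config.n_particles):
        pos1 = rng.uniform(objective.lower, objective.upper)
        pos2 = rng.uniform(objective.lower, objective.upper)
        f1 = objective.evaluate(pos1)
        _check_finite(f1, i, pos1)
        f2 = objective.evaluate(pos2)
        _check_finite(f2, i, pos2)
        if f1 <= f2:
            y, f_y, y2, f_y2 = pos1, f1, pos2, f2
        else:
            y, f_y, y2, f_y2 = pos2, f2, pos1, f1
        particles.append(
            ParticleState(index=i, x=y.copy(), y=y, f_y=f_y, y_second=y2, f_y_second=f_y2)
        )
    return particles, consolidate_global_memory(particles)


def update_memory(
    particle: ParticleState, candidate: np.ndarray, candidate_fitness: float
) -> ParticleState:
    """Hierarchical dual-layer memory update (in place; returns the particle).

    A candidate strictly better than ``y`` demotes ``y`` to the second
    layer; one at least as good as ``y`` but better than ``y_second``
    replaces only the second layer; anything else is discarded.
    """
    if not np.isfinite(candidate_fitness):
        warnings.warn(
            f"discarding candidate with non-finite fitness for particle {particle.index}",
            RuntimeWarning,
            stacklevel=2,
        )
        return particle
    candidate = np.asarray(candidate, dtype=float)
    if candidate_fitness < particle.f_y:
        particle.y_second = particle.y
        particle.f_y_second = particle.f_y
        particle.y = candidate.copy()
        particle.f_y = candidate_fitness
    elif candidate_fitness < particle.f_y_second:
        particle.y_second = candidate.copy()
        particle.f_y_second = candidate_fitness
    return particle


def generate_candidate(
    p1: np.ndarray, p2: np.ndarray, objective: Objective, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian candidate: mean ``(p1+p2)/2``, stdev ``|p1-p2|``, clipped to the box.

    A coordinate where ``p1`` and ``p2`` agree has zero spread and is
    returned exactly (degenerate Gaussian).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    candidate = rng.normal(loc=(p1 + p2) / 2.0, scale=np.abs(p1 - p2))
    return objective.clip(candidate)


def pair_particles(
    particles: Sequence[ParticleState], rng: np.random.Generator
) -> list[tuple[int | None, int]]:
    """Randomly permute particles and pair them (leader, worker).

    Within a pair the particle with the lower memory fitness ``f(y)``
    leads; on a tie the lower original index leads. With an odd swarm the
    leftover particle is returned as ``(None, index)`` — it runs the
    worker role with the global memories standing in for a leader.
    """
    n = len(particles)
    if n < 2:
        raise ValueError("pairing requires at least 2 particles")
    perm = rng.permutation(n)
    pairs: list[tuple[int | None, int]] = []
    for k in range(0, n - 1, 2):
        i, j = int(perm[k]), int(perm[k + 1])
        a, b = particles[i], particles[j]
        if (a.f_y, a.index) <= (b.f_y, b.index):
            pairs.append((i, j))
        else:
            pairs.append((j, i))
    if n % 2 == 1:
        pairs.append((None, int(perm[-1])))
    return pairs


def candidate_combinations(
    role: str,
    pair: tuple[ParticleState, ParticleState],
    global_mem: GlobalMemory,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The four admissible guiding-position pairs for one particle.

    The leader mixes its own two memories with the two global memories;
    the worker mixes its own two memories with the leader's two. Order is
    canonical and fixed so seeded runs are reproducible.
    """
    leader, worker = pair
    if role == "leader":
        return [
            (global_mem.gbest, leader.y),
            (global_mem.gsecond, leader.y),
            (global_mem.gbest, leader.y_second),
            (global_mem.gsecond, leader.y_second),
        ]
    if role == "worker":
        return [
            (leader.y, worker.y),
            (leader.y_second, worker.y),
            (leader.y, worker.y_second),
            (leader.y_second, worker.y_second),
        ]
    raise ValueError(f"unknown role {role!r}")


def dropout_select(
    combinations: Sequence[tuple[np.ndarray, np.ndarray]], rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Keep 2 of the 4 combinations, uniformly without replacement."""
    if len(combinations) != 4:
        raise ValueError("dropout expects exactly 4 combinations")
    chosen = rng.choice(4, size=2, replace=False)
    return [combinations[int(i)] for i in chosen]


def consolidate_global_memory(particles: Iterable[ParticleState]) -> GlobalMemory:
    """Pool every particle's two memories and take the two lowest-fitness entries.

    Ties are broken by particle index, then memory layer (best before
    second-best). Both entries may come from the same particle.
    """
    pool = []
    for p in particles:
        pool.append((p.f_y, p.index, 0, p.y))
        pool.append((p.f_y_second, p.index, 1, p.y_second))
    if not pool:
        raise ValueError("cannot consolidate an empty swarm")
    pool.sort(key=lambda e: (e[0], e[1], e[2]))
    best, second = pool[0], pool[1]
    return GlobalMemory(
        gbest=best[3].copy(),
        gbest_fitness=best[0],
        gsecond=second[3].copy(),
        gsecond_fitness=second[0],
    )


def _process_particle(
    particle: ParticleState,
    role: str,
    pair: tuple[ParticleState, ParticleState],
    global_mem: GlobalMemory,
    objective: Objective,
    rng: np.random.Generator,
) -> None:
    combos = candidate_combinations(role, pair, global_mem)
    chosen = dropout_select(combos, rng)
    best_candidate = None
    best_fitness = np.inf
    for p1, p2 in chosen:
        candidate = generate_candidate(p1, p2, objective, rng)
        fitness = objective.evaluate(candidate)
        update_memory(particle, candidate, fitness)
        if np.isfinite(fitness) and fitness < best_fitness:
            best_candidate, best_fitness = candidate, fitness
    if best_candidate is not None:
        particle.x = best_candidate.copy()


def optimize(objective: Objective, config: OptimizerConfig) -> OptimizationTrace:
    """Run RDBPSO; seeded and bit-reproducible.

    Each iteration: pair the particles, draw 2 dropout-selected candidates
    per particle (2N evaluations), update the dual-layer memories, then
    consolidate the global pool. The per-iteration cost is dominated by
    sorting the 2N pooled memories, i.e. O(N log N) beyond the objective
    calls.
    """
    rng = np.random.default_rng(config.seed)
    particles, global_mem = initialize_swarm(objective, config, rng)
    best_trace = np.empty(config.max_iterations)
    evals_trace = np.empty(config.max_iterations, dtype=int)
    for t in range(config.max_iterations):
        evals_before = objective.n_evaluations
        for leader_idx, worker_idx in pair_particles(particles, rng):
            if leader_idx is None:
                # odd swarm: global memories stand in for the missing leader
                stand_in = ParticleState(
                    index=-1,
                    x=global_mem.gbest,
                    y=global_mem.gbest,
                    f_y=global_mem.gbest_fitness,
                    y_second=global_mem.gsecond,
                    f_y_second=global_mem.gsecond_fitness,
                )
                pair = (stand_in, particles[worker_idx])
                _process_particle(
                    particles[worker_idx], "worker", pair, global_mem, objective, rng
                )
                continue
            pair = (particles[leader_idx], particles[worker_idx])
            _process_particle(particles[leader_idx], "leader", pair, global_mem, objective, rng)
            _process_particle(particles[worker_idx], "worker", pair, global_mem, objective, rng)
        global_mem = consolidate_global_memory(particles)
        best_trace[t] = global_mem.gbest_fitness
        evals_trace[t] = objective.n_evaluations - evals_before
    return OptimizationTrace(
        best_fitness_per_iteration=best_trace,
        evaluations_per_iteration=evals_trace,
        global_memory=global_mem,
        seed=config.seed,
        config={
            "algorithm": "rdbpso",
            "n_particles": config.n_particles,
            "max_iterations": config.max_iterations,
        },
    )


# Canonical constriction-equivalent parameters for the velocity baseline.
PSO_INERTIA = 0.7298
PSO_COGNITIVE = 1.49618
PSO_SOCIAL = 1.49618


def optimize_standard_pso(objective: Objective, config: OptimizerConfig) -> OptimizationTrace:
    """Global-best velocity PSO baseline (inertia 0.7298, c1=c2=1.49618).

    Velocities start at zero and are clamped to the box range; positions
    are clipped to the box. N evaluations per iteration.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_particles, objective.dimension
    span = objective.upper - objective.lower
    X = rng.uniform(objective.lower, objective.upper, size=(n, d))
    V = np.zeros((n, d))
    fitness = np.array([objective.evaluate(x) for x in X])
    if not np.all(np.isfinite(fitness)):
        bad = int(np.argmax(~np.isfinite(fitness)))
        _check_finite(fitness[bad], bad, X[bad])
    pbest = X.copy()
    pbest_f = fitness.copy()
    g = int(np.argmin(pbest_f))
    best_trace = np.empty(config.max_iterations)
    evals_trace = np.empty(config.max_iterations, dtype=int)
    for t in range(config.max_iterations):
        evals_before = objective.n_evaluations
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        V = (
            PSO_INERTIA * V
            + PSO_COGNITIVE * r1 * (pbest - X)
            + PSO_SOCIAL * r2 * (pbest[g] - X)
        )
        V = np.clip(V, -span, span)
        X = np.clip(X + V, objective.lower, objective.upper)
        for i in range(n):
            f = objective.evaluate(X[i])
            if np.isfinite(f) and f < pbest_f[i]:
                pbest[i] = X[i].copy()
                pbest_f[i] = f
        g = int(np.argmin(pbest_f))
        best_trace[t] = pbest_f[g]
        evals_trace[t] = objective.n_evaluations - evals_before
    order = np.argsort(pbest_f, kind="stable")
    gm = GlobalMemory(
        gbest=pbest[order[0]].copy(),
        gbest_fitness=float(pbest_f[order[0]]),
        gsecond=pbest[order[1]].copy(),
        gsecond_fitness=float(pbest_f[order[1]]),
    )
    return OptimizationTrace(
        best_fitness_per_iteration=best_trace,
        evaluations_per_iteration=evals_trace,
        global_memory=gm,
        seed=config.seed,
        config={
            "algorithm": "standard_pso",
            "n_particles": config.n_particles,
            "max_iterations": config.max_iterations,
        },
    )
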