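"""Shark Optimization Algorithm (SOA): a bounded-search swarm maximizer.

A population of candidate solutions ("sharks") moves through a box-bounded
search space under four forces per iteration:

* momentum ``beta`` on the previous velocity,
* a cognitive pull ``c1 r1 (personal_best - S)`` toward each shark's own
  best-found position,
* a social pull ``c2 r2 (global_best - S)`` toward the population's best,
* Gaussian exploration noise of strength ``gamma``.

Positions advance by ``S <- clip(S + alpha_t V, bounds)`` where the control
factor ``alpha_t`` decays linearly from ``alpha_start`` to ``alpha_end``,
shifting the balance from exploration to exploitation.  The incumbent best
is elitist: the best fitness history is monotone non-decreasing.  The
convention is maximization; minimize by negating the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOAConfig",
    "SharkPopulation",
    "initialize_population",
    "step_population",
    "soa_optimize",
    "SharkOptimizer",
]


@dataclass(frozen=True)
class SOAConfig:
    """Swarm hyperparameters; defaults suit low-dimensional weight searches."""

    pop_size: int = 20
    max_iters: int = 100
    c1: float = 1.5
    c2: float = 1.5
    beta: float = 0.7
    gamma: float = 0.1
    alpha_start: float = 1.0
    alpha_end: float = 0.1
    bounds: tuple = ((0.0, 1.0),)
    seed: int = 0
    patience: int = 15
    tol: float = 1e-6

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.c1 < 0 or self.c2 < 0 or self.gamma < 0:
            raise ValueError("c1, c2, gamma must be nonnegative")
        if not self.alpha_start >= self.alpha_end >= 0:
            raise ValueError(
                f"need alpha_start >= alpha_end >= 0, got "
                f"{self.alpha_start}, {self.alpha_end}"
            )
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"each bound must have lo < hi, got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)


@dataclass
class SharkPopulation:
    positions: np.ndarray  # (P, D)
    velocities: np.ndarray  # (P, D)
    fitness: np.ndarray  # (P,)
    personal_bests: np.ndarray  # (P, D)
    personal_best_fitness: np.ndarray  # (P,)
    global_best: np.ndarray  # (D,)
    global_best_fitness: float
    iteration: int = 0
    history: list = field(default_factory=list)  # best fitness per step
    rng: np.random.Generator | None = None


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[np.flatnonzero(~np.isfinite(vals))[0]]
        raise ValueError(f"objective returned a non-finite value at position {bad}")
    return vals


def initialize_population(objective, config: SOAConfig) -> SharkPopulation:
    """Uniform positions in the box, zero velocities, bests from first sweep."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    d = len(config.bounds)
    pos = lo + rng.random((config.pop_size, d)) * (hi - lo)
    fit = _evaluate(objective, pos)
    best = int(np.argmax(fit))
    pop = SharkPopulation(
        positions=pos,
        velocities=np.zeros_like(pos),
        fitness=fit,
        personal_bests=pos.copy(),
        personal_best_fitness=fit.copy(),
        global_best=pos[best].copy(),
        global_best_fitness=float(fit[best]),
        rng=rng,
    )
    pop.history.append(pop.global_best_fitness)
    return pop


def _alpha_at(config: SOAConfig, t: int) -> float:
    if config.max_iters == 1:
        return config.alpha_start
    frac = t / (config.max_iters - 1)
    return config.alpha_start + (config.alpha_end - config.alpha_start) * min(frac, 1.0)


def step_population(pop: SharkPopulation, objective, config: SOAConfig) -> SharkPopulation:
    """One synchronous swarm update (in place); returns ``pop``."""
    rng = pop.rng
    p, d = pop.positions.shape
    r1 = rng.random((p, 1))
    r2 = rng.random((p, 1))
    noise = rng.standard_normal((p, d))
    pop.velocities = (
        config.beta * pop.velocities
        + config.c1 * r1 * (pop.personal_bests - pop.positions)
        + config.c2 * r2 * (pop.global_best - pop.positions)
        + config.gamma * noise
    )
    alpha = _alpha_at(config, pop.iteration)
    pop.positions = np.clip(
        pop.positions + alpha * pop.velocities, config.lower, config.upper
    )
    pop.fitness = _evaluate(objective, pop.positions)
    improved = pop.fitness > pop.personal_best_fitness
    pop.personal_bests[improved] = pop.positions[improved]
    pop.personal_best_fitness[improved] = pop.fitness[improved]
    best = int(np.argmax(pop.personal_best_fitness))
    if pop.personal_best_fitness[best] > pop.global_best_fitness:
        pop.global_best = pop.personal_bests[best].copy()
        pop.global_best_fitness = float(pop.personal_best_fitness[best])
    pop.iteration += 1
    pop.history.append(pop.global_best_fitness)
    return pop


def soa_optimize(objective, config: SOAConfig):
    """Run SOA to completion; returns (best_position, best_fitness, history).

    Stops early once the best fitness has improved by less than ``tol`` for
    ``patience`` consecutive iterations.
    """
    pop = initialize_population(objective, config)
    stale = 0
    for _ in range(config.max_iters):
        prev = pop.global_best_fitness
        step_population(pop, objective, config)
        stale = stale + 1 if pop.global_best_fitness - prev < config.tol else 0
        if config.patience and stale >= config.patience:
            break
    return pop.global_best.copy(), pop.global_best_fitness, list(pop.history)


class SharkOptimizer:
    """Thin object wrapper with sklearn-flavored ergonomics.

    ``SharkOptimizer(**config_fields).maximize(f)`` -> sets
    ``best_position_``, ``best_fitness_``, ``history_``.
    """

    def __init__(self, **config_fields):
        self.config = SOAConfig(**config_fields)

    def maximize(self, objective):
        self.best_position_, self.best_fitness_, self.history_ = soa_optimize(
            objective, self.config
        )
        return self

    def minimize(self, objective):
        self.maximize(lambda x: -objective(x))
        self.best_fitness_ = -self.best_fitness_
        self.history_ = [-h for h in self.history_]
        return self
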