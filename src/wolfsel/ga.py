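"""Genetic-algorithm operators for seeding the binary wolf population.

A chromosome is a binary gene vector of length ``n_features`` (1 = feature
included).  One pass of Initialization -> roulette Selection -> single-point
Crossover -> uniform Mutation -> Decode produces a diversified set of binary
starting positions for the grey wolf search; running more generations is
supported (with single-chromosome elitism) but one pass is the default.

All-zero chromosomes are repaired by switching on one uniformly chosen gene,
because the wrapper's fitness is undefined on an empty feature subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GAConfig", "init_chromosomes", "roulette_select",
           "single_point_crossover", "uniform_mutation",
           "generate_initial_positions"]


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 8
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    generations: int = 1

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def _repair_empty(genes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not genes.any():
        genes = genes.copy()
        genes[rng.integers(genes.size)] = 1
    return genes


def init_chromosomes(pop_size: int, n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Random binary population, fair coin per gene; no all-zero rows."""
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    pop = rng.integers(0, 2, size=(pop_size, n_features), dtype=np.int8)
    for i in range(pop_size):
        pop[i] = _repair_empty(pop[i], rng)
    return pop


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional selection: P(i) = f_i / sum(f)."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0 or np.any(f < 0):
        raise ValueError("fitnesses must be non-negative and non-empty")
    total = f.sum()
    if total <= 0:
        raise ValueError("at least one fitness must be strictly positive")
    u = rng.random() * total
    return int(np.searchsorted(np.cumsum(f), u, side="right"))


def single_point_crossover(
    p1: np.ndarray, p2: np.ndarray, crossover_prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``crossover_prob``, swap gene tails at a uniform cut."""
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise ValueError("parent length mismatch")
    n = p1.size
    if n < 2:
        raise ValueError("chromosomes must have length >= 2")
    if rng.random() < crossover_prob:
        cut = int(rng.integers(1, n))  # cut point in {1..n-1}
        c1 = np.concatenate([p1[:cut], p2[cut:]])
        c2 = np.concatenate([p2[:cut], p1[cut:]])
        return c1, c2
    return p1.copy(), p2.copy()


def uniform_mutation(c: np.ndarray, mutation_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each gene independently with probability ``mutation_prob``."""
    c = np.asarray(c, dtype=np.int8)
    flips = rng.random(c.size) < mutation_prob
    return np.where(flips, 1 - c, c).astype(np.int8)


def generate_initial_positions(
    data,
    fitness_fn,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """GA-evolved binary starting positions for the wolf population.

    ``fitness_fn`` maps a binary flag vector to a non-negative fitness (the
    wrapper's accuracy/size scalarization) and supplies the roulette weights.
    Returns a ``(pop_size, n_features)`` 0/1 float matrix; rows decode 1:1 to
    wolf positions.  Deterministic given the generator state.
    """
    n_features = data.n_features
    pop = init_chromosomes(config.pop_size, n_features, rng)

    for _ in range(config.generations):
        fitnesses = np.array([fitness_fn(c) for c in pop], dtype=float)
        offspring: list[np.ndarray] = []
        if config.generations > 1:  # elitism: the best chromosome survives
            offspring.append(pop[int(np.argmax(fitnesses))].copy())
        while len(offspring) < config.pop_size:
            i = roulette_select(fitnesses, rng)
            j = roulette_select(fitnesses, rng)
            c1, c2 = single_point_crossover(pop[i], pop[j], config.crossover_prob, rng)
            offspring.append(_repair_empty(uniform_mutation(c1, config.mutation_prob, rng), rng))
            if len(offspring) < config.pop_size:
                offspring.append(_repair_empty(uniform_mutation(c2, config.mutation_prob, rng), rng))
        pop = np.array(offspring, dtype=np.int8)

    return pop.astype(float)
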