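"""Continuous grey wolf optimization (GWO) mechanics.

GWO is a population metaheuristic modelled on the social hierarchy and
hunting behaviour of grey wolves: the three best solutions found so far
(alpha, beta, delta) guide every other wolf.  Each wolf X moves by the
encircling/hunting equations, applied once per leader L:

    A = 2 a r1 - a          (component-wise, r1 ~ U[0,1))
    C = 2 r2                (component-wise, r2 ~ U[0,1))
    D = |C * X_L - X|
    X_L' = X_L - A * D

and the new position is the mean of the three leader-guided candidates,
clipped back into the box domain.  The exploration coefficient ``a`` decays
linearly from 2 to 0 over the run, so |A| can exceed 1 early (search away
from the leaders) and shrinks late (converge on them).

Randomness contract: for each wolf update, leaders are processed in the order
alpha, beta, delta, and for each leader a full r1 vector is drawn, then a full
r2 vector, from the supplied ``numpy.random.Generator``.  Fixing this order
makes trajectories bit-reproducible per seed and lets a test replay the exact
stream through an independent transcription of the equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["coefficient_a", "rank_wolves", "update_position", "gwo_maximize",
           "GWOResult", "LeaderArchive"]


def coefficient_a(t: int, T: int) -> float:
    """Linear exploration schedule: 2 at t=0 down to 0 at t=T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration index t={t} outside [0, {T}]")
    return 2.0 * (1.0 - t / T)


def rank_wolves(fitnesses: np.ndarray) -> tuple[int, int, int]:
    """Indices of the three largest fitnesses, descending; ties -> lowest index."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size < 3:
        raise ValueError("need at least 3 wolves to rank alpha/beta/delta")
    order = np.argsort(-fitnesses, kind="stable")
    return int(order[0]), int(order[1]), int(order[2])


def update_position(
    wolf: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    a: float,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
) -> np.ndarray:
    """One encircling/hunting step toward the alpha/beta/delta leaders."""
    wolf = np.asarray(wolf, dtype=float)
    dim = wolf.shape[0]
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    candidates = np.empty((3, dim))
    for i, leader in enumerate(leaders):
        leader = np.asarray(leader, dtype=float)
        if leader.shape != wolf.shape:
            raise ValueError("leader/wolf dimension mismatch")
        r1 = rng.random(dim)
        r2 = rng.random(dim)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * leader - wolf)
        candidates[i] = leader - A * D
    return np.clip(candidates.mean(axis=0), lo, hi)


@dataclass
class LeaderArchive:
    """Best-so-far alpha/beta/delta positions and fitnesses.

    Leaders persist across iterations even if the current population worsens;
    an incumbent is only displaced by a strictly better fitness, so equal-
    fitness newcomers never churn the hierarchy.
    """

    positions: np.ndarray  # (3, dim)
    fitnesses: np.ndarray  # (3,), descending

    @classmethod
    def from_population(cls, positions: np.ndarray, fitnesses: np.ndarray) -> "LeaderArchive":
        a, b, d = rank_wolves(fitnesses)
        idx = [a, b, d]
        return cls(positions=np.array(positions[idx], dtype=float),
                   fitnesses=np.asarray(fitnesses, dtype=float)[idx].copy())

    def update(self, position: np.ndarray, fitness: float) -> None:
        """Insert one candidate, keeping the trio sorted best-first."""
        for slot in range(3):
            if fitness > self.fitnesses[slot]:
                self.positions[slot + 1:] = self.positions[slot:2].copy()
                self.fitnesses[slot + 1:] = self.fitnesses[slot:2].copy()
                self.positions[slot] = np.asarray(position, dtype=float)
                self.fitnesses[slot] = fitness
                return

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[0])

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[0].copy()


@dataclass
class GWOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness, length T + 1


def gwo_maximize(
    objective,
    dim: int,
    pop_size: int = 8,
    iterations: int = 100,
    domain: tuple[float, float] = (0.0, 1.0),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init_positions: np.ndarray | None = None,
) -> GWOResult:
    """Run GWO to maximize ``objective`` over a box domain.

    ``init_positions`` (shape ``(pop_size, dim)``) overrides the default
    uniform initialization — used by the feature-selection wrapper to start
    from a genetic-algorithm-seeded population.  The best-so-far fitness
    history has length ``iterations + 1`` (initial population included) and is
    non-decreasing by construction.
    """
    if pop_size < 3:
        raise ValueError("pop_size must be >= 3")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    lo, hi = domain
    if rng is None:
        rng = np.random.default_rng(seed)

    if init_positions is None:
        positions = rng.uniform(lo, hi, size=(pop_size, dim))
    else:
        positions = np.array(init_positions, dtype=float)
        if positions.shape != (pop_size, dim):
            raise ValueError("init_positions shape must be (pop_size, dim)")
        positions = np.clip(positions, lo, hi)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        vals = np.array([objective(x) for x in pop], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("objective returned a non-finite value")
        return vals

    fitnesses = evaluate(positions)
    archive = LeaderArchive.from_population(positions, fitnesses)
    history = [archive.best_fitness]

    for t in range(iterations):
        a = coefficient_a(t, iterations)
        leaders = (archive.positions[0], archive.positions[1], archive.positions[2])
        for i in range(pop_size):
            positions[i] = update_position(positions[i], leaders, a, rng, lo, hi)
        fitnesses = evaluate(positions)
        for i in range(pop_size):
            archive.update(positions[i], fitnesses[i])
        history.append(archive.best_fitness)

    return GWOResult(best_position=archive.best_position,
                     best_fitness=archive.best_fitness,
                     history=np.array(history))
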