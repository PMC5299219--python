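"""Binary wrapper feature selection: GA-seeded grey wolf search over feature
subsets scored by a kernel extreme learning machine.

A candidate subset is a *flag vector* — one bit per feature, bit i = 1 means
feature i is included.  Its quality is the scalarized fitness

    fitness = alpha * P + beta * (N - L) / N,        beta = 1 - alpha,

where ``P`` in [0, 1] is the KELM classification accuracy on the flagged
columns (by default estimated with an inner stratified k-fold CV whose seed is
independent of the optimizer's), ``L`` is the number of selected features and
``N`` the total.  With the default ``alpha = 0.99`` accuracy dominates and the
size term breaks ties toward smaller subsets.

Three search modes are provided:

* ``IGWO`` — the improved wrapper: a one-pass genetic algorithm diversifies
  the initial binary positions, then grey wolf optimization updates the
  population.  Wolves keep continuous positions in [0, 1]^N between
  iterations; a position is binarized (threshold 0.5, empty subsets repaired
  to the largest component) only when its fitness is evaluated.
* ``GWO``  — identical loop with uniform-random initial positions.
* ``GA``   — a plain generational genetic algorithm baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import ga, gwo
from .cv import stratified_fold_assignment
from .datasets import Dataset
from .kelm import KELMConfig, rbf_kernel

__all__ = ["FitnessWeights", "InnerEval", "RunHistory", "binarize",
           "fitness_from_accuracy", "subset_fitness", "SubsetEvaluator",
           "run_wrapper", "select_features", "write_history_csv",
           "write_mask"]

Mode = Literal["GA", "GWO", "IGWO"]


@dataclass(frozen=True)
class FitnessWeights:
    """Accuracy/size trade-off weights; ``size_weight`` is ``1 - accuracy_weight``."""

    accuracy_weight: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_weight <= 1.0:
            raise ValueError("accuracy_weight must be in [0, 1]")

    @property
    def size_weight(self) -> float:
        return 1.0 - self.accuracy_weight


@dataclass(frozen=True)
class InnerEval:
    """How the accuracy term P is estimated for one feature subset.

    ``method="cv"`` (default) pools correct predictions over a stratified
    k-fold split of the data handed to the wrapper; the folds are drawn once
    per run from ``seed``, independent of the optimizer stream, so every
    subset is scored on identical splits.  ``method="train"`` scores on the
    training data itself (resubstitution); ``method="holdout"`` uses a single
    stratified split with ``1/k`` of the data held out.
    """

    method: Literal["cv", "train", "holdout"] = "cv"
    k: int = 10
    seed: int = 101

    def __post_init__(self) -> None:
        if self.method not in ("cv", "train", "holdout"):
            raise ValueError(f"unknown inner evaluation method {self.method!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class RunHistory:
    """Trace of one wrapper run."""

    mode: Mode
    seed: int
    best_fitness_per_iteration: np.ndarray
    best_flags: np.ndarray
    best_accuracy: float
    n_evaluations: int = 0

    @property
    def best_fitness(self) -> float:
        return float(self.best_fitness_per_iteration[-1])

    @property
    def iterations_to_convergence(self) -> int:
        """First iteration index after which the best fitness never changes."""
        h = self.best_fitness_per_iteration
        changed = np.flatnonzero(h != h[-1])
        return int(changed[-1] + 1) if changed.size else 0


def binarize(position: np.ndarray, *, transfer: str = "threshold",
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Map a continuous position in [0,1]^N to a flag vector.

    ``threshold``: bit i = 1 iff position_i >= 0.5.  ``sigmoid``: bit i = 1
    with probability 1/(1 + exp(-10 (position_i - 0.5))) (requires ``rng``).
    An all-zero result is repaired by switching on the largest-valued
    component (ties to the lowest index).
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 1:
        raise ValueError("position must be a vector")
    if np.any(position < 0) or np.any(position > 1):
        raise ValueError("position entries must lie in [0, 1]")
    if transfer == "threshold":
        flags = (position >= 0.5).astype(np.int8)
    elif transfer == "sigmoid":
        if rng is None:
            raise ValueError("sigmoid transfer requires an rng")
        prob = 1.0 / (1.0 + np.exp(-10.0 * (position - 0.5)))
        flags = (rng.random(position.size) < prob).astype(np.int8)
    else:
        raise ValueError(f"unknown transfer {transfer!r}")
    if not flags.any():
        flags[int(np.argmax(position))] = 1
    return flags


def fitness_from_accuracy(P: float, L: int, N: int,
                          weights: FitnessWeights = FitnessWeights()) -> float:
    """Scalarized subset fitness alpha*P + beta*(N-L)/N."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy P must lie in [0, 1]")
    if not 1 <= L <= N:
        raise ValueError("subset size L must lie in [1, N]")
    fitness = weights.accuracy_weight * P + weights.size_weight * (N - L) / N
    upper = weights.accuracy_weight + weights.size_weight * (N - 1) / N
    assert -1e-12 <= fitness <= upper + 1e-12
    return fitness


def _kelm_cv_accuracy(X: np.ndarray, y: np.ndarray, fold_of: np.ndarray,
                      k: int, config: KELMConfig) -> float:
    """Pooled k-fold KELM accuracy: total correct / n.

    The full pairwise kernel is built once on the selected columns; each fold
    then only slices it and solves one regularized system.
    """
    K = rbf_kernel(X, X, config.gamma)
    y = y.astype(float)
    n = y.size
    correct = 0
    for fold in range(k):
        te = fold_of == fold
        tr = ~te
        A = K[np.ix_(tr, tr)] + np.eye(int(tr.sum())) / config.C
        w = cho_solve(cho_factor(A), y[tr])
        scores = K[np.ix_(te, tr)] @ w
        correct += int(np.sum(np.where(scores >= 0, 1.0, -1.0) == y[te]))
    return correct / n


def _kelm_train_accuracy(X: np.ndarray, y: np.ndarray, config: KELMConfig) -> float:
    K = rbf_kernel(X, X, config.gamma)
    y = y.astype(float)
    A = K + np.eye(y.size) / config.C
    w = cho_solve(cho_factor(A), y)
    scores = K @ w
    return float(np.mean(np.where(scores >= 0, 1.0, -1.0) == y))


class SubsetEvaluator:
    """Memoizing fitness oracle for flag vectors over one dataset.

    The inner-CV folds (or holdout split) are drawn once at construction from
    the inner seed, so repeated evaluations of the same subset — and the
    exhaustive enumeration used as a test oracle — see identical splits.
    ``accuracy_fn`` replaces the KELM inner evaluation entirely when given
    (signature ``(X, y) -> P``), which is how stub classifiers are injected.
    """

    def __init__(self, data: Dataset, kelm_config: KELMConfig = KELMConfig(),
                 weights: FitnessWeights = FitnessWeights(),
                 inner: InnerEval = InnerEval(),
                 accuracy_fn: Callable[[np.ndarray, np.ndarray], float] | None = None):
        self.data = data
        self.kelm_config = kelm_config
        self.weights = weights
        self.inner = inner
        self.accuracy_fn = accuracy_fn
        self.n_evaluations = 0
        self._cache: dict[tuple, tuple[float, float]] = {}
        rng = np.random.default_rng(inner.seed)
        if accuracy_fn is None and inner.method in ("cv", "holdout"):
            k = inner.k
            self._fold_of = stratified_fold_assignment(data.labels, k, rng)
        else:
            self._fold_of = None

    def accuracy(self, flags: np.ndarray) -> float:
        X = self.data.features[:, flags.astype(bool)]
        y = self.data.labels
        if self.accuracy_fn is not None:
            return float(self.accuracy_fn(X, y))
        if self.inner.method == "cv":
            return _kelm_cv_accuracy(X, y, self._fold_of, self.inner.k, self.kelm_config)
        if self.inner.method == "holdout":
            te = self._fold_of == 0
            tr = ~te
            K_tr = rbf_kernel(X[tr], X[tr], self.kelm_config.gamma)
            w = cho_solve(cho_factor(K_tr + np.eye(int(tr.sum())) / self.kelm_config.C),
                          y[tr].astype(float))
            scores = rbf_kernel(X[te], X[tr], self.kelm_config.gamma) @ w
            return float(np.mean(np.where(scores >= 0, 1, -1) == y[te]))
        return _kelm_train_accuracy(X, y, self.kelm_config)

    def __call__(self, flags: np.ndarray) -> tuple[float, float]:
        """(fitness, accuracy P) for a flag vector; L >= 1 required."""
        flags = np.asarray(flags).astype(np.int8)
        L = int(flags.sum())
        if L < 1:
            raise ValueError("empty feature subset")
        key = flags.tobytes()
        if key not in self._cache:
            P = self.accuracy(flags)
            fitness = fitness_from_accuracy(P, L, self.data.n_features, self.weights)
            self._cache[key] = (fitness, P)
            self.n_evaluations += 1
        return self._cache[key]

    def fitness(self, flags: np.ndarray) -> float:
        return self(flags)[0]


def subset_fitness(flags: np.ndarray, data: Dataset,
                   kelm_config: KELMConfig = KELMConfig(),
                   weights: FitnessWeights = FitnessWeights(),
                   eval_plan: InnerEval | Callable = InnerEval()) -> tuple[float, float]:
    """(fitness, accuracy P) of one flag vector.

    ``eval_plan`` is an :class:`InnerEval` or a callable ``(X, y) -> P`` that
    supplies the accuracy term directly.
    """
    if callable(eval_plan) and not isinstance(eval_plan, InnerEval):
        evaluator = SubsetEvaluator(data, kelm_config, weights,
                                    accuracy_fn=eval_plan)
    else:
        evaluator = SubsetEvaluator(data, kelm_config, weights, inner=eval_plan)
    return evaluator(flags)


def _track(best: dict, flags: np.ndarray, fitness: float, P: float) -> None:
    if fitness > best["fitness"]:
        best.update(fitness=fitness, flags=flags.copy(), P=P)


def run_wrapper(
    data: Dataset,
    mode: Mode = "IGWO",
    pop_size: int = 8,
    iterations: int = 100,
    kelm_config: KELMConfig = KELMConfig(),
    weights: FitnessWeights = FitnessWeights(),
    seed: int = 0,
    inner: InnerEval = InnerEval(),
    ga_config: ga.GAConfig | None = None,
    transfer: str = "threshold",
    evaluator: SubsetEvaluator | None = None,
) -> RunHistory:
    """Run one feature-selection search and return its trace.

    The best-so-far fitness history has length ``iterations + 1`` and is
    non-decreasing in every mode.  The GA seeding pass of IGWO is not counted
    against the GWO iteration budget.  Deterministic per ``seed`` (the inner
    evaluation seed lives in ``inner`` and is independent).
    """
    if mode not in ("GA", "GWO", "IGWO"):
        raise ValueError(f"unknown mode {mode!r}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode in ("GWO", "IGWO") and pop_size < 3:
        raise ValueError("pop_size must be >= 3 for wolf-based modes")
    n = data.n_features
    rng = np.random.default_rng(seed)
    if evaluator is None:
        evaluator = SubsetEvaluator(data, kelm_config, weights, inner=inner)
    if ga_config is None:
        ga_config = ga.GAConfig(pop_size=pop_size)

    best = {"fitness": -math.inf, "flags": None, "P": 0.0}
    history: list[float] = []

    if mode == "GA":
        pop = ga.init_chromosomes(pop_size, n, rng)
        fitnesses = np.empty(pop_size)
        for i, c in enumerate(pop):
            fitnesses[i], P = evaluator(c)
            _track(best, c, fitnesses[i], P)
        history.append(best["fitness"])
        gen_cfg = ga.GAConfig(pop_size=pop_size,
                              crossover_prob=ga_config.crossover_prob,
                              mutation_prob=ga_config.mutation_prob,
                              generations=1)
        for _ in range(iterations):
            offspring = [pop[int(np.argmax(fitnesses))].copy()]  # elitism of 1
            while len(offspring) < pop_size:
                i = ga.roulette_select(fitnesses, rng)
                j = ga.roulette_select(fitnesses, rng)
                c1, c2 = ga.single_point_crossover(pop[i], pop[j],
                                                   gen_cfg.crossover_prob, rng)
                for child in (c1, c2):
                    if len(offspring) < pop_size:
                        child = ga.uniform_mutation(child, gen_cfg.mutation_prob, rng)
                        offspring.append(ga._repair_empty(child, rng))
            pop = np.array(offspring, dtype=np.int8)
            for i, c in enumerate(pop):
                fitnesses[i], P = evaluator(c)
                _track(best, c, fitnesses[i], P)
            history.append(best["fitness"])
    else:
        if mode == "IGWO":
            chromosomes = ga.generate_initial_positions(
                data, lambda c: evaluator(c)[0], ga_config, rng)
            if chromosomes.shape[0] != pop_size:
                raise ValueError("ga_config.pop_size must equal pop_size")
            # Embed each chromosome as a continuous position drawn uniformly
            # from its half-interval (gene 1 -> [0.5, 1), gene 0 -> [0, 0.5)):
            # it binarizes back to the seeded subset, and interior positions
            # keep every component mobile under the hunting equations (an
            # exact 0 shared by a wolf and all three leaders has D = 0 and
            # would freeze that component for the rest of the run).
            u = rng.random(chromosomes.shape)
            positions = np.where(chromosomes == 1, 0.5 + 0.5 * u, 0.5 * u)
        else:
            positions = rng.uniform(0.0, 1.0, size=(pop_size, n))

        def eval_position(x: np.ndarray) -> float:
            flags = binarize(x, transfer=transfer,
                             rng=rng if transfer == "sigmoid" else None)
            fitness, P = evaluator(flags)
            _track(best, flags, fitness, P)
            return fitness

        fitnesses = np.array([eval_position(x) for x in positions])
        archive = gwo.LeaderArchive.from_population(positions, fitnesses)
        history.append(best["fitness"])
        for t in range(iterations):
            a = gwo.coefficient_a(t, iterations)
            leaders = tuple(archive.positions)
            for i in range(pop_size):
                positions[i] = gwo.update_position(positions[i], leaders, a, rng,
                                                   0.0, 1.0)
            fitnesses = np.array([eval_position(x) for x in positions])
            for i in range(pop_size):
                archive.update(positions[i], fitnesses[i])
            history.append(best["fitness"])

    return RunHistory(
        mode=mode,
        seed=seed,
        best_fitness_per_iteration=np.array(history),
        best_flags=best["flags"],
        best_accuracy=best["P"],
        n_evaluations=evaluator.n_evaluations,
    )


def select_features(history: RunHistory, data: Dataset) -> Dataset:
    """Column-restricted dataset for the run's best flag vector."""
    return data.subset_features(history.best_flags)


def write_history_csv(history: RunHistory, path: str | Path) -> None:
    """Convergence-curve data: one (iteration, best_fitness) row per iteration."""
    lines = ["iteration,best_fitness"]
    lines += [f"{i},{v!r}" for i, v in enumerate(history.best_fitness_per_iteration)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_mask(history: RunHistory, data: Dataset, path: str | Path) -> None:
    """Named feature mask: one (feature, selected) row per feature."""
    lines = ["feature,selected"]
    lines += [f"{name},{int(flag)}"
              for name, flag in zip(data.feature_names, history.best_flags)]
    Path(path).write_text("\n".join(lines) + "\n")
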