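"""Stratified repeated k-fold partitions.

The allocator satisfies two constraints simultaneously: total fold sizes
differ by at most one sample, and each class's per-fold count stays within
one of its proportional share.  (Allocating each class independently — give
every fold ``n_c // k`` and the first ``n_c % k`` folds one extra — can make
total fold sizes differ by the number of classes, which this avoids.)

A :class:`CVPlan` stores one fold-assignment vector per repeat, all derived
deterministically from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CVPlan", "make_cv_plan", "stratified_fold_assignment"]


@dataclass
class CVPlan:
    """Fold assignments for repeated k-fold cross validation.

    ``assignments`` has shape ``(repeats, n_samples)``; entry ``(r, i)`` is
    the fold index (0..k-1) of sample i in repeat r, i.e. the one fold in
    which sample i is a *test* sample.
    """

    k: int
    repeats: int
    stratified: bool
    seed: int
    assignments: np.ndarray

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


def _class_counts_per_fold(class_sizes: np.ndarray, k: int) -> np.ndarray:
    """Per-class, per-fold sample counts honouring both balance constraints.

    Returns an integer matrix of shape ``(n_classes, k)``.  Fold totals are
    ``n // k`` with the first ``n % k`` folds getting one extra; each class is
    then spread with largest-remainder rounding of its proportional share,
    and the final class absorbs the remaining capacity exactly.
    """
    n = int(class_sizes.sum())
    totals = np.full(k, n // k, dtype=int)
    totals[: n % k] += 1

    counts = np.zeros((len(class_sizes), k), dtype=int)
    remaining = totals.astype(float)
    remaining_n = float(n)
    for c, n_c in enumerate(class_sizes[:-1]):
        ideal = n_c * remaining / remaining_n
        base = np.floor(ideal).astype(int)
        short = int(n_c - base.sum())
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
        counts[c] = base
        remaining -= base
        remaining_n -= n_c
    counts[-1] = remaining.astype(int)
    return counts


def stratified_fold_assignment(labels: np.ndarray, k: int,
                               rng: np.random.Generator) -> np.ndarray:
    """One stratified partition: fold index per sample."""
    labels = np.asarray(labels)
    classes, class_sizes = np.unique(labels, return_counts=True)
    for cls, size in zip(classes, class_sizes):
        if size < k:
            raise ValueError(f"class {cls!r} has {size} samples, fewer than k={k}")

    counts = _class_counts_per_fold(class_sizes, k)
    # Rotate which folds carry the remainders so repeats differ.
    fold_order = rng.permutation(k)

    assignment = np.empty(labels.shape[0], dtype=int)
    for c, cls in enumerate(classes):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        start = 0
        for pos, fold in enumerate(fold_order):
            take = counts[c, pos]
            assignment[idx[start:start + take]] = fold
            start += take
    return assignment


def make_cv_plan(labels: np.ndarray, k: int = 10, repeats: int = 10,
                 seed: int = 0, stratified: bool = True) -> CVPlan:
    """Seeded repeated (stratified) k-fold plan over a label vector."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n_samples]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        if stratified:
            assignments[r] = stratified_fold_assignment(labels, k, rng)
        else:
            perm = rng.permutation(n)
            sizes = np.full(k, n // k, dtype=int)
            sizes[: n % k] += 1
            fold_of = np.repeat(np.arange(k), sizes)
            assignment = np.empty(n, dtype=int)
            assignment[perm] = fold_of
            assignments[r] = assignment
    return CVPlan(k=k, repeats=repeats, stratified=stratified, seed=seed,
                  assignments=assignments)
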