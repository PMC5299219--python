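"""Repeated cross-validation harness, confusion-matrix metrics and reports.

The protocol mirrors the standard wrapper-selection benchmark: stratified
10-fold cross validation repeated 10 times, with the mean +/- sd over repeats
reported for six confusion-matrix metrics (accuracy, sensitivity, specificity,
precision, G-mean, F-measure) and for the selected-subset size, alongside a
per-feature selection-frequency table.

Protocol choices that are genuinely ambiguous in this literature are explicit
flags here:

* ``selection_scope="repeat"`` (default) runs the feature-selection wrapper
  once per CV repeat on the whole dataset and scores the chosen subset on that
  repeat's k test folds — one subset size per repeat, as the benchmark tables
  report.  ``"fold"`` re-runs selection on every training fold (leakage-safe
  but 10x the cost and a different quantity).
* ``normalize="global"`` (default) scales the whole table into [-1, 1] before
  anything else; ``"fold"`` fits the scaling on each training fold only.
* Metrics are micro-averaged: confusion counts are pooled over the k test
  folds of a repeat before computing ratios; ``averaging="macro"`` averages
  per-fold metrics instead.

Metrics are kept as fractions in [0, 1] internally; formatting helpers render
the conventional percentages with two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import kelm, selection
from .cv import CVPlan, make_cv_plan
from .datasets import Dataset, apply_minmax, minmax_params, normalize_minmax
from .kelm import KELMConfig

__all__ = ["ConfusionMatrix", "confusion", "metrics", "MetricsReport",
           "make_cv_plan", "CVPlan", "evaluate_method", "sweep",
           "EvaluationResult", "METRIC_NAMES"]

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "precision",
                "g_mean", "f_measure"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts: TP/FP are predicted-positive, FN/TN predicted-negative."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for +1/-1 encoded label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vector length mismatch")
    for v in (y_true, y_pred):
        if not np.all(np.isin(v, (-1, 1))):
            raise ValueError("labels must be encoded +1 (positive) / -1 (negative)")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
    )


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    """Ratio with the zero-denominator convention: report 0 and flag it."""
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, f_beta: float = 1.0) -> dict:
    """Six confusion-matrix metrics as fractions in [0, 1].

    A zero denominator (e.g. precision with no predicted positives, or an
    F-measure when all positives are misclassified) yields 0 for that metric
    and its name is listed under ``"undefined"`` — keeping aggregation total
    while marking the degenerate cells.
    """
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    sens = _ratio(cm.tp, cm.tp + cm.fn, flags, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, flags, "specificity")
    prec = _ratio(cm.tp, cm.tp + cm.fp, flags, "precision")
    b2 = f_beta * f_beta
    fmeas = _ratio((b2 + 1.0) * prec * sens, b2 * prec + sens, flags, "f_measure")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "g_mean": float(np.sqrt(sens * spec)),
        "f_measure": fmeas,
        "undefined": flags,
    }


@dataclass
class MetricsReport:
    """Mean +/- sd over repeats for the six metrics and the subset size."""

    mean: dict
    sd: dict
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        rows = {m: {"mean": self.mean[m], "sd": self.sd[m]}
                for m in METRIC_NAMES + ["subset_size"]}
        return pd.DataFrame(rows).T

    def format_row(self) -> dict:
        """Percentages to two decimals, subset size to two decimals."""
        out = {"features_size": f"{self.mean['subset_size']:.2f} ± {self.sd['subset_size']:.2f}"}
        for m in METRIC_NAMES:
            out[m] = f"{100 * self.mean[m]:.2f} ± {100 * self.sd[m]:.2f}"
        return out


@dataclass
class EvaluationResult:
    mode: str
    per_repeat: pd.DataFrame          # one row per repeat: metrics + subset_size
    report: MetricsReport
    frequency: pd.DataFrame           # per feature: selected times / frequency
    flags_per_repeat: np.ndarray      # (repeats, n_features)
    histories: list = field(default_factory=list)


def _kelm_classifier(kelm_config: KELMConfig):
    def fit_predict(X_tr, y_tr, X_te):
        K = kelm.rbf_kernel(X_tr, X_tr, kelm_config.gamma)
        w = kelm.solve_output_weights(K, y_tr.astype(float), kelm_config.C)
        scores = kelm.rbf_kernel(X_te, X_tr, kelm_config.gamma) @ w
        return np.where(scores >= 0, 1, -1)
    return fit_predict


def evaluate_method(
    data: Dataset,
    mode: str = "IGWO",
    plan: CVPlan | None = None,
    kelm_config: KELMConfig = KELMConfig(),
    weights: selection.FitnessWeights = selection.FitnessWeights(),
    pop_size: int = 8,
    iterations: int = 100,
    seed: int = 0,
    inner: selection.InnerEval = selection.InnerEval(),
    k: int = 10,
    repeats: int = 10,
    selection_scope: str = "repeat",
    normalize: str = "global",
    averaging: str = "micro",
    classifier: Callable | None = None,
) -> EvaluationResult:
    """Full protocol: wrapper selection + repeated stratified k-fold scoring.

    ``mode`` is ``"GA"``, ``"GWO"``, ``"IGWO"``, or ``"none"`` (no selection:
    all features, e.g. to benchmark the bare classifier).  ``classifier``
    overrides KELM with a callable ``(X_train, y_train, X_test) -> y_pred``
    (+1/-1); used for stub/oracle cross-checks.
    """
    if selection_scope not in ("repeat", "fold"):
        raise ValueError("selection_scope must be 'repeat' or 'fold'")
    if normalize not in ("global", "fold", "none"):
        raise ValueError("normalize must be 'global', 'fold' or 'none'")
    if averaging not in ("micro", "macro"):
        raise ValueError("averaging must be 'micro' or 'macro'")

    if normalize == "global":
        data = normalize_minmax(data)
    if plan is None:
        plan = make_cv_plan(data.labels, k=k, repeats=repeats, seed=seed)
    fit_predict = classifier if classifier is not None else _kelm_classifier(kelm_config)
    n_feat = data.n_features

    rows, histories = [], []
    flags_per_repeat = np.zeros((plan.repeats, n_feat), dtype=int)
    fold_select_counts = np.zeros((plan.repeats, n_feat), dtype=float)

    def run_selection(dset: Dataset, run_seed: int, repeat: int) -> np.ndarray:
        if mode == "none":
            return np.ones(n_feat, dtype=np.int8)
        # Fresh inner folds per repeat (fixed within the run), mirroring the
        # repeated-CV protocol: run-to-run selection variability comes from
        # re-drawn partitions, not from the optimizer stream.
        rep_inner = selection.InnerEval(method=inner.method, k=inner.k,
                                        seed=inner.seed + repeat)
        hist = selection.run_wrapper(dset, mode=mode, pop_size=pop_size,
                                     iterations=iterations, kelm_config=kelm_config,
                                     weights=weights, seed=run_seed,
                                     inner=rep_inner)
        histories.append(hist)
        return hist.best_flags

    for r in range(plan.repeats):
        repeat_seed = seed + 1 + r
        if selection_scope == "repeat":
            flags = run_selection(data, repeat_seed, r)
            flags_per_repeat[r] = flags
            fold_select_counts[r] = flags * plan.k
        per_fold_cms, per_fold_metrics, sizes = [], [], []
        for fold in range(plan.k):
            tr = plan.train_indices(r, fold)
            te = plan.test_indices(r, fold)
            X_tr, X_te = data.features[tr], data.features[te]
            if normalize == "fold":
                params = minmax_params(X_tr)
                X_tr, X_te = apply_minmax(X_tr, params), apply_minmax(X_te, params)
            if selection_scope == "fold":
                fold_data = Dataset(X_tr, data.labels[tr], data.feature_names,
                                    data.positive_label, data.negative_label)
                flags = run_selection(fold_data, repeat_seed * plan.k + fold, r)
                fold_select_counts[r] += flags
            sizes.append(int(np.sum(flags)))
            sel = flags.astype(bool)
            y_pred = fit_predict(X_tr[:, sel], data.labels[tr], X_te[:, sel])
            cm = confusion(data.labels[te], y_pred)
            per_fold_cms.append(cm)
            if averaging == "macro":
                per_fold_metrics.append(metrics(cm))
        if selection_scope == "fold":
            flags_per_repeat[r] = (fold_select_counts[r] > plan.k / 2).astype(int)
        if averaging == "micro":
            pooled = sum(per_fold_cms, ConfusionMatrix(0, 0, 0, 0))
            row = metrics(pooled)
        else:
            row = {m: float(np.mean([pm[m] for pm in per_fold_metrics]))
                   for m in METRIC_NAMES}
            row["undefined"] = sorted({u for pm in per_fold_metrics
                                       for u in pm["undefined"]})
        if row["undefined"]:
            warnings.warn(f"zero-denominator metrics reported as 0: {row['undefined']}")
        row = {m: row[m] for m in METRIC_NAMES}
        row["subset_size"] = float(np.mean(sizes))
        rows.append(row)

    per_repeat = pd.DataFrame(rows)
    mean = per_repeat.mean().to_dict()
    sd = per_repeat.std(ddof=1).to_dict() if plan.repeats > 1 else dict.fromkeys(per_repeat, 0.0)
    report = MetricsReport(mean=mean, sd=sd, n_repeats=plan.repeats)

    frequency = pd.DataFrame({
        "feature": data.feature_names,
        # mean over repeats of how many of the k folds used the feature
        "average_selected_times": fold_select_counts.mean(axis=0),
        # number of repeats whose chosen subset includes the feature
        "run_frequency": flags_per_repeat.sum(axis=0),
    })
    return EvaluationResult(mode=mode, per_repeat=per_repeat, report=report,
                            frequency=frequency, flags_per_repeat=flags_per_repeat,
                            histories=histories)


def sweep(
    data: Dataset,
    parameter: str,
    values: list,
    **fixed,
) -> pd.DataFrame:
    """One :func:`evaluate_method` row per value of ``pop_size`` or ``iterations``."""
    if parameter not in ("pop_size", "iterations"):
        raise ValueError("parameter must be 'pop_size' or 'iterations'")
    if not values:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        kwargs = dict(fixed)
        kwargs[parameter] = v
        result = evaluate_method(data, **kwargs)
        row = {parameter: v}
        row.update({m: 100 * result.report.mean[m] for m in METRIC_NAMES})
        row["subset_size"] = result.report.mean["subset_size"]
        rows.append(row)
    return pd.DataFrame(rows)
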