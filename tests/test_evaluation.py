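"""Confusion metrics, stratified CV plans, and the repeated-CV harness."""

import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm

from wolfsel.cv import make_cv_plan
from wolfsel.datasets import SyntheticSpec, generate_synthetic
from wolfsel.evaluation import (METRIC_NAMES, ConfusionMatrix, confusion,
                                evaluate_method, metrics, sweep)
from conftest import make_perfect_separator


def enc(s):
    return np.array([1 if c == "+" else -1 for c in s])


class TestConfusion:
    def test_all_correct_positives(self):
        cm = confusion(enc("+++++"), enc("+++++"))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 0)

    def test_hand_count(self):
        cm = confusion(enc("++++------"), enc("+++-+-----"))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 1, 5)

    def test_class_swap_symmetry(self, rng):
        y_true = np.where(rng.random(50) < 0.4, 1, -1)
        y_pred = np.where(rng.random(50) < 0.5, 1, -1)
        cm = confusion(y_true, y_pred)
        sw = confusion(-y_true, -y_pred)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (sw.tn, sw.fn, sw.fp, sw.tp)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion(enc("++"), enc("+"))
        with pytest.raises(ValueError):
            confusion(np.array([1, 2]), np.array([1, -1]))


class TestMetrics:
    def test_hand_values(self):
        m = metrics(ConfusionMatrix(tp=3, fn=1, fp=1, tn=5))
        assert m["accuracy"] == pytest.approx(0.80)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["g_mean"] == pytest.approx(np.sqrt(0.75 * 5 / 6))
        assert m["f_measure"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=4, fp=0, fn=0, tn=6))
        assert all(m[name] == 1.0 for name in METRIC_NAMES)

    def test_all_positives_misclassified_gives_zero_f(self):
        m = metrics(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
        assert m["sensitivity"] == 0.0
        assert m["f_measure"] == 0.0
        assert "precision" in m["undefined"]

    def test_identities_and_brute_force_recount(self):
        """g_mean^2 = sens*spec and F1 = harmonic mean(prec, sens); counts
        agree with a direct recount and sklearn on random label vectors."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y_true = np.where(rng.random(n) < rng.random(), 1, -1)
            y_pred = np.where(rng.random(n) < rng.random(), 1, -1)
            cm = confusion(y_true, y_pred)
            # brute-force recount, pair by pair
            tp = sum(t == 1 and p == 1 for t, p in zip(y_true, y_pred))
            fp = sum(t == -1 and p == 1 for t, p in zip(y_true, y_pred))
            fn = sum(t == 1 and p == -1 for t, p in zip(y_true, y_pred))
            tn = sum(t == -1 and p == -1 for t, p in zip(y_true, y_pred))
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert cm.total == n
            m = metrics(cm)
            assert m["g_mean"] ** 2 == pytest.approx(
                m["sensitivity"] * m["specificity"], abs=1e-12)
            if m["precision"] + m["sensitivity"] > 0:
                harm = (2 * m["precision"] * m["sensitivity"]
                        / (m["precision"] + m["sensitivity"]))
                assert m["f_measure"] == pytest.approx(harm, abs=1e-12)
            assert m["accuracy"] == pytest.approx(
                skm.accuracy_score(y_true, y_pred), abs=1e-12)
            if tp + fn and tp + fp:
                assert m["sensitivity"] == pytest.approx(
                    skm.recall_score(y_true, y_pred), abs=1e-12)
                assert m["precision"] == pytest.approx(
                    skm.precision_score(y_true, y_pred, zero_division=0),
                    abs=1e-12)


class TestCVPlan:
    def test_balanced_folds(self):
        labels = np.array([1] * 50 + [-1] * 50)
        plan = make_cv_plan(labels, k=10, repeats=3, seed=0)
        for r in range(3):
            for fold in range(10):
                te = plan.test_indices(r, fold)
                assert len(te) == 10
                assert int((labels[te] == 1).sum()) == 5

    def test_parkinson_shaped_allocation(self):
        labels = np.array([1] * 147 + [-1] * 48)
        plan = make_cv_plan(labels, k=10, repeats=2, seed=1)
        for r in range(2):
            sizes, pos = [], []
            for fold in range(10):
                te = plan.test_indices(r, fold)
                sizes.append(len(te))
                pos.append(int((labels[te] == 1).sum()))
            assert set(sizes) <= {19, 20}
            assert set(pos) <= {14, 15}

    def test_folds_partition_disjoint_exhaustive(self):
        labels = np.array([1] * 37 + [-1] * 25)
        plan = make_cv_plan(labels, k=5, repeats=4, seed=2)
        for r in range(4):
            seen = np.concatenate([plan.test_indices(r, f) for f in range(5)])
            assert sorted(seen) == list(range(62))
            # stratification within +/-1 of proportional per class
            for f in range(5):
                te = plan.test_indices(r, f)
                p = int((labels[te] == 1).sum())
                assert abs(p - 37 * len(te) / 62) <= 1

    def test_same_seed_same_plan(self):
        labels = np.array([1] * 30 + [-1] * 30)
        a = make_cv_plan(labels, k=10, repeats=2, seed=5)
        b = make_cv_plan(labels, k=10, repeats=2, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_class_smaller_than_k(self):
        labels = np.array([1] * 5 + [-1] * 30)
        with pytest.raises(ValueError, match="fewer than k"):
            make_cv_plan(labels, k=10, repeats=1, seed=0)


class TestEvaluateMethod:
    def test_majority_vote_stub_recovers_class_fraction(self):
        d = generate_synthetic(SyntheticSpec(n_samples=120,
                                             positive_fraction=0.75, seed=0))
        maj = 1 if (d.labels == 1).sum() >= 60 else -1

        def stub(X_tr, y_tr, X_te):
            return np.full(len(X_te), maj)

        res = evaluate_method(d, mode="none", repeats=2, seed=0,
                              classifier=stub)
        frac = float((d.labels == maj).mean())
        assert res.report.mean["accuracy"] == pytest.approx(frac, abs=1e-12)
        assert res.report.sd["accuracy"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separator_perfect_scores(self):
        d = make_perfect_separator(n_samples=60, n_features=6)
        res = evaluate_method(d, mode="IGWO", iterations=10, repeats=2, seed=1)
        assert res.report.mean["accuracy"] == pytest.approx(1.0)
        assert res.report.sd["accuracy"] == pytest.approx(0.0)

    def test_bookkeeping_and_frequency_ranges(self, benchmark_dataset):
        res = evaluate_method(benchmark_dataset, mode="IGWO", iterations=10,
                              repeats=3, seed=2)
        # subset_size mean equals the mean of per-repeat sizes
        assert res.report.mean["subset_size"] == pytest.approx(
            res.per_repeat["subset_size"].mean())
        assert res.per_repeat.shape[0] == 3
        freq = res.frequency
        assert ((freq["average_selected_times"] >= 0)
                & (freq["average_selected_times"] <= 10)).all()
        assert ((freq["run_frequency"] >= 0) & (freq["run_frequency"] <= 3)).all()
        # run_frequency is consistent with the stored per-repeat flag masks
        np.testing.assert_array_equal(freq["run_frequency"].to_numpy(),
                                      res.flags_per_repeat.sum(axis=0))

    def test_per_fold_scope_and_macro_averaging(self):
        d = make_perfect_separator(n_samples=60, n_features=5)
        res = evaluate_method(d, mode="IGWO", iterations=5, repeats=1, seed=0,
                              selection_scope="fold", averaging="macro")
        assert res.report.mean["accuracy"] == pytest.approx(1.0)
        assert len(res.histories) == 10  # one wrapper run per fold

    def test_fold_normalization_runs(self, small_dataset):
        res = evaluate_method(small_dataset, mode="none", repeats=1, seed=0,
                              normalize="fold")
        assert 0.0 <= res.report.mean["accuracy"] <= 1.0


class TestSweep:
    def test_table_layout(self, small_dataset):
        table = sweep(small_dataset, "pop_size", [4, 8], mode="GA",
                      iterations=5, repeats=1, seed=0)
        assert list(table["pop_size"]) == [4, 8]
        assert table.shape[0] == 2
        assert "accuracy" in table.columns

    def test_single_value_matches_direct_call(self, small_dataset):
        table = sweep(small_dataset, "iterations", [5], mode="GA",
                      repeats=1, seed=3)
        direct = evaluate_method(small_dataset, mode="GA", iterations=5,
                                 repeats=1, seed=3)
        assert table.loc[0, "accuracy"] == pytest.approx(
            100 * direct.report.mean["accuracy"], abs=1e-12)

    def test_bad_parameter(self, small_dataset):
        with pytest.raises(ValueError):
            sweep(small_dataset, "gamma", [1, 2])
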