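"""Cross-validation protocol and metric oracles."""

import numpy as np
import pytest

from transcell.containers import AlignedTask
from transcell.evaluation import (
    aggregate_ci,
    auc,
    build_benchmark_table,
    f1,
    kfold_split,
    mse,
    quartile_partition,
    rmse,
    run_cv,
    spearman,
    subsample_features,
)


def pair_enumeration_auc(y, scores):
    """Brute force: P(score_pos > score_neg) with ties counting one half."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestKFold:
    def test_near_equal_sizes(self):
        folds = kfold_split([f"s{i}" for i in range(10)], k=5, seed=0)
        sizes = np.bincount(list(folds.values()))
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_seed_reproducible(self):
        ids = [f"s{i}" for i in range(23)]
        assert kfold_split(ids, seed=3) == kfold_split(ids, seed=3)

    def test_stratified_positives_per_fold(self):
        y = np.array([1] * 10 + [0] * 40)
        ids = [f"s{i}" for i in range(50)]
        folds = kfold_split(ids, k=5, seed=1, stratify=y)
        for fold in range(5):
            members = [i for i, s in enumerate(ids) if folds[s] == fold]
            assert y[members].sum() == 2

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=5)


class TestMetrics:
    def test_perfect_prediction(self):
        y = [1.0, 2.0, 3.0]
        assert mse(y, y) == 0.0 and rmse(y, y) == 0.0
        assert spearman([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mse_hand_value(self):
        assert mse([1, 2, 3], [2, 2, 2]) == pytest.approx(2 / 3)
        assert rmse([1, 2, 3], [2, 2, 2]) == pytest.approx(np.sqrt(2 / 3))

    def test_spearman_printed_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_spearman_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_spearman_invariant_under_monotone_transform(self, rng):
        y = rng.normal(size=30)
        s = rng.normal(size=30)
        base = spearman(y, s)
        assert spearman(np.exp(y), s) == pytest.approx(base)
        assert spearman(y, s**3) == pytest.approx(base)

    def test_auc_enumerated_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_auc_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_auc_matches_pair_enumeration(self, rng):
        for _ in range(100):
            n = rng.integers(4, 20)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            assert auc(y, scores) == pytest.approx(pair_enumeration_auc(y, scores))

    def test_auc_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 1, 1], [0.2, 0.4, 0.6])

    def test_f1_balanced_errors_give_half(self):
        # TP=1, FP=1, FN=1 -> precision = recall = 0.5
        y_true = [1, 0, 1, 0]
        y_pred = [1, 1, 0, 0]
        assert f1(y_true, y_pred, "binary") == pytest.approx(0.5)


class TestAggregateCI:
    def test_zero_variance_collapses(self):
        m, lo, hi = aggregate_ci([2.0, 2.0, 2.0])
        assert m == lo == hi == 2.0

    def test_symmetric_about_mean(self):
        m, lo, hi = aggregate_ci([0.0, 1.0])
        assert m == 0.5 and (m - lo) == pytest.approx(hi - m)

    def test_closed_form_half_width(self):
        m, lo, hi = aggregate_ci([1, 2, 3, 4, 5])
        s = np.sqrt(2.5)
        half = 2.7764451052 * s / np.sqrt(5)
        assert m == 3.0
        assert hi - m == pytest.approx(half, rel=1e-9)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            aggregate_ci([1.0])


class _OracleModel:
    """Memorizes X -> y from fit, replays exactly at predict."""

    def fit(self, X, y):
        self._lookup = {tuple(row): yi for row, yi in zip(X, y)}
        self._y = dict(zip(map(tuple, X), y))
        return self

    def predict(self, X):
        return np.array([self._y.get(tuple(row), 0.0) for row in X])


class _MeanModel:
    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def _regression_task(n=500, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = rng.standard_normal(n)
    return AlignedTask(X, y, [f"s{i}" for i in range(n)], ["a", "b", "c"], "f")


class TestRunCV:
    def test_oracle_model_scores_zero_mse(self):
        task = _regression_task(100)
        # oracle memorizes the whole dataset, so held-out rows must be seen:
        # fit on all rows by letting the factory close over the task
        class Oracle:
            def fit(self, X, y):
                return self

            def predict(self, X):
                lookup = {tuple(r): yv for r, yv in zip(task.X, task.y)}
                return np.array([lookup[tuple(r)] for r in X])

        ev = run_cv(task, Oracle, k=5, seed=0)
        assert ev.aggregate["mse"][0] == pytest.approx(0.0, abs=1e-15)

    def test_mean_predictor_mse_matches_target_variance(self):
        task = _regression_task(500, seed=1)
        ev = run_cv(task, _MeanModel, k=5, seed=0)
        assert 0.8 <= ev.aggregate["mse"][0] <= 1.2

    def test_five_folds_disjoint_and_exhaustive(self):
        task = _regression_task(53)
        ev = run_cv(task, _MeanModel, k=5, seed=2)
        assert len(ev.per_fold) == 5
        folds = np.array([ev.fold_assignments[s] for s in task.sample_ids])
        assert set(folds) == {0, 1, 2, 3, 4}
        assert len(folds) == task.n_samples  # every sample in exactly one fold

    def test_rmse_is_sqrt_mse_per_fold(self):
        task = _regression_task(80, seed=3)
        ev = run_cv(task, _MeanModel, k=5, seed=1)
        for fold in ev.per_fold:
            assert fold["rmse"] == pytest.approx(np.sqrt(fold["mse"]), abs=1e-12)

    def test_fit_error_annotated_with_fold(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        task = _regression_task(20)
        with pytest.raises(RuntimeError, match="fold 0"):
            run_cv(task, Broken, k=5, seed=0)


def sort_based_quartiles(values):
    """Independent oracle: numpy sorting + linear interpolation quantile."""
    v = np.sort(np.asarray(values, float))
    def q(p):
        h = (len(v) - 1) * p
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        return v[lo] + (h - lo) * (v[hi] - v[lo])
    return q(0.25), q(0.75)


class TestQuartilePartition:
    def test_interpolated_example(self):
        rmses = {f"f{i}": float(i) for i in range(1, 9)}
        parts = quartile_partition(rmses)
        assert parts["well"] == {"f1", "f2"}
        assert parts["poor"] == {"f7", "f8"}
        assert parts["q1"] == pytest.approx(2.75) and parts["q3"] == pytest.approx(6.25)

    def test_all_equal_gives_empty_sets(self):
        parts = quartile_partition({f"f{i}": 1.0 for i in range(6)})
        assert parts["well"] == set() and parts["poor"] == set()

    def test_symmetric_values_balance(self):
        parts = quartile_partition({f"f{i}": v for i, v in enumerate([1, 2, 3, 4, 5, 6])})
        assert len(parts["well"]) == len(parts["poor"])

    def test_matches_sorting_oracle(self, rng):
        for n in range(4, 51):
            values = {f"f{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
            parts = quartile_partition(values)
            q1, q3 = sort_based_quartiles(list(values.values()))
            assert parts["well"] == {f for f, v in values.items() if v < q1}
            assert parts["poor"] == {f for f, v in values.items() if v > q3}

    def test_too_few_features_errors(self):
        with pytest.raises(ValueError):
            quartile_partition({"a": 1.0, "b": 2.0, "c": 3.0})


class TestSubsample:
    def test_identity_below_cap(self):
        ids = [f"f{i}" for i in range(225)]
        assert subsample_features(ids, cap=2000) == ids

    def test_exact_cap_above(self):
        ids = [f"f{i}" for i in range(5000)]
        out = subsample_features(ids, cap=2000, seed=1)
        assert len(out) == 2000 and len(set(out)) == 2000

    def test_seeded(self):
        ids = [f"f{i}" for i in range(3000)]
        assert subsample_features(ids, seed=9) == subsample_features(ids, seed=9)


class TestBenchmarkTable:
    def test_quartile_labels_only_for_scale_up_method(self):
        task = _regression_task(60)
        evs = []
        for i in range(6):
            t = AlignedTask(task.X, task.y + i, task.sample_ids, task.gene_ids, f"f{i}")
            ev = run_cv(t, _MeanModel, k=5, seed=0)
            ev.method = "mean"
            evs.append(ev)
        table = build_benchmark_table(evs, quartile_method="mean")
        labeled = table[table.partition != ""]
        assert set(labeled.method) <= {"mean"}
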