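"""Confusion-matrix metrics, ROC/AUC, threshold selection, CV and grid search."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxsa.dataset import LabeledDataset
from toxsa.metrics_eval import (
    ConfusionCounts,
    CvPlan,
    acc,
    classification_scorer,
    confusion,
    expand_grid,
    fpr,
    grid_search,
    kfold_cv,
    mcc,
    mse,
    pcc,
    regression_scorer,
    roc_curve,
    select_threshold,
    tpr,
)


def _brute_counts(t, p):
    """Positive = non-toxic (0)."""
    tp = sum(1 for a, b in zip(t, p) if a == 0 and b == 0)
    tn = sum(1 for a, b in zip(t, p) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(t, p) if a == 1 and b == 0)
    fn = sum(1 for a, b in zip(t, p) if a == 0 and b == 1)
    return tp, tn, fp, fn


class TestConfusion:
    def test_perfect_predictions(self):
        t = [0] * 10 + [1] * 10
        c = confusion(t, t)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_all_predicted_nontoxic(self):
        t = [0] * 10 + [1] * 10
        c = confusion(t, [0] * 20)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 10, 0, 0)

    def test_random_tally_oracle(self, rng):
        t = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = confusion(t, p)
        assert (c.tp, c.tn, c.fp, c.fn) == _brute_counts(t, p)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestRateMetrics:
    def test_perfect(self):
        c = ConfusionCounts(10, 10, 0, 0)
        assert (acc(c), tpr(c), fpr(c), mcc(c)) == (1.0, 1.0, 0.0, 1.0)

    def test_everything_wrong(self):
        c = ConfusionCounts(0, 0, 10, 10)
        assert acc(c) == 0.0

    def test_mixed_arithmetic(self):
        c = ConfusionCounts(40, 30, 10, 20)
        assert acc(c) == pytest.approx(0.7)
        assert tpr(c) == pytest.approx(2 / 3)
        assert fpr(c) == pytest.approx(0.25)
        expect = (30 * 40 - 10 * 20) / math.sqrt(
            (40 + 10) * (40 + 20) * (30 + 10) * (30 + 20))
        assert mcc(c) == pytest.approx(expect, abs=1e-15)

    def test_balanced_random_mcc_zero(self):
        assert mcc(ConfusionCounts(25, 25, 25, 25)) == 0.0

    def test_zero_denominator_conventions(self):
        assert mcc(ConfusionCounts(0, 5, 0, 0)) == 0.0
        assert math.isnan(tpr(ConfusionCounts(0, 5, 5, 0)))
        assert math.isnan(fpr(ConfusionCounts(5, 0, 0, 5)))

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_formula_equivalence_property(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        n = tp + tn + fp + fn
        if n:
            assert acc(c) == (tp + tn) / n
        if tp + fn:
            assert tpr(c) == tp / (tp + fn)
        if fp + tn:
            assert fpr(c) == fp / (fp + tn)
        d2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        expect = 0.0 if d2 == 0 else (tn * tp - fp * fn) / math.sqrt(d2)
        assert mcc(c) == pytest.approx(expect, abs=1e-15)


class TestRegressionMetrics:
    def test_identical_vectors(self):
        y = np.array([1.0, 2.0, 3.5])
        assert mse(y, y) == 0.0
        assert pcc(y, y) == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([-2.0, -1.0, 1.0, 2.0])
        assert pcc(-y, y) == pytest.approx(-1.0)

    def test_definition_oracle_random(self, rng):
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            expect_mse = sum((x - y) ** 2 for x, y in zip(a, b)) / 20
            assert mse(a, b) == pytest.approx(expect_mse, abs=1e-12)
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            expect_pcc = cov / (a.std() * b.std())
            assert pcc(a, b) == pytest.approx(expect_pcc, abs=1e-12)
            # independent library cross-check
            assert pcc(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_constant_input_undefined(self):
        assert math.isnan(pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def _concordance_auc(scores, labels):
    """Mann–Whitney statistic: P(score_nontoxic < score_toxic), ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 0]
    neg = [s for s, l in zip(scores, labels) if l == 1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert roc_curve(scores, labels).auc == 1.0

    def test_all_tied_scores(self):
        assert roc_curve([0.5] * 10, [0, 1] * 5).auc == pytest.approx(0.5)

    def test_endpoints_and_monotone_fpr(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        curve = roc_curve(scores, labels)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.points[:, 0]) >= 0)

    def test_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc = roc_curve(scores, labels).auc
            assert auc == pytest.approx(_concordance_auc(scores, labels), abs=1e-9)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        ours = roc_curve(scores, labels).auc
        # positive = non-toxic with low scores: flip both for sklearn
        theirs = roc_auc_score(1 - labels, -scores)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_single_class_undefined(self):
        assert math.isnan(roc_curve([0.1, 0.9], [1, 1]).auc)


class TestSelectThreshold:
    def test_separable_returns_smallest_winning_gridpoint(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        thr, best, table = select_threshold(scores, labels, 0.01)
        assert best == pytest.approx(1.0)
        assert thr == pytest.approx(0.2)

    def test_exhaustive_sweep_oracle(self, rng):
        for _ in range(20):
            scores = rng.random(100)
            labels = rng.integers(0, 2, 100)
            labels[:2] = [0, 1]
            thr, best, table = select_threshold(scores, labels, 0.01)
            assert best == pytest.approx(table["mcc"].max())
            winners = table.loc[
                np.isclose(table["mcc"], table["mcc"].max()), "threshold"]
            assert thr == pytest.approx(winners.min())

    def test_table_covers_grid(self):
        _, _, table = select_threshold([0.1, 0.9], [0, 1], 0.05)
        assert len(table) == 21

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.2], [0, 0])


class TestCv:
    def test_folds_partition_indices(self):
        plan = CvPlan.make(np.arange(10, dtype=float), k=5, seed=0)
        sizes = np.bincount(plan.assignment)
        assert sizes.tolist() == [2] * 5

    def test_stratified_binary_folds(self):
        y = np.array([0] * 6 + [1] * 4)
        plan = CvPlan.make(y, k=2, seed=1)
        for fold in range(2):
            members = y[plan.assignment == fold]
            assert (members == 0).sum() == 3
            assert (members == 1).sum() == 2

    def test_same_seed_same_folds(self):
        y = np.random.default_rng(0).integers(0, 2, 30)
        a = CvPlan.make(y, 5, seed=3)
        b = CvPlan.make(y, 5, seed=3)
        assert np.array_equal(a.assignment, b.assignment)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            CvPlan.make(np.arange(3, dtype=float), k=5, seed=0)

    def test_kfold_cv_validates_each_instance_once(self, tox_ds_small):
        from toxsa.et_toxscore import ForestConfig, predict_toxscore, train_forest

        def trainer(train_ds):
            m = train_forest(train_ds, ForestConfig(n_trees=10, seed=0))
            return lambda X: predict_toxscore(m, X)

        res = kfold_cv(tox_ds_small, 4, 0, trainer, classification_scorer(0.5))
        assert not np.isnan(res.oof_pred).any()
        assert len(res.per_fold) == 4
        assert res.mean["auc"] > 0.9  # separable fixture

    def test_kfold_regression_scorer(self, sa_ds_small):
        def trainer(train_ds):
            mean = float(train_ds.y.mean())
            return lambda X: np.full(X.shape[0], mean)

        res = kfold_cv(sa_ds_small, 3, 1, trainer, regression_scorer)
        assert res.mean["mse"] > 0
        assert set(res.per_fold.columns) == {"mse", "pcc"}


class TestGridSearch:
    def _factory(self, tox_ds):
        from toxsa.et_toxscore import ForestConfig, predict_toxscore, train_forest

        def factory(cfg):
            def trainer(train_ds):
                m = train_forest(train_ds, ForestConfig(
                    n_trees=cfg["n_trees"], seed=0,
                    min_samples_leaf=1, min_samples_split=2))
                return lambda X: predict_toxscore(m, X)
            return trainer
        return factory

    def test_single_point_grid(self, tox_ds_small):
        best, table = grid_search([{"n_trees": 5}], tox_ds_small, 3, 0,
                                  self._factory(tox_ds_small), threshold=0.5)
        assert best == {"n_trees": 5}
        assert len(table) == 1

    def test_planted_optimum_wins(self, tox_ds_small):
        """A 50-tree ensemble beats a single tree on a noisy separable set."""
        grid = {"n_trees": [1, 50]}
        best, table = grid_search(grid, tox_ds_small, 3, 0,
                                  self._factory(tox_ds_small), threshold=0.5)
        assert best == {"n_trees": 50}
        assert len(table) == 2

    def test_expand_grid_order(self):
        grid = expand_grid({"a": [1, 2], "b": ["x", "y"]})
        assert grid == [{"a": 1, "b": "x"}, {"a": 1, "b": "y"},
                        {"a": 2, "b": "x"}, {"a": 2, "b": "y"}]

    def test_empty_grid_rejected(self, tox_ds_small):
        with pytest.raises(ValueError):
            grid_search([], tox_ds_small, 2, 0, self._factory(tox_ds_small))
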