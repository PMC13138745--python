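import itertools

import numpy as np
import pandas as pd
import pytest

from caser.evaluate import (
    EvalReport,
    binary_metrics,
    cross_validate,
    evaluate_on_holdout,
    gene_set_score_comparison,
    threshold_free_metrics,
)
from caser.labels import LabelSet
from caser.synthdata import SimConfig, generate_classification_data
from caser.tables import FeatureTable, impute_missing, zscore_normalize
from caser.tritrain import BaseLearnerSpec, TrainConfig


def auroc_oracle(scores, labels):
    """Exhaustive pairwise comparison; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_confusion_closed_form(self):
        # TP=3, FP=1, FN=2, TN=4
        true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = binary_metrics(pred, true)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-6)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_perfect_prediction(self):
        m = binary_metrics([1, 0, 1], [1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_no_positive_predictions_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            m = binary_metrics([0, 0, 0], [1, 0, 1])
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            binary_metrics([1, 0], [1])


class TestThresholdFree:
    def test_perfect_separation(self):
        m = threshold_free_metrics([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == 1.0

    def test_three_of_four_pairs(self):
        m = threshold_free_metrics([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == pytest.approx(0.75)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # ties likely
            m = threshold_free_metrics(scores, labels)
            assert m["auroc"] == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        a = threshold_free_metrics(scores, labels)["auroc"]
        b = threshold_free_metrics(np.exp(3 * scores), labels)["auroc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_free_metrics([0.5, 0.6], [1, 1])


@pytest.fixture(scope="module")
def separable():
    data = generate_classification_data(SimConfig(
        n_genes=200, n_features=8, effect_size=6.0, n_labeled_pos=20,
        n_labeled_neg=20, n_unlabeled=100, seed=3,
    ))
    full = zscore_normalize(impute_missing(data.table))
    tv, labels = data.training_view()
    table = FeatureTable(full.df.loc[tv.gene_ids], dict(full.categories),
                         dict(full.value_kind))
    return table, labels


class TestCrossValidate:
    def test_separable_data_scores_perfectly(self, separable):
        table, labels = separable
        report = cross_validate(table, labels, TrainConfig(seed=1), k=5, seed=1)
        assert report.mean["accuracy"] == pytest.approx(1.0)
        assert report.std["accuracy"] == pytest.approx(0.0)

    def test_folds_partition_labeled_genes(self, separable):
        table, labels = separable
        report = cross_validate(table, labels, TrainConfig(seed=1), k=5, seed=1)
        assert set(report.fold_assignments) == set(labels.labeled)
        folds = np.array(list(report.fold_assignments.values()))
        assert set(folds) == set(range(5))

    def test_supervised_baseline_spec_accepted(self, separable):
        table, labels = separable
        report = cross_validate(
            table, labels, BaseLearnerSpec(kernel="rbf"), k=5, seed=1
        )
        assert report.mean["auroc"] > 0.95

    def test_reproducible_given_seed(self, separable):
        table, labels = separable
        a = cross_validate(table, labels, TrainConfig(seed=2), k=5, seed=2)
        b = cross_validate(table, labels, TrainConfig(seed=2), k=5, seed=2)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)

    def test_class_smaller_than_k_rejected(self, separable):
        table, labels = separable
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(table, labels, TrainConfig(seed=1), k=50, seed=1)


class TestHoldout:
    def test_leakage_guard(self, fitted_results, small_training):
        # every labeled gene of the fitted model is in its train partition;
        # presenting one of them as a test gene must raise
        table, labels = small_training
        leaky = LabelSet(
            labels.gene_ids, dict(labels.label),
            {g: ("test" if i == 0 else "train")
             for i, g in enumerate(labels.labeled)},
        )
        with pytest.raises(ValueError, match="overlap"):
            evaluate_on_holdout(fitted_results, table, leaky)

    def test_separable_holdout_perfect(self):
        data = generate_classification_data(SimConfig(
            n_genes=200, n_features=8, effect_size=6.0, n_labeled_pos=15,
            n_labeled_neg=15, n_unlabeled=80, seed=9,
        ))
        from caser.model import CaserModel
        full = zscore_normalize(impute_missing(data.table))
        tv, labels = data.training_view()
        table = FeatureTable(full.df.loc[tv.gene_ids], dict(full.categories),
                             dict(full.value_kind))
        res = CaserModel(table, labels, TrainConfig(seed=9), preprocess=False).fit()
        hold, y = data.holdout_xy()
        holdz = FeatureTable(full.df.loc[hold.gene_ids])
        test_labels = LabelSet(
            hold.gene_ids,
            {g: ("positive" if v else "negative") for g, v in zip(hold.gene_ids, y)},
            dict.fromkeys(hold.gene_ids, "test"),
        )
        m = evaluate_on_holdout(res, holdz, test_labels)
        assert m["auroc"] == pytest.approx(1.0)


class TestGeneSetComparison:
    def test_exact_small_sample_p(self):
        scores = pd.Series({"a": 5, "b": 6, "c": 7, "x": 1, "y": 2, "z": 3})
        u, p = gene_set_score_comparison(scores, ["a", "b", "c"], ["x", "y", "z"],
                                         alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_unscored_set_rejected(self):
        scores = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="no scored members"):
            gene_set_score_comparison(scores, ["a"], ["missing"])

    def test_p_uniform_under_null(self, rng):
        from scipy import stats

        ps = []
        for rep in range(300):
            r = np.random.default_rng(rep)
            vals = r.random(30)
            scores = pd.Series(vals, index=[f"g{i}" for i in range(30)])
            a = [f"g{i}" for i in r.choice(30, 15, replace=False)]
            b = [g for g in scores.index if g not in set(a)]
            ps.append(gene_set_score_comparison(scores, a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
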