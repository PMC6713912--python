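"""Balanced sampling, stratified splitting, the three learners, metric
formulas, and the Monte Carlo cross-validation driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairpin3d.classify import (
    ConfusionCounts,
    CVConfig,
    balanced_sample,
    evaluate,
    metrics_from_counts,
    monte_carlo_cv,
    predict,
    repetition_seed,
    split,
    train,
)
from hairpin3d.errors import InputError, SchemaError
from hairpin3d.hairpin_io import FeatureTable


def gaussian_table(n_per_class, seed=0, shift=1.0, sigma=0.1, label_both=True):
    """Two 36-D Gaussian clouds with means +/-shift on the first 6 axes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    matrix = rng.normal(0, sigma, size=(n, 36))
    matrix[:n_per_class, :6] += shift
    matrix[n_per_class:, :6] -= shift
    labels = ["positive"] * n_per_class + ["negative"] * n_per_class
    return FeatureTable(
        ids=[f"g{i}" for i in range(n)],
        matrix=matrix,
        labels=labels if label_both else ["unlabeled"] * n,
    )


def unlabeled_rows(n, seed=1, prefix="u"):
    rng = np.random.default_rng(seed)
    return FeatureTable(
        ids=[f"{prefix}{i}" for i in range(n)], matrix=rng.normal(size=(n, 36))
    )


class TestBalancedSample:
    def test_min_rule_on_imbalanced_corpora(self):
        pos = unlabeled_rows(587, seed=2)
        neg = unlabeled_rows(8492, seed=3)
        sample = balanced_sample(pos, neg, seed=0)
        assert sample.labels.count("positive") == 587
        assert sample.labels.count("negative") == 587

    def test_equal_classes_keep_everything(self):
        sample = balanced_sample(unlabeled_rows(10), unlabeled_rows(10, 5), seed=1)
        assert len(sample) == 20

    def test_deterministic_given_seed(self):
        pos, neg = unlabeled_rows(50), unlabeled_rows(80, 9)
        a = balanced_sample(pos, neg, seed=7)
        b = balanced_sample(pos, neg, seed=7)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_sampling_without_replacement(self):
        sample = balanced_sample(
            unlabeled_rows(30, prefix="p"), unlabeled_rows(30, 4, prefix="n"), seed=2
        )
        assert len(set(sample.ids)) == len(sample)

    def test_empty_class_rejected(self):
        empty = FeatureTable(ids=[], matrix=np.empty((0, 36)))
        with pytest.raises(InputError):
            balanced_sample(empty, unlabeled_rows(5), seed=0)


class TestSplit:
    def test_70_30_on_balanced_100(self):
        table = gaussian_table(50)
        tr, te = split(table, 0.70, seed=0)
        assert len(tr) == 70 and len(te) == 30
        assert tr.labels.count("positive") == 35
        assert te.labels.count("negative") == 15

    def test_half_split_gives_5_5_per_class(self):
        table = gaussian_table(10)
        tr, te = split(table, 0.5, seed=0)
        for part in (tr, te):
            assert part.labels.count("positive") == 5
            assert part.labels.count("negative") == 5

    def test_disjoint_and_exhaustive(self):
        table = gaussian_table(20)
        tr, te = split(table, 0.70, seed=3)
        assert set(tr.ids).isdisjoint(te.ids)
        assert set(tr.ids) | set(te.ids) == set(table.ids)

    def test_deterministic(self):
        table = gaussian_table(20)
        assert split(table, 0.7, seed=5)[0].ids == split(table, 0.7, seed=5)[0].ids

    def test_round_half_up_on_odd_class(self):
        # 7 rows per class at 0.70 -> 4.9 -> 5 train, 2 test per class
        table = gaussian_table(7)
        tr, te = split(table, 0.70, seed=0)
        assert tr.labels.count("positive") == 5
        assert te.labels.count("positive") == 2

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(
            ids=["a", "b", "c"],
            matrix=rng.normal(size=(3, 36)),
            labels=["positive", "negative", "negative"],
        )
        with pytest.raises(InputError, match="stratify"):
            split(table, 0.7, seed=0)


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["decision_tree", "naive_bayes", "random_forest"])
    def test_separable_clouds_high_holdout_accuracy(self, kind):
        table = gaussian_table(50, seed=4)
        tr, te = split(table, 0.70, seed=4)
        model = train(tr, kind, CVConfig(repeats=1, seed=4))
        preds = predict(model, te)
        _, ms = evaluate(preds["label"], te.labels)
        assert ms.accuracy >= 0.95

    def test_single_class_table_rejected(self):
        table = gaussian_table(10)
        only_pos = table.subset(range(10))
        with pytest.raises(InputError, match="single class"):
            train(only_pos, "decision_tree")

    @pytest.mark.parametrize("kind", ["decision_tree", "naive_bayes", "random_forest"])
    def test_same_data_and_seed_identical_predictions(self, kind):
        table = gaussian_table(30, seed=6)
        m1 = train(table, kind, seed=8)
        m2 = train(table, kind, seed=8)
        fresh = unlabeled_rows(15, seed=12)
        np.testing.assert_array_equal(
            predict(m1, fresh)["score"], predict(m2, fresh)["score"]
        )

    def test_score_threshold_tie_goes_positive(self):
        table = gaussian_table(20, seed=1)
        model = train(table, "naive_bayes")
        preds = predict(model, table)
        assert set(preds.loc[preds["score"] >= 0.5, "label"]) <= {"miRNA"}

    def test_empty_table_empty_output(self):
        table = gaussian_table(10)
        model = train(table, "decision_tree")
        empty = FeatureTable(ids=[], matrix=np.empty((0, 36)))
        assert len(predict(model, empty)) == 0

    def test_scores_in_unit_interval(self):
        table = gaussian_table(30, seed=2)
        model = train(table, "random_forest", seed=1)
        scores = predict(model, unlabeled_rows(20))["score"]
        assert scores.between(0, 1).all()


class TestMetrics:
    def test_perfect_classifier(self):
        ms = metrics_from_counts(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert ms.accuracy == 1.0 and ms.f_measure == 1.0
        assert not ms.undefined

    def test_hand_computed_counts(self):
        ms = metrics_from_counts(ConfusionCounts(tp=45, fp=10, tn=40, fn=5))
        assert ms.accuracy == pytest.approx(0.85)
        assert ms.sensitivity == pytest.approx(0.90)
        assert ms.specificity == pytest.approx(0.80)
        assert ms.precision == pytest.approx(45 / 55)
        assert ms.recall == ms.sensitivity
        p, r = 45 / 55, 0.9
        assert ms.f_measure == pytest.approx(2 * p * r / (p + r))

    def test_zero_denominator_flagged_and_zero(self):
        ms = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=8, fn=2))
        assert ms.precision == 0.0
        assert "precision" in ms.undefined

    def test_evaluate_from_labels(self):
        predicted = ["miRNA", "miRNA", "negative", "negative"]
        truth = ["positive", "negative", "positive", "negative"]
        counts, ms = evaluate(predicted, truth)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 1, 1, 1)
        assert ms.accuracy == 0.5

    def test_evaluate_rejects_mismatched_lengths_and_labels(self):
        with pytest.raises(InputError):
            evaluate(["miRNA"], ["positive", "negative"])
        with pytest.raises(InputError):
            evaluate(["yes"], ["positive"])

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 50),
        fn=st.integers(0, 50),
        fp=st.integers(0, 50),
    )
    def test_balanced_accuracy_identity(self, tp, fn, fp):
        # on a balanced evaluated set, accuracy == (sens + spec) / 2
        n_pos = tp + fn
        tn = n_pos - fp
        if n_pos == 0 or tn < 0:
            return
        ms = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert ms.accuracy == pytest.approx((ms.sensitivity + ms.specificity) / 2)

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 30),
        fp=st.integers(0, 30),
        tn=st.integers(0, 30),
        fn=st.integers(0, 30),
    )
    def test_label_swap_symmetry(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        ms = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        swapped = metrics_from_counts(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert ms.sensitivity == swapped.specificity
        assert ms.specificity == swapped.sensitivity
        assert ms.accuracy == swapped.accuracy


class TestMonteCarloCV:
    def test_default_protocol_constants(self):
        cfg = CVConfig()
        assert cfg.repeats == 1000
        assert cfg.train_fraction == 0.70
        assert set(cfg.classifiers) == {
            "decision_tree",
            "naive_bayes",
            "random_forest",
        }

    def test_shape_contract(self):
        pos, neg = unlabeled_rows(30, 1), unlabeled_rows(30, 2)
        res = monte_carlo_cv(pos, neg, CVConfig(repeats=2, seed=0))
        assert len(res.metrics) == 6
        assert len(res.best_models) == 3

    def test_deterministic_metric_tables(self):
        pos, neg = unlabeled_rows(30, 1), unlabeled_rows(30, 2)
        cfg = CVConfig(repeats=3, seed=9)
        a = monte_carlo_cv(pos, neg, cfg).metrics
        b = monte_carlo_cv(pos, neg, cfg).metrics
        pd.testing.assert_frame_equal(a, b)

    def test_best_model_accuracy_is_column_maximum(self):
        table = gaussian_table(25, seed=3, shift=0.3, sigma=0.5)
        pos = table.subset(range(25))
        neg = table.subset(range(25, 50))
        res = monte_carlo_cv(pos, neg, CVConfig(repeats=5, seed=2))
        for kind, best in res.best_accuracies.items():
            col = res.metrics.loc[res.metrics["classifier"] == kind, "accuracy"]
            assert best == col.max()
            rep = res.best_repetitions[kind]
            ties = res.metrics[
                (res.metrics["classifier"] == kind)
                & (res.metrics["accuracy"] == best)
            ]["repetition"]
            assert rep == ties.min()

    def test_repetition_seeds_stable_and_below_2_31(self):
        seeds = [repetition_seed(0, r) for r in range(1, 20)]
        assert seeds == [repetition_seed(0, r) for r in range(1, 20)]
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2**31 for s in seeds)

    def test_schema_mismatch_on_predict(self):
        table = gaussian_table(10)
        model = train(table, "naive_bayes")
        broken = model.__class__(
            kind=model.kind,
            estimator=model.estimator,
            columns=("a", "b"),
            metadata={},
        )
        with pytest.raises(SchemaError):
            predict(broken, table)
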