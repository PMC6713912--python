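"""Two-class hairpin classification under Monte Carlo cross-validation.

Protocol: to remove class imbalance, each repetition draws equally sized
positive and negative subsets (n = min of the two class sizes, without
replacement), splits them 70% training / 30% testing stratified by class,
trains a decision tree, a Gaussian naive Bayes, and a random forest on
the training portion, and scores all metrics on the held-out 30%. The
default protocol runs 1000 such repetitions; per classifier, the model
with the highest held-out accuracy across repetitions is retained (ties
resolved toward the smallest repetition index).

Per-repetition seeds derive from the run seed via
``numpy.random.SeedSequence([seed, r])`` reduced mod 2^31, so any single
repetition is independently reproducible.

Classifier choices: the naive Bayes is Gaussian per feature (the
descriptor is continuous) with class priors from training frequencies
and a 1e-9 variance floor; the decision tree is a single Gini-impurity
recursive partition; the random forest bags 100 trees (configurable)
with sqrt-of-36 = 6 features considered per split. A prediction score of
exactly 0.5 is labeled positive (miRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError, SchemaError
from .hairpin_io import (
    CLASSIFIER_KINDS,
    FeatureTable,
    concat_tables,
)

POSITIVE_LABEL = "miRNA"
NEGATIVE_LABEL = "negative"


@dataclass(frozen=True)
class CVConfig:
    """Monte Carlo cross-validation protocol parameters.

    Defaults reproduce the reference protocol: 1000 repetitions of a
    70/30 learning/testing split over balanced samples.
    """

    repeats: int = 1000
    train_fraction: float = 0.70
    seed: int = 0
    classifiers: tuple = CLASSIFIER_KINDS
    rf_trees: int = 100

    def __post_init__(self):
        if self.repeats < 1:
            raise InputError("repeats must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise InputError("train_fraction must lie in (0, 1)")
        if self.rf_trees < 1:
            raise InputError("rf_trees must be positive")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown or not self.classifiers:
            raise InputError(f"unknown classifier kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts; the positive class is miRNA."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity/recall, specificity, precision, F-measure.

    A ratio with a zero denominator is reported as 0.0 and its name is
    recorded in ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f_measure: float
    undefined: frozenset = frozenset()


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier bound to the 36-column feature schema."""

    kind: str
    estimator: object
    columns: tuple
    metadata: dict = field(default_factory=dict)


@dataclass
class CVRunResult:
    """All per-repetition metrics plus the best model per classifier."""

    metrics: pd.DataFrame  # columns per hairpin_io.METRIC_COLUMNS
    best_models: dict  # kind -> TrainedModel
    best_repetitions: dict  # kind -> repetition index (1-based)
    best_accuracies: dict  # kind -> held-out accuracy of the best model


def repetition_seed(seed: int, repetition: int) -> int:
    """Stable per-repetition seed: SeedSequence([seed, r]) mod 2^31."""
    return int(np.random.SeedSequence([seed, repetition]).generate_state(1)[0] % 2**31)


def balanced_sample(pos: FeatureTable, neg: FeatureTable, seed: int) -> FeatureTable:
    """Draw n = min(|pos|, |neg|) rows per class without replacement.

    Labels are attached (``positive`` / ``negative``) regardless of the
    input tables' labels.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both classes must be non-empty for balanced sampling")
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))
    pos_idx = rng.choice(len(pos), size=n, replace=False)
    neg_idx = rng.choice(len(neg), size=n, replace=False)
    return concat_tables(
        [
            pos.subset(pos_idx).with_labels("positive"),
            neg.subset(neg_idx).with_labels("negative"),
        ]
    )


def split(table: FeatureTable, train_fraction: float, seed: int):
    """Stratified train/test split; train size per class rounds half-up."""
    if not 0.0 < train_fraction < 1.0:
        raise InputError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(table.labels)
    train_idx, test_idx = [], []
    for cls in sorted(set(table.labels)):
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) < 2:
            raise InputError(f"class {cls!r} has fewer than 2 rows; cannot stratify")
        perm = rng.permutation(cls_idx)
        n_train = int(np.floor(train_fraction * len(cls_idx) + 0.5))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return table.subset(train_idx), table.subset(test_idx)


def _make_estimator(kind: str, config: CVConfig, seed: int):
    if kind == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if kind == "naive_bayes":
        return GaussianNB(var_smoothing=1e-9)
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features="sqrt",
            random_state=seed,
        )
    raise InputError(f"unknown classifier kind {kind!r}")


def train(
    train_table: FeatureTable, kind: str, hyper: CVConfig | None = None, seed: int | None = None
) -> TrainedModel:
    """Fit one classifier on a labeled feature table."""
    hyper = hyper or CVConfig()
    seed = hyper.seed if seed is None else seed
    y = np.asarray(train_table.labels)
    if len(set(y)) < 2:
        raise InputError("training table contains a single class")
    est = _make_estimator(kind, hyper, seed)
    est.fit(train_table.matrix, y)
    return TrainedModel(
        kind=kind,
        estimator=est,
        columns=train_table.column_names,
        metadata={"seed": seed, "n_train": len(train_table)},
    )


def predict(model: TrainedModel, table: FeatureTable) -> pd.DataFrame:
    """Per-row predicted label and positive-class score.

    The score is the positive-class probability (naive Bayes posterior,
    tree leaf fraction, forest vote fraction); a row is labeled miRNA
    iff score >= 0.5 (ties go to the positive class).
    """
    if tuple(table.column_names) != tuple(model.columns):
        raise SchemaError("feature table schema does not match the model's")
    if len(table) == 0:
        return pd.DataFrame(columns=["id", "label", "score", "model_kind"])
    proba = model.estimator.predict_proba(table.matrix)
    pos_col = list(model.estimator.classes_).index("positive")
    scores = proba[:, pos_col]
    labels = np.where(scores >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame(
        {
            "id": table.ids,
            "label": labels,
            "score": scores,
            "model_kind": model.kind,
        }
    )


def evaluate(predicted_labels, truth_labels):
    """Confusion counts and the metric set from prediction vs. truth.

    ``predicted_labels`` use {miRNA, negative}; ``truth_labels`` use the
    table tags {positive, negative}. Zero-denominator ratios are flagged
    and reported as 0.
    """
    predicted = list(predicted_labels)
    truth = list(truth_labels)
    if len(predicted) != len(truth):
        raise InputError("predictions and truth have different lengths")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise InputError(f"unknown predicted label {p!r}")
        if t not in ("positive", "negative"):
            raise InputError(f"unknown truth label {t!r}")
        pos_pred = p == POSITIVE_LABEL
        pos_true = t == "positive"
        if pos_pred and pos_true:
            tp += 1
        elif pos_pred:
            fp += 1
        elif pos_true:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, metrics_from_counts(counts)


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    accuracy = ratio(c.tp + c.tn, c.total, "accuracy")
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = sensitivity
    if "sensitivity" in undefined:
        undefined.add("recall")
    if precision + recall == 0:
        undefined.add("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        undefined=frozenset(undefined),
    )


def monte_carlo_cv(
    pos: FeatureTable, neg: FeatureTable, config: CVConfig | None = None
) -> CVRunResult:
    """Run the balanced 70/30 Monte Carlo cross-validation protocol.

    Each repetition r uses its own derived seed for sampling, splitting,
    and training. Returns every repetition's metric row and, per
    classifier, the model with maximal held-out accuracy.
    """
    config = config or CVConfig()
    rows = []
    best_models: dict = {}
    best_reps: dict = {}
    best_acc: dict = {}
    for r in range(1, config.repeats + 1):
        seed_r = repetition_seed(config.seed, r)
        try:
            sample = balanced_sample(pos, neg, seed_r)
            train_table, test_table = split(sample, config.train_fraction, seed_r)
            for kind in config.classifiers:
                model = train(train_table, kind, config, seed=seed_r)
                preds = predict(model, test_table)
                counts, ms = evaluate(preds["label"], test_table.labels)
                rows.append(
                    {
                        "repetition": r,
                        "classifier": kind,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "accuracy": ms.accuracy,
                        "sensitivity": ms.sensitivity,
                        "specificity": ms.specificity,
                        "precision": ms.precision,
                        "recall": ms.recall,
                        "f_measure": ms.f_measure,
                    }
                )
                if kind not in best_acc or ms.accuracy > best_acc[kind]:
                    best_acc[kind] = ms.accuracy
                    best_models[kind] = replace(
                        model,
                        metadata={**model.metadata, "repetition": r, "cv_seed": config.seed},
                    )
                    best_reps[kind] = r
        except InputError as exc:
            raise InputError(f"repetition {r}: {exc}") from exc
    return CVRunResult(
        metrics=pd.DataFrame(rows),
        best_models=best_models,
        best_repetitions=best_reps,
        best_accuracies=best_acc,
    )
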