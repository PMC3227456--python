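"""Functional classification of chains from their descriptor vectors.

The descriptors — not the classifiers — carry the method's contribution, so
the classifiers are standard scikit-learn implementations with fixed
hyperparameters:

* ``naive_bayes``      Gaussian naive Bayes
* ``logistic``         multinomial logistic regression, weak L2 (C=100)
* ``simple_logistic``  L2-regularized logistic regression (C=1), an
  approximation of the LogitBoost-based "simple logistic" classifier of
  older ML suites, which has no exact scikit-learn counterpart

Experiments use stratified train/test splits with no overlap and stratified
n-fold cross-validation, all reproducible from an integer seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB

CLASSIFIERS = ("naive_bayes", "logistic", "simple_logistic")


@dataclass
class LabeledFeatures:
    """Descriptor vectors (rows) with a family label per row."""

    X: np.ndarray  # (n, d)
    labels: list[str]
    scheme: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("row count does not match label count")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaNs")

    def __len__(self) -> int:
        return self.X.shape[0]


def _make_classifier(name: str):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic":
        return LogisticRegression(C=100.0, max_iter=2000)
    if name == "simple_logistic":
        return LogisticRegression(C=1.0, max_iter=2000)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def split_train_test(
    features: LabeledFeatures, n_train: int, n_test: int, seed: int
) -> tuple[LabeledFeatures, LabeledFeatures]:
    """Disjoint stratified train/test draw of the requested sizes.

    Stratification keeps the label proportions in both draws, which
    prevents a class from going missing at small training sizes; if one
    does anyway, an error is raised because the classifier would be
    undefined on it.
    """
    if n_train + n_test > len(features):
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} exceeds dataset size "
            f"{len(features)}"
        )
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=n_train,
        test_size=n_test,
        stratify=features.labels,
        random_state=seed,
    )
    y = np.asarray(features.labels)
    train_labels = set(y[train_idx])
    if train_labels != set(features.labels):
        missing = sorted(set(features.labels) - train_labels)
        raise ValueError(f"classes absent from the training draw: {missing}")
    train = LabeledFeatures(features.X[train_idx], list(y[train_idx]), features.scheme)
    test = LabeledFeatures(features.X[test_idx], list(y[test_idx]), features.scheme)
    return train, test


def train_and_score(
    train: LabeledFeatures, test: LabeledFeatures, classifier: str = "logistic"
) -> float:
    """Fit the named classifier on the training set; return the test
    classification rate (fraction of test rows labeled correctly)."""
    if len(set(train.labels)) < 2:
        raise ValueError("training set needs at least 2 classes")
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError(
            f"feature length mismatch: train {train.X.shape[1]} vs "
            f"test {test.X.shape[1]}"
        )
    clf = _make_classifier(classifier)
    clf.fit(train.X, train.labels)
    return float(clf.score(test.X, test.labels))


def cross_validate(
    features: LabeledFeatures,
    n_folds: int,
    classifier: str = "logistic",
    seed: int = 0,
) -> float:
    """Mean classification rate over stratified n-fold cross-validation."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    smallest = min(Counter(features.labels).values())
    if n_folds > smallest:
        raise ValueError(
            f"n_folds = {n_folds} exceeds the smallest class size {smallest}"
        )
    y = np.asarray(features.labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rates = []
    for train_idx, test_idx in skf.split(features.X, y):
        clf = _make_classifier(classifier)
        clf.fit(features.X[train_idx], y[train_idx])
        rates.append(clf.score(features.X[test_idx], y[test_idx]))
    return float(np.mean(rates))
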