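"""Hair-cell classification from shape-mode scores.

A logistic regression on the shape modes (eight cell modes, or four
nucleus modes) predicts hair-cell identity; performance is reported as
the ROC curve with its AUC and the confusion matrix at a 0.5
probability cutoff on a held-out stratified test split.  The idealized
mean shape of each class — the mesh reconstructed from the class-mean
mode scores — visualizes what the classifier separates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, confusion_matrix, roc_curve

from .shapespace import ShapeSpaceModel, modes_to_mesh

__all__ = [
    "ClassifierReport",
    "stratified_split",
    "fit_and_evaluate",
    "mean_class_shape",
]


@dataclass
class ClassifierReport:
    """ROC/AUC and confusion-matrix summary on the test split."""

    auc: float
    roc_points: np.ndarray  # (n, 2) of (fpr, tpr)
    confusion: np.ndarray  # 2x2, rows = truth (neg, pos), cols = prediction
    split_seed: int
    train_fraction: float
    n_train: int
    n_test: int
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if int(self.confusion.sum()) != self.n_test:
            raise ValueError("confusion counts must sum to the test-set size")


def stratified_split(
    y: np.ndarray, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices with exact stratification.

    Each class is shuffled and split at ``round(train_fraction * n_class)``,
    so the class proportions of both subsets match the population to
    within one cell.  A class with fewer than 2 members is rejected.
    """
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        rows = np.nonzero(y == cls)[0]
        if len(rows) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        rows = rng.permutation(rows)
        n_train = int(round(train_fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        train.append(rows[:n_train])
        test.append(rows[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def fit_and_evaluate(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    c_regularization: float = 1.0,
    split_seed: int = 0,
    train_fraction: float = 0.8,
) -> ClassifierReport:
    """Fit the logistic classifier and score it on the test split.

    A ridge (L2) penalty of strength ``1 / c_regularization`` keeps the
    fit defined under perfect separation; when the training classes are
    linearly separable the report carries a ``perfect_separation`` flag.
    The confusion matrix thresholds the predicted probability at 0.5.
    """
    x_train = np.atleast_2d(np.asarray(x_train, dtype=float))
    x_test = np.atleast_2d(np.asarray(x_test, dtype=float))
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    clf = LogisticRegression(C=c_regularization, solver="lbfgs", max_iter=2000)
    clf.fit(x_train, y_train)
    flags: list[str] = []
    if np.all(clf.predict(x_train) == y_train):
        flags.append("perfect_separation")
    prob = clf.predict_proba(x_test)[:, 1]
    fpr, tpr, _ = roc_curve(y_test, prob)
    conf = confusion_matrix(y_test, (prob >= 0.5).astype(int), labels=[0, 1])
    return ClassifierReport(
        auc=float(auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        confusion=conf,
        split_seed=split_seed,
        train_fraction=train_fraction,
        n_train=len(y_train),
        n_test=len(y_test),
        coefficients=clf.coef_.ravel().copy(),
        flags=tuple(flags),
    )


def classify_cells(
    modes: np.ndarray,
    is_positive_class: np.ndarray,
    train_fraction: float = 0.8,
    seed: int = 0,
    c_regularization: float = 1.0,
) -> ClassifierReport:
    """Convenience wrapper: stratified split, fit, evaluate."""
    y = np.asarray(is_positive_class).astype(int)
    modes = np.atleast_2d(np.asarray(modes, dtype=float))
    tr, te = stratified_split(y, train_fraction, seed)
    return fit_and_evaluate(
        modes[tr], y[tr], modes[te], y[te],
        c_regularization=c_regularization,
        split_seed=seed, train_fraction=train_fraction,
    )


def mean_class_shape(
    modes: np.ndarray,
    in_class: np.ndarray,
    model: ShapeSpaceModel,
) -> trimesh.Trimesh:
    """Idealized mean shape of one class.

    The class-mean shape-mode vector maps through the inverse PCA to SH
    coefficients and then to a surface.
    """
    modes = np.atleast_2d(np.asarray(modes, dtype=float))
    in_class = np.asarray(in_class, dtype=bool)
    if not in_class.any():
        raise ValueError("class is empty")
    return modes_to_mesh(modes[in_class].mean(axis=0), model)
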