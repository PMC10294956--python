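"""Two-fold cross-validated grading of identity images.

Classifier internals are pluggable: anything exposing ``fit(X, y)`` /
``predict(X)`` on flattened image matrices works, including adapters
around external 2D deep models (any resizing or channel replication those
need lives in the adapter).  The built-in reference classifier is a
closed-form ridge model, chosen for determinism and desk-scale speed.

Also enumerates the training hyperparameter grid used by the reference
study's deep classifier (epoch fixed at 100; mini-batch size, learning
rate, learning-rate drop factor and optimizer varied) so experiment
orchestration over all 48 settings is a one-liner.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeClassifier


@dataclass(frozen=True)
class HyperparameterGrid:
    epoch: int = 100
    mini_batch_sizes: tuple[int, ...] = (16, 32)
    learning_rates: tuple[float, ...] = (0.001, 0.0001)
    lrdf_values: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    optimizers: tuple[str, ...] = ("adam", "rmsprop", "sgdm")

    def __post_init__(self):
        for name in ("mini_batch_sizes", "learning_rates", "lrdf_values",
                     "optimizers"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


@dataclass
class CvResult:
    per_fold_accuracy: list[float]
    mean_accuracy: float
    fold_assignment: np.ndarray
    config_used: str = ""


def enumerate_grid(grid: HyperparameterGrid = HyperparameterGrid()
                   ) -> list[dict]:
    """Cartesian product over the four varying hyperparameters.

    Ordering is deterministic: mini-batch size varies slowest, optimizer
    fastest.  The default grid yields 2 * 2 * 4 * 3 = 48 configurations.
    """
    return [
        {"epoch": grid.epoch, "mini_batch_size": mb, "learning_rate": lr,
         "lrdf": lrdf, "optimizer": opt}
        for mb, lr, lrdf, opt in itertools.product(
            grid.mini_batch_sizes, grid.learning_rates,
            grid.lrdf_values, grid.optimizers)
    ]


def stratified_two_fold(labels, seed: int = 0) -> np.ndarray:
    """Seeded stratified assignment of cases to two folds (ids 0 and 1).

    Each class is split as evenly as possible; for an odd class count the
    extra case lands in the first fold (id 0).  Deterministic given seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 cases")
        idx = rng.permutation(idx)
        half = (len(idx) + 1) // 2  # extra case to the first fold
        folds[idx[:half]] = 0
        folds[idx[half:]] = 1
    return folds


def make_linear_classifier(seed: int = 0):
    """The built-in reference classifier: L2-regularized linear model."""
    return RidgeClassifier(alpha=1.0, random_state=seed)


def evaluate_classifier(images, labels, classifier=None,
                        folds: np.ndarray | None = None,
                        seed: int = 0) -> CvResult:
    """Two-fold cross-validated accuracy on flattened identity images.

    Trains on each fold and tests on the other; accuracy per test fold is
    correct/total, and the reported mean is the unweighted average of the
    two test folds.
    """
    labels = np.asarray(labels)
    shapes = {im.values.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    X = np.stack([im.values.ravel() for im in images])
    if len(X) != len(labels):
        raise ValueError("images and labels length mismatch")
    if folds is None:
        folds = stratified_two_fold(labels, seed)
    if classifier is None:
        classifier = make_linear_classifier(seed)

    accs = []
    for test_fold in (0, 1):
        train = folds != test_fold
        test = folds == test_fold
        clf = copy.deepcopy(classifier)
        clf.fit(X[train], labels[train])
        pred = clf.predict(X[test])
        accs.append(float(np.mean(pred == labels[test])))
    return CvResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        fold_assignment=folds,
        config_used=repr(classifier),
    )
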