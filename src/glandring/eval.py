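"""Supervised evaluation protocol in the bag dissimilarity space.

The dataset of bags is split once into a tuning subset (default 25%) and
an evaluation subset. Classifier hyperparameters are chosen by
leave-one-out cross-validation on the tuning subset; the evaluation
subset is then scored by stratified 10-fold cross-validation, repeated
(default 5 times), and accuracies reported as mean +- std in percent.

A bag's features are its distances to the TRAINING bags of the current
fold only — test bags never enter the representation, so there is no
leakage through the dissimilarity space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from glandring.mil import Bag, DissimilarityMatrix, dissimilarity_matrix

CLASSIFIER_FAMILIES = ("svc", "knn", "logistic", "ldc")

# grids ordered least-complex first so argmax tie-break prefers simplicity
_DEFAULT_GRIDS: dict[str, list[dict[str, Any]]] = {
    "svc": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)],
    "knn": [{"n_neighbors": k} for k in (7, 5, 3, 1)],
    "logistic": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "ldc": [{}],
}


@dataclass
class EvalReport:
    """Cross-validated accuracies per classifier family."""

    accuracy_mean: dict[str, float]  # percent
    accuracy_std: dict[str, float]  # percent, over repeats
    n_repeats: int
    n_folds: int
    split_fraction: float
    seed: int
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "accuracy_mean_percent": self.accuracy_mean,
            "accuracy_std_percent": self.accuracy_std,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "params": self.params,
        }


def make_classifier(family: str, params: dict[str, Any] | None = None):
    """Instantiate one of the supported classifier families."""
    params = params or {}
    if family == "svc":
        return SVC(kernel="linear", **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if family == "ldc":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto", **params)
    raise ValueError(f"unknown classifier family {family!r}")


def _fold_accuracy(
    D: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    family: str,
    params: dict[str, Any],
) -> float:
    """Fit on training rows, score test rows; feature columns = train bags."""
    X_train = D[np.ix_(train_idx, train_idx)]
    X_test = D[np.ix_(test_idx, train_idx)]
    if family == "knn":  # neighbor count cannot exceed the training fold
        params = {**params, "n_neighbors": min(params.get("n_neighbors", 5), len(train_idx))}
    clf = make_classifier(family, params)
    clf.fit(X_train, labels[train_idx])
    return float(np.mean(clf.predict(X_test) == labels[test_idx]))


def tune_hyperparameters(
    D_train: np.ndarray | DissimilarityMatrix,
    labels: Sequence,
    family: str,
    grid: list[dict[str, Any]] | None = None,
) -> dict[str, Any]:
    """Pick the grid point maximizing leave-one-out accuracy.

    Each left-out bag is represented by its distances to the remaining
    bags. Ties go to the earlier (least complex) grid entry.
    """
    D = D_train.values if isinstance(D_train, DissimilarityMatrix) else np.asarray(D_train)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("tuning split contains a single class; reseed the split")
    grid = grid if grid is not None else _DEFAULT_GRIDS[family]
    n = D.shape[0]
    best_params, best_acc = grid[0], -1.0
    for params in grid:
        if family == "knn" and params.get("n_neighbors", 1) > n - 1:
            continue
        hits = 0
        for i in range(n):
            rest = np.setdiff1d(np.arange(n), [i])
            hits += _fold_accuracy(D, labels, rest, np.array([i]), family, params)
        acc = hits / n
        if acc > best_acc:
            best_acc, best_params = acc, params
    return dict(best_params)


def evaluate(
    D: DissimilarityMatrix | np.ndarray,
    labels: Sequence,
    classifiers: dict[str, dict[str, Any]] | Sequence[str],
    n_repeats: int = 5,
    n_folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold accuracy per classifier family.

    ``classifiers`` maps family name to its (tuned) parameters, or is a
    sequence of family names run with defaults. Accuracy is averaged over
    folds within a repeat; mean and std are taken over repeats.
    """
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D)
    labels = np.asarray(labels)
    if isinstance(classifiers, dict):
        families = dict(classifiers)
    else:
        families = {f: {} for f in classifiers}
    n = Dv.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match matrix size")

    per_repeat: dict[str, list[float]] = {f: [] for f in families}
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        folds = list(skf.split(np.zeros(n), labels))
        for family, params in families.items():
            accs = [
                _fold_accuracy(Dv, labels, tr, te, family, params)
                for tr, te in folds
            ]
            per_repeat[family].append(float(np.mean(accs)))

    return EvalReport(
        accuracy_mean={f: 100 * float(np.mean(a)) for f, a in per_repeat.items()},
        accuracy_std={f: 100 * float(np.std(a)) for f, a in per_repeat.items()},
        n_repeats=n_repeats,
        n_folds=n_folds,
        split_fraction=float("nan"),
        seed=seed,
        params={f: dict(p) for f, p in families.items()},
    )


def run_protocol(
    bags: list[Bag],
    classifiers: Sequence[str] = CLASSIFIER_FAMILIES,
    tune_fraction: float = 0.25,
    n_repeats: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    metric: str = "euclidean",
) -> EvalReport:
    """End-to-end protocol: 25% LOO tuning split + repeated 10-fold CV.

    A stratified random ``tune_fraction`` of the bags is set aside; SVC
    and KNN hyperparameters are tuned there by leave-one-out. The
    remaining bags are scored by ``n_repeats`` x ``n_folds`` stratified
    cross-validation on their own dissimilarity matrix.
    """
    labels = np.asarray([b.label for b in bags])
    rng = np.random.default_rng(seed)
    tune_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        n_take = max(2, int(round(tune_fraction * members.size)))
        tune_idx.extend(rng.choice(members, size=n_take, replace=False))
    tune_mask = np.zeros(len(bags), dtype=bool)
    tune_mask[tune_idx] = True

    tune_bags = [b for b, m in zip(bags, tune_mask) if m]
    eval_bags = [b for b, m in zip(bags, tune_mask) if not m]

    D_tune = dissimilarity_matrix(tune_bags, metric=metric)
    tuned: dict[str, dict[str, Any]] = {}
    for family in classifiers:
        if len(_DEFAULT_GRIDS[family]) > 1:
            tuned[family] = tune_hyperparameters(
                D_tune, [b.label for b in tune_bags], family
            )
        else:
            tuned[family] = {}

    D_eval = dissimilarity_matrix(eval_bags, metric=metric)
    report = evaluate(
        D_eval,
        [b.label for b in eval_bags],
        tuned,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
    )
    report.split_fraction = tune_fraction
    return report
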