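"""Random-forest classification protocol for smoking and race/ethnicity.

The protocol is an exhaustive grid search over (number of trees, maximum
depth) scored by mean accuracy across 5-fold cross-validation with a fold
assignment fixed across grid cells, followed by a 5-fold cross-validated run
at the winning hyperparameters to obtain out-of-fold predictions for every
sample, and a final refit on all data.  Confusion statistics (accuracy,
Cohen's kappa, per-class sensitivity/specificity/balanced accuracy) are
computed on the pooled out-of-fold predictions.

Folds are stratified by class by default: with class imbalance as extreme as
the study's smallest ancestry group, unstratified folds can starve a class
out of a training split.  Grid ties are broken toward fewer trees, then
shallower depth (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .results import FitResult

DEFAULT_N_TREES = (20, 50, 100, 200, 500, 1000, 2000)
DEFAULT_MAX_DEPTHS = (2, 3, 4, 5, 6, 7)


@dataclass
class RFGrid:
    """Hyperparameter grid for the random-forest search."""

    n_trees: tuple[int, ...] = DEFAULT_N_TREES
    max_depths: tuple[int, ...] = DEFAULT_MAX_DEPTHS
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(int(t) == t and t > 0 for t in self.n_trees):
            raise ValueError("tree counts must be positive integers")
        if not all(int(d) == d and d > 0 for d in self.max_depths):
            raise ValueError("depths must be positive integers")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def combinations(self) -> list[tuple[int, int]]:
        """All (n_trees, max_depth) cells, in tie-break order."""
        return [(t, d) for t in self.n_trees for d in self.max_depths]


@dataclass
class ConfusionStats:
    """Confusion matrix (rows = truth) with summary agreement statistics."""

    matrix: pd.DataFrame
    accuracy: float
    kappa: float
    per_class: pd.DataFrame  # sensitivity, specificity, balanced_accuracy


def _check_class_sizes(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    starving = classes[counts < folds]
    if len(starving):
        raise ValueError(
            f"class(es) {starving.tolist()} have fewer than {folds} members"
        )


def _fold_iter(y, folds, seed, stratify):
    if stratify:
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed).split(
            np.zeros(len(y)), y
        )
    return KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.zeros(len(y)))


def grid_search_rf(
    X, y, grid: RFGrid | None = None, stratify: bool = True, rf_params: dict | None = None
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Exhaustive grid search by mean CV accuracy with a fixed fold assignment.

    Returns the winning ``(n_trees, max_depth)`` and a tidy table of all grid
    cells with their mean accuracies.  Ties go to fewer trees, then shallower
    depth.
    """
    grid = grid or RFGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_class_sizes(y, grid.folds)
    splits = list(_fold_iter(y, grid.folds, grid.seed, stratify))
    rows = []
    best: tuple[int, int] | None = None
    best_acc = -np.inf
    for n_trees, depth in grid.combinations():
        accs = []
        for train, test in splits:
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_depth=depth,
                random_state=grid.seed,
                **(rf_params or {}),
            )
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
        mean_acc = float(np.mean(accs))
        rows.append({"n_trees": n_trees, "max_depth": depth, "cv_accuracy": mean_acc})
        if mean_acc > best_acc:  # strict: earlier (fewer trees/shallower) wins ties
            best_acc = mean_acc
            best = (n_trees, depth)
    return best, pd.DataFrame(rows)


def train_rf_cv(
    X,
    y,
    n_trees: int,
    max_depth: int,
    folds: int = 5,
    seed: int = 0,
    stratify: bool = True,
    features: list[str] | None = None,
    rf_params: dict | None = None,
) -> FitResult:
    """Out-of-fold predictions under k-fold CV plus a final refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_class_sizes(y, folds)
    oof = np.empty(len(y), dtype=y.dtype)
    fold_id = np.full(len(y), -1, dtype=int)
    for k, (train, test) in enumerate(_fold_iter(y, folds, seed, stratify)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_depth=max_depth, random_state=seed, **(rf_params or {})
        )
        clf.fit(X[train], y[train])
        oof[test] = clf.predict(X[test])
        fold_id[test] = k
    final = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, **(rf_params or {})
    )
    final.fit(X, y)
    stats = confusion_stats(y, oof, class_order=list(np.unique(y)))
    return FitResult(
        model=final,
        features=list(features) if features is not None else [f"f{j}" for j in range(X.shape[1])],
        oof_pred=oof,
        fold=fold_id,
        metrics={"oof_accuracy": stats.accuracy, "oof_kappa": stats.kappa},
        provenance={
            "model": "RandomForestClassifier",
            "n_trees": n_trees,
            "max_depth": max_depth,
            "folds": folds,
            "seed": seed,
            "stratified": stratify,
            "rf_params": dict(rf_params or {}),
        },
    )


def confusion_stats(y_true, y_pred, class_order: list, positive_class=None) -> ConfusionStats:
    """Confusion matrix with accuracy, Cohen's kappa and per-class statistics.

    Kappa is (p_o - p_e) / (1 - p_e) with the expected agreement p_e computed
    from row/column marginals.  Sensitivity/specificity are one-vs-rest per
    class; in the binary case read the row of ``positive_class`` (e.g. the
    smoker class, so sensitivity is smoker recall).  Balanced accuracy is the
    mean of sensitivity and specificity.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    extra = (set(y_true) | set(y_pred)) - set(class_order)
    if extra:
        raise ValueError(f"labels outside class_order: {sorted(map(str, extra))}")
    cm = confusion_matrix(y_true, y_pred, labels=class_order)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=class_order))
    rows = {}
    for i, cls in enumerate(class_order):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2.0,
        }
    per_class = pd.DataFrame(rows).T
    if positive_class is not None:
        per_class = per_class.reindex(
            [positive_class] + [c for c in class_order if c != positive_class]
        )
    return ConfusionStats(
        matrix=pd.DataFrame(cm, index=class_order, columns=class_order),
        accuracy=accuracy,
        kappa=kappa,
        per_class=per_class,
    )


class RandomForestGridCV(BaseEstimator, ClassifierMixin):
    """Grid-searched random forest with pooled out-of-fold evaluation.

    Runs the exhaustive (n_trees, max_depth) grid search, re-runs CV at the
    winning cell to collect out-of-fold predictions, and refits on all data.

    Attributes (after ``fit``)
    --------------------------
    best_params_ : dict with the winning ``n_trees`` and ``max_depth``
    cv_results_ : DataFrame of all grid cells and their mean CV accuracies
    oof_pred_ : out-of-fold predicted labels, one per training sample
    confusion_ : ConfusionStats on the out-of-fold predictions
    estimator_ : the final RandomForestClassifier fit on all data
    feature_importances_ : impurity importances of the final forest
    """

    def __init__(
        self,
        n_trees_grid: tuple[int, ...] = DEFAULT_N_TREES,
        max_depths_grid: tuple[int, ...] = DEFAULT_MAX_DEPTHS,
        folds: int = 5,
        seed: int = 0,
        stratify: bool = True,
        positive_class=None,
    ):
        self.n_trees_grid = n_trees_grid
        self.max_depths_grid = max_depths_grid
        self.folds = folds
        self.seed = seed
        self.stratify = stratify
        self.positive_class = positive_class

    def fit(self, X, y):
        grid = RFGrid(tuple(self.n_trees_grid), tuple(self.max_depths_grid), self.folds, self.seed)
        (n_trees, depth), table = grid_search_rf(X, y, grid, stratify=self.stratify)
        self.best_params_ = {"n_trees": n_trees, "max_depth": depth}
        self.cv_results_ = table
        fit = train_rf_cv(
            X, y, n_trees, depth, folds=self.folds, seed=self.seed, stratify=self.stratify
        )
        self.fit_result_ = fit
        self.oof_pred_ = fit.oof_pred
        self.estimator_ = fit.model
        self.classes_ = self.estimator_.classes_
        self.feature_importances_ = self.estimator_.feature_importances_
        self.confusion_ = confusion_stats(
            np.asarray(y), fit.oof_pred, list(self.classes_), positive_class=self.positive_class
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(X)
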