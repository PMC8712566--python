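"""The fusion experiment harness: splits, CV densities, grid search.

One repetition of the experiment mirrors the standard protocol of
fuzzy-measure classifier fusion:

1. stratified 80:20 holdout split of the feature table;
2. per classifier, the fuzzy density = mean accuracy over a stratified
   5-fold cross-validation on the training part;
3. classifiers refit on the full training part; per-class probabilities on
   the test part;
4. for every (operator, t-norm, α) grid cell, each test sample's two class
   score vectors are fused independently (the Sugeno chain is rebuilt for
   each class's score ordering) and the argmax is the fused prediction.

Repetitions use seeds derived deterministically from one master seed, and
accuracy per grid cell is pooled over all repetitions (micro average over
``n_repetitions × test size`` predictions); a per-run macro average is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from eegfuse.aggregators import GENERALIZED_OPERATORS, fuse_class_scores
from eegfuse.sugeno import FuzzyDensities, clip_densities, solve_lambda
from eegfuse.tnorms import TNormSpec

__all__ = [
    "CLASSIFIER_ROSTER",
    "ExperimentConfig",
    "RunRecord",
    "make_classifier",
    "split_holdout",
    "estimate_densities",
    "fuse_sample",
    "run_experiment",
    "summarize",
]

#: The eight base classifiers of the default roster.
CLASSIFIER_ROSTER = (
    "decision_tree",
    "knn",
    "svm_quadratic",
    "svm_cubic",
    "svm_linear",
    "logistic_regression",
    "random_forest",
    "mlp",
)


def make_classifier(name: str, seed: int = 0):
    """Fresh estimator with predict_proba, scaled where the model needs it."""
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("model", est)])
    # SVC has no native predict_proba; wrap in Platt-style calibration
    svm = lambda est: scaled(CalibratedClassifierCV(est, cv=3, ensemble=False))
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "knn":
        return scaled(KNeighborsClassifier(n_neighbors=5))
    if name == "svm_quadratic":
        return svm(SVC(kernel="poly", degree=2, random_state=seed))
    if name == "svm_cubic":
        return svm(SVC(kernel="poly", degree=3, random_state=seed))
    if name == "svm_linear":
        return svm(SVC(kernel="linear", random_state=seed))
    if name == "logistic_regression":
        return scaled(LogisticRegression(max_iter=2000))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "mlp":
        return scaled(
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=800, random_state=seed)
        )
    raise KeyError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    holdout_fraction: float = 0.2
    n_repetitions: int = 200
    cv_folds: int = 5
    classifiers: tuple[str, ...] = CLASSIFIER_ROSTER
    operators: tuple[str, ...] = ("choquet", "CM", "CD2")
    tnorms: tuple[TNormSpec, ...] = ()
    seed: int = 0
    h0: float = 1.0
    positive_channel_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def grid(self) -> list[tuple[str, Optional[TNormSpec]]]:
        """Grid cells: generalized operators cross the t-norm list, the rest
        appear once with no t-norm."""
        cells: list[tuple[str, Optional[TNormSpec]]] = []
        for op in self.operators:
            if op in GENERALIZED_OPERATORS:
                if not self.tnorms:
                    raise ValueError(f"operator {op} requires tnorms in the config")
                cells.extend((op, t) for t in self.tnorms)
            else:
                cells.append((op, None))
        return cells


@dataclass
class RunRecord:
    """Everything one repetition produced before fusion."""

    run: int
    seed: int
    densities: FuzzyDensities
    test_scores: np.ndarray  # (n_test, n_classifiers, 2), rows sum to 1
    y_true: np.ndarray
    individual_correct: np.ndarray  # (n_classifiers,) correct counts on test


def split_holdout(
    table: pd.DataFrame, fraction: float = 0.2, seed: int = 0, label_col: str = "label"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving the class ratio."""
    labels = table[label_col]
    if labels.value_counts().min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    train, test = train_test_split(
        table, test_size=fraction, stratify=labels, random_state=seed
    )
    return train, test


def estimate_densities(
    train: pd.DataFrame,
    classifiers: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    label_col: str = "label",
) -> FuzzyDensities:
    """Fuzzy densities: per-classifier mean stratified-CV accuracy on train."""
    X = train.drop(columns=[label_col]).to_numpy()
    y = train[label_col].to_numpy()
    minority = int(np.bincount(y).min())
    folds = min(folds, minority)
    if folds < 2:
        raise ValueError("training set too small for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = [
        float(np.mean(cross_val_score(make_classifier(name, seed), X, y, cv=cv)))
        for name in classifiers
    ]
    densities = clip_densities(accs)
    return FuzzyDensities(densities.g, tuple(classifiers))


def fuse_sample(
    scores: np.ndarray,
    densities: FuzzyDensities,
    lam: float,
    operator: str,
    tnorm: Optional[TNormSpec] = None,
    h0: float = 1.0,
    positive_channel_only: bool = False,
) -> int:
    """Fuse one sample's (n_classifiers × n_classes) probabilities.

    Each class channel is aggregated independently and the argmax wins; ties
    go to the class with the larger mean raw score, then to the lower class
    index.  With ``positive_channel_only`` the class-1 channel alone is
    fused and thresholded at 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_classifiers, n_classes)")
    kwargs = {"h0": h0} if operator in GENERALIZED_OPERATORS else {}
    if positive_channel_only:
        fused = fuse_class_scores(scores[:, 1], densities, lam, operator, tnorm, **kwargs)
        return int(fused >= 0.5)
    fused = [
        fuse_class_scores(scores[:, c], densities, lam, operator, tnorm, **kwargs)
        for c in range(scores.shape[1])
    ]
    best = max(fused)
    winners = [c for c, v in enumerate(fused) if v == best]
    if len(winners) == 1:
        return winners[0]
    means = scores.mean(axis=0)
    best_mean = max(means[c] for c in winners)
    winners = [c for c in winners if means[c] == best_mean]
    return min(winners)


def run_experiment(
    config: ExperimentConfig, table: pd.DataFrame, label_col: str = "label"
) -> tuple[pd.DataFrame, list[RunRecord]]:
    """Run the repeated split → fit → densities → fuse grid experiment.

    Returns the accuracy grid (one row per (operator, t-norm, α) cell, with
    pooled micro accuracy and per-run macro accuracy) and the run records.
    The pooled count per cell is exactly ``n_repetitions × test size``.
    """
    cells = config.grid()
    rng = np.random.default_rng(config.seed)
    rep_seeds = rng.integers(2**31, size=config.n_repetitions)
    n_cells = len(cells)
    correct = np.zeros(n_cells, dtype=int)
    total = 0
    per_run_acc = np.zeros((config.n_repetitions, n_cells))
    records: list[RunRecord] = []
    individual_correct = np.zeros(len(config.classifiers), dtype=int)

    for r, rep_seed in enumerate(map(int, rep_seeds)):
        train, test = split_holdout(table, config.holdout_fraction, rep_seed, label_col)
        densities = estimate_densities(
            train, config.classifiers, config.cv_folds, rep_seed, label_col
        )
        lam = solve_lambda(densities)
        X_train = train.drop(columns=[label_col]).to_numpy()
        y_train = train[label_col].to_numpy()
        X_test = test.drop(columns=[label_col]).to_numpy()
        y_test = test[label_col].to_numpy()
        n_test = len(y_test)
        scores = np.empty((n_test, len(config.classifiers), 2))
        for ci, name in enumerate(config.classifiers):
            clf = make_classifier(name, rep_seed)
            clf.fit(X_train, y_train)
            proba = clf.predict_proba(X_test)
            order = np.argsort(clf.classes_)  # column for class 0 first
            scores[:, ci, :] = proba[:, order]
        individual_correct += (
            (scores.argmax(axis=2) == y_test[:, None]).sum(axis=0)
        )
        records.append(
            RunRecord(r, rep_seed, densities, scores, y_test,
                      (scores.argmax(axis=2) == y_test[:, None]).sum(axis=0))
        )
        for k, (op, tnorm) in enumerate(cells):
            preds = np.array(
                [
                    fuse_sample(
                        scores[s], densities, lam, op, tnorm,
                        h0=config.h0,
                        positive_channel_only=config.positive_channel_only,
                    )
                    for s in range(n_test)
                ]
            )
            n_ok = int((preds == y_test).sum())
            correct[k] += n_ok
            per_run_acc[r, k] = n_ok / n_test
        total += n_test

    rows = []
    for k, (op, tnorm) in enumerate(cells):
        rows.append(
            {
                "operator": op,
                "tnorm": None if tnorm is None else tnorm.name,
                "alpha": None if tnorm is None else tnorm.alpha,
                "accuracy": correct[k] / total,
                "macro_accuracy": per_run_acc[:, k].mean(),
                "n_correct": int(correct[k]),
                "n_total": total,
            }
        )
    grid = pd.DataFrame(rows)
    grid.attrs["individual_accuracy"] = {
        name: individual_correct[ci] / total
        for ci, name in enumerate(config.classifiers)
    }
    return grid, records


def summarize(grid: pd.DataFrame, top: Optional[int] = None) -> pd.DataFrame:
    """Accuracy table sorted best-first (stable, ties kept adjacent)."""
    if grid.empty:
        raise ValueError("empty accuracy grid")
    out = grid.sort_values("accuracy", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return out if top is None else out.head(top)
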