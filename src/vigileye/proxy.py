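"""Baseline drowsiness classifiers over the 24 ocular features.

A stand-in for the wider family of feature-based systems: one linear
max-margin classifier per timescale, trained on the 24-dimensional
multi-window ocular feature vector.  Features are min-max scaled to [0, 1]
on the training set (no clamping at test time), classes are weighted by
the reciprocal of their training counts, and the regularization strength C
is selected by an inner leave-one-subject-out cross-validation maximizing
balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

__all__ = ["ScalingModel", "ProxyModel", "fit_scaling", "fit_proxy", "predict_proxy", "DEFAULT_C_GRID"]

#: 13-point log-spaced grid over 1e-3 .. 1e3
DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class ScalingModel:
    """Per-feature training min/max; transform is the affine map to [0, 1].

    Constant features (max == min) map to 0.  Test-set values may fall
    outside [0, 1]: the map is linear, never clamped.
    """

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.max_ - self.min_
        safe = np.where(span > 0, span, 1.0)
        out = (np.asarray(X, dtype=float) - self.min_) / safe
        return np.where(span > 0, out, 0.0)


@dataclass
class ProxyModel:
    """Four fitted linear classifiers (one per timescale) plus their scaling."""

    classifiers: list[LinearSVC]
    chosen_C: list[float]
    scaling: ScalingModel
    class_weights: list[dict] = field(default_factory=list)


def fit_scaling(X_train: np.ndarray) -> ScalingModel:
    """Fit the per-feature min-max map on training features."""
    X = np.asarray(X_train, dtype=float)
    return ScalingModel(min_=X.min(axis=0), max_=X.max(axis=0))


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float) -> tuple[LinearSVC, dict]:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class; cannot fit a margin classifier")
    cw = {int(c): 1.0 / int(n) for c, n in zip(classes, counts)}
    clf = LinearSVC(C=C, class_weight=cw, max_iter=20000, tol=1e-4)
    clf.fit(X, y)
    return clf, cw


def fit_proxy(
    features: np.ndarray,
    p: np.ndarray,
    subjects: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> ProxyModel:
    """Fit the four per-timescale classifiers with inner leave-one-subject-out.

    ``features`` is (N, 24), ``p`` the (N, 4) target probabilities and
    ``subjects`` the (N,) subject ids of the training pool.  At each
    timescale, samples with ``p == 0.5`` are discarded; C maximizes the
    mean inner-fold balanced accuracy (one inner fold per training
    subject), and the final classifier is refit on all training subjects.
    """
    features = np.asarray(features, dtype=float)
    p = np.asarray(p, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need at least two training subjects for inner cross-validation")
    scaling = fit_scaling(features)
    Xs = scaling.transform(features)

    classifiers, chosen, weights = [], [], []
    for i in range(4):
        definite = np.isin(p[:, i], (0.0, 1.0))
        X_i, y_i, s_i = Xs[definite], p[definite, i].astype(int), subjects[definite]
        scores = []
        for C in C_grid:
            fold_scores = []
            for held in uniq:
                tr, te = s_i != held, s_i == held
                if not te.any() or np.unique(y_i[tr]).size < 2 or np.unique(y_i[te]).size < 1:
                    continue
                clf, _ = _fit_svc(X_i[tr], y_i[tr], C)
                fold_scores.append(balanced_accuracy_score(y_i[te], clf.predict(X_i[te])))
            scores.append(np.mean(fold_scores) if fold_scores else -np.inf)
        best_C = float(C_grid[int(np.argmax(scores))])
        clf, cw = _fit_svc(X_i, y_i, best_C)
        classifiers.append(clf)
        chosen.append(best_C)
        weights.append(cw)
    return ProxyModel(classifiers=classifiers, chosen_C=chosen, scaling=scaling, class_weights=weights)


def predict_proxy(model: ProxyModel, features: np.ndarray) -> np.ndarray:
    """Binary decisions (N, 4), one column per timescale."""
    Xs = model.scaling.transform(np.asarray(features, dtype=float))
    return np.stack([clf.predict(Xs) for clf in model.classifiers], axis=1).astype(int)
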