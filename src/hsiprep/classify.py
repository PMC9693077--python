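"""Pixel-wise probabilistic classification with a linear SVM.

One linear SVM per class (one-vs-rest, box constraint C=1 by default), with
a monotone sigmoid mapping from decision scores to [0, 1] probabilities
fitted on the training scores; per-pixel class probabilities are
renormalized to sum to one.  Hard labels come from a decision threshold on
the positive class (binary) or the argmax rule (multi-class default 0.5).
``optimize_threshold`` picks the operating point that balances sensitivity
against specificity.

Any object exposing ``fit(X, y)`` and ``predict_proba(X)`` can be plugged in
instead of the SVM (see :func:`train_classifier`'s ``model`` argument), so a
patch-based deep model can replace it without touching the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .hsio import ReflectanceCube

__all__ = [
    "ClassifierConfig",
    "PixelClassifier",
    "train_classifier",
    "predict_proba",
    "predict_proba_cube",
    "apply_threshold",
    "optimize_threshold",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear-SVM settings: kernel is fixed linear; ``box_constraint`` is the
    SVM cost C; ``class_prior`` controls the sigmoid calibration (empirical
    class frequencies or uniform); ``decision_threshold`` applies to the
    positive class in the binary case."""

    kernel: str = "linear"
    box_constraint: float = 1.0
    class_prior: str = "empirical"
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.class_prior not in ("empirical", "uniform"):
            raise ValueError("class_prior must be 'empirical' or 'uniform'")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must lie in [0, 1]")


class PixelClassifier:
    """One-vs-rest linear SVM with per-class sigmoid score calibration."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.classes_: np.ndarray | None = None
        self._svms: list[LinearSVC] = []
        self._calibrators: list[LogisticRegression] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PixelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if len(X) < len(self.classes_):
            raise ValueError("fewer samples than classes")
        cfg = self.config
        weight = "balanced" if cfg.class_prior == "uniform" else None
        self._svms, self._calibrators = [], []
        for cls in self.classes_:
            target = (y == cls).astype(int)
            svm = LinearSVC(
                C=cfg.box_constraint,
                class_weight=weight,
                random_state=cfg.seed,
                dual="auto",
                max_iter=10000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                svm.fit(X, target)
            scores = svm.decision_function(X).reshape(-1, 1)
            calib = LogisticRegression(C=1e6, class_weight=weight, max_iter=1000)
            calib.fit(scores, target)
            self._svms.append(svm)
            self._calibrators.append(calib)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([svm.decision_function(X) for svm in self._svms])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probabilities, renormalized to sum to 1 per sample."""
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        cols = []
        for svm, calib in zip(self._svms, self._calibrators):
            s = svm.decision_function(X).reshape(-1, 1)
            cols.append(calib.predict_proba(s)[:, 1])
        probs = np.column_stack(cols)
        total = probs.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return probs / total

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


def train_classifier(
    train, config: ClassifierConfig | None = None, model=None
) -> PixelClassifier:
    """Fit a pixel classifier on a (reduced) training set.

    ``train`` is a PixelDataset/ReducedSet (or a plain ``(X, y)`` pair).
    ``model`` may supply any plug-in exposing fit/predict_proba; the default
    is the linear SVM above.  Deterministic given ``config.seed``.
    """
    if isinstance(train, tuple):
        X, y = train
    else:
        X, y = train.spectra, train.labels
    clf = model if model is not None else PixelClassifier(config)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y))
    return clf


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    probs = model.predict_proba(np.asarray(X, dtype=float))
    return probs


def predict_proba_cube(model, cube: ReflectanceCube) -> np.ndarray:
    """Score every valid pixel of a cube.

    Returns an array of shape ``(rows, cols, n_classes)``; invalid (glare)
    pixels hold NaN — they are flagged, never scored.
    """
    n_features = model._svms[0].coef_.shape[1] if hasattr(model, "_svms") else None
    if n_features is not None and n_features != cube.n_bands:
        raise ValueError(
            f"model expects {n_features} bands, cube has {cube.n_bands}"
        )
    h, w, _ = cube.shape
    n_classes = len(model.classes_)
    out = np.full((h, w, n_classes), np.nan)
    rows, cols = np.nonzero(cube.valid_mask)
    if len(rows):
        out[rows, cols, :] = model.predict_proba(cube.values[rows, cols, :])
    return out


def apply_threshold(
    probs: np.ndarray,
    classes: np.ndarray,
    positive_class=None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Hard labels from per-class probabilities.

    Binary with an explicit ``positive_class``: positive iff its probability
    is >= ``threshold`` (closed rule: a tie with the threshold is positive).
    Otherwise: argmax over classes (the multi-class default-0.5 rule).
    """
    probs = np.asarray(probs, dtype=float)
    classes = np.asarray(classes)
    if positive_class is not None and len(classes) == 2:
        pos_col = int(np.nonzero(classes == positive_class)[0][0])
        neg = classes[1 - pos_col] if len(classes) == 2 else None
        return np.where(probs[..., pos_col] >= threshold, positive_class, neg)
    flat = probs.reshape(-1, probs.shape[-1])
    labels = classes[np.argmax(flat, axis=1)]
    return labels.reshape(probs.shape[:-1])


def optimize_threshold(probs: np.ndarray, truth: np.ndarray) -> float:
    """Threshold on positive-class probability balancing sensitivity and
    specificity.

    Candidates are midpoints between consecutive distinct sorted scores; the
    winner minimizes ``|sensitivity - specificity|``, ties broken by higher
    Youden J (= sens + spec - 1), then by lower threshold.  With fewer than
    two distinct scores the rule is degenerate (sens/spec are forced to
    {1,0}); the single score is returned with a warning.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present in the truth labels")
    distinct = np.unique(probs)
    if distinct.size < 2:
        warnings.warn("all scores identical: threshold choice is degenerate")
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = truth.sum(), (~truth).sum()
    best = None
    for t in candidates:
        pred = probs >= t
        sens = np.sum(pred & truth) / n_pos
        spec = np.sum(~pred & ~truth) / n_neg
        key = (abs(sens - spec), -(sens + spec - 1.0), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])
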