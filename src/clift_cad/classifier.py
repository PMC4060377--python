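"""Supervised cell classification and the one-well-out cross-validation harness.

The cell classifier is a scikit-learn compatible estimator wrapping
feature standardization and an RBF-kernel support vector machine whose free
parameters (regularization C and kernel width gamma) are chosen by an inner
stratified 5-fold grid search maximizing balanced accuracy — cell classes
are imbalanced, and class weights are set inversely proportional to class
frequency for the same reason. Ties in the grid resolve to the smallest C,
then the smallest gamma.

Evaluation uses one-well-out cross-validation: the cells of one well form
the test set and all other wells the training set, so cells of the same
serum never appear on both sides of a fold. Standardization statistics are
refit inside every fold from its training cells only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import N_FEATURES
from .io import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

C_GRID = (0.1, 1.0, 10.0, 100.0)
GAMMA_SCALE_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)  # divided by n_features


class CellClassifier(ClassifierMixin, BaseEstimator):
    """Max-margin cell classifier with automatic hyperparameter tuning.

    Parameters
    ----------
    C_grid, gamma_scale_grid : iterables of float
        Search grids; gamma values are ``gamma_scale / n_features``.
    n_inner_folds : int
        Folds of the inner stratified CV used for model selection.
    random_state : int
        Seeds the inner CV shuffling; fitting is deterministic given it.

    Attributes (after ``fit``)
    --------------------------
    best_params_ : dict with the selected ``C`` and ``gamma``.
    inner_cv_score_ : balanced accuracy of the selected point.
    zero_variance_mask_ : bool array flagging constant training features
        (their standardization scale is left at 1).
    """

    def __init__(
        self,
        C_grid=C_GRID,
        gamma_scale_grid=GAMMA_SCALE_GRID,
        n_inner_folds: int = 5,
        random_state: int = 0,
    ):
        self.C_grid = C_grid
        self.gamma_scale_grid = gamma_scale_grid
        self.n_inner_folds = n_inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_cells, n_features)")
        classes = set(np.unique(y).tolist())
        if classes != {POSITIVE, NEGATIVE}:
            raise ValueError(
                f"labels must be exactly {{{POSITIVE!r}, {NEGATIVE!r}}}, got {sorted(classes)}"
            )
        n_feat = X.shape[1]
        grid = {
            "svc__C": list(self.C_grid),
            "svc__gamma": [g / n_feat for g in self.gamma_scale_grid],
        }
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", class_weight="balanced")),
            ]
        )
        inner = StratifiedKFold(
            n_splits=self.n_inner_folds, shuffle=True, random_state=self.random_state
        )
        search = GridSearchCV(
            pipe, grid, scoring="balanced_accuracy", cv=inner, n_jobs=1, refit=True
        )
        # grid iteration order is C-major, gamma-minor: the first maximum is
        # the smallest C then the smallest gamma, the documented tie-break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y)
        self.search_ = search
        self.best_params_ = {
            "C": search.best_params_["svc__C"],
            "gamma": search.best_params_["svc__gamma"],
        }
        self.inner_cv_score_ = float(search.best_score_)
        scaler: StandardScaler = search.best_estimator_.named_steps["scale"]
        self.zero_variance_mask_ = scaler.var_ == 0.0
        if self.zero_variance_mask_.any():
            logger.info(
                "%d zero-variance training features (scale left at 1)",
                int(self.zero_variance_mask_.sum()),
            )
        self.classes_ = search.best_estimator_.named_steps["svc"].classes_
        self.n_features_in_ = n_feat
        return self

    def predict(self, X):
        if not hasattr(self, "search_"):
            raise NotFittedError("CellClassifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} features, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.asarray([], dtype=object)
        return self.search_.best_estimator_.predict(X)

    def decision_function(self, X):
        if not hasattr(self, "search_"):
            raise NotFittedError("CellClassifier is not fitted")
        return self.search_.best_estimator_.decision_function(np.asarray(X))


@dataclass
class TrainedModel:
    """A fitted classifier plus its training provenance."""

    classifier: CellClassifier
    feature_dim: int
    wells_used: list[str]
    seed: int
    class_counts: dict[str, int]
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] and X.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature vectors must have length {self.feature_dim}, got {X.shape[1]}"
            )
        return self.classifier.predict(X)

    def save(self, path) -> None:
        import joblib

        joblib.dump({"format_version": self.format_version, "model": self}, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        import joblib

        doc = joblib.load(path)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('format_version')}"
            )
        return doc["model"]


def train(X, y, wells, seed: int = 0) -> TrainedModel:
    """Train the cell classifier on labeled feature vectors.

    Requires at least 10 cells per class and cells from at least 2 wells.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    wells = np.asarray(wells)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError(f"training data contains a single class: {uniq.tolist()}")
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 cells per class, got {dict(zip(uniq.tolist(), counts.tolist()))}"
        )
    if len(np.unique(wells)) < 2:
        raise ValueError("training data must span at least 2 distinct wells")
    clf = CellClassifier(random_state=seed).fit(X, y)
    return TrainedModel(
        classifier=clf,
        feature_dim=X.shape[1],
        wells_used=sorted(np.unique(wells).tolist()),
        seed=seed,
        class_counts={lab: int(n) for lab, n in zip(uniq.tolist(), counts.tolist())},
    )


def predict(model: TrainedModel, X) -> list[str]:
    """Label feature vectors with the trained model; [] stays []."""
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        return []
    return list(model.predict(X))


@dataclass
class CVResult:
    """Per-fold predictions of one-well-out cross-validation."""

    y_true: np.ndarray
    y_pred: np.ndarray
    wells: np.ndarray
    fold_params: dict[str, dict]
    skipped_wells: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())

    def per_well(self) -> dict[str, float]:
        return {
            w: float((self.y_true[self.wells == w] == self.y_pred[self.wells == w]).mean())
            for w in np.unique(self.wells)
        }


def one_well_out_cv(X, y, wells, seed: int = 0) -> CVResult:
    """Leave-one-well-out CV: each fold tests the cells of one well.

    Every cell is predicted exactly once (folds partition the cells). A fold
    whose training set collapses to a single class is skipped with a warning
    and its well reported in ``skipped_wells``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    wells = np.asarray(wells)
    uniq_wells = np.unique(wells)
    if len(uniq_wells) < 3:
        raise ValueError("one-well-out CV requires at least 3 wells")
    y_pred = np.empty(len(y), dtype=object)
    fold_params: dict[str, dict] = {}
    skipped: list[str] = []
    kept = np.zeros(len(y), dtype=bool)
    for w in uniq_wells:
        test = wells == w
        tr = ~test
        if len(np.unique(y[tr])) < 2:
            logger.warning("fold %s skipped: single-class training set", w)
            skipped.append(str(w))
            continue
        clf = CellClassifier(random_state=seed).fit(X[tr], y[tr])
        y_pred[test] = clf.predict(X[test])
        fold_params[str(w)] = dict(clf.best_params_)
        kept |= test
    return CVResult(
        y_true=y[kept],
        y_pred=y_pred[kept].astype(y.dtype) if kept.any() else y_pred[kept],
        wells=wells[kept],
        fold_params=fold_params,
        skipped_wells=skipped,
    )
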