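"""Balanced splitting, cross-validation and the three shallow classifiers.

The benchmark compares a diagonal-covariance linear discriminant, a linear
one-vs-one support vector machine and a k=2 Euclidean nearest-neighbour
rule, trained intra-subject on a balanced 70/30 split with 5-fold
cross-validation on the training share. The KNN sees z-scored features
(scaler statistics learned on the training data only); the SVM and the
scale-free LDA operate on features in their native units, as the field's
common toolchains do by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .postprocess import DecisionStream

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("LDA", "SVM", "KNN")


class SplitError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Balanced train/test row split with per-class-balanced CV folds."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_assignment: np.ndarray  # 1..n_folds, aligned with train_indices
    seed: int
    n_folds: int = 5


def balanced_split(
    y, train_frac: float = 0.7, n_folds: int = 5, seed: int = 0
) -> SplitPlan:
    """Per-class 70/30 split plus balanced fold assignment, deterministic in seed."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx, folds = [], [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if len(idx) < n_folds + 1:
            raise SplitError(
                f"class {label!r} has only {len(idx)} windows; "
                f"needs at least {n_folds + 1}"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, n_folds), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
        folds.append(np.arange(n_train) % n_folds + 1)
    plan = SplitPlan(
        train_indices=np.concatenate(train_idx),
        test_indices=np.concatenate(test_idx),
        fold_assignment=np.concatenate(folds),
        seed=seed,
        n_folds=n_folds,
    )
    return plan


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Gaussian classifier with class means and a shared diagonal covariance.

    The pooled within-class variance is estimated per feature; a class is
    assigned by the maximal Gaussian log-density plus log prior. Zero
    variances are floored at ``var_floor`` with a warning.
    """

    def __init__(self, var_floor: float = 1e-12):
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        self.means_ = np.empty((k, p))
        pooled = np.zeros(p)
        self.priors_ = np.empty(k)
        for c in range(k):
            Xc = X[y_enc == c]
            self.means_[c] = Xc.mean(axis=0)
            pooled += ((Xc - self.means_[c]) ** 2).sum(axis=0)
            self.priors_[c] = len(Xc) / n
        var = pooled / max(n - k, 1)
        if np.any(var < self.var_floor):
            logger.warning(
                "flooring %d zero-variance features at %g",
                int((var < self.var_floor).sum()), self.var_floor,
            )
            var = np.maximum(var, self.var_floor)
        self.var_ = var
        return self

    def _log_density(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        # -(1/2) sum_j (x_j - mu_cj)^2 / var_j + log prior (constants dropped)
        d2 = ((X[:, None, :] - self.means_[None, :, :]) ** 2 / self.var_).sum(axis=2)
        return -0.5 * d2 + np.log(self.priors_)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_density(X), axis=1)]


class NearestTieBreakKNN(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour vote (Euclidean) with nearest-wins tie-breaking.

    With k=2 a 1-1 vote is frequent; ties among modal labels go to the
    label of the closest neighbour carrying a tied label, which is
    deterministic and favours local evidence.
    """

    def __init__(self, n_neighbors: int = 2):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        self._nn = KNeighborsClassifier(n_neighbors=self.n_neighbors)
        self._nn.fit(X, y)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        _, nbr_idx = self._nn.kneighbors(X)  # sorted by distance
        nbr_labels = self._y[nbr_idx]
        out = np.empty(len(nbr_labels), dtype=self._y.dtype)
        for i, row in enumerate(nbr_labels):
            labels, counts = np.unique(row, return_counts=True)
            tied = set(labels[counts == counts.max()].tolist())
            out[i] = next(lab for lab in row if lab in tied)
        return out


SVM_MAX_ITER = 10_000


def make_classifier(
    kind: str,
    C: float = 1.0,
    k: int = 2,
    standardize: bool | None = None,
    max_iter: int = SVM_MAX_ITER,
):
    """Estimator factory for the three benchmark classifiers.

    By default KNN sees z-scored features (Euclidean distance is
    meaningless across mixed physical units) while the SVM and LDA operate
    on the features in their native units: the diagonal LDA is per-feature
    scale-invariant, and the linear SVM is deliberately run the way the
    field's common toolchains run it — on raw feature values with a bounded
    solver budget (``max_iter`` per binary subproblem). ``standardize``
    overrides the per-kind default.
    """
    kind = kind.upper()
    if kind == "LDA":
        return DiagonalLDA()
    if kind == "SVM":
        est = SVC(
            kernel="linear", C=C, decision_function_shape="ovo", max_iter=max_iter
        )
        standardize = False if standardize is None else standardize
    elif kind == "KNN":
        est = NearestTieBreakKNN(n_neighbors=k)
        standardize = True if standardize is None else standardize
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _fit_quiet(est, X, y):
    """Fit, silencing the solver-budget warning the capped SVM emits."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


@dataclass
class TrainedModel:
    kind: str
    hyperparams: dict
    estimator: object
    schema: tuple[str, ...]

    def schema_hash(self) -> int:
        return hash(self.schema)


def _as_array(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def fit(kind: str, X_train, y_train, **hyperparams) -> TrainedModel:
    """Fit one classifier on (already feature-extracted) training windows."""
    Xa, schema = _as_array(X_train)
    y = np.asarray(y_train)
    if np.isnan(Xa).any():
        raise ValueError("training matrix contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    est = make_classifier(kind, **hyperparams)
    _fit_quiet(est, Xa, y)
    return TrainedModel(
        kind=kind.upper(), hyperparams=dict(hyperparams), estimator=est, schema=schema
    )


def cross_validate(kind: str, X_train, y_train, plan: SplitPlan, **hyperparams) -> list[float]:
    """Per-fold accuracies; the model is refit from scratch for every fold.

    ``X_train``/``y_train`` are the full matrices the plan indexes into.
    """
    Xa, _ = _as_array(X_train)
    y = np.asarray(y_train)
    accs = []
    for f in range(1, plan.n_folds + 1):
        hold = plan.train_indices[plan.fold_assignment == f]
        keep = plan.train_indices[plan.fold_assignment != f]
        est = make_classifier(kind, **hyperparams)
        _fit_quiet(est, Xa[keep], y[keep])
        accs.append(float(np.mean(est.predict(Xa[hold]) == y[hold])))
    return accs


def predict(
    model: TrainedModel,
    X_test,
    provenance: pd.DataFrame | None = None,
    update_period: float = 0.075,
) -> DecisionStream:
    """Predict a label per row, ordered by window time within each recording."""
    Xa, schema = _as_array(X_test)
    if isinstance(X_test, pd.DataFrame) and schema != model.schema:
        raise SchemaError("test column schema does not match training schema")
    if Xa.shape[1] != len(model.schema):
        raise SchemaError(
            f"expected {len(model.schema)} features, got {Xa.shape[1]}"
        )
    if len(Xa) == 0:
        return DecisionStream(
            votes=np.empty(0, dtype=int),
            update_period=update_period,
            provenance=provenance,
        )
    order = np.arange(len(Xa))
    if provenance is not None:
        order = np.lexsort(
            (provenance["window_start"].to_numpy(),
             provenance["recording_id"].to_numpy())
        )
        provenance = provenance.iloc[order].reset_index(drop=True)
        provenance["source_row"] = order  # lets callers realign y_true
    votes = model.estimator.predict(Xa[order])
    return DecisionStream(
        votes=votes, update_period=update_period, provenance=provenance
    )
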