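"""Feature-weighted kNN, an RBF-SVM adapter, and the evaluation protocol.

Evaluation follows the standard motor-imagery protocol: a stratified 80/20
holdout and stratified five-fold cross-validation, reporting accuracy,
sensitivity, specificity, precision, F1 and Cohen's kappa with per-fold
values, mean and standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import FeatureTable
from .selection import WeightVector

__all__ = [
    "FWKNN",
    "fwknn_fit_predict",
    "svm_rbf_fit_predict",
    "build_classifier",
    "EvalReport",
    "evaluate_holdout",
    "evaluate_cv",
]


class FWKNN(BaseEstimator, ClassifierMixin):
    """k-nearest neighbors with per-feature weights inside the distance.

    Distance between z-scored samples (train statistics) is
    ``d(a, b) = sqrt(sum_f w_f (a_f - b_f)^2)``.  Prediction is a majority
    vote over the ``k`` nearest training samples; vote ties are broken by
    the smaller summed distance, then by the lower class id.

    Parameters
    ----------
    k : int
        Neighborhood size (odd by default to avoid ties).
    weights : array-like or None
        Per-feature nonnegative weights; ``None`` means unweighted (all 1),
        reducing to plain kNN.
    """

    def __init__(self, k: int = 5, weights=None) -> None:
        self.k = k
        self.weights = weights

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds the training size {X.shape[0]}")
        self.classes_, self._y_enc = np.unique(y, return_inverse=True)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self._Z = (X - self._mu) / sd
        if self.weights is None:
            w = np.ones(X.shape[1])
        else:
            w = np.asarray(
                self.weights.weights
                if isinstance(self.weights, WeightVector)
                else self.weights,
                dtype=float,
            )
            if len(w) != X.shape[1]:
                raise ValueError("weights length must equal the feature count")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
        self._w = w
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_Z")
        X = np.asarray(X, dtype=float)
        Z = (X - self._mu) / self._sd
        # weighted squared Euclidean distances, all test x train at once
        d2 = (
            ((Z**2) * self._w).sum(axis=1)[:, None]
            + ((self._Z**2) * self._w).sum(axis=1)[None, :]
            - 2.0 * (Z * self._w) @ self._Z.T
        )
        d = np.sqrt(np.maximum(d2, 0.0))
        out = np.empty(len(X), dtype=self.classes_.dtype)
        n_cls = len(self.classes_)
        for i in range(len(X)):
            nn = np.argsort(d[i], kind="stable")[: self.k]
            votes = np.bincount(self._y_enc[nn], minlength=n_cls)
            top = votes.max()
            tied = np.nonzero(votes == top)[0]
            if len(tied) == 1:
                out[i] = self.classes_[tied[0]]
            else:
                sums = np.array(
                    [d[i][nn[self._y_enc[nn] == c]].sum() for c in tied]
                )
                out[i] = self.classes_[tied[int(np.argmin(sums))]]
        return out


def fwknn_fit_predict(
    train: FeatureTable, test_rows: np.ndarray, weights, k: int = 5
) -> np.ndarray:
    """Fit FWkNN on a labeled table and predict for raw test rows."""
    est = FWKNN(k=k, weights=weights).fit(train.values, train.labels)
    return est.predict(np.atleast_2d(test_rows))


def svm_rbf_fit_predict(
    train: FeatureTable,
    test_rows: np.ndarray,
    C: float = 1.0,
    gamma="scale",
) -> np.ndarray:
    """Thin adapter over an established RBF-kernel SVM implementation.

    ``gamma="scale"`` is ``1 / (n_features * var(X))``.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    est = SVC(C=C, gamma=gamma, kernel="rbf", random_state=0)
    est.fit(train.values, train.labels)
    return est.predict(np.atleast_2d(test_rows))


def build_classifier(kind: str = "svm_rbf", **params):
    """Factory: ``"fwknn"`` or ``"svm_rbf"`` -> unfitted estimator."""
    if kind == "fwknn":
        return FWKNN(**params)
    if kind == "svm_rbf":
        params.setdefault("kernel", "rbf")
        params.setdefault("random_state", 0)
        return SVC(**params)
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class EvalReport:
    """Classification metrics (rates in [0, 1]) with per-fold breakdown."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    confusion: np.ndarray
    per_fold: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    positive_class: object = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "kappa": self.kappa,
            "confusion": np.asarray(self.confusion).tolist(),
            "per_fold": {k: list(map(float, v)) for k, v in self.per_fold.items()},
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "positive_class": str(self.positive_class),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _binary_metrics(y_true, y_pred, classes, positive) -> dict:
    """Metric suite from the confusion matrix; kappa = (po - pe)/(1 - pe)."""
    classes = np.asarray(classes)
    if positive is None:
        positive = classes[-1]
    idx = {c: i for i, c in enumerate(classes)}
    n_cls = len(classes)
    cm = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    acc = float(np.trace(cm) / n)
    po = acc
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum() / n**2)
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    pi = idx[positive]
    tp = cm[pi, pi]
    fn = cm[pi].sum() - tp
    fp = cm[:, pi].sum() - tp
    tn = n - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": acc,
        "sensitivity": float(sens),
        "specificity": float(spec),
        "precision": float(prec),
        "f1": float(f1),
        "kappa": float(kappa),
        "confusion": cm,
        "positive": positive,
    }


def evaluate_holdout(
    table: FeatureTable,
    estimator,
    split: float = 0.8,
    seed: int = 0,
    positive=None,
) -> EvalReport:
    """Stratified holdout evaluation (default 80% train / 20% test)."""
    X, y = table.values, table.labels
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )
    est = clone(estimator).fit(X_tr, y_tr)
    y_hat = est.predict(X_te)
    m = _binary_metrics(y_te, y_hat, np.unique(y), positive)
    return EvalReport(
        m["accuracy"], m["sensitivity"], m["specificity"], m["precision"],
        m["f1"], m["kappa"], m["confusion"], positive_class=m["positive"],
    )


def evaluate_cv(
    table: FeatureTable,
    estimator,
    folds: int = 5,
    seed: int = 0,
    positive=None,
) -> EvalReport:
    """Stratified k-fold cross-validation with per-fold metric breakdown.

    Folds are disjoint and exhaustive with sizes differing by at most one;
    the report's top-level rates are computed on the pooled out-of-fold
    predictions, while ``per_fold`` / ``mean`` / ``sd`` carry the per-fold
    statistics (SD is the population SD of the per-fold values).
    """
    X, y = table.values, table.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    metric_names = ("accuracy", "sensitivity", "specificity", "precision",
                    "f1", "kappa")
    per_fold: dict[str, list[float]] = {k: [] for k in metric_names}
    classes = np.unique(y)
    pooled_true, pooled_pred = [], []
    for tr, te in skf.split(X, y):
        est = clone(estimator).fit(X[tr], y[tr])
        y_hat = est.predict(X[te])
        m = _binary_metrics(y[te], y_hat, classes, positive)
        for k in metric_names:
            per_fold[k].append(m[k])
        pooled_true.extend(y[te])
        pooled_pred.extend(y_hat)
    pooled = _binary_metrics(np.asarray(pooled_true), np.asarray(pooled_pred),
                             classes, positive)
    mean = {k: float(np.mean(v)) for k, v in per_fold.items()}
    sd = {k: float(np.std(v)) for k, v in per_fold.items()}
    return EvalReport(
        pooled["accuracy"], pooled["sensitivity"], pooled["specificity"],
        pooled["precision"], pooled["f1"], pooled["kappa"],
        pooled["confusion"], per_fold, mean, sd, pooled["positive"],
    )
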