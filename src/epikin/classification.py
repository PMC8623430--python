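"""KNN and SVM classifiers for before/after-surgery heart motion.

Both models consume the 14 unstandardized frequency-domain predictors
and are sklearn-style estimators (``fit`` / ``predict`` /
``decision_score``, clonable via ``get_params``), so they compose with
the optimization and evaluation helpers below:

* :func:`grouped_kfold` — seed-deterministic folds partitioning
  *patients* (never recordings), so no patient leaks between training
  and validation;
* :func:`cv_error` — pooled cross-validated misclassification rate;
* :func:`optimize` — seeded random search (default 100 iterations)
  minimizing the cross-validated error, with a full per-iteration trace;
* :func:`evaluate` — pooled cross-validated confusion matrix, per-class
  TPR/FNR, ROC points and trapezoidal AUC.

Class conventions: labels are ``{"unhealthy", "healthy"}``; "unhealthy"
(before surgery) is reported first, and every tie (equal vote, zero
decision value) resolves to "unhealthy" — a clinically conservative
default that prefers a false alarm over a missed risk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .errors import ConvergenceError
from .recording import CLASS_LABELS

__all__ = [
    "KnnVideoClassifier",
    "SvmVideoClassifier",
    "EvaluationReport",
    "OptimizationTrace",
    "grouped_kfold",
    "cv_error",
    "optimize",
    "evaluate",
    "report_from_predictions",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]

#: Row order of confusion matrices and report dictionaries.
CLASS_ORDER = ("unhealthy", "healthy")
POSITIVE_SCORE_CLASS = "healthy"  # decision scores grow toward "healthy"

KNN_METRICS = ("euclidean", "cityblock", "chebyshev", "minkowski")
KNN_WEIGHTINGS = ("equal", "inverse", "squared_inverse")


def _validate_xy(X, y, require_both_classes=True):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2:
        raise ValueError("X must be a 2D feature matrix")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite values")
    bad = set(map(str, np.unique(y))) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")
    if require_both_classes and len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    return X, np.asarray([str(v) for v in y], dtype=object)


class KnnVideoClassifier(ClassifierMixin, BaseEstimator):
    """Weighted-vote k-nearest-neighbor classifier on unstandardized features.

    Parameters
    ----------
    n_neighbors : int
        Number of neighbors k (>= 1, <= training rows).
    metric : {"euclidean", "cityblock", "chebyshev", "minkowski"}
        Distance metric; "minkowski" uses exponent ``p``.
    p : float
        Minkowski exponent (>= 1); ignored by the named metrics.
    weighting : {"equal", "inverse", "squared_inverse"}
        Neighbor vote weight: 1, 1/d or 1/d^2.

    Notes
    -----
    Distance ties are broken toward the lowest training-row index
    (stable sort); tied votes resolve to "unhealthy".  A query that
    coincides with training rows (zero distance) is decided by those
    rows alone.  The decision score is the weighted vote fraction for
    "healthy", in [0, 1].
    """

    def __init__(self, n_neighbors: int = 1, metric: str = "euclidean", p: float = 2.0,
                 weighting: str = "squared_inverse"):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.p = p
        self.weighting = weighting

    def fit(self, X, y):
        if self.metric not in KNN_METRICS:
            raise ValueError(f"metric must be one of {KNN_METRICS}")
        if self.weighting not in KNN_WEIGHTINGS:
            raise ValueError(f"weighting must be one of {KNN_WEIGHTINGS}")
        if self.metric == "minkowski" and not self.p >= 1:
            raise ValueError("minkowski exponent p must be >= 1")
        X, y = _validate_xy(X, y, require_both_classes=False)
        if not 1 <= self.n_neighbors <= X.shape[0]:
            raise ValueError("n_neighbors must be in [1, n training rows]")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"query must have {self.n_features_in_} features")
        if self.metric == "minkowski":
            return cdist(X, self.X_, metric="minkowski", p=self.p)
        return cdist(X, self.X_, metric=self.metric)

    def decision_score(self, X) -> np.ndarray:
        """Weighted "healthy" vote fraction per query row, in [0, 1]."""
        dist = self._distances(X)
        k = self.n_neighbors
        scores = np.empty(dist.shape[0])
        for i, d in enumerate(dist):
            order = np.argsort(d, kind="stable")[:k]
            dk = d[order]
            if self.weighting == "equal":
                w = np.ones(k)
            elif (dk == 0).any():
                # coincident training rows carry all the weight
                w = (dk == 0).astype(float)
            elif self.weighting == "inverse":
                w = 1.0 / dk
            else:
                w = 1.0 / dk**2
            healthy = self.y_[order] == "healthy"
            scores[i] = float(w[healthy].sum() / w.sum())
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_score(X)
        # score == 0.5 is a tied vote -> unhealthy
        return np.where(scores > 0.5, "healthy", "unhealthy").astype(object)


class SvmVideoClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin Gaussian-kernel SVM on unstandardized features.

    The kernel is K(u, v) = exp(-||u - v||^2 / kernel_scale^2) and the
    box constraint C bounds every dual coefficient.  The decision score
    is the signed decision value (positive => "healthy"); a value of
    exactly 0 resolves to "unhealthy".

    The dual problem is solved by libsvm (via scikit-learn) with
    convergence tolerance ``tol`` (default 1e-6) and an iteration cap
    ``max_iter`` (default 1e6); hitting the cap raises
    :class:`~epikin.errors.ConvergenceError`.  The fitted decision
    function is kept as explicit support rows / dual coefficients /
    bias, so serialized models evaluate without refitting.
    """

    def __init__(self, C: float = 1.0, kernel_scale: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 1_000_000):
        self.C = C
        self.kernel_scale = kernel_scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError("box constraint C must be finite and > 0")
        if not (np.isfinite(self.kernel_scale) and self.kernel_scale > 0):
            raise ValueError("kernel_scale must be finite and > 0")
        X, y = _validate_xy(X, y)
        y_bin = (y == "healthy").astype(int)  # healthy = +1 side
        svc = SVC(C=self.C, kernel="rbf", gamma=1.0 / self.kernel_scale**2,
                  tol=self.tol, max_iter=self.max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            svc.fit(X, y_bin)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ConvergenceError(
                f"SVM solver hit the iteration cap ({self.max_iter}) "
                f"at C={self.C:g}, kernel_scale={self.kernel_scale:g}, tol={self.tol:g}"
            )
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_score(self, X) -> np.ndarray:
        """Signed decision value; positive means "healthy"."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"query must have {self.n_features_in_} features")
        sq = cdist(X, self.support_vectors_, metric="sqeuclidean")
        kernel = np.exp(-sq / self.kernel_scale**2)
        return kernel @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_score(X) > 0, "healthy", "unhealthy").astype(object)


# ---------------------------------------------------------------------------
# Cross-validation, optimization, evaluation
# ---------------------------------------------------------------------------

def grouped_kfold(patient_ids, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign a fold index to every recording, partitioning patients.

    Patients (not recordings) are shuffled with ``seed`` and split into
    ``k`` folds whose sizes differ by at most one patient; all of a
    patient's recordings share a fold.
    """
    patient_ids = np.asarray(patient_ids)
    unique = pd.unique(patient_ids)
    if unique.size < k:
        raise ValueError(f"need at least k={k} distinct patients, got {unique.size}")
    rng = np.random.default_rng(seed)
    shuffled = unique[rng.permutation(unique.size)]
    fold_of = {}
    for fold, chunk in enumerate(np.array_split(shuffled, k)):
        for patient in chunk:
            fold_of[patient] = fold
    return np.asarray([fold_of[p] for p in patient_ids], dtype=int)


def _cv_predictions(estimator, X, y, patient_ids, k, seed):
    """Pooled out-of-fold predictions and scores."""
    X, y = _validate_xy(X, y)
    folds = grouped_kfold(patient_ids, k=k, seed=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    for fold in range(k):
        test = folds == fold
        if not test.any():
            continue
        model = clone(estimator).fit(X[~test], y[~test])
        y_pred[test] = model.predict(X[test])
        scores[test] = model.decision_score(X[test])
    return y, y_pred, scores


def cv_error(estimator, X, y, patient_ids, k: int = 10, seed: int = 0) -> float:
    """Patient-grouped k-fold cross-validated classification error.

    Misclassified recordings over total recordings, pooled across folds.
    """
    y_true, y_pred, _ = _cv_predictions(estimator, X, y, patient_ids, k, seed)
    return float(np.mean(y_true != y_pred))


@dataclass
class OptimizationTrace:
    """Per-iteration record of a hyperparameter search."""

    records: list[dict] = field(default_factory=list)

    def append(self, iteration: int, params: dict, error: float) -> None:
        best = min(error, self.records[-1]["best_so_far"]) if self.records else error
        self.records.append(
            {"iteration": iteration, "params": dict(params), "cv_error": error, "best_so_far": best}
        )

    @property
    def best_index(self) -> int:
        errors = [r["cv_error"] for r in self.records]
        return int(np.argmin(errors))  # first minimum wins

    @property
    def best_params(self) -> dict:
        return dict(self.records[self.best_index]["params"])

    @property
    def best_error(self) -> float:
        return float(self.records[self.best_index]["cv_error"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _sample_knn_params(rng: np.random.Generator, n_rows: int) -> dict:
    k_max = min(20, n_rows)
    k = int(round(np.exp(rng.uniform(0.0, np.log(k_max)))))
    params = {
        "n_neighbors": int(np.clip(k, 1, k_max)),
        "metric": str(rng.choice(KNN_METRICS)),
        "weighting": str(rng.choice(KNN_WEIGHTINGS)),
    }
    if params["metric"] == "minkowski":
        params["p"] = float(np.exp(rng.uniform(0.0, np.log(10.0))))
    return params


def _sample_svm_params(rng: np.random.Generator) -> dict:
    return {
        "C": float(np.exp(rng.uniform(np.log(1e-3), np.log(1e3)))),
        "kernel_scale": float(np.exp(rng.uniform(np.log(1e-3), np.log(1e3)))),
    }


def optimize(
    family: str,
    X,
    y,
    patient_ids,
    n_iter: int = 100,
    k: int = 10,
    seed: int = 0,
    candidates: list[dict] | None = None,
):
    """Random-search hyperparameter optimization by cross-validated error.

    Parameters
    ----------
    family : {"knn", "svm"}
        Model family to optimize.
    candidates : list of dict, optional
        Explicit candidate parameter sets; when given, they are cycled
        instead of sampling the default search space (KNN: k in {1..20}
        log-uniform, all four metrics, three weightings; SVM: C and
        kernel scale log-uniform in [1e-3, 1e3]).

    Returns
    -------
    (estimator, OptimizationTrace)
        An unfitted estimator carrying the best-point hyperparameters
        (minimum cross-validated error; first minimum on ties) and the
        full iteration trace.
    """
    if family not in ("knn", "svm"):
        raise ValueError("family must be 'knn' or 'svm'")
    X = np.asarray(X, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    trace = OptimizationTrace()
    n_train_min = X.shape[0] - int(np.ceil(X.shape[0] / k))  # smallest training split
    for it in range(n_iter):
        if candidates is not None:
            params = dict(candidates[it % len(candidates)])
        elif family == "knn":
            params = _sample_knn_params(rng, max(1, n_train_min))
        else:
            params = _sample_svm_params(rng)
        est = KnnVideoClassifier(**params) if family == "knn" else SvmVideoClassifier(**params)
        try:
            err = cv_error(est, X, y, patient_ids, k=k, seed=seed)
        except ConvergenceError:
            err = 1.0  # non-converging candidate is never the best point
        trace.append(it, params, err)
    best = KnnVideoClassifier(**trace.best_params) if family == "knn" else SvmVideoClassifier(**trace.best_params)
    return best, trace


@dataclass
class EvaluationReport:
    """Cross-validated classifier performance summary.

    ``confusion`` rows are true classes and columns predicted classes,
    both in :data:`CLASS_ORDER` (unhealthy first); TPR/FNR are per true
    class; ROC points sweep the pooled "healthy" scores and ``auc`` is
    their trapezoidal area.
    """

    confusion: np.ndarray
    class_order: tuple[str, str]
    tpr: dict[str, float]
    fnr: dict[str, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "tpr": self.tpr,
            "fnr": self.fnr,
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
            "auc": self.auc,
        }


def report_from_predictions(y_true, y_pred, scores) -> EvaluationReport:
    """Confusion matrix, per-class rates and ROC/AUC from pooled predictions."""
    y_true = np.asarray([str(v) for v in y_true], dtype=object)
    y_pred = np.asarray([str(v) for v in y_pred], dtype=object)
    scores = np.asarray(scores, dtype=float)
    for cls in CLASS_ORDER:
        if not (y_true == cls).any():
            raise ValueError(f"class {cls!r} is absent from the true labels")
    confusion = np.zeros((2, 2), dtype=int)
    for i, true_cls in enumerate(CLASS_ORDER):
        for j, pred_cls in enumerate(CLASS_ORDER):
            confusion[i, j] = int(np.sum((y_true == true_cls) & (y_pred == pred_cls)))
    tpr = {cls: float(confusion[i, i] / confusion[i].sum()) for i, cls in enumerate(CLASS_ORDER)}
    fnr = {cls: 1.0 - tpr[cls] for cls in CLASS_ORDER}
    fpr_pts, tpr_pts, _ = roc_curve(y_true == POSITIVE_SCORE_CLASS, scores)
    return EvaluationReport(
        confusion=confusion,
        class_order=CLASS_ORDER,
        tpr=tpr,
        fnr=fnr,
        roc_fpr=fpr_pts,
        roc_tpr=tpr_pts,
        auc=float(_trapezoid_auc(fpr_pts, tpr_pts)),
    )


def evaluate(estimator, X, y, patient_ids, k: int = 10, seed: int = 0) -> EvaluationReport:
    """Cross-validated evaluation of a model specification.

    The estimator's hyperparameters are refit per fold; confusion counts
    and ROC scores are pooled over the out-of-fold predictions.
    """
    y_true, y_pred, scores = _cv_predictions(estimator, X, y, patient_ids, k, seed)
    return report_from_predictions(y_true, y_pred, scores)


# ---------------------------------------------------------------------------
# Model serialization (JSON)
# ---------------------------------------------------------------------------

def model_to_json(model) -> dict:
    """Serialize a fitted model to a JSON-compatible dict."""
    if isinstance(model, KnnVideoClassifier):
        return {
            "family": "knn",
            "params": model.get_params(),
            "training_X": model.X_.tolist(),
            "training_y": model.y_.tolist(),
        }
    if isinstance(model, SvmVideoClassifier):
        return {
            "family": "svm",
            "params": model.get_params(),
            "support_vectors": model.support_vectors_.tolist(),
            "dual_coef": model.dual_coef_.tolist(),
            "intercept": model.intercept_,
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def model_from_json(payload: dict):
    """Rebuild a fitted model from :func:`model_to_json` output."""
    family = payload.get("family")
    if family == "knn":
        model = KnnVideoClassifier(**payload["params"])
        return model.fit(np.asarray(payload["training_X"], dtype=float),
                         np.asarray(payload["training_y"], dtype=object))
    if family == "svm":
        model = SvmVideoClassifier(**payload["params"])
        model.support_vectors_ = np.asarray(payload["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(payload["dual_coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.classes_ = np.asarray(CLASS_ORDER, dtype=object)
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model
    raise ValueError(f"unknown model family {family!r}")


def save_model(model, path) -> None:
    Path(path).write_text(json.dumps(model_to_json(model)))


def load_model(path):
    return model_from_json(json.loads(Path(path).read_text()))
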