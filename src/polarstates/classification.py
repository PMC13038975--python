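"""Single-trial classification of microstate label sequences.

Features are the per-trial integer label sequences over an analysis window
grid (ordinal coding, exactly as the sequences are written). Six model
families are supported — SVM, Random Forest, Logistic Regression, XGBoost
and LightGBM gradient boosting, plus an unsupervised K-means baseline — each
evaluated with nested five-fold cross-validation: an outer trial-level split
for scoring and an inner five-fold grid search maximizing F1 for
hyperparameter selection. "target" is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data_model import SENTINEL, LabelSequence

__all__ = [
    "ConfusionCounts",
    "CvSpec",
    "ModelSpec",
    "ClassifResult",
    "SUPERVISED_FAMILIES",
    "DEFAULT_GRIDS",
    "f1_score",
    "auc_score",
    "confusion_counts",
    "features_from_sequence",
    "nested_cv_classify",
    "temporal_generalization",
    "compare_conditions",
]

POSITIVE_CLASS = "target"

SUPERVISED_FAMILIES = (
    "svm",
    "random_forest",
    "logistic_regression",
    "gradient_boosting_xgb",
    "gradient_boosting_lgbm",
)

# The SVM grid follows the published search space; the other families use
# modest reproducible defaults, overridable through ModelSpec.grid.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {
        "C": [0.01, 0.1, 1, 10, 100],
        "kernel": ["linear", "rbf", "sigmoid"],
        "gamma": ["scale", "auto", 1],
    },
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [3, 6, None],
    },
    "logistic_regression": {
        "C": [0.01, 0.1, 1, 10],
    },
    "gradient_boosting_xgb": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 6],
    },
    "gradient_boosting_lgbm": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 6],
    },
    "kmeans_baseline": {},
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "target" as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class CvSpec:
    """Nested cross-validation layout (outer scoring, inner grid search)."""

    n_outer_folds: int = 5
    n_inner_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be at least 2")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameter search grid."""

    family: str
    grid: dict[str, list] | None = None

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])
        if self.family != "kmeans_baseline" and not self.grid:
            raise ValueError("supervised families need a nonempty grid")


@dataclass
class ClassifResult:
    """Nested-CV outcome: per-fold F1, pooled AUC, out-of-fold predictions."""

    fold_f1: list[float]
    mean_f1: float
    auc: float
    fold_auc: list[float]
    best_params: list[dict]
    oof_pred: np.ndarray             # predicted class string per trial
    oof_score: np.ndarray            # continuous score per trial (higher = target)
    fold_of_trial: np.ndarray


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of precision and recall.

    Defined as 0 when the denominator vanishes (no positive predictions and
    no positive truths).
    """
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        import warnings

        warnings.warn("F1 undefined (no positives anywhere); returning 0", stacklevel=2)
        return 0.0
    return 2 * c.TP / denom


def confusion_counts(truth: np.ndarray, pred: np.ndarray,
                     positive: str = POSITIVE_CLASS) -> ConfusionCounts:
    t = np.asarray(truth).astype(str) == positive
    p = np.asarray(pred).astype(str) == positive
    return ConfusionCounts(
        TP=int(np.sum(t & p)), FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)), FN=int(np.sum(t & ~p)),
    )


def auc_score(scores: np.ndarray, truth: np.ndarray,
              positive: str = POSITIVE_CLASS) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted 0.5)."""
    y = np.asarray(truth).astype(str) == positive
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y.astype(int), np.asarray(scores, dtype=float)))


class SentinelImputer(TransformerMixin, BaseEstimator):
    """Replace sentinel labels by the per-window modal training label."""

    def __init__(self, sentinel: int = SENTINEL):
        self.sentinel = sentinel

    def fit(self, X, y=None):
        X = np.asarray(X)
        modes = np.zeros(X.shape[1], dtype=X.dtype)
        for j in range(X.shape[1]):
            col = X[:, j][X[:, j] != self.sentinel]
            if col.size:
                vals, counts = np.unique(col, return_counts=True)
                modes[j] = vals[np.argmax(counts)]
        self.modes_ = modes
        return self

    def transform(self, X):
        X = np.asarray(X).copy()
        mask = X == self.sentinel
        if mask.any():
            X[mask] = np.broadcast_to(self.modes_, X.shape)[mask]
        return X


class KMeansBaseline(ClassifierMixin, BaseEstimator):
    """Unsupervised baseline: 2-means on training features, clusters mapped
    to their majority training class, prediction by nearest centroid.

    The continuous score is the signed difference of centroid distances
    (distance to the negative-mapped centroid minus distance to the
    positive-mapped one), so higher means more target-like.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        km = KMeans(n_clusters=2, n_init=10, random_state=self.random_state)
        assign = km.fit_predict(X)
        self.centroids_ = km.cluster_centers_
        self.cluster_class_ = np.empty(2, dtype=int)
        for c in range(2):
            members = y[assign == c]
            if members.size:
                vals, counts = np.unique(members, return_counts=True)
                self.cluster_class_[c] = int(vals[np.argmax(counts)])
            else:
                self.cluster_class_[c] = c
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None], axis=2)
        if self.cluster_class_[0] == self.cluster_class_[1]:
            return np.zeros(X.shape[0])
        pos = int(np.nonzero(self.cluster_class_ == 1)[0][0])
        return d[:, 1 - pos] - d[:, pos]

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None], axis=2)
        return self.cluster_class_[np.argmin(d, axis=1)]


def _base_estimator(family: str, seed: int):
    if family == "svm":
        return SVC(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "gradient_boosting_xgb":
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                             verbosity=0)
    if family == "gradient_boosting_lgbm":
        # min_child_samples eased for trial-level EEG datasets, where a
        # training fold often holds only a few dozen trials per class
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              min_child_samples=5)
    if family == "kmeans_baseline":
        return KMeansBaseline(random_state=seed)
    raise ValueError(f"unknown model family {family!r}")


def features_from_sequence(
    seq: LabelSequence, t_start: float | None = None, t_end: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (trials x windows of integer labels) and 0/1 targets.

    Optionally restricts to windows starting in ``[t_start, t_end)``.
    """
    cols = np.ones(seq.n_windows, dtype=bool)
    if t_start is not None:
        cols &= seq.window_starts >= t_start - 1e-9
    if t_end is not None:
        cols &= seq.window_starts < t_end - 1e-9
    X = seq.labels[:, cols].astype(float)
    y = (seq.classes.astype(str) == POSITIVE_CLASS).astype(int)
    return X, y


def _scores_from(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def _outer_splitter(cv: CvSpec):
    cls = StratifiedKFold if cv.stratified else KFold
    return cls(n_splits=cv.n_outer_folds, shuffle=True, random_state=cv.seed)


def _fit_fold_model(model: ModelSpec, cv: CvSpec, X_tr, y_tr):
    """Inner grid search on the outer-training data; returns (fitted, params)."""
    pipe = Pipeline([
        ("impute", SentinelImputer()),
        ("clf", _base_estimator(model.family, cv.seed)),
    ])
    if model.family == "kmeans_baseline" or not model.grid:
        pipe.fit(X_tr, y_tr)
        return pipe, {}
    inner_cls = StratifiedKFold if cv.stratified else KFold
    inner = inner_cls(n_splits=cv.n_inner_folds, shuffle=True,
                      random_state=cv.seed + 1)
    grid = {f"clf__{k}": v for k, v in model.grid.items()}
    search = GridSearchCV(pipe, grid, scoring="f1", cv=inner, refit=True, n_jobs=1)
    search.fit(X_tr, y_tr)
    params = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return search.best_estimator_, params


def nested_cv_classify(
    seq: LabelSequence,
    model: ModelSpec,
    cv: CvSpec = CvSpec(),
    t_start: float | None = None,
    t_end: float | None = None,
) -> ClassifResult:
    """Nested five-fold cross-validated classification of a label sequence.

    The outer split scores held-out trials (each trial is in exactly one
    outer test fold); hyperparameters are chosen per outer fold by an inner
    grid search maximizing F1, then the best model is refit on the whole
    outer-training set. Returns per-fold F1, pooled out-of-fold AUC, and the
    out-of-fold predictions and scores.
    """
    X, y = features_from_sequence(seq, t_start, t_end)
    if len(np.unique(y)) < 2:
        raise ValueError("both stimulus classes must be present")
    counts = np.bincount(y)
    if counts[0] != counts[1]:
        import warnings

        warnings.warn(
            f"classes are unbalanced ({counts[0]} vs {counts[1]}); "
            "consider balance_trials first", stacklevel=2,
        )

    n = len(y)
    oof_pred = np.empty(n, dtype=object)
    oof_score = np.full(n, np.nan)
    fold_of_trial = np.full(n, -1, dtype=int)
    fold_f1, fold_auc, best_params = [], [], []
    for fold, (tr, te) in enumerate(_outer_splitter(cv).split(X, y)):
        est, params = _fit_fold_model(model, cv, X[tr], y[tr])
        best_params.append(params)
        pred = np.asarray(est.predict(X[te])).astype(int)
        score = _scores_from(est, X[te])
        truth = np.where(y[te] == 1, POSITIVE_CLASS, "standard")
        pred_s = np.where(pred == 1, POSITIVE_CLASS, "standard")
        fold_f1.append(f1_score(confusion_counts(truth, pred_s)))
        fold_auc.append(
            auc_score(score, truth) if len(np.unique(y[te])) == 2 else float("nan")
        )
        oof_pred[te] = pred_s
        oof_score[te] = score
        fold_of_trial[te] = fold

    truth_all = np.where(y == 1, POSITIVE_CLASS, "standard")
    return ClassifResult(
        fold_f1=fold_f1,
        mean_f1=float(np.mean(fold_f1)),
        auc=auc_score(oof_score, truth_all),
        fold_auc=fold_auc,
        best_params=best_params,
        oof_pred=oof_pred,
        oof_score=oof_score,
        fold_of_trial=fold_of_trial,
    )


def temporal_generalization(
    seq: LabelSequence,
    model: ModelSpec = ModelSpec("svm"),
    cv: CvSpec = CvSpec(),
    search: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal generalization matrix of mean F1 scores.

    For every interior window t, a model is trained on the three-window
    feature (t-1, t, t+1) of the outer-training trials and tested at every
    interior position t' using (t'-1, t', t'+1); F1 is averaged over the
    outer folds. Boundary windows are excluded, so the matrix is
    (n_windows - 2) squared. With ``search=False`` the first grid value of
    each hyperparameter is used without an inner search.

    Returns ``(matrix, window_starts_of_interior_windows)``.
    """
    if seq.n_windows < 3:
        raise ValueError("temporal generalization needs at least 3 windows")
    X_all, y = features_from_sequence(seq)
    if len(np.unique(y)) < 2:
        raise ValueError("both stimulus classes must be present")
    interior = np.arange(1, seq.n_windows - 1)
    m = len(interior)
    spec = model if search else ModelSpec(
        model.family, {k: [v[0]] for k, v in model.grid.items()} or None
    )
    mat = np.zeros((m, m))
    splits = list(_outer_splitter(cv).split(X_all, y))
    for a, t_tr in enumerate(interior):
        cols_tr = [t_tr - 1, t_tr, t_tr + 1]
        for tr, te in splits:
            est, _ = _fit_fold_model(spec, cv, X_all[np.ix_(tr, cols_tr)], y[tr])
            truth = np.where(y[te] == 1, POSITIVE_CLASS, "standard")
            for b, t_te in enumerate(interior):
                cols_te = [t_te - 1, t_te, t_te + 1]
                pred = np.asarray(est.predict(X_all[np.ix_(te, cols_te)])).astype(int)
                pred_s = np.where(pred == 1, POSITIVE_CLASS, "standard")
                mat[a, b] += f1_score(confusion_counts(truth, pred_s))
    mat /= len(splits)
    return mat, seq.window_starts[interior]


def compare_conditions(
    results: dict[tuple[str, str, str], ClassifResult]
) -> pd.DataFrame:
    """Tidy long-format score table over (variant, polarity, model) runs.

    One row per outer fold with its F1 and the run's pooled AUC — ready for
    external ANOVA software or a quick pivot summary.
    """
    rows = []
    for (variant, polarity, model), res in results.items():
        for fold, f1 in enumerate(res.fold_f1):
            rows.append({
                "variant": variant, "polarity": polarity, "model": model,
                "fold": fold, "f1": f1, "auc": res.auc,
            })
    if not rows:
        raise ValueError("no completed runs to compare")
    return pd.DataFrame(rows)
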