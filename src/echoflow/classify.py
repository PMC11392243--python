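"""Multi-view feature fusion and the cross-validated classifier bank.

The per-view 1024-d motion features are concatenated (A2C block first) into
one 2048-d subject descriptor and fed to five classifier families — KNN,
decision tree, random forest, SVM and MLP — each tuned by an exhaustive grid
search with inner cross-validation on the training fold only, and evaluated
under stratified 5-fold cross-validation.  Features are standardised with
train-fold statistics before the distance/margin-based models (KNN, SVM,
MLP); tree models see raw features.  Out-of-fold predictions cover every
subject exactly once per classifier, and a leakage guard asserts that train
and test subjects never overlap within a fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import (POSITIVE, MetricReport, aggregate_folds, confusion,
                         metrics, roc_auc)
from .tsn import FEATURE_DIM, MotionFeatureVector

__all__ = [
    "FusedFeature",
    "CVPlan",
    "GridSearchSpace",
    "DetectionResult",
    "CLASSIFIER_NAMES",
    "DEFAULT_GRIDS",
    "fuse_views",
    "make_cv_plan",
    "grid_search_fit",
    "run_detection",
]

CLASSIFIER_NAMES = ("KNN", "DT", "RF", "SVM", "MLP")

#: classifiers that need standardised inputs
_SCALED = {"KNN", "SVM", "MLP"}

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "KNN": [{"n_neighbors": [3, 5, 7, 9]}],
    "DT": [{"max_depth": [3, 5, 10, None]}],
    "RF": [{"n_estimators": [100, 300]}],
    "SVM": [{"kernel": ["rbf", "linear"], "C": [0.1, 1, 10]}],
    "MLP": [{"hidden_layer_sizes": [(128,), (256,)]}],
}


@dataclass
class FusedFeature:
    """2048-d multi-view descriptor: A2C block (0:1024) then A4C (1024:2048)."""

    values: np.ndarray
    subject_id: str
    label: str


@dataclass
class CVPlan:
    n_folds: int
    fold_of_subject: np.ndarray   # test-fold index per subject
    seed: int

    def folds(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(self.n_folds):
            test = np.flatnonzero(self.fold_of_subject == f)
            train = np.flatnonzero(self.fold_of_subject != f)
            yield train, test


@dataclass
class GridSearchSpace:
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))

    def for_classifier(self, name: str) -> list[dict]:
        if name not in self.grids or not self.grids[name]:
            raise ValueError(f"no grid defined for classifier {name!r}")
        return self.grids[name]


@dataclass
class DetectionResult:
    classifier: str
    fold_reports: list[MetricReport]
    aggregates: dict
    predictions: list[dict]          # per subject: id, fold, score, predicted, true
    chosen_params: list[dict]        # per fold
    mean_auc: float


def fuse_views(a2c: MotionFeatureVector | np.ndarray, a4c: MotionFeatureVector | np.ndarray,
               subject_id: str = "", label: str = "") -> FusedFeature:
    """Concatenate the two per-view 1024-d features, A2C block first."""
    va = a2c.values if isinstance(a2c, MotionFeatureVector) else np.asarray(a2c)
    vb = a4c.values if isinstance(a4c, MotionFeatureVector) else np.asarray(a4c)
    if va is None or vb is None:
        raise ValueError("both views are required; no imputation for missing views")
    if va.shape != (FEATURE_DIM,) or vb.shape != (FEATURE_DIM,):
        raise ValueError(
            f"per-view features must be length {FEATURE_DIM}, got {va.shape} and {vb.shape}")
    return FusedFeature(values=np.concatenate([va, vb]), subject_id=subject_id, label=label)


def make_cv_plan(labels, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Stratified fold assignment; every class needs >= n_folds members."""
    labels = np.asarray(list(labels))
    for cls, cnt in zip(*np.unique(labels, return_counts=True)):
        if cnt < n_folds:
            raise ValueError(f"class {cls!r} has {cnt} subjects; needs >= {n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test] = f
    return CVPlan(n_folds=n_folds, fold_of_subject=fold_of, seed=seed)


def _make_estimator(name: str, params: dict, seed: int):
    if name == "KNN":
        est = KNeighborsClassifier(**params)
    elif name == "DT":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif name == "RF":
        est = RandomForestClassifier(random_state=seed, **params)
    elif name == "SVM":
        est = SVC(random_state=seed, **params)
    elif name == "MLP":
        est = MLPClassifier(random_state=seed, max_iter=400, **params)
    else:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    if name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def grid_search_fit(name: str, space: GridSearchSpace, X: np.ndarray, y: np.ndarray,
                    inner_seed: int = 0, inner_folds: int = 3):
    """Exhaustive grid search by inner stratified CV on the training data only.

    The best parameter set by mean inner accuracy wins; ties are broken by
    first-in-grid order (strict improvement required to replace the leader).
    Returns ``(fitted_estimator, chosen_params)``.
    """
    grids = space.for_classifier(name)
    best_score, best_params = -np.inf, None
    min_class = int(np.bincount(np.asarray(y, dtype=int)).min())
    if min_class < 2:
        raise ValueError("inner CV needs at least 2 training subjects per class")
    inner = StratifiedKFold(n_splits=min(inner_folds, min_class), shuffle=True,
                            random_state=inner_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)  # unscorable grid points
        for params in ParameterGrid(grids):
            est = _make_estimator(name, params, seed=inner_seed)
            score = cross_val_score(est, X, y, cv=inner, scoring="accuracy").mean()
            if np.isfinite(score) and score > best_score:
                best_score, best_params = score, params
        if best_params is None:  # every grid point unscorable at this n
            best_params = next(iter(ParameterGrid(grids)))
        fitted = _make_estimator(name, best_params, seed=inner_seed)
        fitted.fit(X, y)
    return fitted, best_params


def _decision_scores(est, X) -> np.ndarray:
    """Continuous score for the positive class (for ROC)."""
    if hasattr(est, "decision_function"):
        try:
            return np.asarray(est.decision_function(X), dtype=float)
        except AttributeError:
            pass
    proba = est.predict_proba(X)
    pos = list(est.classes_).index(1)
    return np.asarray(proba[:, pos], dtype=float)


def run_detection(features: list[FusedFeature], plan: CVPlan,
                  classifiers=CLASSIFIER_NAMES, space: GridSearchSpace | None = None,
                  inner_seed: int = 0) -> dict[str, DetectionResult]:
    """Out-of-fold evaluation of the classifier bank on fused features.

    Per fold and classifier: grid search + fit on the training subjects only,
    predict the held-out subjects, and compute the confusion-matrix metrics;
    per-classifier fold metrics are aggregated as max/mean/min.
    """
    space = space or GridSearchSpace()
    X = np.stack([f.values for f in features])
    y_str = [f.label for f in features]
    y = np.asarray([1 if l == POSITIVE else 0 for l in y_str])
    results: dict[str, DetectionResult] = {}
    for name in classifiers:
        fold_reports, predictions, chosen, aucs = [], [], [], []
        seen = np.zeros(len(features), dtype=bool)
        for fold, (train, test) in enumerate(plan.folds()):
            if np.intersect1d(train, test).size:
                raise RuntimeError("leakage: train and test folds overlap")
            est, params = grid_search_fit(name, space, X[train], y[train],
                                          inner_seed=inner_seed + fold)
            chosen.append(params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                y_pred = est.predict(X[test])
                scores = _decision_scores(est, X[test])
            pred_str = [POSITIVE if p == 1 else "non-RWMA" for p in y_pred]
            true_str = [y_str[i] for i in test]
            cm = confusion(true_str, pred_str)
            rep = metrics(cm)
            if len(set(true_str)) == 2:
                rep.auc, _, _ = roc_auc(scores, true_str)
                aucs.append(rep.auc)
            fold_reports.append(rep)
            seen[test] = True
            for i, sid_idx in enumerate(test):
                predictions.append({
                    "subject_id": features[sid_idx].subject_id, "fold": fold,
                    "classifier": name, "score": float(scores[i]),
                    "predicted": pred_str[i], "true": true_str[i],
                })
        if not seen.all():
            raise RuntimeError("out-of-fold coverage incomplete")
        results[name] = DetectionResult(
            classifier=name, fold_reports=fold_reports,
            aggregates=aggregate_folds(fold_reports), predictions=predictions,
            chosen_params=chosen,
            mean_auc=float(np.mean(aucs)) if aucs else float("nan"))
    return results
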