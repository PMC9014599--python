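"""Stacking ensemble (SVM + logistic regression bases, LR meta-learner) for
lymph-node-metastasis prediction.

The cohort is split 7:3 stratified by label; hyperparameters are chosen by
cross-validated grid search on the training portion only; the meta-learner is
trained on out-of-fold probability predictions of the base learners (5 inner
folds), so base models never predict on rows they trained on.  Performance is
reported as sensitivity, specificity, accuracy, PPV, NPV and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_labels import LABEL_NEGATIVE, LABEL_POSITIVE, SampleTable

logger = logging.getLogger(__name__)

#: compact default search grid (kernelized and linear SVM arms)
_SVM = "svm__svc__estimator"
DEFAULT_GRID = [
    {f"{_SVM}__kernel": ["rbf"], f"{_SVM}__C": [0.1, 1, 10, 100],
     f"{_SVM}__gamma": ["scale", 0.01, 0.001], "lr__C": [0.1, 1, 10]},
    {f"{_SVM}__kernel": ["linear"], f"{_SVM}__C": [0.1, 1, 10, 100],
     "lr__C": [0.1, 1, 10]},
]


def split_cohort(labels: SampleTable, ratio: float = 0.7, seed: int = 0):
    """Stratified train/test split of labeled tumor samples (7:3 default)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    pos = labels.ids_with_label(LABEL_POSITIVE)
    neg = labels.ids_with_label(LABEL_NEGATIVE)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two samples per class to split")
    ids = np.array(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    train, test = train_test_split(ids, train_size=ratio, stratify=y,
                                   random_state=seed)
    return list(train), list(test)


def _base_stacking(seed: int) -> StackingClassifier:
    # continuous SVM outputs for the meta-learner come from a sigmoid (Platt)
    # calibration fitted on out-of-fold decision values
    svm = Pipeline([
        ("scale", StandardScaler()),
        ("svc", CalibratedClassifierCV(
            SVC(random_state=seed), method="sigmoid", ensemble=False,
            cv=StratifiedKFold(5, shuffle=True, random_state=seed))),
    ])
    lr = LogisticRegression(max_iter=5000)
    return StackingClassifier(
        estimators=[("svm", svm), ("lr", lr)],
        final_estimator=LogisticRegression(max_iter=5000),
        cv=StratifiedKFold(5, shuffle=True, random_state=seed),
        stack_method="predict_proba",
    )


@dataclass
class StackingModel:
    """Fitted stacking ensemble plus the grid-search choices that produced it."""

    estimator: StackingClassifier
    best_params: dict
    best_cv_auc: float
    seed: int

    def predict_proba(self, scores) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(scores))[:, 1]

    def predict(self, scores, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(scores) >= threshold).astype(int)


def fit_stacking(train_scores, train_labels, grid=None, seed: int = 0,
                 inner_folds: int = 5) -> StackingModel:
    """Grid-search the stacking ensemble on training data and refit on all of it.

    Selection metric is AUC over ``inner_folds`` stratified folds.
    """
    x = np.asarray(train_scores, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < inner_folds:
        raise ValueError(
            f"need >= {inner_folds} samples per class for {inner_folds}-fold "
            "meta-feature generation")
    search = GridSearchCV(
        _base_stacking(seed), grid if grid is not None else DEFAULT_GRID,
        scoring="roc_auc",
        cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        n_jobs=1, refit=True,
    )
    search.fit(x, y)
    logger.info("grid search: best CV AUC %.3f with %s",
                search.best_score_, search.best_params_)
    return StackingModel(estimator=search.best_estimator_,
                         best_params=dict(search.best_params_),
                         best_cv_auc=float(search.best_score_), seed=seed)


@dataclass
class MetricsReport:
    """Confusion counts and the derived operating-point metrics plus AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None

    @property
    def sn(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def acc(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def as_dict(self) -> dict:
        return {"SN": self.sn, "SP": self.sp, "ACC": self.acc, "PPV": self.ppv,
                "NPV": self.npv, "AUC": self.auc, "TP": self.tp, "FP": self.fp,
                "TN": self.tn, "FN": self.fn}


def auc_trapezoid(y_true, y_score) -> float | None:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    y_true = np.asarray(y_true, dtype=int)
    if np.unique(y_true).size < 2:
        return None
    fpr, tpr, _ = roc_curve(y_true, np.asarray(y_score, dtype=float))
    return float(np.trapezoid(tpr, fpr))


def auc_rank(y_true, y_score) -> float | None:
    """AUC as the normalized Mann–Whitney U statistic (rank formulation)."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(y_score)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def metrics_from_predictions(y_true, y_pred, y_score=None) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    auc = auc_trapezoid(y_true, y_score) if y_score is not None else None
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)


def evaluate(model: StackingModel, scores, labels) -> MetricsReport:
    """Operating-point metrics at the fixed 0.5 probability cut, plus AUC."""
    prob = model.predict_proba(scores)
    return metrics_from_predictions(labels, (prob >= 0.5).astype(int), prob)


def cross_validate(scores, labels, estimator=None, k: int = 5,
                   seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation, pooled (micro-averaged) report.

    ``estimator`` is an unfitted classifier configuration (defaults to the
    un-searched stacking ensemble); a clone is refit per fold and out-of-fold
    predictions are pooled into one confusion matrix / AUC.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} samples for {k}-fold CV")
    est = estimator if estimator is not None else _base_stacking(seed)
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    prob = np.empty(y.size)
    for tr, te in skf.split(x, y):
        m = clone(est)
        m.fit(x[tr], y[tr])
        prob[te] = m.predict_proba(x[te])[:, 1]
    return metrics_from_predictions(y, (prob >= 0.5).astype(int), prob)
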