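"""Random-forest classification of subjects from irreversibility features.

Repeated stratified 5-fold cross-validation (default 50 repeats) of a
random forest, with weighted-KNN imputation of missing features fitted
inside each training fold (no leakage into the held-out fold), and the
standard binary metric suite: ROC-AUC, precision, sensitivity,
specificity, accuracy, F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

METRICS = ("auc", "precision", "sensitivity", "specificity", "accuracy", "f1")


@dataclass
class FeatureTable:
    """Subjects × named features plus a binary group label per subject.

    Missing values (NaN) are permitted before imputation; the positive
    class is the first label of ``classes`` (AD by convention).
    """

    features: pd.DataFrame
    labels: pd.Series
    positive_class: str = "AD"

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the subject index")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        counts = self.labels.value_counts()
        if len(counts) != 2 or counts.min() < 2:
            raise ValueError("need two classes with >= 2 subjects each")
        if self.features.isna().all(axis=1).any():
            raise ValueError("a subject is missing all features")
        if self.features.isna().all(axis=0).any():
            raise ValueError("a feature is missing for all subjects")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == self.positive_class).to_numpy().astype(int)


def _standardized_knn(X_fit: np.ndarray, k: int) -> tuple[KNNImputer, np.ndarray, np.ndarray]:
    mu = np.nanmean(X_fit, axis=0)
    sd = np.nanstd(X_fit, axis=0)
    sd[sd == 0] = 1.0
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    imputer.fit((X_fit - mu) / sd)
    return imputer, mu, sd


def knn_impute(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Weighted K-nearest-neighbor imputation of missing feature cells.

    Distances are Euclidean over mutually observed features after
    per-feature standardization; each missing cell becomes the
    inverse-distance-weighted mean of its k nearest subjects' values. A
    table without missing values is returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not table.features.isna().any().any():
        return table
    X = table.features.to_numpy(dtype=float)
    imputer, mu, sd = _standardized_knn(X, k)
    filled = imputer.transform((X - mu) / sd) * sd + mu
    out = pd.DataFrame(filled, index=table.features.index,
                       columns=table.features.columns)
    return FeatureTable(out, table.labels, table.positive_class)


def classification_metrics(
    tp: int, fp: int, fn: int, tn: int,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict[str, float | None]:
    """Binary classification metrics from a confusion table (+ optional scores).

    Undefined ratios (zero denominator) are reported as None, never as 0.
    AUC is computed from ``scores`` against ``y_true`` when both are given.
    """
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be nonnegative with positive total")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    auc = None
    if scores is not None and y_true is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return {"auc": auc, "precision": precision, "sensitivity": sensitivity,
            "specificity": specificity, "accuracy": accuracy, "f1": f1}


@dataclass
class CVResult:
    """Per-repeat metrics and their mean ± SD aggregates."""

    per_repeat: pd.DataFrame  # one row per repeat, columns = METRICS
    folds: int
    repeats: int

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_repeat.std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def crossval_rf(
    table: FeatureTable,
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
    n_trees: int = 100,
    impute_k: int = 5,
) -> CVResult:
    """Repeated stratified K-fold random-forest cross-validation.

    Per repeat, subjects are stratified into ``folds`` folds from the
    seeded generator; the forest (``n_trees`` trees, √(#features)
    candidate splits) is fitted on the training folds and scored on the
    held-out fold. Imputation, when needed, is fitted on each training
    fold only. Out-of-fold vote fractions are pooled per repeat for the
    ROC; threshold metrics use 0.5. Same seed ⇒ identical folds and
    metrics.
    """
    X = table.features.to_numpy(dtype=float)
    y = table.y
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError("each class needs at least `folds` members")
    rows = []
    for rep in range(repeats):
        rep_seed = (seed * 1_000 + rep) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        scores = np.empty(len(y))
        for fold_i, (train, test) in enumerate(skf.split(X, y)):
            X_tr, X_te = X[train], X[test]
            if np.isnan(X_tr).any() or np.isnan(X_te).any():
                imputer, mu, sd = _standardized_knn(X_tr, impute_k)
                X_tr = imputer.transform((X_tr - mu) / sd) * sd + mu
                X_te = imputer.transform((X_te - mu) / sd) * sd + mu
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt",
                random_state=(rep_seed + fold_i) % (2**31 - 1), n_jobs=1,
            )
            rf.fit(X_tr, y[train])
            scores[test] = rf.predict_proba(X_te)[:, list(rf.classes_).index(1)]
        pred = (scores >= 0.5).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        m = classification_metrics(tp, fp, fn, tn, scores=scores, y_true=y)
        rows.append({k: (np.nan if v is None else v) for k, v in m.items()})
    return CVResult(per_repeat=pd.DataFrame(rows, columns=list(METRICS)),
                    folds=folds, repeats=repeats)
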