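"""Classifier training and evaluation under subject-wise cross-validation.

Three classifier families (random forest with 100 unpruned trees, kNN
with Euclidean distance, and SVM / nu-SVC with six kernel choices) are
evaluated with grouped k-fold cross-validation: folds partition
*subjects*, never records, so repeated laughs from one subject cannot
leak between training and validation. Validation predictions from all
folds are pooled into a single confusion matrix from which the accuracy
rate (AR, %), per-class rates, sensitivity/specificity, the Matthews
correlation coefficient and the ROC curve with its AUC are computed.
The PD class is the positive class throughout; classification ties
resolve toward PD (the clinically conservative direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, NuSVC

from .errors import ConfigError, DataError
from .features import META_COLUMNS, features_to_frame

POSITIVE = "pd"

SVM_KERNELS = ("linear", "poly3", "rbf", "nu_linear", "nu_poly3", "nu_rbf")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str  # {"rf", "knn", "svm"}
    rf_trees: int = 100
    knn_k: int = 5
    svm_kernel: str = "nu_linear"
    svm_nu: float = 0.5
    standardize: bool | None = None  # None -> auto: off for rf, on otherwise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rf", "knn", "svm"):
            raise ConfigError(f"unknown classifier family {self.family!r}")
        if self.family == "rf" and self.rf_trees < 1:
            raise ConfigError("rf_trees must be >= 1")
        if self.family == "knn" and not 1 <= self.knn_k <= 10:
            raise ConfigError("knn_k must lie in 1..10")
        if self.family == "svm":
            if self.svm_kernel not in SVM_KERNELS:
                raise ConfigError(f"unknown SVM kernel {self.svm_kernel!r}; valid: {SVM_KERNELS}")
            if not 0 < self.svm_nu < 1:
                raise ConfigError("svm_nu must lie in (0, 1)")

    @property
    def wants_standardization(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.family != "rf"  # trees are scale-invariant


@dataclass(frozen=True)
class CVPlan:
    """Assignment of subject groups to folds."""

    k_folds: int
    fold_of_group: dict[str, int]

    def record_folds(self, groups: np.ndarray) -> np.ndarray:
        missing = set(groups) - set(self.fold_of_group)
        if missing:
            raise DataError(f"records reference groups absent from the CV plan: {sorted(missing)[:5]}")
        return np.array([self.fold_of_group[g] for g in groups])


def make_folds(groups, k: int = 10, seed: int = 0) -> CVPlan:
    """Shuffle distinct groups by seed and deal them round-robin into k folds."""
    unique = sorted(set(map(str, groups)))
    if k < 2:
        raise ConfigError("k_folds must be >= 2 (one fold leaves no training segment)")
    if len(unique) < k:
        raise ConfigError(f"{len(unique)} groups cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(unique))
    return CVPlan(
        k_folds=k,
        fold_of_group={unique[idx]: i % k for i, idx in enumerate(order)},
    )


@dataclass(frozen=True)
class EvalReport:
    ar_percent: float
    tp: int
    fp: int
    tn: int
    fn: int
    tp_rate: float
    fp_rate: float
    tn_rate: float
    fn_rate: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR)
    per_fold_ar: tuple[float, ...]
    n_records: int

    def to_dict(self) -> dict:
        return {
            "ar_percent": round(self.ar_percent, 6),
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "tp_rate": round(self.tp_rate, 6),
            "fp_rate": round(self.fp_rate, 6),
            "tn_rate": round(self.tn_rate, 6),
            "fn_rate": round(self.fn_rate, 6),
            "sensitivity": round(self.sensitivity, 6),
            "specificity": round(self.specificity, 6),
            "mcc": round(self.mcc, 6),
            "auc": round(self.auc, 6),
            "per_fold_ar": [round(a, 6) for a in self.per_fold_ar],
            "n_records": self.n_records,
        }


def mcc_from_confusion(tp: float, fp: float, tn: float, fn: float) -> float:
    """Matthews correlation; 0 by convention when any marginal is empty."""
    if min(tp, fp, tn, fn) < 0:
        raise DataError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep over unique scores; trapezoidal AUC.

    Tied scores move the operating point in one step, which makes the
    trapezoidal area equal to the tie-corrected Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order]
    # indices where the score changes: one ROC vertex per unique score
    boundaries = np.nonzero(np.diff(sorted_scores))[0]
    cum_tp = np.cumsum(sorted_pos)
    cum_fp = np.cumsum(~sorted_pos)
    vertex_idx = np.concatenate([boundaries, [scores.size - 1]])
    tpr = np.concatenate([[0.0], cum_tp[vertex_idx] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[vertex_idx] / n_neg])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _build_model(spec: ClassifierSpec):
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees,
            max_features="sqrt",
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    kernel_map = {
        "linear": ("svc", "linear"),
        "poly3": ("svc", "poly"),
        "rbf": ("svc", "rbf"),
        "nu_linear": ("nu", "linear"),
        "nu_poly3": ("nu", "poly"),
        "nu_rbf": ("nu", "rbf"),
    }
    variant, kernel = kernel_map[spec.svm_kernel]
    if variant == "nu":
        return NuSVC(nu=spec.svm_nu, kernel=kernel, degree=3, random_state=spec.seed)
    return SVC(kernel=kernel, degree=3, random_state=spec.seed)


def _feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return features_to_frame(list(features))


def _split_xy(df: pd.DataFrame, columns: list[str] | None = None):
    cols = columns or [c for c in df.columns if c not in META_COLUMNS]
    x = df[cols].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DataError("feature matrix contains non-finite values")
    y = (df["class_label"] == POSITIVE).to_numpy()
    groups = df["subject_id"].astype(str).to_numpy()
    return x, y, groups


def train_eval(
    features,
    spec: ClassifierSpec,
    plan: CVPlan | None = None,
    k_folds: int = 10,
    feature_columns: list[str] | None = None,
) -> EvalReport:
    """Grouped-CV evaluation of one classifier on a labeled feature table.

    Per fold the training-fold mean/SD standardize both splits (for the
    scale-sensitive families), the model is fitted on the training
    records and scores the validation records with a continuous PD score
    (RF: tree-vote fraction; kNN: neighbor-class fraction; SVM: decision
    value). Pooled validation predictions across folds produce one
    report.
    """
    df = _feature_frame(features)
    x, y, groups = _split_xy(df, feature_columns)
    plan = plan or make_folds(groups, k=k_folds, seed=spec.seed)
    folds = plan.record_folds(groups)

    scores = np.zeros(y.size)
    preds = np.zeros(y.size, dtype=bool)
    per_fold_ar = []
    for fold in range(plan.k_folds):
        val = folds == fold
        train = ~val
        if val.sum() == 0:
            continue
        y_train = y[train]
        if y_train.all() or not y_train.any():
            raise DataError(f"training split of fold {fold} contains a single class")
        x_train, x_val = x[train], x[val]
        if spec.wants_standardization:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            x_train = (x_train - mu) / sd
            x_val = (x_val - mu) / sd
        model = _build_model(spec)
        model.fit(x_train, y_train)
        if spec.family == "svm":
            fold_scores = model.decision_function(x_val)
            fold_preds = fold_scores >= 0.0  # tie toward PD
        else:
            pos_col = int(np.nonzero(model.classes_)[0][0])
            fold_scores = model.predict_proba(x_val)[:, pos_col]
            fold_preds = fold_scores >= 0.5  # even-vote tie toward PD
        scores[val] = fold_scores
        preds[val] = fold_preds
        per_fold_ar.append(100.0 * np.mean(fold_preds == y[val]))

    tp = int(np.sum(preds & y))
    fp = int(np.sum(preds & ~y))
    tn = int(np.sum(~preds & ~y))
    fn = int(np.sum(~preds & y))
    n_pos, n_neg = tp + fn, tn + fp
    roc_points, auc = roc_auc(scores, y)
    return EvalReport(
        ar_percent=100.0 * (tp + tn) / y.size,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tp_rate=tp / n_pos if n_pos else 0.0,
        fn_rate=fn / n_pos if n_pos else 0.0,
        tn_rate=tn / n_neg if n_neg else 0.0,
        fp_rate=fp / n_neg if n_neg else 0.0,
        sensitivity=tp / n_pos if n_pos else 0.0,
        specificity=tn / n_neg if n_neg else 0.0,
        mcc=mcc_from_confusion(tp, fp, tn, fn),
        auc=auc,
        roc_points=roc_points,
        per_fold_ar=tuple(per_fold_ar),
        n_records=int(y.size),
    )


def ablation_pitch(
    features_with_pitch: pd.DataFrame,
    spec: ClassifierSpec,
    plan: CVPlan | None = None,
    k_folds: int = 10,
) -> dict[str, EvalReport]:
    """Evaluate pitch-only, cepstra-only and combined inputs with one protocol."""
    pitch_cols = [c for c in features_with_pitch.columns if c.startswith("pitch.")]
    if not pitch_cols:
        raise DataError("feature table has no pitch.* columns; join pitch statistics first")
    cepstral_cols = [
        c for c in features_with_pitch.columns if c not in META_COLUMNS and c not in pitch_cols
    ]
    if plan is None:
        groups = features_with_pitch["subject_id"].astype(str).to_numpy()
        plan = make_folds(groups, k=k_folds, seed=spec.seed)
    return {
        "pitch_only": train_eval(features_with_pitch, spec, plan, feature_columns=pitch_cols),
        "cepstra_only": train_eval(features_with_pitch, spec, plan, feature_columns=cepstral_cols),
        "combined": train_eval(
            features_with_pitch, spec, plan, feature_columns=cepstral_cols + pitch_cols
        ),
    }
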