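"""Model benchmarking: six baseline classifiers under pooled 5-fold CV.

The baselines and their hyperparameters are fixed:
gradient boosting (min_samples_split 5, min_samples_leaf 2, max_depth 3),
SVM (rbf, C=1, gamma='scale'), AdaBoost (50 estimators), Gaussian naive
Bayes, decision tree (min_samples_split 5, min_samples_leaf 2, max_depth 3),
and random forest (10 estimators, min_samples_split 5, min_samples_leaf 2,
max_depth 3). Folds are random 80/20 splits pooled over all participants
(a grouped-by-participant mode exists but is off by default: pooled folds
let a participant appear in both train and test, which is the replicated
protocol, not a leakage-free one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, FEATURE_GROUPS


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)


BASELINE_SPECS = {
    "gradient_boosting": ModelSpec("gradient_boosting",
                                   {"min_samples_split": 5,
                                    "min_samples_leaf": 2, "max_depth": 3}),
    "support_vector": ModelSpec("support_vector",
                                {"kernel": "rbf", "C": 1.0, "gamma": "scale"}),
    "adaptive_boosting": ModelSpec("adaptive_boosting", {"n_estimators": 50}),
    "naive_bayes": ModelSpec("naive_bayes", {}),
    "decision_tree": ModelSpec("decision_tree",
                               {"min_samples_split": 5,
                                "min_samples_leaf": 2, "max_depth": 3}),
    "random_forest": ModelSpec("random_forest",
                               {"n_estimators": 10, "min_samples_split": 5,
                                "min_samples_leaf": 2, "max_depth": 3}),
}


def build_estimator(spec: ModelSpec, seed: int = 0):
    from sklearn.ensemble import (AdaBoostClassifier,
                                  GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    hp = dict(spec.hyperparameters)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if spec.family == "support_vector":
        return SVC(random_state=seed, **hp)
    if spec.family == "adaptive_boosting":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.family == "naive_bayes":
        return GaussianNB(**hp)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown model family: {spec.family}")


def metrics(tp: int, fp: int, fn: int, tn: int):
    """Precision, recall, F1 with the zero-denominator -> 0 convention."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


@dataclass
class CvResult:
    fold_precision: np.ndarray
    fold_recall: np.ndarray
    fold_f1: np.ndarray
    fold_assignments: np.ndarray
    seed: int

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.fold_recall))


def _fit_predict_fold(X_tr, y_tr, X_te, spec, seed):
    from sklearn.impute import SimpleImputer
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("model", build_estimator(spec, seed)),
    ])
    pipe.fit(X_tr, y_tr)
    return pipe, pipe.predict(X_te)


def cross_validate(pairs: pd.DataFrame, spec: ModelSpec,
                   feature_mask: list | None = None, seed: int = 0,
                   n_splits: int = 5, grouped: bool = False,
                   select=None) -> CvResult:
    """Pooled random 5-fold CV of one model spec on a pair table.

    ``pairs`` holds the feature columns plus a binary ``target``.
    Imputation (train-fold medians) and standardization are fitted on
    training folds only. ``select`` may be a callable
    ``(X_tr, y_tr) -> column indices`` applied per fold (e.g. CFS).
    """
    cols = feature_mask if feature_mask is not None else FEATURE_COLUMNS
    X = pairs[cols].to_numpy(dtype=float)
    y = pairs["target"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("cross-validation needs both target classes")
    if len(y) < 10:
        raise ValueError("need at least 10 pairs")
    from sklearn.model_selection import GroupKFold, KFold
    assign = np.empty(len(y), dtype=int)
    if grouped:
        splitter = GroupKFold(n_splits=n_splits)
        splits = splitter.split(X, y, groups=pairs["participant_id"])
    else:
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    prs, rcs, f1s = [], [], []
    for k, (tr, te) in enumerate(splits):
        assign[te] = k
        X_tr, y_tr, X_te = X[tr], y[tr], X[te]
        if select is not None:
            keep = select(X_tr, y_tr)
            X_tr, X_te = X_tr[:, keep], X_te[:, keep]
        _, pred = _fit_predict_fold(X_tr, y_tr, X_te, spec, seed)
        y_te = y[te]
        tp = int(np.sum((pred == 1) & (y_te == 1)))
        fp = int(np.sum((pred == 1) & (y_te == 0)))
        fn = int(np.sum((pred == 0) & (y_te == 1)))
        tn = int(np.sum((pred == 0) & (y_te == 0)))
        p, r, f = metrics(tp, fp, fn, tn)
        prs.append(p); rcs.append(r); f1s.append(f)
    return CvResult(np.array(prs), np.array(rcs), np.array(f1s), assign, seed)


def majority_baseline_f1(y: np.ndarray) -> float:
    """F1 of always predicting the positive class (the prevalence baseline)."""
    p = float(np.mean(y))
    return 2 * p / (1 + p) if p > 0 else 0.0


ABLATION_COMBOS = [
    ("sensor",), ("ema",), ("intervention",),
    ("sensor", "ema"), ("intervention", "ema"), ("intervention", "sensor"),
    ("sensor", "ema", "intervention"),
]


def feature_group_ablation(pairs: pd.DataFrame, seed: int = 0,
                           spec: ModelSpec | None = None,
                           include_covariates: bool = True) -> pd.DataFrame:
    """Evaluate the six printed feature-type combinations plus all-features
    with the random-forest spec. Covariates ride along in every combination."""
    spec = spec or BASELINE_SPECS["random_forest"]
    rows = []
    for combo in ABLATION_COMBOS:
        cols = []
        for g in combo:
            cols.extend(FEATURE_GROUPS[g])
        if include_covariates:
            cols.extend(FEATURE_GROUPS["covariates"])
        if not cols:
            continue
        res = cross_validate(pairs, spec, feature_mask=cols, seed=seed)
        rows.append({
            "combination": "+".join(combo) if len(combo) < 3 else "all",
            "n_features": len(cols),
            "mean_precision": res.mean_precision,
            "mean_recall": res.mean_recall,
            "mean_f1": res.mean_f1,
        })
    return pd.DataFrame(rows)
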