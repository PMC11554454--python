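"""Acupuncture-response labeling and gradient-boosted prediction.

Remission after treatment is defined on the 24-item Hamilton scale:
a reduction rate (baseline - post) / baseline strictly greater than 30%,
or a post-treatment score below 7.  A gradient-boosted tree classifier
(XGBoost) predicts this label from the 24 baseline microstate features
under stratified 5-fold cross-validation, with each fold serving once as
the 20% test set; performance is summarized per fold and pooled over the
out-of-fold scores, and feature importance is the total split gain
averaged across the fold models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .temporal import FEATURE_NAMES


@dataclass(frozen=True)
class SubjectOutcome:
    """HAMD-24 scores with the derived reduction rate and remission flag."""

    hamd_baseline: float
    hamd_post: float
    reduction_rate: float
    remission: bool


def label_remission(baseline: float, post: float) -> SubjectOutcome:
    """Apply the remission rule: reduction rate > 0.30 (strict) or post < 7."""
    if baseline <= 0:
        raise ValueError("baseline HAMD must be positive to define a reduction rate")
    if post < 0:
        raise ValueError("post HAMD cannot be negative")
    rate = (baseline - post) / baseline
    return SubjectOutcome(float(baseline), float(post), float(rate),
                          bool(rate > 0.30 or post < 7))


@dataclass
class ModelConfig:
    """Gradient-boosting and validation settings.

    The boosting hyperparameters mirror a conservative clinical setup:
    slow learning (0.01) with moderately deep trees, L2 penalty 1, and a
    minimum child weight of 2.  ``n_rounds`` is an upper bound; early
    stopping with patience ``early_stopping_rounds`` on an inner
    validation split picks the effective length.
    """

    learning_rate: float = 0.01
    max_depth: int = 6
    min_child_weight: float = 2.0
    reg_lambda: float = 1.0
    n_folds: int = 5
    test_ratio: float = 0.2
    n_rounds: int = 500
    early_stopping_rounds: int = 50
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.n_rounds <= 0:
            raise ValueError("learning_rate and n_rounds must be positive")
        if self.max_depth < 1 or self.n_folds < 2:
            raise ValueError("max_depth >= 1 and n_folds >= 2 required")


@dataclass
class EvalReport:
    """Classification metrics at a fixed threshold plus rank-based AUC."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: tuple[int, int, int, int]    # TP, FP, TN, FN
    auc_defined: bool = True


def compute_metrics(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion-based metrics and midrank AUC from probability scores.

    AUC is the Mann-Whitney rank statistic (ties counted half), i.e. the
    probability a random positive outscores a random negative; undefined
    (flagged, reported 0.5) when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos)); fp = int(np.sum(pred & neg))
    tn = int(np.sum(~pred & neg)); fn = int(np.sum(~pred & pos))
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    auc_defined = pos.any() and neg.any()
    auc = float(roc_auc_score(labels, scores)) if auc_defined else 0.5
    return EvalReport(auc, accuracy, sensitivity, specificity, f1,
                      (tp, fp, tn, fn), bool(auc_defined))


@dataclass
class CVResult:
    """Cross-validated model: fold boosters, out-of-fold scores, reports."""

    pooled: EvalReport
    per_fold: list[EvalReport]
    oof_scores: np.ndarray
    labels: np.ndarray
    boosters: list = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)


def _make_classifier(config: ModelConfig):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=config.n_rounds,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        min_child_weight=config.min_child_weight,
        reg_lambda=config.reg_lambda,
        objective="binary:logistic",
        eval_metric="logloss",
        early_stopping_rounds=config.early_stopping_rounds,
        random_state=config.seed,
        n_jobs=1,
        verbosity=0,
    )


def fit_predict(features: pd.DataFrame, labels, config: ModelConfig | None = None
                ) -> CVResult:
    """Stratified k-fold cross-validation of the boosted-tree classifier.

    Each fold once serves as the held-out test set (1/n_folds = the 20%
    test ratio at the default 5 folds); early stopping monitors an inner
    stratified split of the training fold so the test fold never informs
    model selection.  Metrics are computed per fold and pooled over the
    out-of-fold scores.
    """
    config = config or ModelConfig()
    if all(c in features.columns for c in FEATURE_NAMES):
        X = features.loc[:, list(FEATURE_NAMES)]
    else:
        X = features
    if X.shape[1] == 0:
        raise ValueError("no feature columns found")
    y = np.asarray(labels).astype(int)
    if y.size != len(X):
        raise ValueError("labels length must match feature rows")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if y.size < 2 * config.n_folds:
        raise ValueError("too few subjects for the requested fold count")

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    oof = np.full(y.size, np.nan)
    per_fold, boosters = [], []
    Xv = X.to_numpy(dtype=float)
    for train_idx, test_idx in skf.split(Xv, y):
        # early stopping monitors an inner stratified split of the
        # training fold, keeping the test fold untouched by model choice
        inner_tr, inner_val = train_test_split(
            train_idx, test_size=config.test_ratio, random_state=config.seed,
            stratify=y[train_idx])
        clf = _make_classifier(config)
        clf.fit(Xv[inner_tr], y[inner_tr],
                eval_set=[(Xv[inner_val], y[inner_val])], verbose=False)
        scores = clf.predict_proba(Xv[test_idx])[:, 1]
        oof[test_idx] = scores
        per_fold.append(compute_metrics(scores, y[test_idx], config.threshold))
        boosters.append(clf.get_booster())
    pooled = compute_metrics(oof, y, config.threshold)
    return CVResult(pooled, per_fold, oof, y, boosters, list(X.columns))


def fit_full(features: pd.DataFrame, labels, config: ModelConfig | None = None):
    """Fit one boosted-tree model on the full dataset (no validation split).

    Used for in-sample diagnostics and optional final refits; runs the
    configured number of rounds without early stopping.
    """
    config = config or ModelConfig()
    if all(c in features.columns for c in FEATURE_NAMES):
        features = features.loc[:, list(FEATURE_NAMES)]
    y = np.asarray(labels).astype(int)
    cfg = ModelConfig(**{**config.__dict__})
    clf = _make_classifier(cfg)
    clf.early_stopping_rounds = None
    clf.fit(features.to_numpy(dtype=float), y, verbose=False)
    return clf


def rank_features(result: CVResult, top: int = 10) -> pd.DataFrame:
    """Total-gain feature importance averaged over the fold models.

    Features never used by any tree have zero gain; the returned table
    is sorted descending and truncated to the top ``top`` features with
    positive gain.
    """
    if not result.boosters:
        raise ValueError("no trained fold models to rank")
    names = result.feature_names
    gains = pd.Series(0.0, index=names)
    for booster in result.boosters:
        booster.feature_names = list(names)
        fold_gain = booster.get_score(importance_type="total_gain")
        for feat, g in fold_gain.items():
            gains[feat] += g
    gains /= len(result.boosters)
    table = (gains.rename("total_gain").rename_axis("feature").reset_index()
             .sort_values(["total_gain", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True))
    positive = table[table["total_gain"] > 0]
    return positive.head(top) if top is not None else positive
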