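"""Binary classification between diagnostic groups with LOSO cross-validation.

The discriminative analysis fits a ridge-stabilized maximum-likelihood
logistic regression on z-scored features and evaluates it by
leave-one-subject-out (LOSO) cross-validation: each subject's class
probability comes from a model fitted on all other subjects, with the
z-scoring statistics likewise estimated on the training fold only (no
leakage).  Discrimination is summarized by the ROC area (Mann-Whitney
formulation), sensitivity and specificity at a 0.5 operating point, and
feature importance as absolute coefficients of the all-data fit on z-scored
features.

The ridge penalty (default 1e-4) is near-maximum-likelihood; it exists only
so that linearly separable training folds — common at LOSO sample sizes —
have a finite optimum.

The positive class is the more-affected group of each pair (PD against HC,
MSA against either), so sensitivity reads as disease detection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data_model import FEATURE_NAMES, SubjectRecord

__all__ = [
    "ClassifierResult",
    "SEVERITY_ORDER",
    "positive_class",
    "zscore_fit_apply",
    "fit_logistic",
    "loso_probabilities",
    "roc_auc",
    "roc_curve_points",
    "sens_spec",
    "feature_importance",
    "classify_pair",
    "feature_subset_search",
]

#: Clinical severity ordering used to pick the positive (disease) class.
SEVERITY_ORDER = ("HC", "PD", "MSA")

DEFAULT_RIDGE = 1e-4


@dataclass(frozen=True)
class ClassifierResult:
    """LOSO evaluation of one group-pair classifier."""

    pair: tuple[str, str]
    features: tuple[str, ...]
    probabilities: pd.Series  # P(positive class), indexed by subject_id
    labels: pd.Series  # 1 = positive class
    positive: str
    auc: float
    sensitivity: float
    specificity: float
    importance: pd.Series  # |coefficient| on z-scored features, descending


def positive_class(pair: Sequence[str]) -> str:
    """The more-affected group of a pair under HC < PD < MSA."""
    return max(pair, key=SEVERITY_ORDER.index)


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize train and test columns by the TRAIN mean and SD only.

    Raises on a zero-variance training column, naming the feature.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("training matrix must be 2-D with at least 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            [feature_names[j] for j in zero]
            if feature_names is not None
            else zero.tolist()
        )
        raise ValueError(f"zero-variance training feature(s): {names}")
    return (train - mean) / sd, (test - mean) / sd


def _neg_loglik(w: np.ndarray, X1: np.ndarray, y: np.ndarray, ridge: float) -> float:
    eta = X1 @ w
    # log(1 + e^eta) - y*eta, numerically stable
    ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
    return float(ll + 0.5 * ridge * np.sum(w[1:] ** 2))


def fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE, max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Ridge-penalized logistic regression by Newton iterations with step
    halving; intercept unpenalized.  Returns [intercept, coefficients]."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    X1 = np.column_stack([np.ones(n), X])
    w = np.zeros(d + 1)
    pen = np.full(d + 1, ridge)
    pen[0] = 0.0
    obj = _neg_loglik(w, X1, y, ridge)
    for _ in range(max_iter):
        p = expit(X1 @ w)
        g = X1.T @ (p - y) + pen * w
        W = np.maximum(p * (1 - p), 1e-12)
        H = (X1 * W[:, None]).T @ X1 + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the penalized deviance does not increase
        alpha = 1.0
        for _ in range(30):
            w_new = w - alpha * step
            obj_new = _neg_loglik(w_new, X1, y, ridge)
            if obj_new <= obj + 1e-12:
                break
            alpha *= 0.5
        moved = float(np.max(np.abs(w_new - w)))
        w, obj = w_new, obj_new
        if moved < tol:
            break
    return w


def loso_probabilities(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    ridge: float = DEFAULT_RIDGE,
    scale_outside_folds: bool = False,
) -> pd.Series:
    """Leave-one-subject-out class probabilities.

    For each subject, z-scoring statistics and the logistic model are fitted
    on the other n-1 subjects and applied to the held-out one.  Raises when
    any training fold would lose a class (a class with fewer than 2 members).

    ``scale_outside_folds=True`` standardizes once on the full data set
    before cross-validating — a mild leakage, offered only to replicate
    analyses that scaled globally.
    """
    if isinstance(features, pd.DataFrame):
        index = features.index
        names: Sequence[str] | None = list(features.columns)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, dtype=float)
        index = pd.RangeIndex(X.shape[0])
        names = None
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("features and labels disagree in length")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("a LOSO training fold would lose a class entirely")
    if scale_outside_folds:
        X, _ = zscore_fit_apply(X, X, names)
    probs = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if scale_outside_folds:
            Xtr, Xte = X[mask], X[~mask]
        else:
            Xtr, Xte = zscore_fit_apply(X[mask], X[~mask], names)
        w = fit_logistic(Xtr, y[mask], ridge=ridge)
        probs[i] = float(expit(w[0] + Xte[0] @ w[1:]))
        mask[i] = True
    return pd.Series(probs, index=index, name="p_positive")


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area via the Mann-Whitney statistic:
    P(score_pos > score_neg) + 0.5 P(tie)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(p)
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def roc_curve_points(
    probabilities: Sequence[float], labels: Sequence[int]
) -> pd.DataFrame:
    """ROC curve as (threshold, fpr, tpr) rows, thresholds descending over
    the distinct scores plus sentinels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    thresholds = np.concatenate([[np.inf], np.unique(p)[::-1], [-np.inf]])
    n_pos = np.sum(y == 1)
    n_neg = np.sum(y == 0)
    rows = []
    for thr in thresholds:
        pred = p >= thr
        tpr = float(np.sum(pred & (y == 1)) / n_pos) if n_pos else np.nan
        fpr = float(np.sum(pred & (y == 0)) / n_neg) if n_neg else np.nan
        rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)


def sens_spec(
    probabilities: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float]:
    """(sensitivity, specificity) at a probability threshold; prediction is
    positive when probability >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be present")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def feature_importance(
    features: pd.DataFrame, labels: Sequence[int], ridge: float = DEFAULT_RIDGE
) -> pd.Series:
    """Absolute logistic coefficients of the all-data fit on z-scored
    features, sorted descending — comparable across features because of the
    z-scoring."""
    X = features.to_numpy(float)
    Xz, _ = zscore_fit_apply(X, X, list(features.columns))
    w = fit_logistic(Xz, np.asarray(labels, dtype=int), ridge=ridge)
    imp = pd.Series(np.abs(w[1:]), index=features.columns, name="importance")
    return imp.sort_values(ascending=False, kind="stable")


def _pair_data(
    features: pd.DataFrame,
    records: Sequence[SubjectRecord],
    pair: Sequence[str],
    feature_subset: Sequence[str] | None,
) -> tuple[pd.DataFrame, pd.Series, str]:
    pos = positive_class(pair)
    by_id = {r.subject_id: r.group for r in records}
    ids = [sid for sid in features.index if by_id.get(sid) in pair]
    cols = list(feature_subset) if feature_subset is not None else [
        c for c in FEATURE_NAMES if c in features.columns
    ]
    sub = features.loc[ids, cols].dropna()
    labels = pd.Series(
        [1 if by_id[sid] == pos else 0 for sid in sub.index], index=sub.index, name="label"
    )
    return sub, labels, pos


def classify_pair(
    features: pd.DataFrame,
    records: Sequence[SubjectRecord],
    pair: Sequence[str] = ("PD", "MSA"),
    feature_subset: Sequence[str] | None = None,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = 0.5,
) -> ClassifierResult:
    """Full LOSO evaluation of one group pair on a feature subset (default:
    all 8 features).  Subjects with any missing value in the subset are
    dropped."""
    sub, labels, pos = _pair_data(features, records, pair, feature_subset)
    probs = loso_probabilities(sub, labels, ridge=ridge)
    auc = roc_auc(probs, labels)
    sens, spec = sens_spec(probs, labels, threshold=threshold)
    imp = feature_importance(sub, labels, ridge=ridge)
    return ClassifierResult(
        pair=tuple(pair),
        features=tuple(sub.columns),
        probabilities=probs,
        labels=labels,
        positive=pos,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        importance=imp,
    )


def feature_subset_search(
    features: pd.DataFrame,
    records: Sequence[SubjectRecord],
    pair: Sequence[str] = ("PD", "MSA"),
    candidates: Sequence[str] | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[tuple[str, ...], ClassifierResult, pd.DataFrame]:
    """Exhaustive search over all non-empty feature subsets, ranked by LOSO
    AUC; ties prefer smaller subsets, then canonical feature order.

    Returns (best subset, its ClassifierResult, the full search log as a
    DataFrame with one row per subset).
    """
    if candidates is None:
        candidates = [c for c in FEATURE_NAMES if c in features.columns]
    candidates = list(candidates)
    order = {name: i for i, name in enumerate(FEATURE_NAMES)}
    log_rows = []
    best_key = None
    best_subset: tuple[str, ...] | None = None
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            sub, labels, _ = _pair_data(features, records, pair, subset)
            probs = loso_probabilities(sub, labels, ridge=ridge)
            auc = roc_auc(probs, labels)
            log_rows.append({"subset": ",".join(subset), "size": r, "auc": auc})
            key = (-auc, r, tuple(order.get(f, 99) for f in subset))
            if best_key is None or key < best_key:
                best_key = key
                best_subset = subset
    assert best_subset is not None
    result = classify_pair(features, records, pair, feature_subset=best_subset, ridge=ridge)
    log = pd.DataFrame(log_rows).sort_values(
        ["auc", "size", "subset"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return best_subset, result, log
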