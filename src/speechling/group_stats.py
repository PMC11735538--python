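"""Covariate-adjusted group comparison and clinical correlation.

The primary analysis is a one-way analysis of covariance (ANCOVA) per
feature: a linear model ``feature ~ group + age + sex + topic`` (optionally
plus the MDS-UPDRS III speech item), with the group main effect tested by a
partial F comparing the full model against the covariates-only model.
Pairwise group contrasts use Fisher's least-significant-difference procedure:
t tests on adjusted mean differences with the pooled residual variance and
no multiplicity correction.

Adjusted means are computed by g-computation: every subject's covariates are
kept as observed while their group is set counterfactually, and the model
predictions are averaged.  With covariates orthogonal to group this
reproduces the raw group means.

Clinical correlations are partial correlations by the residual method,
with the correlation flavour (Pearson vs Spearman) gated per clinical
variable by a Shapiro-Wilk normality test at alpha = 0.05.

Tests are two-tailed; alpha = 0.05 throughout.  No multiple-testing
correction is applied across features: the feature set is deliberately small,
which is the design's control on the type-I error budget.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data_model import GROUPS, SubjectRecord, ValidationError

__all__ = [
    "AncovaResult",
    "PosthocEntry",
    "PartialCorrelationResult",
    "records_to_frame",
    "build_design",
    "ancova",
    "fisher_lsd",
    "normality_gate",
    "partial_correlation",
    "clinical_correlations",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PosthocEntry:
    pair: tuple[str, str]
    difference: float  # adjusted mean of pair[0] minus pair[1]
    t: float
    p: float


@dataclass(frozen=True)
class AncovaResult:
    feature: str
    group_F: float
    group_p: float
    adjusted_means: Mapping[str, float]
    residual_df: int
    mse: float
    posthoc: tuple[PosthocEntry, ...]
    covariates_used: tuple[str, ...]
    n: int
    coefficients: Mapping[str, float] = field(default_factory=dict)
    degenerate: bool = False


@dataclass(frozen=True)
class PartialCorrelationResult:
    x: str
    y: str
    method: str  # {pearson, spearman}
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Manifest records as a DataFrame indexed by subject_id, clinical scores
    expanded into columns."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "topic": r.topic,
            "speech_item": np.nan if r.speech_item is None else r.speech_item,
        }
        row.update(r.clinical_scores)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def _collapse_rare_topics(topic: pd.Series, min_count: int) -> pd.Series:
    if min_count <= 1:
        return topic
    counts = topic.value_counts()
    rare = counts[counts < min_count].index
    return topic.where(~topic.isin(rare), "other")


def build_design(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    min_topic_count: int = 1,
    include_group: bool = True,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix with intercept, treatment-coded group, and covariates.

    Categorical covariates (sex, topic) enter as indicator contrasts dropping
    a reference level; numeric covariates enter as-is.  Returns the matrix,
    its column names, and the names of the group-indicator columns.
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    group_cols: list[str] = []
    if include_group:
        levels = [g for g in GROUPS if g in set(frame["group"])]
        if len(levels) < 2:
            raise ValidationError("need at least 2 groups")
        for g in levels[1:]:
            cols.append((frame["group"] == g).to_numpy(float))
            name = f"group[{g}]"
            names.append(name)
            group_cols.append(name)
    for cov in covariates:
        if cov == "sex":
            cols.append((frame["sex"] == "M").to_numpy(float))
            names.append("sex[M]")
        elif cov == "topic":
            topic = _collapse_rare_topics(frame["topic"].astype(str), min_topic_count)
            levels = sorted(topic.unique())
            for lv in levels[1:]:
                cols.append((topic == lv).to_numpy(float))
                names.append(f"topic[{lv}]")
        else:
            vals = frame[cov].to_numpy(float)
            if np.isnan(vals).any():
                raise ValidationError(f"covariate {cov!r} has missing values")
            cols.append(vals)
            names.append(cov)
    return np.column_stack(cols), names, group_cols


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns past the rank are the (a) collinear set
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def ancova(
    features: pd.DataFrame,
    records: Sequence[SubjectRecord],
    feature: str,
    covariates: Sequence[str] = ("age", "sex", "topic"),
    include_speech_item: bool = False,
    min_topic_count: int = 1,
) -> AncovaResult:
    """One-way ANCOVA of one feature across groups, adjusted for covariates.

    Subjects with a missing feature value (or missing speech item when it is
    a covariate) are dropped listwise.  A zero-variance response yields the
    degenerate result F = 0, p = 1.
    """
    frame = records_to_frame(records)
    if feature not in features.columns:
        raise KeyError(f"unknown feature {feature!r}")
    covs = list(covariates)
    if include_speech_item and "speech_item" not in covs:
        covs.append("speech_item")
    y_all = features[feature].astype(float)
    frame = frame.join(y_all.rename("_y"), how="inner")
    keep = frame["_y"].notna()
    if "speech_item" in covs:
        keep &= frame["speech_item"].notna()
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{feature}: dropped {dropped} subjects listwise", stacklevel=2)
    frame = frame[keep]
    n = len(frame)
    y = frame["_y"].to_numpy(float)

    X_full, names, group_cols = build_design(frame, covs, min_topic_count)
    levels = [g for g in GROUPS if g in set(frame["group"])]
    if n <= len(names):
        raise ValidationError(f"{feature}: only {n} usable subjects for {len(names)} parameters")

    if np.ptp(y) == 0:
        means = {g: float(y[0]) for g in levels}
        posthoc = tuple(
            PosthocEntry(pair=p, difference=0.0, t=0.0, p=1.0)
            for p in itertools.combinations(levels, 2)
        )
        return AncovaResult(
            feature=feature, group_F=0.0, group_p=1.0, adjusted_means=means,
            residual_df=n - len(names), mse=0.0, posthoc=posthoc,
            covariates_used=tuple(covs), n=n, degenerate=True,
        )

    _check_rank(X_full, names)
    beta, rss_full = _ols(X_full, y)
    df_resid = n - X_full.shape[1]
    mse = rss_full / df_resid

    keep_cols = [j for j, nm in enumerate(names) if nm not in group_cols]
    X_restricted = X_full[:, keep_cols]
    _, rss_restricted = _ols(X_restricted, y)
    df_num = len(group_cols)
    if mse == 0:
        F, p = np.inf, 0.0
    else:
        F = ((rss_restricted - rss_full) / df_num) / mse
        F = max(F, 0.0)
        p = float(stats.f.sf(F, df_num, df_resid))

    # adjusted means by g-computation; record each group's mean design row
    group_rows: dict[str, np.ndarray] = {}
    adjusted: dict[str, float] = {}
    col_index = {nm: j for j, nm in enumerate(names)}
    for g in levels:
        Xg = X_full.copy()
        for name in group_cols:
            Xg[:, col_index[name]] = 1.0 if name == f"group[{g}]" else 0.0
        row = Xg.mean(axis=0)
        group_rows[g] = row
        adjusted[g] = float(row @ beta)

    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    posthoc = []
    for g1, g2 in itertools.combinations(levels, 2):
        c = group_rows[g1] - group_rows[g2]
        diff = float(c @ beta)
        se = float(np.sqrt(mse * (c @ XtX_inv @ c)))
        t = diff / se if se > 0 else 0.0
        pval = float(2 * stats.t.sf(abs(t), df_resid)) if se > 0 else 1.0
        posthoc.append(PosthocEntry(pair=(g1, g2), difference=diff, t=t, p=pval))

    return AncovaResult(
        feature=feature, group_F=float(F), group_p=p, adjusted_means=adjusted,
        residual_df=df_resid, mse=float(mse), posthoc=tuple(posthoc),
        covariates_used=tuple(covs), n=n,
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
    )


def fisher_lsd(result: AncovaResult, pair: tuple[str, str]) -> PosthocEntry:
    """Look up the LSD contrast for one group pair (order-insensitive; the
    sign of the difference follows the stored pair order)."""
    for entry in result.posthoc:
        if entry.pair == tuple(pair):
            return entry
        if entry.pair == (pair[1], pair[0]):
            return PosthocEntry(
                pair=tuple(pair), difference=-entry.difference, t=-entry.t, p=entry.p
            )
    raise KeyError(f"pair {pair} not in ANCOVA result (groups: {list(result.adjusted_means)})")


def normality_gate(values: Sequence[float], alpha: float = ALPHA) -> str:
    """Shapiro-Wilk gate: ``normal`` (use Pearson) or ``non_normal`` (use
    Spearman).  Constant input is non-normal by convention; n < 3 raises."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError("normality test requires at least 3 observations")
    if np.ptp(arr) == 0:
        return "non_normal"
    stat = stats.shapiro(arr)
    return "normal" if stat.pvalue > alpha else "non_normal"


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    method: str = "pearson",
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Partial correlation of x and y controlling for covariates.

    Residual method: regress x and y each on the covariates (plus intercept)
    and correlate the residuals; for Spearman, all variables are rank
    transformed first.  The p-value uses a t reference with n - k - 2
    degrees of freedom, k the number of covariate columns.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(xv), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    mask = ~(np.isnan(xv) | np.isnan(yv) | np.isnan(Z).any(axis=1))
    xv, yv, Z = xv[mask], yv[mask], Z[mask]
    n = len(xv)
    k = Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    if method == "spearman":
        xv = stats.rankdata(xv)
        yv = stats.rankdata(yv)
        Z = np.column_stack([stats.rankdata(Z[:, j]) for j in range(k)]) if k else Z
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("collinear covariates in partial correlation")
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x=x_name, y=y_name, method=method, r=r, p=p, n=n, covariates=covariate_names
    )


def clinical_correlations(
    features: pd.DataFrame,
    records: Sequence[SubjectRecord],
    clinical_names: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "sex", "topic"),
    group: str | None = None,
) -> list[PartialCorrelationResult]:
    """Partial correlations of every feature against every clinical score,
    Shapiro-Wilk gated per clinical variable, controlling for the covariates.

    ``group`` restricts to one group (clinical scales are typically scored in
    a single diagnostic group).
    """
    frame = records_to_frame(records).join(features, how="inner")
    if group is not None:
        frame = frame[frame["group"] == group]
    if clinical_names is None:
        reserved = {"group", "age", "sex", "topic", "speech_item", *features.columns}
        clinical_names = [c for c in frame.columns if c not in reserved]
    results = []
    for clin in clinical_names:
        sub = frame[frame[clin].notna()]
        if len(sub) < 3:
            continue
        gate = normality_gate(sub[clin])
        method = "pearson" if gate == "normal" else "spearman"
        Z_cols = []
        names: list[str] = []
        for cov in covariates:
            if cov == "sex":
                Z_cols.append((sub["sex"] == "M").to_numpy(float))
                names.append("sex")
            elif cov == "topic":
                levels = sorted(sub["topic"].unique())
                for lv in levels[1:]:
                    Z_cols.append((sub["topic"] == lv).to_numpy(float))
                names.append("topic")
            else:
                Z_cols.append(sub[cov].to_numpy(float))
                names.append(cov)
        Z = np.column_stack(Z_cols) if Z_cols else None
        for feat in features.columns:
            pair = sub[[feat, clin]].dropna()
            if len(pair) < (0 if Z is None else Z.shape[1]) + 3:
                continue
            mask = sub[feat].notna() & sub[clin].notna()
            try:
                res = partial_correlation(
                    sub.loc[mask, feat],
                    sub.loc[mask, clin],
                    covariates=Z[mask.to_numpy()] if Z is not None else None,
                    method=method,
                    x_name=feat,
                    y_name=clin,
                    covariate_names=tuple(names),
                )
            except (ValueError, ValidationError):
                continue
            results.append(res)
    return results
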