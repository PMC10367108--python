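"""CRT-response classification.

A logistic-regression classifier on a hybrid table of clinical covariates
and model-derived dyssynchrony indices.  Preprocessing standardizes
non-categorical columns and removes one column of every pair whose absolute
Pearson correlation exceeds 0.85.  Honest evaluation uses leave-one-out
cross-validation with feature selection refitted inside every fold.  The
classifier's output probability is the ML-score; the default decision
cutoff is 0.51.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

#: the seven features of the final response model
DEFAULT_FEATURES = (
    "lvef", "bmi", "edd",
    "scar_lvps", "tat95_LBBB", "ad_rvlv_LBBB", "ad_rvlv_BiV",
)

SELECTORS = ("univariate-rank", "L1-path", "recursive-elimination")


@dataclass
class PreprocessStats:
    """Fitted normalization transform and filter decisions."""

    means: pd.Series
    sds: pd.Series
    kept: list[str]
    dropped_correlated: list[str]
    dropped_zero_variance: list[str]
    categorical: tuple[str, ...] = ()

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df[self.kept].copy()
        for c in self.kept:
            if c not in self.categorical:
                out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


#: distance (mm) standing in for "no scar anywhere": beyond any geodesic
#: distance attainable on the synthetic ventricles
SCAR_DISTANCE_CEILING = 120.0

def impute_missing(df: pd.DataFrame, fallbacks: dict | None = None) -> pd.DataFrame:
    """Fill missing values with the per-column maximum.

    Used for the scar-distance feature of scar-free models, where "missing"
    means "as far from scar as possible"; a missing value is never silently
    treated as zero.  A column that is missing everywhere needs an entry in
    ``fallbacks`` and raises otherwise; by default the scar-distance column
    of an entirely scar-free cohort falls back to the distance ceiling.
    """
    if fallbacks is None:
        fallbacks = {"scar_lvps": SCAR_DISTANCE_CEILING}
    out = df.copy()
    for c in out.columns:
        if out[c].isna().any():
            mx = out[c].max()
            if np.isnan(mx):
                if fallbacks and c in fallbacks:
                    mx = fallbacks[c]
                else:
                    raise ValueError(f"column {c!r} is entirely missing")
            out[c] = out[c].fillna(mx)
    return out


def preprocess(
    df: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    corr_threshold: float = 0.85,
) -> tuple[pd.DataFrame, PreprocessStats]:
    """Standardize, drop zero-variance columns, filter correlated pairs.

    For each pair with |Pearson r| > ``corr_threshold`` the later column (in
    the documented column order) is dropped.
    """
    if len(df) < 2:
        raise ValueError("need at least two rows")
    df = impute_missing(df)
    numeric = [c for c in df.columns if c not in categorical]

    dropped_zv = [c for c in numeric if df[c].std(ddof=0) == 0]
    if dropped_zv:
        log.warning("dropping zero-variance columns: %s", dropped_zv)
    cols = [c for c in df.columns if c not in dropped_zv]

    means = df[cols].mean()
    sds = df[cols].std(ddof=0)
    std = df[cols].copy()
    for c in cols:
        if c not in categorical:
            std[c] = (std[c] - means[c]) / sds[c]

    corr = std.corr().abs()
    kept: list[str] = []
    dropped_corr: list[str] = []
    for c in cols:
        if any(corr.loc[c, k] > corr_threshold for k in kept):
            dropped_corr.append(c)
        else:
            kept.append(c)
    if not kept:
        raise ValueError("all columns removed by preprocessing")

    stats = PreprocessStats(
        means=means[kept], sds=sds[kept], kept=kept,
        dropped_correlated=dropped_corr, dropped_zero_variance=dropped_zv,
        categorical=categorical,
    )
    return std[kept], stats


def _fit_lr(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit, ridge fallback on separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        lr.fit(X, y)
    if not np.isfinite(lr.coef_).all() or np.abs(lr.coef_).max() > 50.0:
        log.warning("near-perfect separation; refitting with weak ridge penalty")
        lr = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000)
        lr.fit(X, y)
    return lr


def _select_features(
    X: pd.DataFrame, y: np.ndarray, selector: str, n_select: int
) -> list[str]:
    n_select = min(n_select, X.shape[1])
    if selector == "univariate-rank":
        with warnings.catch_warnings():
            # tiny folds can have zero between-group variance; scored as 0
            warnings.simplefilter("ignore", RuntimeWarning)
            score, _ = f_classif(X.values, y)
        score = np.nan_to_num(score)
        order = np.argsort(-score, kind="stable")
        return [X.columns[i] for i in order[:n_select]]
    if selector == "L1-path":
        # walk the l1 path from strong to weak penalty; rank features by the
        # penalty strength at which their coefficient first becomes active
        entry = {c: np.inf for c in X.columns}
        for rank, C in enumerate(np.logspace(-2, 2, 25)):
            lr = LogisticRegression(l1_ratio=1, C=C, solver="liblinear", max_iter=500)
            lr.fit(X.values, y)
            for c, w in zip(X.columns, lr.coef_[0]):
                if w != 0 and entry[c] == np.inf:
                    entry[c] = rank
            if sum(v < np.inf for v in entry.values()) >= n_select:
                break
        order = sorted(X.columns, key=lambda c: (entry[c], list(X.columns).index(c)))
        return list(order[:n_select])
    if selector == "recursive-elimination":
        est = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
        rfe = RFE(est, n_features_to_select=n_select)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            rfe.fit(X.values, y)
        return [c for c, s in zip(X.columns, rfe.support_) if s]
    raise ValueError(f"unknown selector {selector!r}; choose from {SELECTORS}")


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome."""

    scores: np.ndarray               # held-out ML-score per patient
    labels: np.ndarray
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    cutoff: float
    selection_frequency: dict[str, float]


def loo_cv(
    df: pd.DataFrame,
    labels,
    selector: str = "univariate-rank",
    n_select: int = 7,
    cutoff: float = 0.51,
    categorical: tuple[str, ...] = (),
) -> CVResult:
    """Leave-one-out CV with per-fold preprocessing and feature selection.

    All fitting — normalization statistics, the correlation filter, feature
    selection and the logistic fit — uses only the n-1 training rows of each
    fold, so the held-out score is free of selection bias.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    n = len(df)
    scores = np.empty(n)
    counts: dict[str, int] = {c: 0 for c in df.columns}
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, stats = preprocess(df.iloc[tr], categorical=categorical)
        feats = _select_features(Xtr, y[tr], selector, n_select)
        lr = _fit_lr(Xtr[feats].values, y[tr])
        # transform the held-out row with *training* statistics
        row = impute_missing(pd.concat([df.iloc[tr], df.iloc[[i]]])).iloc[[-1]]
        xt = stats.transform(row)[feats].values
        scores[i] = lr.predict_proba(xt)[0, 1]
        for c in feats:
            counts[c] += 1

    pred = scores > cutoff
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return CVResult(
        scores=scores,
        labels=y,
        auc=roc_auc(scores, y),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        cutoff=cutoff,
        selection_frequency={c: counts[c] / n for c in df.columns},
    )


@dataclass
class LRModel:
    """Final logistic response model on the normalized feature scale."""

    features: list[str]
    coef: np.ndarray
    intercept: float
    means: pd.Series
    sds: pd.Series
    cutoff: float = 0.51

    def __post_init__(self):
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if len(self.coef) != len(self.features):
            raise ValueError("one coefficient per feature required")


def train_final(
    df: pd.DataFrame,
    labels,
    feature_list=DEFAULT_FEATURES,
    cutoff: float = 0.51,
) -> LRModel:
    """Fit the final logistic model on the full table, selected features only."""
    missing = [f for f in feature_list if f not in df.columns]
    if missing:
        raise KeyError(f"features absent from the table: {missing}")
    y = np.asarray(labels).astype(int)
    sub = impute_missing(df[list(feature_list)])
    means = sub.mean()
    sds = sub.std(ddof=0).replace(0.0, 1.0)
    X = ((sub - means) / sds).values
    lr = _fit_lr(X, y)
    return LRModel(
        features=list(feature_list),
        coef=lr.coef_[0].copy(),
        intercept=float(lr.intercept_[0]),
        means=means,
        sds=sds,
        cutoff=cutoff,
    )


def ml_score(model: LRModel, record) -> float:
    """Probability of positive CRT response for one feature record."""
    if isinstance(record, pd.Series):
        record = record.to_dict()
    x = []
    for f in model.features:
        if f not in record or record[f] is None or (
            isinstance(record[f], float) and np.isnan(record[f])
        ):
            raise KeyError(f"missing feature {f!r}")
        x.append((record[f] - model.means[f]) / model.sds[f])
    z = model.intercept + float(np.dot(model.coef, x))
    return float(1.0 / (1.0 + np.exp(-z)))


def classify(model: LRModel, record) -> bool:
    """Positive response prediction iff ML-score exceeds the cutoff."""
    return ml_score(model, record) > model.cutoff


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties count one half)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
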