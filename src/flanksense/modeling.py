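"""Feature pruning, train/test split, normalization and the four classifiers.

The modeling stage is deliberately plain tabular machine learning: prune
highly collinear window features with a greedy pairwise-correlation filter,
split rows 75/25 at random, z-score both partitions with training-set
statistics, and fit one of four standard classifiers (random forest,
k-nearest-neighbors, gradient-boosted trees, RBF support vector machine).
Classifier hyperparameters are package defaults, overridable per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES

ALGORITHMS = ("RF", "KNN", "XGB", "SVM")

DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "RF": {"n_estimators": 500, "max_features": "sqrt"},
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "XGB": {"n_estimators": 200, "max_depth": 6, "learning_rate": 0.3},
    "SVM": {"C": 1.0, "kernel": "rbf", "gamma": "auto"},  # gamma = 1/p
}


@dataclass
class PruneResult:
    removed: list[str]
    retained: list[str]
    correlation_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.removed) & set(self.retained):
            raise ValueError("removed and retained overlap")


def prune_correlated(
    table: pd.DataFrame,
    cutoff: float = 0.8,
    feature_cols: Sequence[str] | None = None,
) -> PruneResult:
    """Greedy removal of highly correlated features.

    While any retained pair has absolute Pearson correlation ≥ ``cutoff``,
    take the worst such pair and drop the member with the larger mean
    absolute correlation against all other retained features (ties break on
    column order).  Constant columns cannot enter a correlation and are
    removed up front.  Deterministic given the table.
    """
    cols = list(feature_cols) if feature_cols is not None else [c for c in FEATURE_NAMES if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 feature columns to prune")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")

    x = table[cols].to_numpy(float)
    constant = [c for c, s in zip(cols, x.std(axis=0)) if s == 0]
    live = [c for c in cols if c not in constant]
    corr = table[live].corr().abs()

    removed = list(constant)
    keep = list(live)
    c = corr.to_numpy().copy()
    np.fill_diagonal(c, 0.0)
    alive = np.ones(len(live), bool)
    while True:
        sub = np.where(np.outer(alive, alive), c, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < cutoff:
            break
        # mean |r| against all other live features decides the victim
        mi = sub[i, alive].sum() / (alive.sum() - 1)
        mj = sub[j, alive].sum() / (alive.sum() - 1)
        victim = i if (mi > mj or (mi == mj and i < j)) else j
        alive[victim] = False
        removed.append(live[victim])
    keep = [f for f, a in zip(live, alive) if a]

    result = PruneResult(removed=removed, retained=keep, correlation_matrix=corr)
    # post-state guarantee
    if keep:
        resid = corr.loc[keep, keep].to_numpy().copy()
        np.fill_diagonal(resid, 0.0)
        assert resid.max(initial=0.0) < cutoff
    return result


@dataclass
class Normalization:
    """Per-feature z-scoring statistics learned on the training rows."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.mean.index] = (table[self.mean.index] - self.mean) / self.sd
        return out


@dataclass
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_and_normalize(
    table: pd.DataFrame,
    spec: SplitSpec,
    feature_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, Normalization]:
    """Uniform random row split plus training-statistics z-scoring.

    The split is simple random (not stratified, not grouped by animal);
    both partitions are normalized with the training partition's per-column
    mean and (n−1) standard deviation.  Deterministic given ``spec.seed``.
    Raises if any feature is constant on the training rows.
    """
    if table.empty:
        raise ValueError("cannot split an empty table")
    cols = list(feature_cols) if feature_cols is not None else [c for c in FEATURE_NAMES if c in table.columns]

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(table))
    n_train = int(round(spec.train_fraction * len(table)))
    train = table.iloc[order[:n_train]].reset_index(drop=True)
    test = table.iloc[order[n_train:]].reset_index(drop=True)

    mean = train[cols].mean()
    sdev = train[cols].std(ddof=1)
    dead = sdev.index[(sdev == 0) | sdev.isna()]
    if len(dead):
        raise ValueError(f"feature(s) constant on the training rows: {list(dead)}")
    norm = Normalization(mean=mean, sd=sdev)
    return norm.transform(train), norm.transform(test), norm


@dataclass
class ModelSpec:
    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def params(self) -> dict[str, Any]:
        return {**DEFAULT_HYPERPARAMS[self.algorithm], **self.hyperparameters}


def _build_estimator(spec: ModelSpec):
    p = spec.params()
    if spec.algorithm == "RF":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(**p)
    if spec.algorithm == "SVM":
        return SVC(random_state=spec.seed, **p)
    return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0, **p)


def fit_predict(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: Sequence[str],
    label_col: str,
) -> np.ndarray:
    """Train the requested classifier and predict the test rows' labels.

    Expects pruned, normalized tables.  Seeded backends (RF, XGB, SVM
    tie-breaking) are reproducible given ``spec.seed``.  A class present in
    test but absent from train simply cannot be predicted; the metrics
    layer accounts for it.
    """
    xtr = train[list(feature_cols)].to_numpy(float)
    xte = test[list(feature_cols)].to_numpy(float)
    ytr = train[label_col].to_numpy()

    est = _build_estimator(spec)
    if spec.algorithm == "XGB":
        # xgboost wants integer class codes; softmax objective once the
        # problem is genuinely multi-class
        enc = LabelEncoder().fit(ytr)
        if len(enc.classes_) > 2:
            est.set_params(objective="multi:softmax", num_class=len(enc.classes_))
        est.fit(xtr, enc.transform(ytr))
        return enc.inverse_transform(est.predict(xte))
    est.fit(xtr, ytr)
    return est.predict(xte)
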