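"""Feature assembly and cross-validated naive Bayes discrimination."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.naive_bayes import GaussianNB

from .coherence import CoherenceProfile, TrajectoryFit
from .lexical import LexicalProfile
from .pos import POS_CATEGORIES, POSProfile
from .stats import ClinicalRatings

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ClassificationResult",
    "FEATURE_SETS",
    "build_features",
    "preprocess",
    "cross_validate_nb",
    "roc_auc",
]

FEATURE_SETS = (
    "clinical",
    "nlp",
    "combined",
    "clinical_edu",
    "nlp_edu",
    "combined_edu",
)

POSITIVE_LABEL = "SSD"


@dataclass
class FeatureMatrix:
    data: pd.DataFrame  # one row per participant, index = participant_id
    labels: pd.Series  # aligned with data
    feature_set: str

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels must align with feature rows")
        if self.labels.isna().any():
            raise ValueError("every participant needs a label")


@dataclass
class ClassificationResult:
    feature_set: str
    cv_scheme: str
    probabilities: pd.Series  # out-of-fold P(positive class)
    auc: float
    accuracy: float
    dropped_features: list[str]


def build_features(
    labels: Mapping[str, str],
    feature_set: str,
    ratings: Mapping[str, ClinicalRatings] | None = None,
    lexical: Mapping[str, LexicalProfile] | None = None,
    pos: Mapping[str, POSProfile] | None = None,
    coherence: Mapping[str, CoherenceProfile] | None = None,
    trajectories: Mapping[str, TrajectoryFit | None] | None = None,
    word_aggregate: Mapping[str, float] | None = None,
    education: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Assemble the requested per-participant feature matrix.

    Feature sets: ``clinical`` = 18 TLC items + global + total; ``nlp`` =
    word-score aggregate, mean NSP, trajectory intercept/slope, ten POS
    rates, incomplete-word count, uh:um ratio; ``combined`` = union. A
    ``*_edu`` suffix appends education years as a predictor. Missing values
    (e.g., undefined uh:um ratio) stay as NaN for fold-wise imputation.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}; choose from {FEATURE_SETS}")
    base = feature_set.removesuffix("_edu")
    with_edu = feature_set.endswith("_edu")
    pids = sorted(labels)
    rows: dict[str, dict[str, float]] = {pid: {} for pid in pids}

    def put(pid: str, name: str, value) -> None:
        rows[pid][name] = np.nan if value is None else float(value)

    if base in ("clinical", "combined"):
        if ratings is None:
            raise ValueError("clinical feature set requires ratings")
        for pid in pids:
            r = ratings[pid]
            for i, v in enumerate(r.items, start=1):
                put(pid, f"tlc_item_{i}", v)
            put(pid, "tlc_global", r.global_score)
            put(pid, "tlc_total", r.total)

    if base in ("nlp", "combined"):
        for pid in pids:
            put(pid, "wordscore_sum", (word_aggregate or {}).get(pid))
            cp = (coherence or {}).get(pid)
            put(pid, "mean_nsp", cp.mean_nsp if cp is not None else None)
            tf = (trajectories or {}).get(pid)
            put(pid, "traj_intercept", tf.intercept if tf is not None else None)
            put(pid, "traj_slope", tf.slope if tf is not None else None)
            pp = (pos or {}).get(pid)
            for cat in POS_CATEGORIES:
                put(pid, f"pos_{cat}", pp.rates[cat] if pp is not None else None)
            lp = (lexical or {}).get(pid)
            put(pid, "incomplete_count", lp.incomplete_count if lp is not None else None)
            put(pid, "uh_um_ratio", lp.uh_um_ratio if lp is not None else None)

    if with_edu:
        for pid in pids:
            put(pid, "education_years", (education or {}).get(pid))

    data = pd.DataFrame.from_dict(rows, orient="index").loc[pids]
    empty = data.index[data.isna().all(axis=1)]
    if len(empty):
        raise ValueError(f"participants with no features: {list(empty)}")
    return FeatureMatrix(
        data=data,
        labels=pd.Series({pid: labels[pid] for pid in pids}).loc[pids],
        feature_set=feature_set,
    )


def preprocess(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Impute (training-fold mean) then z-score (training-fold mean/SD).

    Statistics come from the training fold only; SD uses n-1 weighting so a
    3-point column standardizes to exact unit steps. Constant columns map
    to zeros; columns entirely missing in the training fold are dropped
    (and reported) for that fold.
    """
    means = train.mean(axis=0, skipna=True)
    dropped = [str(c) for c in train.columns[means.isna()]]
    if dropped:
        logger.info("preprocess: dropping all-missing features %s", dropped)
    cols = [c for c in train.columns if c not in dropped]

    tr = train[cols].fillna(means[cols])
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=1).replace(0.0, np.nan)
    tr_z = ((tr - mu) / sd).fillna(0.0)

    te_z = None
    if test is not None:
        te = test[cols].fillna(means[cols])
        te_z = ((te - mu) / sd).fillna(0.0).to_numpy(dtype=float)
    return tr_z.to_numpy(dtype=float), te_z, dropped


def roc_auc(scores: Sequence[float], labels: Sequence[str | int]) -> float:
    """AUC as the probability a random positive outscores a random negative.

    Ties count one half (Mann-Whitney identity, computed via midranks).
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    return (arr == POSITIVE_LABEL).astype(int)


def _loo_folds(n: int):
    for i in range(n):
        yield [j for j in range(n) if j != i], [i]


def _stratified_kfold(y: np.ndarray, k: int, seed: int):
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(j for f in folds[:i] + folds[i + 1 :] for j in f)
        yield train, test


def cross_validate_nb(
    matrix: FeatureMatrix,
    scheme: str = "loo",
    k: int = 5,
    seed: int = 0,
) -> ClassificationResult:
    """Gaussian naive Bayes with out-of-fold probability predictions.

    Per-fold preprocessing (imputation + standardization) uses training-fold
    statistics only. Class priors come from training-fold frequencies
    (scikit-learn default). Accuracy thresholds P(positive) at 0.5; AUC is
    computed over the pooled out-of-fold probabilities.
    """
    y = _binary_labels(matrix.labels.to_numpy())
    n = len(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 participants per class")

    if scheme == "loo":
        folds = _loo_folds(n)
        scheme_name = "loo"
    elif scheme in ("kfold", f"kfold({k})"):
        folds = _stratified_kfold(y, k, seed)
        scheme_name = f"kfold({k})"
    else:
        raise ValueError(f"unknown cv scheme {scheme!r}")

    probs = np.full(n, np.nan)
    dropped_all: list[str] = []
    for train_idx, test_idx in folds:
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training fold lost a class; reduce k or add data")
        X_tr, X_te, dropped = preprocess(
            matrix.data.iloc[train_idx], matrix.data.iloc[test_idx]
        )
        dropped_all.extend(d for d in dropped if d not in dropped_all)
        clf = GaussianNB()
        clf.fit(X_tr, y_tr)
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        probs[test_idx] = clf.predict_proba(X_te)[:, pos_col]

    assert not np.isnan(probs).any()
    accuracy = float(np.mean((probs >= 0.5).astype(int) == y))
    auc = roc_auc(probs, y)
    return ClassificationResult(
        feature_set=matrix.feature_set,
        cv_scheme=scheme_name,
        probabilities=pd.Series(probs, index=matrix.data.index),
        auc=auc,
        accuracy=accuracy,
        dropped_features=dropped_all,
    )
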