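"""Group-comparison statistics: normality, rank tests, outliers, ANCOVA,
effect sizes, and clinician-rating score arithmetic."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRatings",
    "GroupTestResult",
    "tlc_total",
    "read_ratings_csv",
    "write_ratings_csv",
    "shapiro_normality",
    "wilcoxon_rank_sum",
    "boxplot_outliers",
    "cohens_d",
    "ancova_group_effect",
    "group_linear_model",
    "write_results_table",
]

N_ITEMS = 18
_ITEM_RANGE = range(0, 5)


def tlc_total(items: Sequence[int]) -> int:
    """Total score: 2 * (sum of items 1-11) + (sum of items 12-18)."""
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if int(v) != v or v not in _ITEM_RANGE:
            raise ValueError(f"item {i} value {v!r} outside 0..4")
    return 2 * sum(int(v) for v in items[:11]) + sum(int(v) for v in items[11:])


@dataclass
class ClinicalRatings:
    participant_id: str
    items: list[int]
    global_score: int
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if self.global_score not in _ITEM_RANGE:
            raise ValueError(f"global score {self.global_score} outside 0..4")
        self.total = tlc_total(self.items)


@dataclass
class GroupTestResult:
    feature: str
    test: str  # wilcoxon | ancova | linear_model
    statistic: float
    p_value: float
    cohens_d: float
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def read_ratings_csv(path: str | Path) -> list[ClinicalRatings]:
    """Read ratings (participant_id, tlc_item_1..tlc_item_18, tlc_global)."""
    df = pd.read_csv(path)
    cols = [f"tlc_item_{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols + ["participant_id", "tlc_global"] if c not in df.columns]
    if missing:
        raise ValueError(f"ratings CSV missing columns: {missing}")
    return [
        ClinicalRatings(
            participant_id=str(row["participant_id"]),
            items=[int(row[c]) for c in cols],
            global_score=int(row["tlc_global"]),
        )
        for _, row in df.iterrows()
    ]


def write_ratings_csv(ratings: Sequence[ClinicalRatings], path: str | Path) -> None:
    rows = []
    for r in ratings:
        row = {"participant_id": r.participant_id}
        row.update({f"tlc_item_{i + 1}": v for i, v in enumerate(r.items)})
        row["tlc_global"] = r.global_score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p. Constant input reports non-normal."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: normality undefined, reported non-normal")
        return float("nan"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    return float(stat), float(p)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when min(n) <= 8 and the pooled sample has no ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction, matching the exact-p conventions in the examples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def boxplot_outliers(values: Sequence[float]) -> list[int]:
    """Indices outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interp quartiles)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        logger.warning("boxplot_outliers: n=%d < 4, no outliers flagged", len(x))
        return []
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [int(i) for i in np.flatnonzero((x < lo) | (x > hi))]


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """(mean_a - mean_b) / pooled SD, pooled with n-1 weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


_CATEGORICAL_COVARIATES = frozenset({"sex", "race", "cohort"})


def _design_matrix(
    groups: Sequence[str],
    covariates: Mapping[str, Sequence] | pd.DataFrame | None,
    group_a: str,
) -> pd.DataFrame:
    n = len(groups)
    cols: dict[str, np.ndarray] = {
        "const": np.ones(n),
        "group": np.array([1.0 if g == group_a else 0.0 for g in groups]),
    }
    if covariates is not None:
        cov_df = pd.DataFrame(dict(covariates))
        if len(cov_df) != n:
            raise ValueError("covariates must align with observations")
        for name in cov_df.columns:
            col = cov_df[name]
            if name in _CATEGORICAL_COVARIATES or col.dtype == object:
                # one-hot with first-observed level as reference
                levels = list(dict.fromkeys(col))
                for lev in levels[1:]:
                    cols[f"{name}[{lev}]"] = (col == lev).to_numpy(dtype=float)
            else:
                cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for col in X.columns:
            if col == "const":
                continue
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _fit_group_model(
    feature: str,
    values: Sequence[float],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence] | pd.DataFrame | None,
    test_name: str,
    group_a: str,
    group_b: str,
) -> GroupTestResult:
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    keep = ~np.isnan(y)
    if not keep.all():
        y = y[keep]
        groups = [g for g, k in zip(groups, keep) if k]
        if covariates is not None:
            covariates = pd.DataFrame(dict(covariates)).loc[np.asarray(keep)].reset_index(drop=True)
    if sum(g == group_a for g in groups) < 2 or sum(g == group_b for g in groups) < 2:
        raise ValueError("need at least 2 participants per group")

    a_vals = y[[g == group_a for g in groups]]
    b_vals = y[[g == group_b for g in groups]]
    try:
        d = cohens_d(a_vals, b_vals)
    except ValueError:
        d = 0.0

    X = _design_matrix(groups, covariates, group_a)
    # drop covariate columns with no variance (degenerate limit = plain ANOVA)
    for col in [c for c in X.columns if c not in ("const", "group")]:
        if np.ptp(X[col].to_numpy()) == 0:
            X = X.drop(columns=[col])
    cov_names = tuple(c for c in X.columns if c not in ("const", "group"))
    _check_rank(X)

    if np.ptp(y) == 0:
        return GroupTestResult(feature, test_name, 0.0, 1.0, d, cov_names)

    model = sm.OLS(y, X).fit()
    tstat = float(model.tvalues["group"])
    p = float(model.pvalues["group"])
    ssr = float(np.sum(model.resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if math.isnan(p) or (sst > 0 and ssr <= 1e-12 * sst):
        # numerically perfect fit: standard errors are float noise; decide
        # on the group coefficient alone
        scale = math.sqrt(sst / len(y))
        if abs(model.params["group"]) > 1e-8 * max(scale, 1.0):
            tstat, p = math.inf, 0.0
        else:
            tstat, p = 0.0, 1.0
    return GroupTestResult(feature, test_name, tstat, p, d, cov_names)


def ancova_group_effect(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence] | pd.DataFrame | None = None,
    feature: str = "",
    group_a: str = "SSD",
    group_b: str = "HC",
) -> GroupTestResult:
    """Group effect from a linear model adjusting for covariates.

    ``sex``/``race``/``cohort`` (and any object-dtype column) are one-hot
    encoded with the first observed level as reference. Cohen's d is
    computed from raw group means and pooled SD, unadjusted.
    """
    return _fit_group_model(feature, values, groups, covariates, "ancova", group_a, group_b)


def group_linear_model(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence] | pd.DataFrame | None = None,
    feature: str = "",
    group_a: str = "SSD",
    group_b: str = "HC",
) -> GroupTestResult:
    """Linear model of a continuous outcome on group + covariates."""
    return _fit_group_model(
        feature, values, groups, covariates, "linear_model", group_a, group_b
    )


def write_results_table(results: Sequence[GroupTestResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "d": [r.cohens_d for r in results],
            "covariates": ["+".join(r.covariates) for r in results],
        }
    ).to_csv(path, index=False)
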