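"""Statistical selection of discriminating network attributes.

Edge attributes are compared between the true and false networks with
Welch two-sample t-tests (Bonferroni-adjusted over the four attributes) and
against the STRING combined score with Pearson correlation; node attributes
are ranked by a ridge-penalized logistic regression and a random forest,
aggregated by mean rank, with a stratified cross-validated ROC AUC as the
overall separation score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .edge_metrics import EDGE_ATTRIBUTES, FALSE_EDGE, TRUE_EDGE
from .node_metrics import NODE_ATTRIBUTES, FALSE_NET, TRUE_NET


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    n: int


@dataclass(frozen=True)
class TwoSampleTestResult:
    attribute: str
    t_stat: float
    df: float
    p_value: float
    adjusted_p: float


@dataclass
class EdgeAttributeRanking:
    """Welch-test results for the four edge attributes, sorted by adjusted p.

    ``best_attribute`` is None when the ranking is inconclusive (no attribute
    reaches adjusted p < 1).
    """

    results: list[TwoSampleTestResult]
    best_attribute: Optional[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "attribute": r.attribute,
                    "t": r.t_stat,
                    "df": r.df,
                    "p": r.p_value,
                    "adjusted_p": r.adjusted_p,
                }
                for r in self.results
            ]
        )


@dataclass
class FeatureImportanceReport:
    """Per-attribute importances from the two classifiers plus CV separation."""

    table: pd.DataFrame  # attribute, linear_importance, forest_importance, mean_rank
    roc_auc: float
    n_folds: int

    @property
    def best_attribute(self) -> str:
        return str(self.table.iloc[0]["attribute"])


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation; errors on constant input."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("sequences must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    for name, arr in (("x", xa), ("y", ya)):
        if np.ptp(arr) == 0:
            raise ValueError(f"variable {name} is constant (zero variance)")
    r = float(stats.pearsonr(xa, ya).statistic)
    return CorrelationResult("x", "y", r, len(xa))


def correlate_edge_attributes(true_rows: pd.DataFrame) -> list[CorrelationResult]:
    """Correlate the STRING combined score with each link-prediction attribute.

    *true_rows* must be TRUE_EDGE rows carrying ``string_score``.
    """
    rows = true_rows[true_rows["origin"] == TRUE_EDGE]
    if rows["string_score"].isna().any():
        raise ValueError("true-edge rows must all carry a string_score")
    score = rows["string_score"].to_numpy(dtype=float)
    out = []
    for attr in EDGE_ATTRIBUTES:
        res = pearson_r(score, rows[attr].to_numpy(dtype=float))
        out.append(CorrelationResult("string_score", attr, res.r, res.n))
    return out


def correlate_node_attributes(rows: pd.DataFrame) -> pd.DataFrame:
    """6x6 symmetric Pearson correlation matrix over the node attributes.

    Rows must belong to a single origin. A constant attribute yields NaN in
    its row/column (undefined, not fatal).
    """
    if rows["origin"].nunique() != 1:
        raise ValueError("rows must belong to a single origin network")
    if len(rows) < 3:
        raise ValueError("need at least 3 rows")
    mat = pd.DataFrame(
        np.eye(len(NODE_ATTRIBUTES)), index=NODE_ATTRIBUTES, columns=NODE_ATTRIBUTES
    )
    for i, a in enumerate(NODE_ATTRIBUTES):
        for b in NODE_ATTRIBUTES[i + 1 :]:
            try:
                r = pearson_r(rows[a], rows[b]).r
            except ValueError:
                r = np.nan
            mat.loc[a, b] = mat.loc[b, a] = r
        if np.ptp(rows[a].to_numpy(dtype=float)) == 0:
            mat.loc[a, a] = np.nan
    return mat


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float], m_tests: int = 1
) -> TwoSampleTestResult:
    """Welch unequal-variance t-test, two-sided, with Welch-Satterthwaite df.

    ``adjusted_p`` is the Bonferroni-adjusted p for a family of *m_tests*.
    """
    a, b = _as_array(sample_a, "sample_a"), _as_array(sample_b, "sample_b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            # identical constants: no evidence of difference
            return TwoSampleTestResult("", 0.0, float(len(a) + len(b) - 2), 1.0, 1.0)
        raise ValueError("both samples are constant (zero pooled variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return TwoSampleTestResult(
        "", float(res.statistic), float(res.df), p, min(1.0, m_tests * p)
    )


def rank_edge_attributes(
    true_rows: pd.DataFrame, false_rows: pd.DataFrame
) -> EdgeAttributeRanking:
    """One Welch test per edge attribute (true vs false rows), Bonferroni m=4.

    Results are sorted by ascending adjusted p; the top attribute is the
    discriminating edge attribute (None when nothing separates).
    """
    if len(true_rows) == 0 or len(false_rows) == 0:
        raise ValueError("both row sets must be non-empty")
    results = []
    for attr in EDGE_ATTRIBUTES:
        r = welch_t_test(true_rows[attr], false_rows[attr], m_tests=len(EDGE_ATTRIBUTES))
        results.append(
            TwoSampleTestResult(attr, r.t_stat, r.df, r.p_value, r.adjusted_p)
        )
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.attribute))
    best = results[0].attribute if results[0].adjusted_p < 1.0 else None
    return EdgeAttributeRanking(results, best)


def rank_node_attributes(
    true_rows: pd.DataFrame,
    false_rows: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
) -> FeatureImportanceReport:
    """Rank node attributes by their power to separate true from false networks.

    A ridge-penalized logistic regression (on standardized features) and a
    200-tree random forest are fit to origin labels; per-attribute
    importances are |standardized coefficient| and mean impurity decrease,
    aggregated by mean rank (ties broken by the linear importance). The
    separation score is the stratified ``n_folds``-fold cross-validated ROC
    AUC of the logistic model on all six attributes.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    frames = []
    for rows, label in ((true_rows, 1), (false_rows, 0)):
        f = rows.loc[:, list(NODE_ATTRIBUTES)].astype(float).copy()
        f["label"] = label
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    y = data.pop("label").to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both origins must be represented")
    X = data.to_numpy()

    scaler = StandardScaler().fit(X)
    linear = LogisticRegression(C=1.0, max_iter=5000)
    linear.fit(scaler.transform(X), y)
    linear_imp = np.abs(linear.coef_[0])

    forest = RandomForestClassifier(n_estimators=200, random_state=seed)
    forest.fit(X, y)
    forest_imp = forest.feature_importances_

    # rank 1 = most important within each method
    lin_rank = stats.rankdata(-linear_imp, method="average")
    for_rank = stats.rankdata(-forest_imp, method="average")
    mean_rank = (lin_rank + for_rank) / 2.0

    table = pd.DataFrame(
        {
            "attribute": NODE_ATTRIBUTES,
            "linear_importance": linear_imp,
            "forest_importance": forest_imp,
            "linear_rank": lin_rank,
            "forest_rank": for_rank,
            "mean_rank": mean_rank,
        }
    ).sort_values(
        ["mean_rank", "linear_importance"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = make_pipeline(
        StandardScaler(), LogisticRegression(C=1.0, max_iter=5000)
    )
    auc = float(np.mean(cross_val_score(model, X, y, cv=cv, scoring="roc_auc")))
    return FeatureImportanceReport(table=table, roc_auc=auc, n_folds=n_folds)
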