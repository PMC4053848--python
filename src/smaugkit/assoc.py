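"""Relating SRE scores to binding and repression: regression, rank
correlation, group medians and overlap statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ti import wilcoxon_rank_sum


def ols_regression(response, predictors: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least squares with intercept; returns a coefficient table
    (coef, se, t, p).  Rank-deficient designs raise, naming the collinear
    columns."""
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="raise")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    bad = []
    arr = design.to_numpy()
    full_rank = np.linalg.matrix_rank(arr)
    for i, c in enumerate(cols):
        reduced = np.delete(arr, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(c)
    return bad


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (tie-averaged ranks) with t-approximation
    p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_medians(scores: pd.Series, labels: pd.Series
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group medians plus pairwise Wilcoxon rank-sum p-values."""
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    by = {g: scores[labels == g] for g in groups}
    for g, vals in by.items():
        if vals.empty:
            raise ValueError(f"empty group {g!r}")
    medians = pd.Series({g: float(v.median()) for g, v in by.items()})
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            _, p = wilcoxon_rank_sum(by[a].to_numpy(), by[b].to_numpy())
            rows.append({"group_a": a, "group_b": b, "p": p})
    return medians, pd.DataFrame(rows)


def four_class_partition(bound: set, regulated: set, expressed: set) -> dict[str, set]:
    """Partition expressed genes into bound+regulated / only-bound /
    only-regulated / neither."""
    if not bound <= expressed or not regulated <= expressed:
        raise ValueError("bound and regulated must be subsets of expressed")
    return {
        "bound_regulated": bound & regulated,
        "bound_only": bound - regulated,
        "regulated_only": regulated - bound,
        "neither": expressed - bound - regulated,
    }


def overlap_stats(set_a: set, set_b: set, expressed_in_both: set) -> dict:
    """Overlap counts and integer percentages after restricting both sets
    to genes expressed in both datasets."""
    a = set_a & expressed_in_both
    b = set_b & expressed_in_both
    if not a or not b:
        raise ValueError("empty set after restriction to expressed genes")
    inter = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(inter),
        "pct_of_a": round(100.0 * len(inter) / len(a)),
        "pct_of_b": round(100.0 * len(inter) / len(b)),
    }
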