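"""Translation index (TI) computation and the comparison statistics built
on it.

The TI of a gene is log2 of the ratio between its polysomal signal (the
geometric mean of gradient pools 3 and 4) and its free-mRNA signal (pool
1); pool 2 is a mixed population and is excluded by default.  The shift
dTI = TI(mutant) - TI(wild type) measures loss of translational
repression in the mutant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

EPS_FLOOR = 1e-6

_POOL_RANGES = {1: (0, 4), 2: (4, 6), 3: (6, 9), 4: (9, 12)}


def fractions_to_pools(levels) -> np.ndarray:
    """Sum 12 gradient-fraction levels into the four standard pools
    (fractions 1-4, 5-6, 7-9, 10-12)."""
    arr = np.asarray(levels, dtype=float)
    if arr.shape[-1] != 12:
        raise ValueError("expected 12 fraction levels")
    return np.stack([arr[..., lo:hi].sum(axis=-1) for lo, hi in _POOL_RANGES.values()],
                    axis=-1)


def compute_ti(p1, p2, p3, p4, include_pool2: bool = False,
               mean_mode: str = "geometric", eps: float = EPS_FLOOR):
    """TI = log2(polysomal mean / p1).  Nonpositive pool-1 signal makes the
    gene unquantifiable (NaN, to be excluded downstream); zero polysomal
    signals are floored at ``eps``."""
    p1 = np.asarray(p1, dtype=float)
    pools = [np.maximum(np.asarray(p, dtype=float), eps)
             for p in ((p2, p3, p4) if include_pool2 else (p3, p4))]
    if mean_mode == "geometric":
        num = np.exp(np.mean([np.log(p) for p in pools], axis=0))
    elif mean_mode == "arithmetic":
        num = np.mean(pools, axis=0)
    else:
        raise ValueError("mean_mode must be 'geometric' or 'arithmetic'")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p1 > 0, np.log2(num / np.where(p1 > 0, p1, 1.0)), np.nan)
    return out if out.shape else float(out)


def pool_levels(m: ExpressionMatrix, genotype: str) -> pd.DataFrame:
    """Replicate-averaged pool levels (columns pool1..pool4) for one
    genotype, spike-ins excluded."""
    vals = m.values.loc[m.assay_ids]
    out = {}
    for pool in range(1, 5):
        cols = m.columns_where(genotype=genotype, pool=pool)
        if not cols:
            raise ValueError(f"no samples for genotype={genotype!r} pool={pool}")
        out[f"pool{pool}"] = vals[cols].mean(axis=1)
    return pd.DataFrame(out)


def ti_table(wt: ExpressionMatrix, mut: ExpressionMatrix,
             include_pool2: bool = False, mean_mode: str = "geometric") -> pd.DataFrame:
    """Per-gene TI in both genotypes, dTI and dTI rank (1 = largest
    increase, ties averaged).  Genes unquantifiable in either genotype are
    dropped."""
    lw = pool_levels(wt, "wt")
    lm = pool_levels(mut, "mut")
    ti_wt = compute_ti(lw["pool1"], lw["pool2"], lw["pool3"], lw["pool4"],
                       include_pool2, mean_mode)
    ti_mut = compute_ti(lm["pool1"], lm["pool2"], lm["pool3"], lm["pool4"],
                        include_pool2, mean_mode)
    df = pd.DataFrame({"ti_wt": ti_wt, "ti_mut": ti_mut}, index=lw.index).dropna()
    df["delta_ti"] = df["ti_mut"] - df["ti_wt"]
    df["rank"] = rank_by_delta(df["delta_ti"].to_numpy())
    return df


def log2_to_linear(x: float) -> float:
    """Linear fold change 2**x."""
    return float(2.0 ** np.asarray(x, dtype=float))


def format_fold_change(x: float) -> float:
    """Linear fold change rounded to the two-decimal reporting convention
    (2.97, 0.99, 1.07, ...)."""
    return round(log2_to_linear(x), 2)


def rank_by_delta(delta: np.ndarray) -> np.ndarray:
    """Descending dTI ranks, ties averaged (rank 1 = largest increase)."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("no records to rank")
    return stats.rankdata(-delta, method="average")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum; exact enumeration for
    small tie-free samples, normal approximation with tie correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (hypergeometric mass <= observed)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if t.shape == (2, 2) and np.allclose(t, np.round(t)) and (t >= 0).all():
            t = t.astype(int)
        else:
            raise ValueError("table must be a nonnegative integer 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def below_median_enrichment(subset_ids, records: pd.DataFrame,
                            column: str = "delta_ti") -> tuple[int, float]:
    """How many subset genes fall below the all-gene median of ``column``,
    with a two-sided Fisher exact p for the 2x2 split
    (subset membership x below/above median)."""
    subset = [g for g in subset_ids]
    if not subset:
        raise ValueError("empty subset")
    missing = set(subset) - set(records.index)
    if missing:
        raise ValueError(f"subset ids missing from records: {sorted(missing)[:5]}")
    med = records[column].median()
    below = records[column] < med
    in_sub = records.index.isin(subset)
    n_below = int((below & in_sub).sum())
    table = [[n_below, int(in_sub.sum()) - n_below],
             [int((below & ~in_sub).sum()), int((~below & ~in_sub).sum())]]
    return n_below, fisher_exact_2x2(table)
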