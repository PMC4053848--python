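"""SAM-style moderated statistics with permutation-estimated FDR.

Two flavours are provided, matching how microarray studies of this design
call genes:

* one-class: is a gene's signal reproducibly above background?  The null
  is generated by random sign-flips of the replicate values.
* two-class unpaired: does a gene differ between two sample groups?  The
  null is generated by permuting the group labels.

The statistic is d = (difference of means) / (s + s0): a t-like score
whose pooled standard error ``s`` is damped by the exchangeability factor
``s0`` (default: the 5th percentile of all per-gene ``s`` values) so that
genes with tiny variance cannot dominate.  For a threshold t, the FDR is
the median number of permutation scores exceeding t divided by the number
of observed scores exceeding t; a gene's q-value is the smallest such FDR
over thresholds it passes.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd


def pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """SAM pooled standard error per gene (rows are genes)."""
    na, nb = a.shape[1], b.shape[1]
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))


def moderated_d(group_a: np.ndarray, group_b: np.ndarray, s0: float) -> np.ndarray:
    """d = (mean(B) - mean(A)) / (s + s0)."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (b.mean(axis=1) - a.mean(axis=1)) / (pooled_se(a, b) + s0)
    return np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)


def one_class_d(values: np.ndarray, s0: float) -> np.ndarray:
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n = v.shape[1]
    if n < 3:
        raise ValueError("one-class analysis needs >= 3 replicates")
    s = v.std(axis=1, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = v.mean(axis=1) / (s + s0)
    return np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)


def choose_s0(s_values: np.ndarray, percentile: float = 5.0) -> float:
    """Exchangeability factor: a percentile of the per-gene standard
    errors (linear-interpolation percentile rule)."""
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty standard-error vector")
    return float(np.percentile(s, percentile))


def _qvalues(abs_d: np.ndarray, abs_d_star: np.ndarray) -> np.ndarray:
    """q-values from observed |d| and a perms x genes matrix of null |d*|.

    FDR(t) = median_perm #{|d*| >= t} / #{|d| >= t}; q(gene) = min over
    thresholds t <= |d_gene|, clipped to [0, 1].  Monotone nonincreasing
    in |d| by construction.
    """
    order = np.argsort(abs_d)[::-1]
    thresholds = abs_d[order]                      # descending
    denom = np.arange(1, abs_d.size + 1)
    sorted_null = np.sort(abs_d_star, axis=1)
    counts = np.empty((abs_d_star.shape[0], thresholds.size))
    for p in range(abs_d_star.shape[0]):
        counts[p] = abs_d_star.shape[1] - np.searchsorted(sorted_null[p], thresholds, side="left")
    fdr = np.median(counts, axis=0) / denom
    # suffix minimum: q at rank r = min over k >= r of FDR_k
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return np.clip(q, 0.0, 1.0)


def _significance_table(gene_ids, d, q, fdr_cutoff) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": list(gene_ids),
        "score": d,
        "q_value": q,
        "called": q < fdr_cutoff,
    }).set_index("gene_id")


def sam_two_class(values: pd.DataFrame, labels, n_perm: int = 1000,
                  seed: int = 0, fdr_cutoff: float = 0.05,
                  s0: float | None = None) -> pd.DataFrame:
    """Two-class unpaired SAM on a genes x samples table; ``labels`` is a
    0/1 vector over the columns."""
    labels = np.asarray(labels)
    v = values.to_numpy(dtype=float)
    idx_a = np.flatnonzero(labels == 0)
    idx_b = np.flatnonzero(labels == 1)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("labels must give two groups of >= 2 samples")
    if idx_a.size + idx_b.size != labels.size:
        raise ValueError("labels must be 0/1 over all samples")

    if s0 is None:
        s0 = choose_s0(pooled_se(v[:, idx_a], v[:, idx_b]))
    d = moderated_d(v[:, idx_a], v[:, idx_b], s0)

    from math import comb
    n, nb = labels.size, idx_b.size
    all_perms = comb(n, nb)
    rng = np.random.default_rng(seed)
    if all_perms <= n_perm:
        perm_sets = [np.array(c) for c in combinations(range(n), nb)]
    else:
        perm_sets = [rng.permutation(n)[:nb] for _ in range(n_perm)]
    d_star = np.empty((len(perm_sets), v.shape[0]))
    cols = np.arange(n)
    for p, bset in enumerate(perm_sets):
        mask = np.zeros(n, dtype=bool)
        mask[bset] = True
        d_star[p] = moderated_d(v[:, cols[~mask]], v[:, cols[mask]], s0)
    q = _qvalues(np.abs(d), np.abs(d_star))
    return _significance_table(values.index, d, q, fdr_cutoff)


def sam_one_class(values: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
                  fdr_cutoff: float = 0.05, s0: float | None = None) -> pd.DataFrame:
    """One-class SAM: scores mean signal against a sign-flip null."""
    v = values.to_numpy(dtype=float)
    n = v.shape[1]
    if n < 3:
        raise ValueError("one-class analysis needs >= 3 replicates")
    if s0 is None:
        s0 = choose_s0(v.std(axis=1, ddof=1) / np.sqrt(n))
    d = one_class_d(v, s0)
    rng = np.random.default_rng(seed)
    if 2 ** n <= n_perm:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
    else:
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    d_star = np.empty((signs.shape[0], v.shape[0]))
    for p in range(signs.shape[0]):
        d_star[p] = one_class_d(v * signs[p], s0)
    q = _qvalues(np.abs(d), np.abs(d_star))
    return _significance_table(values.index, d, q, fdr_cutoff)


def expressed_gene_sets(wt_calls: dict[int, set], mut_calls: dict[int, set]) -> set:
    """Genes expressed in both genotypes: intersection of the per-genotype
    unions over the four pools."""
    for name, calls in (("wild-type", wt_calls), ("mutant", mut_calls)):
        if set(calls) != {1, 2, 3, 4}:
            raise ValueError(f"{name} calls must cover pools 1-4")
    wt = set().union(*wt_calls.values())
    mut = set().union(*mut_calls.values())
    return wt & mut
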