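"""Translation index arithmetic and the attached comparison statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom, rankdata

from smaugkit.ti import (below_median_enrichment, compute_ti, fisher_exact_2x2,
                         format_fold_change, fractions_to_pools, log2_to_linear,
                         rank_by_delta, wilcoxon_rank_sum)


def test_fractions_to_pools_counting():
    assert np.allclose(fractions_to_pools(np.ones(12)), [4, 2, 3, 3])


def test_fractions_to_pools_point_mass():
    levels = np.zeros(12)
    levels[11] = 7.0
    assert np.allclose(fractions_to_pools(levels), [0, 0, 0, 7.0])


def test_fractions_to_pools_random_matches_range_sums(rng):
    v = rng.random(12)
    pools = fractions_to_pools(v)
    expected = [v[0:4].sum(), v[4:6].sum(), v[6:9].sum(), v[9:12].sum()]
    assert np.allclose(pools, expected)
    with pytest.raises(ValueError):
        fractions_to_pools(np.ones(11))


def test_compute_ti_exact_values():
    assert compute_ti(2.0, 1.0, 4.0, 16.0) == pytest.approx(2.0)
    assert compute_ti(5.0, 1.0, 5.0, 5.0) == pytest.approx(0.0)


def test_compute_ti_floor_rule():
    eps = 1e-6
    expected = math.log2(math.sqrt(4.0 * eps) / 2.0)
    assert compute_ti(2.0, 1.0, 4.0, 0.0) == pytest.approx(expected)


def test_compute_ti_zero_pool1_flagged():
    assert np.isnan(compute_ti(0.0, 1.0, 2.0, 3.0))


def test_compute_ti_scale_invariant(rng):
    p = rng.lognormal(0, 1, 4)
    for c in (0.1, 3.0, 1000.0):
        assert compute_ti(*(c * p)) == pytest.approx(compute_ti(*p))


def test_compute_ti_pool2_mode_and_means():
    geo = compute_ti(1.0, 2.0, 4.0, 8.0, include_pool2=True)
    assert geo == pytest.approx(math.log2((2.0 * 4.0 * 8.0) ** (1 / 3)))
    ari = compute_ti(1.0, 2.0, 4.0, 8.0, mean_mode="arithmetic")
    assert ari == pytest.approx(math.log2(6.0))


def test_fold_change_reporting_matches_printed_pairs():
    assert format_fold_change(1.57) == 2.97
    assert format_fold_change(-0.01) == 0.99
    assert format_fold_change(0.10) == 1.07
    assert format_fold_change(0.12) == 1.09
    assert format_fold_change(0.0) == 1.0
    assert log2_to_linear(1.0) == pytest.approx(2.0)


def test_rank_by_delta_basics():
    assert np.allclose(rank_by_delta([3.0, 1.0, 2.0]), [1, 3, 2])
    assert np.allclose(rank_by_delta([1.0, 1.0, 1.0]), [2, 2, 2])


def test_rank_by_delta_matches_sort_oracle(rng):
    v = rng.normal(0, 1, 50)
    assert np.allclose(rank_by_delta(v), rankdata(-v))


def test_wilcoxon_exact_enumeration_oracle():
    x, y = [1.0, 2.0], [3.0, 4.0]
    u, p = wilcoxon_rank_sum(x, y)
    assert u == 0.0
    # enumerate all C(4,2) label assignments of the pooled values
    pooled = np.array(x + y)
    us = []
    for idx in itertools.combinations(range(4), 2):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(4) if i not in idx]]
        us.append(sum(1 for a in xs for b in ys if a > b)
                  + 0.5 * sum(1 for a in xs for b in ys if a == b))
    us = np.array(us)
    expected = (us <= 0).mean() + (us >= 4).mean()
    assert p == pytest.approx(expected)


def test_wilcoxon_identical_samples_p_near_one(rng):
    x = rng.normal(0, 1, 30)
    _, p = wilcoxon_rank_sum(x, x)
    assert p > 0.9


def test_wilcoxon_null_pvalues_roughly_uniform():
    ps = []
    for seed in range(200):
        r = np.random.default_rng(seed)
        _, p = wilcoxon_rank_sum(r.normal(0, 1, 25), r.normal(0, 1, 25))
        ps.append(p)
    from scipy.stats import kstest
    assert kstest(ps, "uniform").pvalue > 0.01


def _fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration over the margin family."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


@pytest.mark.parametrize("table", [
    [[1, 1], [1, 1]],
    [[0, 5], [5, 0]],
    [[3, 1], [1, 3]],
    [[8, 2], [1, 5]],
    [[0, 0], [3, 4]],
])
def test_fisher_matches_enumeration(table):
    assert fisher_exact_2x2(table) == pytest.approx(_fisher_enumeration(table))


def test_fisher_extreme_table_smallest_p():
    n = 6
    p_extreme = fisher_exact_2x2([[0, n], [n, 0]])
    assert p_extreme == pytest.approx(2.0 / comb(2 * n, n), rel=1e-9)
    with pytest.raises(ValueError):
        fisher_exact_2x2([[-1, 2], [3, 4]])


def test_below_median_enrichment():
    records = pd.DataFrame({"delta_ti": np.arange(10.0)},
                           index=[f"g{i}" for i in range(10)])
    subset = [f"g{i}" for i in range(5)]   # the bottom half
    count, p = below_median_enrichment(subset, records)
    assert count == 5
    assert p == pytest.approx(_fisher_enumeration([[5, 0], [0, 5]]))
    with pytest.raises(ValueError):
        below_median_enrichment([], records)


def test_below_median_random_subset_near_half(rng):
    records = pd.DataFrame({"delta_ti": rng.normal(0, 1, 400)},
                           index=[f"g{i}" for i in range(400)])
    counts = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        subset = [f"g{i}" for i in r.choice(400, 200, replace=False)]
        counts.append(below_median_enrichment(subset, records)[0])
    assert abs(np.mean(counts) - 100) < 3 * np.std(counts) / np.sqrt(20) + 5
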