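"""Estimating the number of repressed genes by reference-set density
deconvolution.

Kernel density estimates of the dTI distribution are built for the top-N
and bottom-N binders (empirical positive and negative references).  Each
expressed gene then receives a positive probability

    p(x) = f_pos(x) / (f_pos(x) + f_neg(x)),

with both densities looked up at the closest grid point at or above x
(clamped to the last grid point beyond the grid).  The expected number of
repressed genes is the sum of positive probabilities over all genes,
repeated for each reference-set size N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRID_POINTS = 100
DENSITY_FLOOR = 1e-12


@dataclass
class DensityEstimate:
    grid: np.ndarray       # 100 ascending abscissae
    density: np.ndarray    # nonnegative
    bandwidth: float


@dataclass
class MixtureEstimate:
    n_reference: int
    probabilities: pd.Series   # per-gene positive probability
    pos: DensityEstimate
    neg: DensityEstimate

    @property
    def expected_count(self) -> float:
        return float(self.probabilities.sum())


def normal_reference_bandwidth(values: np.ndarray) -> float:
    """h = sd * (4 / (3n))^(1/5), the normal-reference rule."""
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) * (4.0 / (3.0 * v.size)) ** 0.2)


def kde_100(values, bandwidth: float | None = None,
            grid_range: tuple[float, float] | None = None) -> DensityEstimate:
    """Gaussian-kernel density on 100 equally spaced points spanning
    [min - h, max + h] (or an explicit ``grid_range``, widened by h).

    When two reference densities are compared gene by gene, both should be
    evaluated on a common grid spanning all the data, so that no lookup
    falls off the grid and far tails decay genuinely to zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("need >= 10 values for a density estimate")
    h = normal_reference_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("zero bandwidth (constant input)")
    lo, hi = (v.min(), v.max()) if grid_range is None else grid_range
    grid = np.linspace(lo - h, hi + h, GRID_POINTS)
    z = (grid[:, None] - v[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2.0 * np.pi))
    return DensityEstimate(grid, density, h)


def density_lookup(est: DensityEstimate, x: float) -> float:
    """Density at the smallest grid point >= x (last grid point if x lies
    beyond the grid)."""
    idx = int(np.searchsorted(est.grid, x, side="left"))
    if idx >= est.grid.size:
        idx = est.grid.size - 1
    return float(est.density[idx])


def positive_probability(x: float, pos: DensityEstimate, neg: DensityEstimate,
                         floor: float = DENSITY_FLOOR) -> float:
    fp = density_lookup(pos, x)
    fn = density_lookup(neg, x)
    if fp < floor and fn < floor:
        return 0.5
    fp = max(fp, floor)
    fn = max(fn, floor)
    return fp / (fp + fn)


def estimate_repressed_count(delta_ti: pd.Series, binder_ranking,
                             n_reference: int) -> MixtureEstimate:
    """Deconvolve the dTI distribution using the top-N / bottom-N genes of
    ``binder_ranking`` (best binder first) as positive / negative
    references."""
    ranking = [g for g in binder_ranking if g in delta_ti.index]
    if n_reference > len(ranking) // 2:
        raise ValueError("reference sets would overlap: N > n_genes / 2")
    top = ranking[:n_reference]
    bottom = ranking[-n_reference:]
    if set(top) & set(bottom):
        raise ValueError("top-N and bottom-N reference sets overlap")
    span = (float(delta_ti.min()), float(delta_ti.max()))
    pos = kde_100(delta_ti.loc[top].to_numpy(), grid_range=span)
    neg = kde_100(delta_ti.loc[bottom].to_numpy(), grid_range=span)
    probs = delta_ti.map(lambda x: positive_probability(x, pos, neg))
    return MixtureEstimate(n_reference, probs, pos, neg)


def estimate_over_reference_sizes(delta_ti: pd.Series, binder_ranking,
                                  sizes=(250, 500, 1000)) -> dict[int, MixtureEstimate]:
    return {n: estimate_repressed_count(delta_ti, binder_ranking, n) for n in sizes}
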