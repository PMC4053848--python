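"""Intensity normalization: quantile normalization across samples followed
by spike-in-anchored linear rescaling of each sample."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of per-rank
    cross-sample means; ties receive the average of the tied reference
    values.  Rank order within each sample is preserved."""
    vals = m.values
    if vals.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input")
        return m.with_values(vals.copy())
    arr = vals.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    ranks_grid = np.arange(1, n + 1)
    for c in range(arr.shape[1]):
        ranks = rankdata(arr[:, c], method="average")
        out[:, c] = np.interp(ranks, ranks_grid, ref)
    return m.with_values(pd.DataFrame(out, index=vals.index, columns=vals.columns))


def rescale_by_spikeins(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample linear transform x -> a*x + b, with (a, b) least-squares
    fitted so the sample's spike-in signals match the cross-sample mean
    spike-in signal.  Idempotent."""
    if len(m.spikein_ids) < 2:
        raise ValueError("need >= 2 spike-in rows for rescaling")
    vals = m.values
    spikes = vals.loc[m.spikein_ids].to_numpy(dtype=float)
    target = spikes.mean(axis=1)
    out = {}
    for c, col in enumerate(vals.columns):
        x = spikes[:, c]
        if np.ptp(x) == 0:
            raise ValueError(f"zero-variance spike-ins in sample {col!r}")
        a, b = np.polyfit(x, target, 1)
        out[col] = a * vals[col].to_numpy(dtype=float) + b
    return m.with_values(pd.DataFrame(out, index=vals.index))


def median_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide every sample by its median signal (rescaled by the grand
    mean of medians, so magnitudes stay comparable).

    The right array-level correction when samples have genuinely
    different signal distributions — e.g. IP versus control versus input
    in a RIP design, where quantile normalization would erase the very
    enrichment being measured.  Linear per column, hence rank-preserving.
    """
    vals = m.values
    medians = vals.median(axis=0)
    if (medians <= 0).any():
        raise ValueError("nonpositive column median")
    out = vals / medians * float(medians.mean())
    return m.with_values(out)


def normalize_pipeline(m: ExpressionMatrix, quantile: bool = True,
                       spikein: bool = True) -> ExpressionMatrix:
    """Quantile normalization first, then spike-in rescaling (narrative
    order of the underlying protocol)."""
    if quantile:
        m = quantile_normalize(m)
    if spikein and m.spikein_ids:
        m = rescale_by_spikeins(m)
    return m
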