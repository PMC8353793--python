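"""Count filtering, RLE normalisation, CPM and BH adjustment.

Size factors follow the relative log expression (RLE, median-of-ratios)
recipe: for each sample, the median over reference features of the ratio
between its count and the feature's geometric mean across samples, rescaled
so the size factors have geometric mean one. The reference set is restricted
to features with strictly positive counts in every sample; if no such
feature exists, per-feature geometric means fall back to positive entries
only. These factors absorb sequencing depth, so normalised abundances are
``counts / (s_j * Nbar)`` with ``Nbar`` the geometric-mean library size (a
constant that keeps CPM units interpretable). Scaling one sample's counts by
``c`` scales its size factor by exactly ``c`` (up to the common geometric
rescale shared by all samples), leaving every between-sample fold change
unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, FractxError


def filter_low_counts(cm: CountMatrix, min_cpm: float = 2.0, min_samples: int = 2) -> CountMatrix:
    """Retain features with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    CPM here is computed on raw library sizes (pre-normalisation), and the
    boundary is inclusive on both thresholds.
    """
    lib = cm.library_sizes().to_numpy(dtype=float)
    if (lib <= 0).any():
        raise FractxError("library size is zero for at least one sample")
    cpm_raw = cm.counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm_raw >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise FractxError(
            "low-count filter removed every feature; review min_cpm/min_samples thresholds"
        )
    return CountMatrix(cm.counts.loc[keep], cm.samples.reset_index(drop=True))


def rle_size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """RLE (median-of-ratios) size factors, rescaled to geometric mean one."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if counts.size == 0:
        raise FractxError("cannot compute size factors on an empty matrix")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        ref = arr[positive]
        geomean = np.exp(np.mean(np.log(ref), axis=1))
        ratios = ref / geomean[:, None]
    else:
        # fallback: geometric mean over positive entries only, per feature
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr, where=arr > 0), np.nan)
        geomean = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(arr > 0, arr / geomean[:, None], np.nan)
    s = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise FractxError("size factor estimation failed (non-positive or non-finite factor)")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def effective_library_sizes(cm: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    """Effective library size per sample: s_j times the geometric-mean depth."""
    lib = cm.library_sizes().astype(float)
    if (lib <= 0).any():
        raise FractxError("library size is zero for at least one sample")
    if factors is None:
        return lib
    factors = factors.reindex(cm.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise FractxError("size factors must be positive and match the samples")
    nbar = np.exp(np.mean(np.log(lib)))
    return factors * nbar


def cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    In log mode the prior count is scaled per sample in proportion to its
    effective library size (the standard prior-count convention), so a
    sample's depth does not leak into its log-CPM floor.
    """
    eff = effective_library_sizes(cm, factors).to_numpy()
    arr = cm.counts.to_numpy(dtype=float)
    if not log:
        return pd.DataFrame(arr / eff * 1e6, index=cm.counts.index, columns=cm.counts.columns)
    prior = prior_count * eff / eff.mean()
    vals = np.log2((arr + prior) / (eff + 2 * prior) * 1e6)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise FractxError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
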