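"""Sequencing-depth arithmetic, MDS sample diagnostics and marker summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, FractxError
from .norm import cpm


@dataclass(frozen=True)
class CoverageParams:
    """Inputs to the Lander/Waterman fold-coverage calculation.

    ``n_reads`` counts read pairs when ``paired`` is true (the paired
    multiplier of 2 is applied explicitly); ``transcribed_fraction`` scales
    the genome down to the transcribed target.
    """

    read_length: float
    n_reads: float
    paired: bool
    genome_size: float
    transcribed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.n_reads <= 0 or self.genome_size <= 0:
            raise FractxError("read_length, n_reads and genome_size must be positive")
        if not (0 < self.transcribed_fraction <= 1):
            raise FractxError("transcribed_fraction must lie in (0, 1]")


def lander_waterman_coverage(params: CoverageParams) -> float:
    """Fold coverage = (read length x base-yielding reads) / target size."""
    mult = 2.0 if params.paired else 1.0
    return (mult * params.read_length * params.n_reads) / (
        params.genome_size * params.transcribed_fraction
    )


def sample_mds(logcpm: pd.DataFrame, top_n: int = 500, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of samples on log-CPM distances.

    Pairwise Euclidean distances are computed on the ``top_n`` most variable
    features (across-sample variance); the embedding double-centres the
    squared distance matrix and takes the leading eigenvectors. Axis signs
    are canonicalised by making each axis's largest-magnitude coordinate
    positive, so output is deterministic and invariant to feature order.
    """
    n = logcpm.shape[1]
    if n < 3:
        raise FractxError("MDS needs at least 3 samples")
    if n < dims + 1:
        raise FractxError(f"MDS with dims={dims} needs at least {dims + 1} samples")
    var = logcpm.var(axis=1)
    top = var.sort_values(ascending=False, kind="stable").index[: min(top_n, len(var))]
    X = logcpm.loc[top].to_numpy(dtype=float).T  # samples x features
    sq = (X**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(D2, 0.0)
    D2 = np.maximum(D2, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    for d in range(dims):
        lam = max(evals[d], 0.0)
        axis = evecs[:, d] * np.sqrt(lam)
        pivot = np.argmax(np.abs(axis))
        if axis[pivot] < 0:
            axis = -axis
        coords[:, d] = axis
    return pd.DataFrame(
        coords, index=logcpm.columns, columns=[f"dim{i + 1}" for i in range(dims)]
    )


@dataclass(frozen=True)
class MarkerSet:
    """A named set of marker feature ids (e.g. neuronal markers)."""

    name: str
    feature_ids: frozenset

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise FractxError(f"marker set {self.name!r} is empty")


def marker_summary(
    cm: CountMatrix,
    markers: list[MarkerSet],
    factors: pd.Series | None = None,
    group_by: list[str] | None = None,
    floor_cpm: float = 2.0**-10,
    eff_lib: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean log2-CPM of each marker set per sample (or per sample group).

    Marker ids absent from the matrix are tolerated; the fraction found is
    reported. The summary is ``log2(max(mean CPM across present markers,
    floor))`` so all-zero sets sit at the log floor and doubling every
    marker count under a fixed normalisation (``eff_lib`` pins the
    effective library sizes) raises the summary by exactly one log2 unit.
    A set with no present markers is flagged absent (NaN summary).
    """
    if eff_lib is not None:
        eff = eff_lib.reindex(cm.counts.columns).to_numpy(dtype=float)
        cpm_mat = pd.DataFrame(
            cm.counts.to_numpy(dtype=float) / eff * 1e6,
            index=cm.counts.index,
            columns=cm.counts.columns,
        )
    else:
        cpm_mat = cpm(cm, factors, log=False)
    rows = []
    for ms in markers:
        present = [f for f in ms.feature_ids if f in cpm_mat.index]
        coverage = len(present) / len(ms.feature_ids)
        if not present:
            summary = pd.Series(np.nan, index=cpm_mat.columns)
        else:
            mean_cpm = cpm_mat.loc[present].mean(axis=0)
            summary = np.log2(np.maximum(mean_cpm, floor_cpm))
        for sample_id, value in summary.items():
            rows.append(
                {
                    "marker_set": ms.name,
                    "sample_id": sample_id,
                    "mean_log2cpm": value,
                    "fraction_found": coverage,
                    "absent": not present,
                }
            )
    out = pd.DataFrame(rows)
    if group_by:
        meta = cm.samples.set_index("sample_id")[group_by]
        out = out.join(meta, on="sample_id")
        out = (
            out.groupby(["marker_set"] + group_by, as_index=False)
            .agg(mean_log2cpm=("mean_log2cpm", "mean"), fraction_found=("fraction_found", "first"),
                 absent=("absent", "first"))
        )
    return out
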