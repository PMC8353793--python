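"""Simplified differential exon-usage testing.

For every exon of a multi-exon gene, its count is compared against the sum
of the gene's remaining exons between two sample groups through a 2x2
association test on group-pooled counts. Biological replicate variability
makes pooled counts overdispersed relative to the binomial, so each exon's
Pearson chi-square statistic is deflated by a moderated overdispersion
factor: the replicate-level quasi-binomial dispersion (within-group
heterogeneity chi-square over its degrees of freedom) is shrunk across
exons by scaled-F moment matching (the same variance-squeezing estimator
used for the quasi-likelihood DE stage) and floored at one. Because the
overdispersion is itself estimated, the deflated statistic is referred to
an F distribution on (1, replicate df + prior df) — the quasi-likelihood
convention — rather than a chi-square; p-values are BH adjusted across all
tested exons and an exon is called significant when its q-value is below
the FDR threshold.

Single-exon genes cannot have differential *usage* and are excluded (logged,
not an error); a gene with zero counts in one group is skipped. A gene-level
rollup (gene has at least one significant exon) is provided as an
interpretation-level convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import squeeze_var
from .io import FractxError, get_logger
from .norm import bh_adjust

logger = get_logger("fractx.exon")


@dataclass
class ExonCountMatrix:
    """Exon x sample counts with an exon -> gene assignment."""

    counts: pd.DataFrame
    gene_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_map.index):
            self.gene_map = self.gene_map.reindex(self.counts.index)
            if self.gene_map.isna().any():
                missing = list(self.counts.index[self.gene_map.isna()])[:5]
                raise FractxError(f"exons without gene assignment: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise FractxError("exon counts must be non-negative")


class ExonUsageModel:
    """Two-group differential exon-usage model.

    ``groups`` assigns one of exactly two labels to every sample (in sample
    order); ``pair`` optionally fixes which label is the reference for the
    reported usage difference (defaults to order of appearance).
    """

    def __init__(self, exons: ExonCountMatrix, groups, pair: tuple[str, str] | None = None):
        labels = pd.Series(list(groups), index=exons.counts.columns)
        levels = list(labels.unique()) if pair is None else list(pair)
        if labels.nunique() != 2 or len(levels) != 2:
            raise FractxError("exon-usage test requires exactly two groups")
        self.exons = exons
        self.labels = labels
        self.levels = levels

    def fit(self, fdr: float = 0.05) -> "ExonUsageResults":
        counts = self.exons.counts.to_numpy(dtype=float)
        genes = self.exons.gene_map.to_numpy()
        ia = np.flatnonzero((self.labels == self.levels[0]).to_numpy())
        ib = np.flatnonzero((self.labels == self.levels[1]).to_numpy())

        gene_totals = (
            self.exons.counts.groupby(self.exons.gene_map).transform("sum").to_numpy(dtype=float)
        )
        exon_per_gene = self.exons.gene_map.groupby(self.exons.gene_map).transform("size")
        single = (exon_per_gene < 2).to_numpy()
        n_single = int(pd.unique(genes[single]).size)
        if n_single:
            logger.info("excluding %d single-exon gene(s) from exon-usage testing", n_single)

        other = gene_totals - counts  # per sample: the gene's remaining exons
        zero_group = (gene_totals[:, ia].sum(axis=1) == 0) | (gene_totals[:, ib].sum(axis=1) == 0)
        testable = ~single & ~zero_group

        xA = counts[:, ia].sum(axis=1)
        oA = other[:, ia].sum(axis=1)
        xB = counts[:, ib].sum(axis=1)
        oB = other[:, ib].sum(axis=1)
        nA, nB = xA + oA, xB + oB
        with np.errstate(divide="ignore", invalid="ignore"):
            piA = np.where(nA > 0, xA / nA, np.nan)
            piB = np.where(nB > 0, xB / nB, np.nan)
            p_pool = (xA + xB) / np.maximum(nA + nB, 1.0)
        # Pearson chi-square of the pooled 2x2 table
        var_term = p_pool * (1.0 - p_pool)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = (piA - piB) ** 2 / (var_term * (1.0 / np.maximum(nA, 1) + 1.0 / np.maximum(nB, 1)))
        degenerate = ~np.isfinite(chi2) | (var_term <= 0)
        chi2 = np.where(degenerate, 0.0, chi2)

        # replicate-level overdispersion per exon (quasi-binomial)
        disp_num = np.zeros(counts.shape[0])
        disp_df = np.zeros(counts.shape[0])
        for idx, phat in ((ia, piA), (ib, piB)):
            n_rep = gene_totals[:, idx]
            x_rep = counts[:, idx]
            v = n_rep * phat[:, None] * (1.0 - phat[:, None])
            ok = v > 0
            contrib = np.where(ok, (x_rep - n_rep * phat[:, None]) ** 2 / np.where(ok, v, 1.0), 0.0)
            disp_num += contrib.sum(axis=1)
            disp_df += np.maximum(ok.sum(axis=1) - 1, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(disp_df > 0, disp_num / np.maximum(disp_df, 1), 1.0)
        df_rep = float(np.median(disp_df[testable])) if testable.any() else 1.0
        disp_mod = disp.copy()
        d0 = np.inf
        if testable.any() and df_rep > 0:
            squeezed, d0, s02 = squeeze_var(np.maximum(disp[testable], 1e-8), df_rep)
            disp_mod[testable] = squeezed
        disp_mod = np.maximum(disp_mod, 1.0)

        stat = chi2 / disp_mod
        from scipy import stats as sps

        df2 = df_rep + (d0 if np.isfinite(d0) else 0.0)
        if np.isfinite(d0):
            p = np.where(testable, sps.f.sf(stat, 1, max(df2, 1.0)), np.nan)
        else:
            p = np.where(testable, sps.chi2.sf(stat, df=1), np.nan)
        p = np.where(testable & degenerate, 1.0, p)
        q = np.full_like(p, np.nan)
        if testable.any():
            q[testable] = bh_adjust(p[testable])
        significant = np.where(np.isnan(q), False, q < fdr)

        table = pd.DataFrame(
            {
                "gene_id": genes,
                "pi_a": piA,
                "pi_b": piB,
                "overdispersion": disp_mod,
                "p": p,
                "q": q,
                "significant": significant,
                "tested": testable,
            },
            index=self.exons.counts.index.rename("exon_id"),
        )
        return ExonUsageResults(table=table, fdr=fdr, groups=tuple(self.levels),
                                n_excluded=int((~testable).sum()))


@dataclass
class ExonUsageResults:
    table: pd.DataFrame
    fdr: float
    groups: tuple[str, str]
    n_excluded: int

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["tested"]]

    def significant_genes(self) -> set[str]:
        """Genes with at least one significant exon (interpretation-level rollup)."""
        sig = self.table[self.table["significant"].fillna(False)]
        return set(sig["gene_id"])

    def summary(self) -> str:
        t = self.tested
        return (
            f"Differential exon usage: {self.groups[0]} vs {self.groups[1]}\n"
            f"  exons tested:      {len(t)} (excluded: {self.n_excluded})\n"
            f"  significant exons: {int(t['significant'].sum())} at FDR {self.fdr:g}\n"
            f"  genes affected:    {len(self.significant_genes())}"
        )


def exon_usage_test(
    exons: ExonCountMatrix,
    groups,
    fdr: float = 0.05,
    pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit :class:`ExonUsageModel` and return its table."""
    return ExonUsageModel(exons, groups, pair=pair).fit(fdr=fdr).table
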