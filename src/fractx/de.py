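"""Negative-binomial differential expression with quasi-likelihood testing.

Model
-----
For feature ``g`` and sample ``j`` the counts are negative binomial with
mean ``mu_gj`` and variance ``mu + phi_g * mu**2`` (``phi_g`` the NB
dispersion). A log-link GLM with a one-way group design and effective
library sizes as offsets is fitted per feature. Dispersions are estimated
genewise by maximising the Cox-Reid adjusted profile likelihood, a trend is
fitted to the genewise values by local regression on mean abundance, and the
genewise values are shrunk towards the trend on the log scale with weight
``prior_df / (prior_df + resid_df)`` (an empirical-Bayes compromise between
per-feature likelihood and the shared mean-dispersion relationship).

Testing uses the quasi-likelihood route: the per-feature residual deviance
divided by its degrees of freedom estimates a quasi-dispersion; these are
moderated by fitting a scaled F prior across features (moment matching on
the log scale, the classic variance-squeezing estimator) and the contrast is
tested with an F statistic ``(dev_null - dev_full) / s2_posterior`` on
``(1, resid_df + prior_df)`` degrees of freedom. A likelihood-ratio
chi-square mode (``test="lrt"``) is also provided; with dispersion fixed at
zero it coincides with a Poisson GLM likelihood-ratio test.

Features are flagged differentially expressed under the joint rule
``|log2FC| > log2(fc_threshold)`` and ``p < p_threshold`` (raw p, two-sided;
BH q-values are reported alongside but do not gate the flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix, FractxError
from .norm import bh_adjust, cpm, effective_library_sizes, rle_size_factors

_PHI_MIN = 1e-6
_PHI_MAX = 10.0


# ---------------------------------------------------------------------------
# contrasts


@dataclass(frozen=True)
class Contrast:
    """Two-group contrast over sample metadata.

    ``group_a`` and ``group_b`` are column->value predicates over the sample
    sheet; the direction convention is ``log2fc = log2(group_b / group_a)``.
    """

    name: str
    group_a: Mapping[str, str]
    group_b: Mapping[str, str]

    def _select(self, samples: pd.DataFrame, pred: Mapping[str, str]) -> list[str]:
        mask = np.ones(len(samples), dtype=bool)
        for col, val in pred.items():
            mask &= (samples[col] == val).to_numpy()
        return list(samples.loc[mask, "sample_id"])

    def groups(self, samples: pd.DataFrame) -> tuple[list[str], list[str]]:
        a = self._select(samples, self.group_a)
        b = self._select(samples, self.group_b)
        if set(a) & set(b):
            raise FractxError(f"contrast {self.name!r}: groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise FractxError(
                f"contrast {self.name!r}: each group needs >= 2 samples "
                f"(got {len(a)} vs {len(b)})"
            )
        return a, b


def standard_contrast(name: str, fraction: str = "whole_cell") -> Contrast:
    """The study's three standard contrasts, per fraction.

    ``c9_disease``: C9 vs healthy, both on control RNAi.
    ``c9_treated``: SRSF1-RNAi vs control RNAi within C9 lines.
    ``h_treated``: SRSF1-RNAi vs control RNAi within healthy lines.
    """
    table = {
        "c9_disease": (
            {"genotype": "healthy", "treatment": "ctrl_rnai"},
            {"genotype": "c9", "treatment": "ctrl_rnai"},
        ),
        "c9_treated": (
            {"genotype": "c9", "treatment": "ctrl_rnai"},
            {"genotype": "c9", "treatment": "srsf1_rnai"},
        ),
        "h_treated": (
            {"genotype": "healthy", "treatment": "ctrl_rnai"},
            {"genotype": "healthy", "treatment": "srsf1_rnai"},
        ),
    }
    if name not in table:
        raise FractxError(f"unknown contrast {name!r}; known: {sorted(table)}")
    a, b = ({**pred, "fraction": fraction} for pred in table[name])
    return Contrast(name, a, b)


# ---------------------------------------------------------------------------
# vectorised NB GLM machinery


def _nb_fit_groups(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    """Fit per-group log-means (one-way NB GLM with offsets), vectorised.

    ``y``: (G, n) counts; ``offsets``: (n,) natural-log effective library
    sizes; ``phi``: (G,) dispersions; ``groups``: lists of column indices.
    Returns fitted means ``mu`` (G, n). The per-group coefficient solves the
    NB score equation by damped Newton iterations; with ``phi = 0`` this is
    the Poisson solution (fitted group totals match observed totals).
    """
    G, n = y.shape
    mu = np.empty((G, n), dtype=float)
    t = np.exp(offsets)
    phi = np.asarray(phi, dtype=float)[:, None]
    for idx in groups:
        yg = y[:, idx]
        tg = t[idx][None, :]
        beta = np.log((yg.sum(axis=1) + 0.5) / tg.sum())[:, None]
        for _ in range(60):
            mug = np.exp(beta) * tg
            denom = 1.0 + phi * mug
            score = ((yg - mug) / denom).sum(axis=1, keepdims=True)
            info = (mug * (1.0 + phi * yg) / denom**2).sum(axis=1, keepdims=True)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -3.0, 3.0)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu[:, idx] = np.exp(beta) * tg
    return mu


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-feature NB residual deviance (Poisson limit at phi = 0)."""
    phi = np.asarray(phi, dtype=float)[:, None]
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    pois = term1 - (y - mu)
    phi_safe = np.where(phi > 0, phi, 1.0)
    nb = term1 - (y + 1.0 / phi_safe) * np.log((1.0 + phi_safe * y) / (1.0 + phi_safe * mu))
    unit = np.where(phi > 0, nb, pois)
    return np.maximum(2.0 * unit.sum(axis=1), 0.0)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood (Poisson limit at phi = 0)."""
    phi = np.asarray(phi, dtype=float)[:, None]
    mu = np.maximum(mu, 1e-12)
    if np.all(phi == 0):
        ll = y * np.log(mu) - mu - special.gammaln(y + 1.0)
        return ll.sum(axis=1)
    r = 1.0 / np.where(phi > 0, phi, 1.0)
    nb = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )
    pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    return np.where(phi[:, 0] > 0, nb.sum(axis=1), pois.sum(axis=1))


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionEstimates:
    """Genewise, trended and shrunk NB dispersions per feature."""

    genewise: pd.Series
    trend: pd.Series
    shrunk: pd.Series
    prior_df: float
    weight: float

    def for_features(self, feature_ids) -> np.ndarray:
        sub = self.shrunk.reindex(feature_ids)
        if sub.isna().any():
            missing = list(sub.index[sub.isna()])[:5]
            raise FractxError(f"dispersions missing for features: {missing}")
        return sub.to_numpy()


def _group_indices(samples: pd.DataFrame, groups) -> list[np.ndarray]:
    labels = pd.Series(list(groups), index=samples["sample_id"])
    return [np.flatnonzero((labels == lv).to_numpy()) for lv in labels.unique()]


def estimate_dispersion(
    cm: CountMatrix,
    groups,
    factors: pd.Series | None = None,
    prior_df: float = 10.0,
    grid_size: int = 41,
) -> DispersionEstimates:
    """Empirical-Bayes NB dispersion estimation.

    ``groups`` assigns each sample to a design cell (one label per sample,
    in sample order). Genewise dispersions maximise the Cox-Reid adjusted
    profile likelihood over a log-spaced grid; the abundance trend is a
    lowess fit of log dispersion on mean log2-CPM; shrinkage combines the
    two on the log scale with weight ``prior_df / (prior_df + resid_df)``.
    """
    y = cm.counts.to_numpy(dtype=float)
    if (y.sum(axis=1) == 0).any():
        raise FractxError("all-zero feature reached dispersion estimation; filter first")
    labels = list(groups)
    if len(labels) != cm.n_samples:
        raise FractxError("groups must provide one label per sample")
    idx_groups = _group_indices(cm.samples, labels)
    if max(len(ix) for ix in idx_groups) < 2:
        raise FractxError("at least one design cell must contain >= 2 samples")
    if factors is None:
        factors = rle_size_factors(cm)
    offsets = np.log(effective_library_sizes(cm, factors).to_numpy())

    grid = np.exp(np.linspace(np.log(_PHI_MIN), np.log(_PHI_MAX), grid_size))
    apl = np.empty((y.shape[0], grid_size))
    for k, phi in enumerate(grid):
        phi_vec = np.full(y.shape[0], phi)
        mu = _nb_fit_groups(y, offsets, phi_vec, idx_groups)
        ll = _nb_loglik(y, mu, phi_vec)
        # Cox-Reid adjustment: -0.5 * log det of the per-group Fisher information
        w = mu / (1.0 + phi * mu)
        cr = 0.0
        for ix in idx_groups:
            cr = cr + 0.5 * np.log(np.maximum(w[:, ix].sum(axis=1), 1e-12))
        apl[:, k] = ll - cr
    best = np.argmax(apl, axis=1)
    genewise = grid[best]

    # quadratic refinement in log-phi around the grid maximum
    inner = (best > 0) & (best < grid_size - 1)
    if inner.any():
        i = best[inner]
        x0, x1, x2 = (np.log(grid[i - 1]), np.log(grid[i]), np.log(grid[i + 1]))
        f0 = apl[inner, i - 1]
        f1 = apl[inner, i]
        f2 = apl[inner, i + 1]
        denom = f0 - 2.0 * f1 + f2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        genewise = genewise.copy()
        genewise[inner] = np.exp(x1 + shift * (x2 - x1))

    mean_log2cpm = cpm(cm, factors, log=True).mean(axis=1).to_numpy()
    from statsmodels.nonparametric.smoothers_lowess import lowess

    eps = 1e-4
    fit = lowess(np.log(genewise + eps), mean_log2cpm, frac=0.4, it=1, return_sorted=False)
    trend = np.clip(np.exp(fit) - eps, 0.0, _PHI_MAX)

    resid_df = y.shape[1] - len(idx_groups)
    weight = prior_df / (prior_df + max(resid_df, 1))
    shrunk = np.exp(
        weight * np.log(trend + eps) + (1.0 - weight) * np.log(genewise + eps)
    ) - eps
    lo = np.minimum(genewise, trend)
    hi = np.maximum(genewise, trend)
    shrunk = np.clip(shrunk, lo, hi)
    shrunk = np.maximum(shrunk, 0.0)

    index = cm.counts.index
    return DispersionEstimates(
        genewise=pd.Series(np.where(genewise <= 1.5 * _PHI_MIN, 0.0, genewise), index=index),
        trend=pd.Series(trend, index=index),
        shrunk=pd.Series(np.where(shrunk <= 1.5 * _PHI_MIN, 0.0, shrunk), index=index),
        prior_df=prior_df,
        weight=weight,
    )


# ---------------------------------------------------------------------------
# variance squeezing (scaled-F moment matching on the log scale)


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Moderate per-feature variances towards a common prior.

    Assumes ``s2 ~ s0^2 * F(df, prior_df)`` and estimates ``(s0^2,
    prior_df)`` by matching the mean and variance of ``log s2``; returns the
    posterior variances ``(prior_df * s0^2 + df * s2) / (prior_df + df)``.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        s0 = float(np.mean(s2)) if s2.size else 1.0
        return np.full_like(s2, max(s0, 1e-8)), np.inf, max(s0, 1e-8)
    z = np.log(s2[pos])
    zmean = z.mean()
    zvar = z.var(ddof=1)
    resid = zvar - special.polygamma(1, df / 2.0)
    base = zmean - special.digamma(df / 2.0) + np.log(df / 2.0)
    if resid <= 0:
        d0 = np.inf
        s02 = float(np.exp(base))
        post = np.full_like(s2, s02)
        return post, d0, s02
    d0 = 2.0 * _trigamma_inverse(resid)
    s02 = float(np.exp(base + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


# ---------------------------------------------------------------------------
# the DE model


class NBQLModel:
    """NB GLM differential-expression model for one two-group contrast.

    Parameters
    ----------
    cm : CountMatrix
        Filtered count matrix (run :func:`fractx.norm.filter_low_counts`
        first).
    contrast : Contrast
        Two-group contrast; log2FC is ``log2(group_b / group_a)``.
    dispersions : DispersionEstimates, float or None
        Per-feature shrunk dispersions; a scalar applies one dispersion to
        every feature; ``None`` estimates them from the contrast's samples.
    """

    def __init__(
        self,
        cm: CountMatrix,
        contrast: Contrast,
        dispersions: DispersionEstimates | float | None = None,
        factors: pd.Series | None = None,
    ) -> None:
        ids_a, ids_b = contrast.groups(cm.samples)
        self.contrast = contrast
        self.full = cm
        self.cm = cm.subset_samples(ids_a + ids_b)
        self.ids_a, self.ids_b = ids_a, ids_b
        self.factors = rle_size_factors(self.cm) if factors is None else factors
        if dispersions is None:
            groups = ["a"] * len(ids_a) + ["b"] * len(ids_b)
            dispersions = estimate_dispersion(self.cm, groups, self.factors)
        if isinstance(dispersions, DispersionEstimates):
            self.phi = dispersions.for_features(self.cm.counts.index)
        else:
            self.phi = np.full(self.cm.n_features, float(dispersions))
        if (self.phi < 0).any():
            raise FractxError("dispersions must be non-negative")

    def fit(
        self,
        fc_threshold: float = 2.0,
        p_threshold: float = 0.05,
        test: str = "ql",
    ) -> "NBQLResults":
        y = self.cm.counts.to_numpy(dtype=float)
        n = y.shape[1]
        na = len(self.ids_a)
        ia = np.arange(na)
        ib = np.arange(na, n)
        offsets = np.log(effective_library_sizes(self.cm, self.factors).to_numpy())

        mu_full = _nb_fit_groups(y, offsets, self.phi, [ia, ib])
        mu_null = _nb_fit_groups(y, offsets, self.phi, [np.arange(n)])
        dev_full = _nb_deviance(y, mu_full, self.phi)
        dev_null = _nb_deviance(y, mu_null, self.phi)
        lr = np.maximum(dev_null - dev_full, 0.0)
        df_resid = n - 2

        if test == "lrt":
            p = stats.chi2.sf(lr, df=1)
            s2_post, d0, s02 = np.ones_like(lr), np.inf, 1.0
        elif test == "ql":
            s2 = dev_full / df_resid
            s2_post, d0, s02 = squeeze_var(s2, df_resid)
            fstat = lr / np.maximum(s2_post, 1e-12)
            if np.isinf(d0):
                p = stats.chi2.sf(fstat, df=1)
            else:
                p = stats.f.sf(fstat, 1, df_resid + d0)
        else:
            raise FractxError(f"unknown test {test!r}; use 'ql' or 'lrt'")

        # fold change from prior-augmented mean CPM per group (CPM units make
        # the estimate exactly invariant to rescaling any one sample)
        eff = np.exp(offsets)
        norm = y / eff * 1e6
        prior = 0.5  # CPM
        mean_a = norm[:, ia].mean(axis=1)
        mean_b = norm[:, ib].mean(axis=1)
        log2fc = np.log2(mean_b + prior) - np.log2(mean_a + prior)

        mean_log2cpm = cpm(self.cm, self.factors, log=True).mean(axis=1).to_numpy()
        q = bh_adjust(p)
        is_deg = (np.abs(log2fc) > np.log2(fc_threshold)) & (p < p_threshold)
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "mean_log2cpm": mean_log2cpm,
                "p": p,
                "q": q,
                "is_deg": is_deg,
            },
            index=self.cm.counts.index.rename("feature_id"),
        )
        return NBQLResults(
            table=table,
            contrast=self.contrast,
            fc_threshold=fc_threshold,
            p_threshold=p_threshold,
            test=test,
            prior_df_ql=d0,
            s02=s02,
            resid_df=df_resid,
        )


@dataclass
class NBQLResults:
    """Per-feature DE results with the selection rule applied.

    ``table`` columns: log2fc, mean_log2cpm, p, q, is_deg.
    """

    table: pd.DataFrame
    contrast: Contrast
    fc_threshold: float
    p_threshold: float
    test: str
    prior_df_ql: float
    s02: float
    resid_df: int

    @property
    def deg_ids(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])

    def top_table(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("p").head(n)

    def summary(self) -> str:
        t = self.table
        up = int(((t["is_deg"]) & (t["log2fc"] > 0)).sum())
        down = int(((t["is_deg"]) & (t["log2fc"] < 0)).sum())
        lines = [
            f"NB {self.test.upper()} differential expression: {self.contrast.name}",
            f"  features tested:   {len(t)}",
            f"  selection rule:    |FC| > {self.fc_threshold:g} and p < {self.p_threshold:g}",
            f"  DEGs:              {up + down} ({up} up, {down} down)",
            f"  residual df:       {self.resid_df}",
            f"  QL prior df:       {self.prior_df_ql:.3g}" if self.test == "ql" else "",
        ]
        return "\n".join(line for line in lines if line)


def de_test(
    cm: CountMatrix,
    contrast: Contrast,
    dispersions: DispersionEstimates | float | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    test: str = "ql",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit :class:`NBQLModel` and return the result table."""
    model = NBQLModel(cm, contrast, dispersions, factors=factors)
    return model.fit(fc_threshold=fc_threshold, p_threshold=p_threshold, test=test).table


# ---------------------------------------------------------------------------
# one-way ANOVA for continuous expression matrices (microarray-style)


def anova_de(
    exprs: pd.DataFrame,
    groups,
    pair: tuple[str, str] | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-feature one-way between-subject ANOVA on a log2 expression matrix.

    ``groups`` gives one label per column. ``pair`` names ``(reference,
    other)`` groups for the reported log2fc (``mean_other - mean_ref``);
    defaults to the first two labels in order of appearance. Features with
    zero total variance are reported with ``p = 1`` and ``log2fc = 0``.
    """
    labels = pd.Series(list(groups), index=exprs.columns)
    levels = list(labels.unique())
    if len(levels) < 2:
        raise FractxError("ANOVA needs at least two groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise FractxError(f"ANOVA groups with < 2 samples: {small}")
    if pair is None:
        pair = (levels[0], levels[1])
    X = exprs.to_numpy(dtype=float)
    n = X.shape[1]
    k = len(levels)
    grand = X.mean(axis=1, keepdims=True)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    means = {}
    for lv in levels:
        idx = np.flatnonzero((labels == lv).to_numpy())
        sub = X[:, idx]
        m = sub.mean(axis=1)
        means[lv] = m
        ss_between += len(idx) * (m - grand[:, 0]) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), df1, df2), np.nan)
    degenerate = (ss_between + ss_within) < 1e-300
    # zero within-group variance but real between-group differences: p -> 0
    p = np.where(~degenerate & ~np.isfinite(F), 0.0, p)
    p = np.where(degenerate, 1.0, p)
    log2fc = means[pair[1]] - means[pair[0]]
    log2fc = np.where(degenerate, 0.0, log2fc)
    q = bh_adjust(p)
    is_deg = (np.abs(log2fc) > np.log2(fc_threshold)) & (p < p_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_log2cpm": X.mean(axis=1),
            "p": p,
            "q": q,
            "is_deg": is_deg,
        },
        index=exprs.index.rename("feature_id"),
    )
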