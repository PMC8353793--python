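"""Truth-labelled synthetic fractionated RNA-seq data.

The generator emulates the study design the analysis modules expect: two
genotypes (healthy, C9) x two RNAi treatments (control, SRSF1) x two
fractions (whole-cell, cytoplasmic) with ``n`` individuals per genotype,
each individual contributing all four treatment-by-fraction samples.

For feature ``g`` and sample ``j`` the whole-cell expected count is

    mu_gj = L_j * w_gj / sum_g w_gj,
    w_gj  = 2 ** (baseline_g + jitter_{g,ind(j)}
                  + disease_g * [genotype = c9]
                  + treatment_g * [treatment = srsf1_rnai])

with ``L_j`` the sample's library size. The cytoplasmic expected count is
``f_g * mu_gj * 2**(export_g * [treatment = srsf1_rnai])`` where ``f_g`` in
(0, 1] is the feature's cytoplasmic fraction: export effects perturb the
cytoplasmic compartment only, never whole-cell abundance, and both
compartments of an individual share the same latent whole-cell mean. Counts
are negative binomial with variance ``mu + phi_g * mu**2``.

Planted effect classes (disjoint feature sets except where stated):

* disease features: ``disease_log2fc != 0``; a subset is additionally given
  a treatment effect, either *reversed* (opposite sign, emulating
  disease-modifying normalisation) or *concordant* (same sign);
* treatment-only features respond to SRSF1-RNAi without a disease change;
* export features shift their cytoplasmic abundance under SRSF1-RNAi;
* exon-usage features shift one exon's within-gene usage between genotypes.

All randomness flows from a single seed via named child streams, so an
identical config reproduces bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, FractxError


@dataclass
class SimConfig:
    """Configuration of the synthetic fractionated dataset.

    Defaults give a desk-scale analogue of the study's design: three
    individuals per genotype (24 samples), a few thousand features with
    log-normal abundances spanning several orders of magnitude, moderate NB
    dispersion around 0.1, per-individual baseline jitter of 0.3 log2 units,
    and planted effect sets small relative to the transcriptome.
    """

    n_features: int = 2000
    n_individuals_per_genotype: int = 3
    seed: int = 0
    baseline_logmean: tuple[float, float] = (5.0, 2.0)  # mean, sd of log2 expression
    dispersion_lognormal: tuple[float, float] = (float(np.log(0.1)), 0.3)  # ln-scale mu, sd
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    individual_sd: float = 0.3
    n_disease_de: int = 100
    disease_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_treatment_reversed: int = 30
    n_treatment_concordant: int = 5
    n_treatment_only: int = 20
    treatment_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_export_altered: int = 50
    export_log2fc_range: tuple[float, float] = (2.0, 3.0)
    cytoplasmic_fraction_range: tuple[float, float] = (0.2, 0.9)
    min_effect_log2mean: float | None = None
    n_exons_per_gene_range: tuple[int, int] = (2, 6)
    n_exon_usage_altered: int = 20
    exon_usage_pi: tuple[float, float] = (0.5, 0.1)

    def validate(self) -> None:
        if self.n_features <= 0 or self.n_individuals_per_genotype <= 0:
            raise FractxError("n_features and n_individuals_per_genotype must be positive")
        if self.n_treatment_reversed + self.n_treatment_concordant > self.n_disease_de:
            raise FractxError("reversed + concordant treatment features must be <= n_disease_de")
        n_effect = self.n_disease_de + self.n_treatment_only + self.n_export_altered
        if n_effect > self.n_features:
            raise FractxError(
                f"planted effect features ({n_effect}) exceed n_features ({self.n_features})"
            )
        for name in (
            "baseline_logmean",
            "library_size_range",
            "disease_log2fc_range",
            "treatment_log2fc_range",
            "export_log2fc_range",
            "cytoplasmic_fraction_range",
            "n_exons_per_gene_range",
            "exon_usage_pi",
        ):
            lo_hi = getattr(self, name)
            if len(lo_hi) != 2:
                raise FractxError(f"{name} must be a (lo, hi) pair")
        for name in ("library_size_range", "disease_log2fc_range", "treatment_log2fc_range",
                     "export_log2fc_range", "cytoplasmic_fraction_range", "n_exons_per_gene_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise FractxError(f"{name} must be ordered (lo <= hi)")
        lo, hi = self.cytoplasmic_fraction_range
        if not (0 < lo <= hi <= 1):
            raise FractxError("cytoplasmic_fraction_range must lie in (0, 1]")
        if self.dispersion_lognormal[1] < 0:
            raise FractxError("dispersion sd must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimDataset:
    """Paired whole-cell / cytoplasmic count matrices with planted truth."""

    wct: CountMatrix
    cyt: CountMatrix
    truth: pd.DataFrame
    config: SimConfig
    exons: "object | None" = None  # ExonCountMatrix, attached by simulate_exon_counts


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, phi) draws with variance mean + phi*mean^2; Poisson at phi = 0."""
    mean = np.maximum(mean, 1e-12)
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for genotype, tag in (("healthy", "H"), ("c9", "C9")):
        for i in range(1, config.n_individuals_per_genotype + 1):
            ind = f"{tag}{i}"
            for treatment, ttag in (("ctrl_rnai", "ctrl"), ("srsf1_rnai", "srsf1")):
                for fraction, ftag in (("whole_cell", "wct"), ("cytoplasmic", "cyt")):
                    rows.append(
                        {
                            "sample_id": f"{ind}_{ttag}_{ftag}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "fraction": fraction,
                            "individual_id": ind,
                            "replicate": 1,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_fractionated_counts(config: SimConfig) -> SimDataset:
    """Generate paired WCT/CyT NB count matrices with planted truth labels."""
    config.validate()
    rngs = _streams(
        config.seed,
        ("baseline", "effects", "jitter", "library", "wct_counts", "cyt_counts",
         "exons", "species_link"),
    )
    G = config.n_features
    features = np.array([f"g{str(i).zfill(5)}" for i in range(G)])

    rb = rngs["baseline"]
    baseline = rb.normal(config.baseline_logmean[0], config.baseline_logmean[1], G)
    mu_ln, sd_ln = config.dispersion_lognormal
    phi = np.exp(rb.normal(mu_ln, sd_ln, G)) if sd_ln > 0 else np.full(G, float(np.exp(mu_ln)))
    lo, hi = config.cytoplasmic_fraction_range
    cyt_fraction = rb.uniform(lo, hi, G)

    re = rngs["effects"]
    disease = np.zeros(G)
    treatment = np.zeros(G)
    export = np.zeros(G)
    eligible = np.arange(G)
    if config.min_effect_log2mean is not None:
        eligible = np.flatnonzero(baseline >= config.min_effect_log2mean)
    n_needed = config.n_disease_de + config.n_treatment_only + config.n_export_altered
    if len(eligible) < n_needed:
        raise FractxError(
            f"only {len(eligible)} features satisfy min_effect_log2mean; {n_needed} needed"
        )
    chosen = re.choice(eligible, size=n_needed, replace=False)
    disease_idx = chosen[: config.n_disease_de]
    tonly_idx = chosen[config.n_disease_de : config.n_disease_de + config.n_treatment_only]
    export_idx = chosen[config.n_disease_de + config.n_treatment_only :]

    def draw_fc(rng, n, rng_range):
        mag = rng.uniform(rng_range[0], rng_range[1], n)
        sign = rng.choice([-1.0, 1.0], n)
        return mag * sign

    disease[disease_idx] = draw_fc(re, len(disease_idx), config.disease_log2fc_range)
    reversed_idx = disease_idx[: config.n_treatment_reversed]
    concordant_idx = disease_idx[
        config.n_treatment_reversed : config.n_treatment_reversed + config.n_treatment_concordant
    ]
    tmag = re.uniform(*config.treatment_log2fc_range, len(reversed_idx))
    treatment[reversed_idx] = -np.sign(disease[reversed_idx]) * tmag
    cmag = re.uniform(*config.treatment_log2fc_range, len(concordant_idx))
    treatment[concordant_idx] = np.sign(disease[concordant_idx]) * cmag
    treatment[tonly_idx] = draw_fc(re, len(tonly_idx), config.treatment_log2fc_range)
    export[export_idx] = draw_fc(re, len(export_idx), config.export_log2fc_range)

    samples = _sample_sheet(config)
    individuals = samples["individual_id"].unique()
    jitter = {ind: rngs["jitter"].normal(0.0, config.individual_sd, G) for ind in individuals}

    lib_lo, lib_hi = config.library_size_range
    # one library size per (individual, treatment); both fractions share the
    # latent whole-cell depth, the cytoplasmic one is thinned by f_g below
    libs = {}
    for ind in individuals:
        for trt in ("ctrl_rnai", "srsf1_rnai"):
            libs[(ind, trt)] = rngs["library"].uniform(lib_lo, lib_hi)

    is_c9 = (samples["genotype"] == "c9").to_numpy()
    is_srsf1 = (samples["treatment"] == "srsf1_rnai").to_numpy()
    is_cyt = (samples["fraction"] == "cytoplasmic").to_numpy()

    n_samples = len(samples)
    wct_mean = np.empty((G, n_samples))
    cyt_mean = np.empty((G, n_samples))
    for j in range(n_samples):
        row = samples.iloc[j]
        log2rel = baseline + jitter[row["individual_id"]]
        if is_c9[j]:
            log2rel = log2rel + disease
        if is_srsf1[j]:
            log2rel = log2rel + treatment
        w = np.exp2(log2rel)
        L = libs[(row["individual_id"], row["treatment"])]
        mu = L * w / w.sum()
        wct_mean[:, j] = mu
        shift = np.exp2(export) if is_srsf1[j] else 1.0
        cyt_mean[:, j] = cyt_fraction * mu * shift

    wct_cols = ~is_cyt
    cyt_cols = is_cyt
    wct_counts = _nb_draw(rngs["wct_counts"], wct_mean[:, wct_cols], phi)
    cyt_counts = _nb_draw(rngs["cyt_counts"], cyt_mean[:, cyt_cols], phi)

    wct_samples = samples.loc[wct_cols].reset_index(drop=True)
    cyt_samples = samples.loc[cyt_cols].reset_index(drop=True)
    wct = CountMatrix(
        pd.DataFrame(wct_counts, index=features, columns=wct_samples["sample_id"]), wct_samples
    )
    cyt = CountMatrix(
        pd.DataFrame(cyt_counts, index=features, columns=cyt_samples["sample_id"]), cyt_samples
    )

    truth = pd.DataFrame(
        {
            "baseline_log2mean": baseline,
            "dispersion": phi,
            "cyt_fraction": cyt_fraction,
            "disease_log2fc": disease,
            "treatment_log2fc": treatment,
            "export_log2fc": export,
            "exon_usage_altered": False,
            "seed": config.seed,
        },
        index=pd.Index(features, name="feature_id"),
    )
    truth["is_null"] = (
        (truth["disease_log2fc"] == 0)
        & (truth["treatment_log2fc"] == 0)
        & (truth["export_log2fc"] == 0)
    )
    dataset = SimDataset(wct=wct, cyt=cyt, truth=truth, config=config)
    dataset._rng_exons = rngs["exons"]  # type: ignore[attr-defined]
    return dataset


def simulate_exon_counts(dataset: SimDataset, config: SimConfig | None = None):
    """Split whole-cell gene counts into exon counts by multinomial sampling.

    Each gene receives a fixed per-gene exon proportion vector (Dirichlet
    draw). For exon-usage-altered genes, the first exon's usage is
    ``exon_usage_pi[0]`` in healthy samples and ``exon_usage_pi[1]`` in C9
    samples, with the remaining exons sharing the balance proportionally.
    Exon counts sum exactly to the gene count in every sample.
    """
    from .exon import ExonCountMatrix

    config = config or dataset.config
    rng = getattr(dataset, "_rng_exons", None)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])
    lo, hi = config.n_exons_per_gene_range
    genes = dataset.wct.feature_ids
    G = len(genes)
    n_exons = rng.integers(lo, hi + 1, G)
    altered = np.zeros(G, dtype=bool)
    if config.n_exon_usage_altered > 0:
        cand = np.flatnonzero(n_exons >= 2)
        if len(cand) < config.n_exon_usage_altered:
            raise FractxError("not enough multi-exon genes for the requested usage alterations")
        altered[rng.choice(cand, config.n_exon_usage_altered, replace=False)] = True
    if (altered & (n_exons < 2)).any():
        raise FractxError("a gene with < 2 exons cannot be exon_usage_altered")

    pi0, pi1 = config.exon_usage_pi
    is_c9 = (dataset.wct.samples["genotype"] == "c9").to_numpy()
    counts = dataset.wct.counts.to_numpy()
    exon_rows = []
    exon_ids = []
    gene_of_exon = []
    for g in range(G):
        k = int(n_exons[g])
        base = rng.dirichlet(np.full(k, 2.0))
        if altered[g]:
            rest = base[1:] / base[1:].sum()
            props_h = np.concatenate([[pi0], (1 - pi0) * rest])
            props_c9 = np.concatenate([[pi1], (1 - pi1) * rest])
        else:
            props_h = props_c9 = base
        gene_counts = counts[g]
        mat = np.empty((k, len(gene_counts)), dtype=np.int64)
        for j, total in enumerate(gene_counts):
            p = props_c9 if is_c9[j] else props_h
            mat[:, j] = rng.multinomial(int(total), p)
        exon_rows.append(mat)
        exon_ids.extend(f"{genes[g]}:e{e + 1}" for e in range(k))
        gene_of_exon.extend([genes[g]] * k)
    exon_counts = pd.DataFrame(
        np.vstack(exon_rows),
        index=pd.Index(exon_ids, name="exon_id"),
        columns=dataset.wct.counts.columns,
    )
    gene_map = pd.Series(gene_of_exon, index=exon_counts.index, name="gene_id")
    dataset.truth["exon_usage_altered"] = altered
    ecm = ExonCountMatrix(counts=exon_counts, gene_map=gene_map, samples=dataset.wct.samples)
    dataset.exons = ecm
    return ecm


def simulate_two_species(
    config_a: SimConfig,
    config_b: SimConfig,
    n_conserved: int,
    n_opposite: int,
    n_reciprocal: int = 2,
    n_null_links: int = 20,
) -> tuple[SimDataset, SimDataset, pd.DataFrame]:
    """Paired two-species datasets with a truth-labelled homology table.

    ``n_conserved`` homology pairs share the sign of their planted disease
    effect across the species, ``n_opposite`` have opposite signs. The first
    ``n_reciprocal`` conserved pairs are drawn from *reversed* features in
    both species (disease change undone by treatment), so they — and only
    they — surface downstream as fully-conserved reciprocal pairs; the
    remaining conserved and all opposite pairs come from disease-only
    features. ``n_null_links`` additional pairs connect null features. The
    returned table has columns ``gene_a, gene_b, planted_class`` with class
    in {reciprocal, conserved, opposite, null}.
    """
    if n_reciprocal > n_conserved:
        raise FractxError("n_reciprocal must be <= n_conserved")
    ds_a = simulate_fractionated_counts(config_a)
    ds_b = simulate_fractionated_counts(config_b)

    def pools(truth: pd.DataFrame):
        d = truth["disease_log2fc"]
        t = truth["treatment_log2fc"]
        reversed_pos = list(truth.index[(d > 0) & (t < 0)])
        donly_pos = list(truth.index[(d > 0) & (t == 0)])
        donly_neg = list(truth.index[(d < 0) & (t == 0)])
        nulls = list(truth.index[truth["is_null"]])
        return reversed_pos, donly_pos, donly_neg, nulls

    rev_a, pos_a, neg_a, null_a = pools(ds_a.truth)
    rev_b, pos_b, neg_b, null_b = pools(ds_b.truth)

    n_cons_rest = n_conserved - n_reciprocal
    need_pos = n_cons_rest + n_opposite
    if (
        len(rev_a) < n_reciprocal
        or len(rev_b) < n_reciprocal
        or len(pos_a) < need_pos
        or len(neg_b) < n_opposite
        or len(pos_b) < n_cons_rest
    ):
        raise FractxError("requested homology pairs exceed available planted effect features")

    rows = []
    for i in range(n_reciprocal):
        rows.append((rev_a[i], rev_b[i], "reciprocal"))
    for i in range(n_cons_rest):
        rows.append((pos_a[i], pos_b[i], "conserved"))
    for i in range(n_opposite):
        rows.append((pos_a[n_cons_rest + i], neg_b[i], "opposite"))
    for i in range(min(n_null_links, len(null_a), len(null_b))):
        rows.append((null_a[i], null_b[i], "null"))
    gene_a, gene_b, cls = zip(*rows) if rows else ((), (), ())
    # species-qualified ids keep the two feature namespaces distinct
    homology = pd.DataFrame(
        {
            "gene_a": [f"A:{g}" for g in gene_a],
            "gene_b": [f"B:{g}" for g in gene_b],
            "planted_class": list(cls),
        }
    )
    for ds, prefix in ((ds_a, "A"), (ds_b, "B")):
        mapper = lambda g, p=prefix: f"{p}:{g}"
        ds.wct.counts.index = ds.wct.counts.index.map(mapper)
        ds.cyt.counts.index = ds.cyt.counts.index.map(mapper)
        ds.truth.index = ds.truth.index.map(mapper)
    return ds_a, ds_b, homology
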