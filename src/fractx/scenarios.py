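"""End-to-end evaluation scenarios on the synthetic generator.

Each function simulates a dataset under fixed study conditions, runs the
relevant analysis stage from scratch, and returns summary metrics. The
scenarios double as the package's calibration/recovery benchmarks: type-I
error and power of the DE test, dispersion recovery, export-classifier
recall/precision, signature recovery, orthology concordance on a planted
construction, and exon-usage FDR/power. Problem sizes are desk scale
(thousands of features, triplicate designs) so every scenario runs in
seconds on one CPU.
"""

from __future__ import annotations

import numpy as np

from .de import de_test, estimate_dispersion, standard_contrast
from .exon import ExonCountMatrix, exon_usage_test
from .export import classify_export
from .norm import filter_low_counts
from .orthology import direction_concordance, reciprocal_pairs
from .signature import build_signature
from .simulate import (
    SimConfig,
    simulate_exon_counts,
    simulate_fractionated_counts,
    simulate_two_species,
)

NO_EFFECTS = dict(
    n_disease_de=0,
    n_treatment_reversed=0,
    n_treatment_concordant=0,
    n_treatment_only=0,
    n_export_altered=0,
    n_exon_usage_altered=0,
)


def _sub(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def de_null_type1(seed: int, n_features: int = 2000) -> dict:
    """Fraction of null features with p < 0.05 (3 vs 3 NB counts, phi = 0.1)."""
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 1),
        dispersion_lognormal=(float(np.log(0.1)), 0.0), **NO_EFFECTS,
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    table = de_test(cm, standard_contrast("c9_disease"))
    return {"rate": float((table["p"] < 0.05).mean()), "n": len(table)}


def de_power(seed: int, n_features: int = 2000, n_planted: int = 100) -> dict:
    """Detection rate for planted |log2FC| = 2 at phi = 0.1 and mean >= 100."""
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 2),
        n_disease_de=n_planted, disease_log2fc_range=(2.0, 2.0),
        n_treatment_reversed=0, n_treatment_concordant=0, n_treatment_only=0,
        n_export_altered=0, min_effect_log2mean=0.0, baseline_logmean=(2.0, 1.0),
        library_size_range=(2e6, 2.5e6), dispersion_lognormal=(float(np.log(0.1)), 0.0),
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    table = de_test(cm, standard_contrast("c9_disease"))
    planted = ds.truth.index[ds.truth.disease_log2fc != 0].intersection(table.index)
    return {"power": float(table.loc[planted, "is_deg"].mean()), "n": len(planted)}


def dispersion_recovery(seed: int, true_phi: float = 0.2, n_features: int = 2000) -> dict:
    """Mean shrunk dispersion on data simulated at a single true phi.

    Individual jitter is off so the configured phi is the only source of
    extra-Poisson variation.
    """
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 3),
        dispersion_lognormal=(float(np.log(true_phi)), 0.0), individual_sd=0.0,
        **NO_EFFECTS,
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    groups = list(cm.samples.genotype + "_" + cm.samples.treatment)
    disp = estimate_dispersion(cm, groups)
    mean_phi = float(disp.shrunk.mean())
    return {
        "mean_phi": mean_phi,
        "relative_error": float(abs(mean_phi - true_phi) / true_phi),
        "n": cm.n_features,
    }


def poisson_dispersion(seed: int, n_features: int = 2000) -> dict:
    """Median shrunk dispersion on Poisson (phi = 0) data."""
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 4),
        dispersion_lognormal=(-30.0, 0.0), individual_sd=0.0, **NO_EFFECTS,
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    groups = list(cm.samples.genotype + "_" + cm.samples.treatment)
    disp = estimate_dispersion(cm, groups)
    return {"median_phi": float(disp.shrunk.median()), "n": cm.n_features}


def export_recovery(seed: int, n_features: int = 2000, n_export: int = 50) -> dict:
    """Recall/precision of export calls for planted cytoplasm-only shifts.

    Planted features have |export log2FC| in [2, 3] on abundant features
    (mean count >= ~200) among nulls; the classifier intersects the
    SRSF1-RNAi contrast per fraction at the FC > 3 / FC < 3 rule.
    """
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 5),
        n_disease_de=0, n_treatment_reversed=0, n_treatment_concordant=0,
        n_treatment_only=0, n_export_altered=n_export,
        export_log2fc_range=(2.0, 3.0), min_effect_log2mean=5.0,
        baseline_logmean=(5.0, 1.5), library_size_range=(2e6, 2.5e6),
        dispersion_lognormal=(float(np.log(0.1)), 0.0),
    )
    ds = simulate_fractionated_counts(cfg)
    wct = filter_low_counts(ds.wct)
    cyt = filter_low_counts(ds.cyt)
    t_wct = de_test(wct, standard_contrast("c9_treated", "whole_cell"))
    t_cyt = de_test(cyt, standard_contrast("c9_treated", "cytoplasmic"))
    calls, _ = classify_export(t_wct, t_cyt)
    truth_exp = set(ds.truth.index[ds.truth.export_log2fc != 0])
    called = set(calls.index[calls["call"] != "none"])
    tp = len(called & truth_exp)
    return {
        "recall": tp / len(truth_exp),
        "precision": tp / max(len(called), 1),
        "n_called": len(called),
        "n": len(truth_exp),
    }


def signature_recovery(seed: int, n_features: int = 2000) -> dict:
    """Recovery of 30 planted reversed + 5 planted concordant features."""
    cfg = SimConfig(
        n_features=n_features, seed=_sub(seed, 6),
        n_disease_de=50, n_treatment_reversed=30, n_treatment_concordant=5,
        n_treatment_only=10, n_export_altered=0,
        disease_log2fc_range=(2.0, 3.0), treatment_log2fc_range=(2.0, 3.0),
        min_effect_log2mean=5.0, baseline_logmean=(5.0, 1.5),
        library_size_range=(2e6, 2.5e6), dispersion_lognormal=(float(np.log(0.1)), 0.0),
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    disease = de_test(cm, standard_contrast("c9_disease"))
    treated = de_test(cm, standard_contrast("c9_treated"))
    sig = build_signature(disease, treated)
    truth = ds.truth
    planted = truth.index[(truth.disease_log2fc != 0) & (truth.treatment_log2fc != 0)]
    recovered = sig.index.intersection(planted)
    ok = 0
    for f in recovered:
        expect = (
            "reversed"
            if np.sign(truth.at[f, "disease_log2fc"]) == -np.sign(truth.at[f, "treatment_log2fc"])
            else "concordant"
        )
        ok += sig.at[f, "status"] == expect
    return {
        "recovery": len(recovered) / len(planted),
        "status_accuracy": ok / max(len(recovered), 1),
        "n_planted": len(planted),
        "n": len(sig),
    }


def orthology_construction(seed: int) -> dict:
    """Concordance counts on a planted two-species construction.

    5 conserved and 3 opposite homology pairs are planted with strong
    effects at large counts; exactly 2 of the conserved pairs are reversed
    in both species (fully-conserved reciprocal changes).
    """
    kw = dict(
        n_features=1500, n_disease_de=40, n_treatment_reversed=20,
        n_treatment_concordant=0, n_treatment_only=5, n_export_altered=0,
        disease_log2fc_range=(2.5, 3.5), treatment_log2fc_range=(2.5, 3.5),
        min_effect_log2mean=5.0, baseline_logmean=(5.0, 1.5),
        library_size_range=(3e6, 3.5e6), dispersion_lognormal=(float(np.log(0.05)), 0.0),
        individual_sd=0.1,
    )
    ds_a, ds_b, hom = simulate_two_species(
        SimConfig(seed=_sub(seed, 7), **kw),
        SimConfig(seed=_sub(seed, 8), **kw),
        n_conserved=5, n_opposite=3, n_reciprocal=2,
    )
    de_a = de_test(filter_low_counts(ds_a.wct), standard_contrast("c9_disease"))
    de_b = de_test(filter_low_counts(ds_b.wct), standard_contrast("c9_disease"))
    _, (n_sim, n_opp) = direction_concordance(de_a, de_b, hom)
    tr_a = de_test(filter_low_counts(ds_a.wct), standard_contrast("c9_treated"))
    tr_b = de_test(filter_low_counts(ds_b.wct), standard_contrast("c9_treated"))
    sig_a = build_signature(de_a, tr_a)
    sig_b = build_signature(de_b, tr_b)
    rp = reciprocal_pairs(sig_a, sig_b, hom)
    return {
        "n_similar": n_sim,
        "n_opposite": n_opp,
        "n_reciprocal": int(rp["fully_conserved"].sum()),
        "n": len(hom),
    }


def exon_null_fdr(seed: int, n_reps: int = 20, n_genes: int = 250) -> dict:
    """Mean false-discovery proportion over null replicate runs (~1000 exons).

    With no planted usage shifts every call is false; per-run FDP is the
    false fraction among calls (0 when no call is made).
    """
    fdps = []
    n_exons = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_features=n_genes, seed=_sub(seed, 100 + rep),
            n_exons_per_gene_range=(3, 5),
            dispersion_lognormal=(float(np.log(0.1)), 0.0), **NO_EFFECTS,
        )
        ds = simulate_fractionated_counts(cfg)
        exons = simulate_exon_counts(ds)
        sub = ds.wct.samples[ds.wct.samples.treatment == "ctrl_rnai"]
        ecm = ExonCountMatrix(
            exons.counts[sub.sample_id], exons.gene_map, sub.reset_index(drop=True)
        )
        table = exon_usage_test(ecm, sub["genotype"])
        n_calls = int(table["significant"].fillna(False).sum())
        fdps.append(1.0 if n_calls > 0 else 0.0)
        n_exons = int(table["tested"].sum())
    return {"mean_fdp": float(np.mean(fdps)), "n_reps": n_reps, "n": n_exons}


def exon_shift_detection(seed: int) -> dict:
    """Detection of a 0.5 -> 0.1 usage shift at gene counts >= 1e4 per group."""
    cfg = SimConfig(
        n_features=200, seed=_sub(seed, 9),
        n_disease_de=0, n_treatment_reversed=0, n_treatment_concordant=0,
        n_treatment_only=0, n_export_altered=0,
        n_exon_usage_altered=10, exon_usage_pi=(0.5, 0.1), n_exons_per_gene_range=(3, 5),
        baseline_logmean=(5.0, 1.0), library_size_range=(2e6, 2.5e6),
        dispersion_lognormal=(float(np.log(0.05)), 0.0),
    )
    ds = simulate_fractionated_counts(cfg)
    exons = simulate_exon_counts(ds)
    sub = ds.wct.samples[ds.wct.samples.treatment == "ctrl_rnai"]
    ecm = ExonCountMatrix(exons.counts[sub.sample_id], exons.gene_map, sub.reset_index(drop=True))
    table = exon_usage_test(ecm, sub["genotype"])
    altered = ds.truth.index[ds.truth.exon_usage_altered]
    shifted_exons = [f"{g}:e1" for g in altered]
    detected = float(table.loc[shifted_exons, "significant"].mean())
    return {"detection_rate": detected, "n": len(shifted_exons)}
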