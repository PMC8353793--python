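import numpy as np
import pandas as pd
import pytest

from fractx import (
    SimConfig,
    simulate_exon_counts,
    simulate_fractionated_counts,
    simulate_two_species,
)
from fractx.io import FractxError
from fractx.simulate import _nb_draw

NO_EFFECTS = dict(
    n_disease_de=0,
    n_treatment_reversed=0,
    n_treatment_concordant=0,
    n_treatment_only=0,
    n_export_altered=0,
    n_exon_usage_altered=0,
)


def test_no_effects_config_gives_all_zero_truth():
    ds = simulate_fractionated_counts(SimConfig(n_features=100, seed=3, **NO_EFFECTS))
    assert (ds.truth[["disease_log2fc", "treatment_log2fc", "export_log2fc"]] == 0).all().all()
    assert ds.truth["is_null"].all()


def test_same_seed_is_bit_identical():
    cfg = SimConfig(n_features=300, seed=5)
    a = simulate_fractionated_counts(cfg)
    b = simulate_fractionated_counts(SimConfig(n_features=300, seed=5))
    pd.testing.assert_frame_equal(a.wct.counts, b.wct.counts)
    pd.testing.assert_frame_equal(a.cyt.counts, b.cyt.counts)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_design_layout():
    cfg = SimConfig(n_features=50, seed=1, **NO_EFFECTS)
    ds = simulate_fractionated_counts(cfg)
    for cm, fraction in ((ds.wct, "whole_cell"), (ds.cyt, "cytoplasmic")):
        assert cm.n_samples == 12  # 2 genotypes x 3 individuals x 2 treatments
        assert (cm.samples["fraction"] == fraction).all()
    assert ds.wct.feature_ids == ds.cyt.feature_ids
    assert set(ds.wct.samples["individual_id"]) == set(ds.cyt.samples["individual_id"])


def test_export_effect_alters_cytoplasm_only_ratio_matches_construction():
    """For a planted export feature, CyT/WCT mean ratio in affected samples is ~2^fc * f_g."""
    cfg = SimConfig(
        n_features=60,
        seed=9,
        n_individuals_per_genotype=50,  # 200 affected sample pairs total
        n_disease_de=0,
        n_treatment_reversed=0,
        n_treatment_concordant=0,
        n_treatment_only=0,
        n_export_altered=5,
        export_log2fc_range=(1.0, 1.0),
        baseline_logmean=(6.0, 0.5),
        library_size_range=(1e6, 1e6),
        individual_sd=0.1,
    )
    ds = simulate_fractionated_counts(cfg)
    srsf1_wct = ds.wct.samples.sample_id[ds.wct.samples.treatment == "srsf1_rnai"]
    srsf1_cyt = ds.cyt.samples.sample_id[ds.cyt.samples.treatment == "srsf1_rnai"]
    exported = ds.truth.index[ds.truth.export_log2fc != 0]
    for g in exported:
        f_g = ds.truth.at[g, "cyt_fraction"]
        ratio = ds.cyt.counts.loc[g, srsf1_cyt].mean() / ds.wct.counts.loc[g, srsf1_wct].mean()
        assert ratio == pytest.approx(2.0 * f_g, rel=0.10)
    # unaffected (ctrl) samples keep the plain f_g ratio
    ctrl_wct = ds.wct.samples.sample_id[ds.wct.samples.treatment == "ctrl_rnai"]
    ctrl_cyt = ds.cyt.samples.sample_id[ds.cyt.samples.treatment == "ctrl_rnai"]
    g = exported[0]
    ratio0 = ds.cyt.counts.loc[g, ctrl_cyt].mean() / ds.wct.counts.loc[g, ctrl_wct].mean()
    assert ratio0 == pytest.approx(ds.truth.at[g, "cyt_fraction"], rel=0.10)


def test_nb_draw_construction_fidelity():
    """Empirical means of 500 draws match configured means within 5% for means >= 100."""
    rng = np.random.default_rng(17)
    means = np.full((4, 500), 0.0) + np.array([100.0, 300.0, 1000.0, 5000.0])[:, None]
    draws = _nb_draw(rng, means, np.full(4, 0.1))
    emp = draws.mean(axis=1)
    assert np.allclose(emp, means[:, 0], rtol=0.05)


def test_effect_count_overflow_rejected():
    with pytest.raises(FractxError, match="exceed"):
        SimConfig(n_features=10, n_disease_de=8, n_treatment_reversed=0,
                  n_treatment_concordant=0, n_treatment_only=2, n_export_altered=1).validate()


def test_reversed_exceeding_disease_rejected():
    with pytest.raises(FractxError, match="n_disease_de"):
        SimConfig(n_disease_de=5, n_treatment_reversed=6, n_treatment_concordant=0).validate()


def test_reversal_sign_structure():
    cfg = SimConfig(n_features=300, seed=2, n_disease_de=40, n_treatment_reversed=20,
                    n_treatment_concordant=5, n_treatment_only=0, n_export_altered=0)
    truth = simulate_fractionated_counts(cfg).truth
    both = truth[(truth.disease_log2fc != 0) & (truth.treatment_log2fc != 0)]
    reversed_ = both[np.sign(both.disease_log2fc) == -np.sign(both.treatment_log2fc)]
    concordant = both[np.sign(both.disease_log2fc) == np.sign(both.treatment_log2fc)]
    assert len(reversed_) == 20 and len(concordant) == 5


# ---------------------------------------------------------------------------
# exon counts


def test_exon_counts_sum_exactly_to_gene_counts():
    cfg = SimConfig(n_features=40, seed=6, n_exon_usage_altered=5, **{k: v for k, v in NO_EFFECTS.items() if k != "n_exon_usage_altered"})
    ds = simulate_fractionated_counts(cfg)
    exons = simulate_exon_counts(ds)
    sums = exons.counts.groupby(exons.gene_map).sum()
    pd.testing.assert_frame_equal(
        sums.loc[ds.wct.counts.index], ds.wct.counts, check_names=False
    )


def test_unaltered_genes_have_genotype_stable_proportions():
    cfg = SimConfig(n_features=60, seed=8, baseline_logmean=(8.0, 0.3),
                    library_size_range=(5e6, 5e6), **NO_EFFECTS)
    ds = simulate_fractionated_counts(cfg)
    exons = simulate_exon_counts(ds)
    h = ds.wct.samples.sample_id[ds.wct.samples.genotype == "healthy"]
    c9 = ds.wct.samples.sample_id[ds.wct.samples.genotype == "c9"]
    gene_tot = exons.counts.groupby(exons.gene_map).transform("sum")
    prop_h = exons.counts[h].sum(axis=1) / gene_tot[h].sum(axis=1)
    prop_c9 = exons.counts[c9].sum(axis=1) / gene_tot[c9].sum(axis=1)
    assert np.abs(prop_h - prop_c9).max() < 0.05


def test_planted_usage_shift_recovered_empirically():
    """A 0.5 -> 0.1 usage shift is visible in raw proportions within +-0.05 at large counts."""
    cfg = SimConfig(n_features=30, seed=12, n_exon_usage_altered=5, exon_usage_pi=(0.5, 0.1),
                    baseline_logmean=(8.0, 0.3), library_size_range=(2e6, 2e6),
                    **{k: v for k, v in NO_EFFECTS.items() if k != "n_exon_usage_altered"})
    ds = simulate_fractionated_counts(cfg)
    exons = simulate_exon_counts(ds)
    h = ds.wct.samples.sample_id[ds.wct.samples.genotype == "healthy"]
    c9 = ds.wct.samples.sample_id[ds.wct.samples.genotype == "c9"]
    for gene in ds.truth.index[ds.truth.exon_usage_altered]:
        first = f"{gene}:e1"
        tot_h = ds.wct.counts.loc[gene, h].sum()
        tot_c9 = ds.wct.counts.loc[gene, c9].sum()
        assert tot_h >= 1e4 and tot_c9 >= 1e4
        assert exons.counts.loc[first, h].sum() / tot_h == pytest.approx(0.5, abs=0.05)
        assert exons.counts.loc[first, c9].sum() / tot_c9 == pytest.approx(0.1, abs=0.05)


# ---------------------------------------------------------------------------
# two species


def test_two_species_null_links_only_when_no_pairs_requested():
    kw = dict(n_features=200, n_disease_de=10, n_treatment_reversed=5,
              n_treatment_concordant=0, n_treatment_only=0, n_export_altered=0)
    a, b, hom = simulate_two_species(
        SimConfig(seed=1, **kw), SimConfig(seed=2, **kw), n_conserved=0, n_opposite=0,
        n_reciprocal=0,
    )
    assert (hom["planted_class"] == "null").all()
    assert a.truth.loc[hom["gene_a"], "is_null"].all()
    assert b.truth.loc[hom["gene_b"], "is_null"].all()


def test_two_species_pair_classes_and_determinism():
    kw = dict(n_features=300, n_disease_de=30, n_treatment_reversed=15,
              n_treatment_concordant=0, n_treatment_only=0, n_export_altered=0)
    args = (SimConfig(seed=3, **kw), SimConfig(seed=4, **kw))
    a, b, hom = simulate_two_species(*args, n_conserved=5, n_opposite=3)
    assert (hom["planted_class"].value_counts()[["reciprocal", "conserved", "opposite"]]
            == [2, 3, 3]).all()
    # conserved/reciprocal pairs share the disease sign; opposite pairs do not
    for _, row in hom[hom.planted_class != "null"].iterrows():
        sa = np.sign(a.truth.at[row.gene_a, "disease_log2fc"])
        sb = np.sign(b.truth.at[row.gene_b, "disease_log2fc"])
        assert (sa == sb) == (row.planted_class in ("conserved", "reciprocal"))
    _, _, hom2 = simulate_two_species(
        SimConfig(seed=3, **kw), SimConfig(seed=4, **kw), n_conserved=5, n_opposite=3
    )
    pd.testing.assert_frame_equal(hom, hom2)


def test_two_species_insufficient_features_rejected():
    kw = dict(n_features=100, n_disease_de=4, n_treatment_reversed=2,
              n_treatment_concordant=0, n_treatment_only=0, n_export_altered=0)
    with pytest.raises(FractxError, match="exceed"):
        simulate_two_species(SimConfig(seed=1, **kw), SimConfig(seed=2, **kw),
                             n_conserved=30, n_opposite=10)
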