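import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fractx import (
    CountMatrix,
    Contrast,
    NBQLModel,
    SimConfig,
    anova_de,
    de_test,
    estimate_dispersion,
    filter_low_counts,
    rle_size_factors,
    simulate_fractionated_counts,
    standard_contrast,
)
from fractx.io import FractxError
from tests.conftest import make_sheet


def two_group_cm(counts: np.ndarray) -> CountMatrix:
    sheet = make_sheet(n_per_cell=3)
    sheet = sheet[sheet.treatment == "ctrl_rnai"].reset_index(drop=True)
    frame = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=sheet["sample_id"]
    )
    return CountMatrix(frame, sheet)


DISEASE = standard_contrast("c9_disease")


# ---------------------------------------------------------------------------
# contrasts


def test_contrast_rejects_overlap_and_small_groups(small_sheet):
    overlap = Contrast("bad", {"genotype": "healthy"}, {"treatment": "ctrl_rnai"})
    with pytest.raises(FractxError, match="overlap"):
        overlap.groups(small_sheet)
    tiny = Contrast("tiny", {"individual_id": "H1"}, {"individual_id": "C91"})
    with pytest.raises(FractxError, match=">= 2 samples"):
        tiny.groups(small_sheet[small_sheet.treatment == "ctrl_rnai"].reset_index(drop=True))


def test_standard_contrast_direction_convention(small_sheet):
    a, b = standard_contrast("c9_disease").groups(small_sheet)
    assert all(s.startswith("H") for s in a) and all(s.startswith("C9") for s in b)


# ---------------------------------------------------------------------------
# dispersion estimation


def test_identical_replicates_give_zero_genewise_dispersion():
    counts = np.tile([[50], [200], [1000]], (1, 6))
    cm = two_group_cm(counts)
    disp = estimate_dispersion(cm, ["a"] * 3 + ["b"] * 3)
    assert (disp.genewise == 0).all()


def test_shrunk_lies_between_genewise_and_trend(null_dataset):
    cm = filter_low_counts(null_dataset.wct)
    groups = list(cm.samples.genotype + "_" + cm.samples.treatment)
    disp = estimate_dispersion(cm, groups)
    lo = np.minimum(disp.genewise, disp.trend)
    hi = np.maximum(disp.genewise, disp.trend)
    assert ((disp.shrunk >= lo - 1e-9) & (disp.shrunk <= hi + 1e-9)).all()
    assert 0 < disp.weight < 1


def test_all_zero_feature_rejected():
    counts = np.vstack([np.zeros((1, 6), dtype=int), np.full((1, 6), 100)])
    with pytest.raises(FractxError, match="filter"):
        estimate_dispersion(two_group_cm(counts), ["a"] * 3 + ["b"] * 3)


# ---------------------------------------------------------------------------
# de_test


def test_identical_groups_give_zero_log2fc_no_degs():
    block = np.random.default_rng(0).integers(50, 500, size=(20, 3))
    counts = np.hstack([block, block])
    table = de_test(two_group_cm(counts), DISEASE, dispersions=0.05)
    assert np.allclose(table["log2fc"], 0.0)
    assert not table["is_deg"].any()


def test_lrt_matches_statsmodels_poisson_glm():
    """With dispersion fixed at zero the LRT reduces to a Poisson GLM LRT."""
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    counts = rng.poisson(200, size=(12, 6))
    counts[3, 3:] *= 3
    cm = two_group_cm(counts)
    factors = rle_size_factors(cm)
    table = de_test(cm, DISEASE, dispersions=0.0, test="lrt", factors=factors)
    from fractx.norm import effective_library_sizes

    offset = np.log(effective_library_sizes(cm, factors).to_numpy())
    design = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)]])
    for i, fid in enumerate(cm.counts.index):
        y = cm.counts.iloc[i].to_numpy()
        full = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
        null = sm.GLM(y, design[:, :1], family=sm.families.Poisson(), offset=offset).fit()
        lr = 2 * (full.llf - null.llf)
        p_ref = stats.chi2.sf(lr, 1)
        assert table.loc[fid, "p"] == pytest.approx(p_ref, abs=1e-6)


def test_fc_threshold_monotonicity():
    rng = np.random.default_rng(7)
    counts = rng.negative_binomial(10, 10 / (10 + 300), size=(50, 6))
    cm = two_group_cm(counts)
    t1 = de_test(cm, DISEASE, dispersions=0.1, fc_threshold=1.5)
    t2 = de_test(cm, DISEASE, dispersions=0.1, fc_threshold=3.0)
    assert set(t2.index[t2.is_deg]) <= set(t1.index[t1.is_deg])


def test_scale_invariance_of_log2fc():
    """Multiplying one sample's counts by c only changes its size factor."""
    rng = np.random.default_rng(8)
    counts = rng.poisson(300, size=(40, 6))
    cm1 = two_group_cm(counts)
    scaled = counts.copy()
    scaled[:, 0] *= 4
    cm2 = two_group_cm(scaled)
    t1 = de_test(cm1, DISEASE, dispersions=0.1, factors=rle_size_factors(cm1))
    t2 = de_test(cm2, DISEASE, dispersions=0.1, factors=rle_size_factors(cm2))
    assert np.allclose(t1["log2fc"], t2["log2fc"], atol=1e-6)


def test_log2fc_recovery_unbiased_at_high_counts():
    """Planted log2 fold changes are recovered within +-0.1 at mean >= 100."""
    cfg = SimConfig(
        n_features=2000, seed=23, n_disease_de=100, disease_log2fc_range=(2.0, 2.0),
        n_treatment_reversed=0, n_treatment_concordant=0, n_treatment_only=0,
        n_export_altered=0, min_effect_log2mean=0.0, baseline_logmean=(2.0, 1.0),
        library_size_range=(2e6, 2.5e6), dispersion_lognormal=(float(np.log(0.1)), 0.0),
        individual_sd=0.0,
    )
    ds = simulate_fractionated_counts(cfg)
    cm = filter_low_counts(ds.wct)
    table = de_test(cm, DISEASE)
    planted = ds.truth[ds.truth.disease_log2fc != 0]
    shared = planted.index.intersection(table.index)
    err = table.loc[shared, "log2fc"] - planted.loc[shared, "disease_log2fc"]
    assert abs(err.mean()) < 0.1


def test_group_smaller_than_two_rejected(small_sheet):
    cm = two_group_cm(np.full((3, 6), 100))
    bad = Contrast("bad", {"individual_id": "H1"}, {"genotype": "c9"})
    with pytest.raises(FractxError):
        de_test(cm, bad, dispersions=0.1)


def test_results_summary_mentions_rule(null_dataset):
    cm = filter_low_counts(null_dataset.wct)
    res = NBQLModel(cm, DISEASE).fit()
    text = res.summary()
    assert "p < 0.05" in text and "DEGs" in text


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(5)
    exprs = pd.DataFrame(rng.normal(8, 1, size=(30, 6)),
                         columns=[f"s{i}" for i in range(6)])
    groups = ["a"] * 3 + ["b"] * 3
    table = anova_de(exprs, groups)
    for i in range(30):
        t, p_ref = stats.ttest_ind(exprs.iloc[i, 3:], exprs.iloc[i, :3])
        assert table.iloc[i]["p"] == pytest.approx(p_ref, rel=1e-9)


def test_anova_hand_computed_example():
    # classic one-way ANOVA, two groups of three
    exprs = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], columns=list("abcdef"))
    groups = ["g1"] * 3 + ["g2"] * 3
    table = anova_de(exprs, groups)
    # SSB = 6*(mean diff/2)^2 = 13.5, SSW = 4, F = 13.5/(4/4) = 13.5
    p_ref = stats.f.sf(13.5, 1, 4)
    assert table.iloc[0]["p"] == pytest.approx(p_ref, rel=1e-9)
    assert table.iloc[0]["log2fc"] == pytest.approx(3.0)
    scipy_F, scipy_p = stats.f_oneway([1, 2, 3], [4, 5, 6])
    assert table.iloc[0]["p"] == pytest.approx(scipy_p, rel=1e-9)


def test_anova_degenerate_feature_convention():
    exprs = pd.DataFrame([[5.0] * 6], columns=list("abcdef"))
    table = anova_de(exprs, ["g1"] * 3 + ["g2"] * 3)
    assert table.iloc[0]["p"] == 1.0
    assert table.iloc[0]["log2fc"] == 0.0


def test_anova_single_sample_group_rejected():
    exprs = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
    with pytest.raises(FractxError, match="< 2"):
        anova_de(exprs, ["g1", "g1", "g2"])
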