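import numpy as np
import pandas as pd
import pytest

from fractx import CountMatrix, SimConfig, simulate_fractionated_counts


def make_sheet(n_per_cell=1, fractions=("whole_cell",)):
    rows = []
    for genotype, tag in (("healthy", "H"), ("c9", "C9")):
        for i in range(1, n_per_cell + 1):
            for treatment, ttag in (("ctrl_rnai", "ctrl"), ("srsf1_rnai", "srsf1")):
                for fraction in fractions:
                    ftag = {"whole_cell": "wct", "cytoplasmic": "cyt"}[fraction]
                    rows.append(
                        {
                            "sample_id": f"{tag}{i}_{ttag}_{ftag}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "fraction": fraction,
                            "individual_id": f"{tag}{i}",
                            "replicate": 1,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def small_sheet():
    """12 whole-cell samples: 3 individuals x 2 genotypes x 2 treatments."""
    return make_sheet(n_per_cell=3)


@pytest.fixture
def tiny_cm():
    """Ten features x 6 samples (healthy/c9 ctrl-RNAi triplicates), hand-sized counts."""
    sheet = make_sheet(n_per_cell=3)
    sheet = sheet[sheet.treatment == "ctrl_rnai"].reset_index(drop=True)
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(10, len(sheet))),
        index=[f"g{i}" for i in range(10)],
        columns=sheet["sample_id"],
    )
    return CountMatrix(counts, sheet)


@pytest.fixture(scope="session")
def null_dataset():
    """Synthetic dataset with no planted effects (shared across tests)."""
    cfg = SimConfig(
        n_features=2000,
        seed=11,
        n_disease_de=0,
        n_treatment_reversed=0,
        n_treatment_concordant=0,
        n_treatment_only=0,
        n_export_altered=0,
        n_exon_usage_altered=0,
        dispersion_lognormal=(float(np.log(0.1)), 0.0),
    )
    return simulate_fractionated_counts(cfg)
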