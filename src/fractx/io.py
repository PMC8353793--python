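"""Tabular I/O for count matrices, sample sheets and result tables.

The canonical interchange format is TSV. Count matrices are features x
samples with a header row of sample ids and the feature id in the first
column; sparse matrices may instead be supplied as MatrixMarket ``.mtx``
triplets with ``<stem>.features.tsv`` / ``<stem>.samples.tsv`` sidecar id
files (one id per line). Sample sheets carry the experimental design:
``sample_id, genotype, treatment, fraction, individual_id, replicate``.

Every result table written by this package starts with a ``#`` comment line
recording the tool version, a config hash and the random seed so that runs
are auditable; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__

GENOTYPES = ("healthy", "c9")
TREATMENTS = ("ctrl_rnai", "srsf1_rnai")
FRACTIONS = ("whole_cell", "cytoplasmic", "nuclear")
SAMPLE_COLUMNS = (
    "sample_id",
    "genotype",
    "treatment",
    "fraction",
    "individual_id",
    "replicate",
)


class FractxError(ValueError):
    """Base class for user-facing validation errors."""


def get_logger(name: str = "fractx", logfile: str | Path | None = None) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet; returns a copy indexed by sample_id."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns and c != "replicate"]
    if missing:
        raise FractxError(f"sample sheet is missing required columns: {missing}")
    samples = samples.copy()
    if "replicate" not in samples.columns:
        samples["replicate"] = 1
    samples["sample_id"] = samples["sample_id"].astype(str)
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise FractxError(f"duplicated sample ids in sample sheet: {sorted(set(dup))}")
    for col, levels in (("genotype", GENOTYPES), ("treatment", TREATMENTS), ("fraction", FRACTIONS)):
        bad = set(samples[col]) - set(levels)
        if bad:
            raise FractxError(f"invalid {col} value(s) {sorted(bad)}; allowed: {levels}")
    if (samples["replicate"].astype(int) < 1).any():
        raise FractxError("replicate must be a positive integer")
    samples = samples.loc[:, list(SAMPLE_COLUMNS)]
    samples.index = pd.Index(samples["sample_id"], name="sample_id")
    return samples


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with sample metadata.

    ``counts`` is a features x samples DataFrame; ``samples`` is the sample
    sheet (one row per column of ``counts``, in column order).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()]
            raise FractxError(f"duplicated feature ids: {sorted(set(dups))[:5]}")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise FractxError("count matrix columns must match the sample sheet order")
        if self.counts.isna().any().any():
            raise FractxError("count matrix contains missing values")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise FractxError(
                    f"non-integer count at feature {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FractxError(
                f"negative count at feature {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts.loc[:, ids], self.samples.loc[ids].reset_index(drop=True))

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.samples.reset_index(drop=True))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str}))


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a TSV or MatrixMarket count matrix together with its sample sheet.

    Samples are reordered to follow the sample sheet. A sheet row with no
    matching matrix column, or a matrix column with no sheet row, is an error
    naming the offending sample.
    """
    path = Path(path)
    samples = read_sample_sheet(sample_sheet_path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        stem = path.with_suffix("")
        features = pd.read_csv(f"{stem}.features.tsv", sep="\t", header=None)[0].astype(str)
        cols = pd.read_csv(f"{stem}.samples.tsv", sep="\t", header=None)[0].astype(str)
        mat = np.asarray(mmread(path).todense())
        counts = pd.DataFrame(mat, index=features, columns=cols)
    else:
        counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        counts.columns = counts.columns.astype(str)
        counts.index = counts.index.astype(str)
    missing = set(samples["sample_id"]) - set(counts.columns)
    if missing:
        raise FractxError(f"sample sheet lists sample(s) absent from count matrix: {sorted(missing)}")
    extra = set(counts.columns) - set(samples["sample_id"])
    if extra:
        raise FractxError(f"count matrix column(s) missing from sample sheet: {sorted(extra)}")
    counts = counts.loc[:, list(samples["sample_id"])]
    counts.index.name = "feature_id"
    return CountMatrix(counts, samples.reset_index(drop=True))


def write_count_matrix(cm: CountMatrix, path: str | Path, sample_sheet_path: str | Path | None = None) -> None:
    counts = cm.counts.copy()
    counts.index.name = "feature_id"
    counts.to_csv(path, sep="\t")
    if sample_sheet_path is not None:
        cm.samples.to_csv(sample_sheet_path, sep="\t", index=False)


def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def results_header(config: Mapping | None = None, seed: int | None = None) -> str:
    return f"# fractx v{__version__} config_hash={config_hash(config)} seed={seed}"


def write_results_table(
    table: pd.DataFrame,
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    """Write a result table as TSV with an audit comment line.

    Floats are serialised with 12 significant digits so round-trips preserve
    values to within serialisation precision.
    """
    with open(path, "w") as fh:
        fh.write(results_header(config, seed) + "\n")
        table.to_csv(fh, sep="\t", float_format="%.12g", index=index)


def read_results_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_homology_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column homology table (gene_a, gene_b); extra columns are kept."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if table.shape[1] < 2:
        raise FractxError("homology table must have at least two columns")
    table = table.rename(columns={table.columns[0]: "gene_a", table.columns[1]: "gene_b"})
    if table.duplicated(["gene_a", "gene_b"]).any():
        raise FractxError("homology table contains duplicated pairs")
    return table


def write_homology_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
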