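"""Disease-modifying signature extraction and reversal analysis.

The signature is the set of features differentially expressed in *both* the
disease contrast and the treatment contrast. Each member is classified as
*reversed* when the treatment fold change opposes the disease fold change in
sign (the treatment pushes the feature back toward its healthy level) or
*concordant* otherwise. No magnitude criterion is imposed on reversal; a
descriptive restoration metric ``|log2fc_disease + log2fc_treated|`` is
reported alongside but never used for classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import FractxError


def build_signature(disease: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Intersect two DE tables on their DEG flags and classify reversal.

    Entries are sorted by status (reversed first) then by ``|log2fc_disease|``
    descending, ties broken by feature id.
    """
    for name, table in (("disease", disease), ("treated", treated)):
        if "is_deg" not in table.columns or "log2fc" not in table.columns:
            raise FractxError(f"{name} table must carry is_deg and log2fc columns")
    deg_d = disease.index[disease["is_deg"].astype(bool)]
    deg_t = treated.index[treated["is_deg"].astype(bool)]
    common = deg_d.intersection(deg_t)
    fc_d = disease.loc[common, "log2fc"].astype(float)
    fc_t = treated.loc[common, "log2fc"].astype(float)
    if (fc_d == 0).any() or (fc_t == 0).any():
        bad = list(common[(fc_d == 0) | (fc_t == 0)])[:5]
        raise FractxError(
            f"DEG-flagged feature(s) with log2fc exactly 0 (upstream inconsistency): {bad}"
        )
    status = np.where(np.sign(fc_d) == -np.sign(fc_t), "reversed", "concordant")
    table = pd.DataFrame(
        {
            "log2fc_disease": fc_d,
            "log2fc_treated": fc_t,
            "status": status,
            "restoration": np.abs(fc_d + fc_t),
        },
        index=common.rename("feature_id"),
    )
    table = table.reset_index()
    table["_absfc"] = table["log2fc_disease"].abs()
    table = table.sort_values(
        ["status", "_absfc", "feature_id"], ascending=[False, False, True]
    ).drop(columns="_absfc")
    # 'reversed' > 'concordant' lexicographically, so descending puts reversed first
    return table.set_index("feature_id")


def venn_decompose(*sets) -> dict[str, int]:
    """Exact region cardinalities of a 2- or 3-set Venn decomposition.

    Region keys are binary membership patterns over the input order, e.g.
    ``"110"`` for elements in sets 1 and 2 but not 3. Regions are disjoint
    and sum to the union's size.
    """
    if len(sets) == 1 and not isinstance(sets[0], (set, frozenset)):
        sets = tuple(sets[0])
    sets = tuple(set(s) for s in sets)
    if len(sets) not in (2, 3):
        raise FractxError("venn_decompose supports 2 or 3 sets")
    universe = set().union(*sets)
    counts: dict[str, int] = {}
    k = len(sets)
    for pattern in range(1, 2**k):
        key = format(pattern, f"0{k}b")
        region = universe.copy()
        for i, bit in enumerate(key):
            region = region & sets[i] if bit == "1" else region - sets[i]
        counts[key] = len(region)
    return counts


def signature_matrix(entries: pd.DataFrame, cluster: bool = False) -> pd.DataFrame:
    """Ordered (log2fc_disease, log2fc_treated) fold-change matrix.

    With ``cluster=True`` rows are reordered by average-linkage hierarchical
    clustering on the Euclidean distance of the signed fold-change pairs
    (deterministic: ties resolved by input order, as in the standard
    agglomeration implementation).
    """
    if len(entries) == 0:
        raise FractxError("signature is empty; nothing to order")
    mat = entries[["log2fc_disease", "log2fc_treated"]].astype(float)
    if not cluster or len(mat) < 3:
        return mat.copy()
    Z = hierarchy.linkage(pdist(mat.to_numpy(), metric="euclidean"), method="average")
    order = hierarchy.leaves_list(Z)
    return mat.iloc[order]


def signature_linkage(entries: pd.DataFrame) -> np.ndarray:
    """Average-linkage merge table for the signature fold-change pairs."""
    mat = entries[["log2fc_disease", "log2fc_treated"]].astype(float).to_numpy()
    return hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
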