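"""Cross-species ortholog mapping and direction-of-change concordance.

Homology is consumed as a static two-column table (gene_a, gene_b);
one-to-many and many-to-many relations expand into multiple pairs, and the
counting unit throughout is the homology *pair*. A pair is classified
*similar* when the signed fold changes of its two genes agree in direction
in matched contrasts and *opposite* otherwise. The strict view requires
both sides to be differentially expressed; a lenient view additionally
lists one-sided pairs (only one side a DEG), taking the other side's
direction from its raw fold-change sign. Fully-conserved reciprocal pairs
are those whose genes sit in both species' disease-modifying signatures
with matching disease directions across species and treatment opposing
disease in both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FractxError


def map_orthologs(deg_ids, table: pd.DataFrame, side: str = "a->b") -> pd.DataFrame:
    """All homology pairs whose source-side gene is in ``deg_ids``.

    ``side`` selects the source column: ``"a->b"`` filters on ``gene_a``,
    ``"b->a"`` on ``gene_b``. One-to-many relations yield multiple pairs.
    """
    if side == "a->b":
        col = "gene_a"
    elif side == "b->a":
        col = "gene_b"
    else:
        raise FractxError(f"unknown side {side!r}; use 'a->b' or 'b->a'")
    deg_ids = set(deg_ids)
    return table.loc[table[col].isin(deg_ids), ["gene_a", "gene_b"]].reset_index(drop=True)


def direction_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    table: pd.DataFrame,
    contrast_name: str = "",
    lenient: bool = False,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Classify homology pairs by agreement of fold-change direction.

    Strict mode (default) keeps pairs where both sides are DEGs; lenient
    mode keeps pairs with at least one DEG side, the sub-threshold side
    contributing its raw fold-change sign. Pairs referencing features absent
    from both DE tables are skipped. Returns ``(records, (n_similar,
    n_opposite))``.
    """
    rows = []
    for gene_a, gene_b in table[["gene_a", "gene_b"]].itertuples(index=False):
        in_a = gene_a in de_a.index
        in_b = gene_b in de_b.index
        if not in_a and not in_b:
            continue
        if not in_a or not in_b:
            continue  # direction needs both sides quantified
        fa = float(de_a.at[gene_a, "log2fc"])
        fb = float(de_b.at[gene_b, "log2fc"])
        deg_a = bool(de_a.at[gene_a, "is_deg"])
        deg_b = bool(de_b.at[gene_b, "is_deg"])
        keep = (deg_a and deg_b) if not lenient else (deg_a or deg_b)
        if not keep or fa == 0 or fb == 0:
            continue
        rows.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "contrast": contrast_name,
                "direction_a": "up" if fa > 0 else "down",
                "direction_b": "up" if fb > 0 else "down",
                "class": "similar" if np.sign(fa) == np.sign(fb) else "opposite",
                "both_deg": deg_a and deg_b,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "contrast", "direction_a", "direction_b", "class", "both_deg"],
    )
    n_similar = int((records["class"] == "similar").sum()) if len(records) else 0
    n_opposite = int((records["class"] == "opposite").sum()) if len(records) else 0
    return records, (n_similar, n_opposite)


def reciprocal_pairs(
    sig_a: pd.DataFrame,
    sig_b: pd.DataFrame,
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Homology pairs present in both species' signatures, with conservation.

    ``fully_conserved`` requires matching disease directions across species,
    matching treatment directions across species, and treatment opposing
    disease (reversal) within each species.
    """
    rows = []
    for gene_a, gene_b in table[["gene_a", "gene_b"]].itertuples(index=False):
        if gene_a not in sig_a.index or gene_b not in sig_b.index:
            continue
        da = float(sig_a.at[gene_a, "log2fc_disease"])
        ta = float(sig_a.at[gene_a, "log2fc_treated"])
        db = float(sig_b.at[gene_b, "log2fc_disease"])
        tb = float(sig_b.at[gene_b, "log2fc_treated"])
        fully = (
            np.sign(da) == np.sign(db)
            and np.sign(ta) == np.sign(tb)
            and np.sign(da) == -np.sign(ta)
            and np.sign(db) == -np.sign(tb)
        )
        rows.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "disease_dir_a": "up" if da > 0 else "down",
                "disease_dir_b": "up" if db > 0 else "down",
                "treated_dir_a": "up" if ta > 0 else "down",
                "treated_dir_b": "up" if tb > 0 else "down",
                "fully_conserved": bool(fully),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "disease_dir_a",
            "disease_dir_b",
            "treated_dir_a",
            "treated_dir_b",
            "fully_conserved",
        ],
    )
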