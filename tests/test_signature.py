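import itertools

import numpy as np
import pandas as pd
import pytest

from fractx import build_signature, signature_matrix, venn_decompose
from fractx.io import FractxError
from fractx.signature import signature_linkage


def de_table(entries: dict[str, tuple[float, bool]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "log2fc": [v[0] for v in entries.values()],
            "p": 0.01,
            "q": 0.05,
            "is_deg": [v[1] for v in entries.values()],
        },
        index=pd.Index(list(entries.keys()), name="feature_id"),
    )


def test_reversal_classification_examples():
    disease = de_table({"g1": (1.2, True), "g2": (1.2, True), "g3": (2.0, True)})
    treated = de_table({"g1": (-1.1, True), "g2": (1.4, True), "g3": (1.0, False)})
    sig = build_signature(disease, treated)
    assert sig.at["g1", "status"] == "reversed"
    assert sig.at["g2", "status"] == "concordant"
    assert "g3" not in sig.index  # not a DEG in the treated contrast


def test_membership_equals_naive_intersection_and_counts_partition():
    rng = np.random.default_rng(11)
    ids = [f"g{i}" for i in range(150)]
    disease = de_table({g: (rng.normal(), rng.random() < 0.4) for g in ids})
    treated = de_table({g: (rng.normal(), rng.random() < 0.4) for g in ids})
    sig = build_signature(disease, treated)
    naive = {
        g
        for g in ids
        for h in ids
        if g == h and disease.at[g, "is_deg"] and treated.at[h, "is_deg"]
    }
    assert set(sig.index) == naive
    n_rev = (sig.status == "reversed").sum()
    n_con = (sig.status == "concordant").sum()
    assert n_rev + n_con == len(sig)


def test_direction_negation_swaps_labels():
    rng = np.random.default_rng(13)
    ids = [f"g{i}" for i in range(60)]
    disease = de_table({g: (rng.normal(), True) for g in ids})
    treated_map = {g: (rng.normal(), True) for g in ids}
    sig = build_signature(disease, de_table(treated_map))
    flipped = build_signature(
        disease, de_table({g: (-v, d) for g, (v, d) in treated_map.items()})
    )
    swap = {"reversed": "concordant", "concordant": "reversed"}
    assert (flipped.loc[sig.index, "status"] == sig["status"].map(swap)).all()


def test_zero_fold_change_deg_is_upstream_error():
    disease = de_table({"g1": (0.0, True)})
    treated = de_table({"g1": (1.0, True)})
    with pytest.raises(FractxError, match="inconsistency"):
        build_signature(disease, treated)


def test_sort_order_reversed_first_then_magnitude():
    disease = de_table({"g1": (1.0, True), "g2": (-3.0, True), "g3": (2.0, True)})
    treated = de_table({"g1": (-1.0, True), "g2": (2.0, True), "g3": (2.5, True)})
    sig = build_signature(disease, treated)
    assert list(sig.index) == ["g2", "g1", "g3"]  # reversed by |fc| desc, then concordant


# ---------------------------------------------------------------------------
# Venn decomposition


def test_venn_two_set_example():
    counts = venn_decompose({1, 2}, {2, 3})
    assert counts == {"10": 1, "01": 1, "11": 1}


def test_venn_identical_sets():
    counts = venn_decompose({1, 2, 3}, {1, 2, 3})
    assert counts == {"10": 0, "01": 0, "11": 3}


def test_venn_three_sets_against_brute_force():
    rng = np.random.default_rng(21)
    pool = list(range(40))
    sets = [set(rng.choice(pool, 15, replace=False)) for _ in range(3)]
    counts = venn_decompose(*sets)
    universe = set().union(*sets)
    brute: dict[str, int] = {}
    for el in universe:
        key = "".join("1" if el in s else "0" for s in sets)
        brute[key] = brute.get(key, 0) + 1
    for key, n in counts.items():
        assert n == brute.get(key, 0)
    assert sum(counts.values()) == len(universe)


def test_venn_rejects_four_sets():
    with pytest.raises(FractxError):
        venn_decompose({1}, {2}, {3}, {4})


# ---------------------------------------------------------------------------
# signature matrix ordering


def sig_entries(pairs):
    return pd.DataFrame(
        {
            "log2fc_disease": [p[0] for p in pairs],
            "log2fc_treated": [p[1] for p in pairs],
            "status": "reversed",
        },
        index=pd.Index([f"g{i}" for i in range(len(pairs))], name="feature_id"),
    )


def test_single_entry_matrix():
    mat = signature_matrix(sig_entries([(1.5, -1.2)]))
    assert mat.shape == (1, 2)
    assert mat.iloc[0, 0] == 1.5


def test_duplicated_rows_cluster_adjacently():
    entries = sig_entries([(2, -2), (-3, 3), (2, -2), (-1, 1), (2, -2), (5, -5)])
    mat = signature_matrix(entries, cluster=True)
    dup_pos = [i for i, g in enumerate(mat.index) if g in {"g0", "g2", "g4"}]
    assert max(dup_pos) - min(dup_pos) == 2  # contiguous block


def test_average_linkage_matches_naive_agglomeration():
    """Merge heights and member sets agree with a hand-rolled average-linkage trace."""
    pairs = [(0.0, 0.0), (0.1, 0.0), (4.0, 4.0), (4.3, 4.0), (10.0, -10.0), (0.5, 0.2)]
    entries = sig_entries(pairs)
    Z = signature_linkage(entries)

    # naive agglomeration: repeatedly merge the closest pair of clusters,
    # distance = average pairwise Euclidean distance between members
    pts = np.array(pairs)
    clusters = {i: [i] for i in range(len(pts))}
    merges = []
    next_id = len(pts)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [np.linalg.norm(pts[i] - pts[j]) for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    for (members, height), row in zip(merges, Z):
        assert height == pytest.approx(row[2], rel=1e-9)
    assert int(Z[-1][3]) == len(pts)


def test_empty_signature_matrix_is_error():
    with pytest.raises(FractxError, match="empty"):
        signature_matrix(sig_entries([]).iloc[0:0])
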