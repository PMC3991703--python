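"""Data containers, I/O round-trips, transforms, diversity and rarefaction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amfassembly import (
    CommunityTable,
    am_sequence_fraction,
    bray_curtis,
    diversity,
    euclidean_distance,
    hellinger_transform,
    mao_tau,
    read_community_table,
    reconstruct_counts,
    table1_totals,
)
from conftest import exhaustive_rarefaction


# ---------------------------------------------------------------------------
# Container contracts and file I/O
# ---------------------------------------------------------------------------

def test_roundtrip_tsv(tmp_path):
    ab = pd.DataFrame([[3.0, 1.0], [0.0, 2.0]], index=["s1", "s2"], columns=["A", "B"])
    path = tmp_path / "community.tsv"
    ab.to_csv(path, sep="\t")
    table = read_community_table(path)
    assert table.abundance.equals(ab)


def test_negative_abundance_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample_id\tA\tB\ns1\t1\t-2\n")
    with pytest.raises(ValueError, match="negative"):
        read_community_table(path)


def test_duplicate_ids_rejected():
    ab = pd.DataFrame([[1.0], [2.0]], index=["s1", "s1"], columns=["A"])
    with pytest.raises(ValueError, match="duplicate"):
        CommunityTable(ab)


# ---------------------------------------------------------------------------
# Packaged field table
# ---------------------------------------------------------------------------

def test_table1_shape_and_spot_values(table1):
    assert len(table1.phylotype_ids) == 30
    assert len(table1.sample_ids) == 7
    assert table1["Glo-2", "Nb-HD"] == pytest.approx(37.0)
    assert table1["Glo-14", "Lv-HD"] == pytest.approx(30.1)
    # percentages: every pooled community sums to ~100
    sums = table1.abundance.sum(axis=1)
    assert (np.abs(sums - 100.0) <= 0.5).all()


def test_table1_phylotype_counts(table1):
    """30 phylotypes overall; 26 in focal roots, 23 in neighborhood roots.

    Direct counting also gives 19 shared phylotypes (26 + 23 - 30); the
    fixture follows the printed table.
    """
    ab = table1.abundance
    md = table1.metadata
    focal = ab.loc[md.index[md["root_system"] == "focal"]]
    nb = ab.loc[md.index[md["root_system"] == "neighborhood"]]
    n_focal = int((focal.sum(axis=0) > 0).sum())
    n_nb = int((nb.sum(axis=0) > 0).sum())
    assert int((ab.sum(axis=0) > 0).sum()) == 30
    assert n_focal == 26
    assert n_nb == 23
    assert n_focal + n_nb - 30 == 19


def test_am_sequence_fraction_bookkeeping():
    assert am_sequence_fraction() == pytest.approx(74.5)


# ---------------------------------------------------------------------------
# Count reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_counts_simple():
    ab = pd.DataFrame([[50.0, 50.0]], index=["s"], columns=["A", "B"])
    counts, disc = reconstruct_counts(CommunityTable(ab), {"s": 10})
    assert counts.abundance.loc["s"].tolist() == [5.0, 5.0]
    assert disc["s"] == 0


def test_reconstruct_counts_rounding():
    ab = pd.DataFrame([[33.3, 66.7]], index=["s"], columns=["A", "B"])
    counts, _ = reconstruct_counts(CommunityTable(ab), {"s": 3})
    assert counts.abundance.loc["s"].tolist() == [1.0, 2.0]


def test_reconstruct_counts_identity_on_exact_tables():
    rng = np.random.default_rng(3)
    raw = rng.integers(0, 30, size=(4, 6)).astype(float)
    raw[:, 0] += 1  # keep row sums positive
    ab = pd.DataFrame(raw, index=list("abcd"), columns=list("uvwxyz"))
    t = CommunityTable(ab)
    pct = t.relative_abundance().abundance * 100.0
    totals = {sid: int(ab.loc[sid].sum()) for sid in ab.index}
    counts, disc = reconstruct_counts(CommunityTable(pct, t.metadata), totals)
    assert np.allclose(counts.values(), raw)
    assert all(v == 0 for v in disc.values())


def test_reconstruct_counts_table1_pooled(table1, pooled_sads):
    assert int((pooled_sads["focal"] > 0).sum()) == 26
    assert int((pooled_sads["neighborhood"] > 0).sum()) == 23


def test_reconstruct_counts_rejects_bad_total(table1):
    with pytest.raises(ValueError):
        reconstruct_counts(table1, {sid: 0 for sid in table1.sample_ids})


# ---------------------------------------------------------------------------
# Transforms and distances
# ---------------------------------------------------------------------------

def test_hellinger_rows():
    ab = pd.DataFrame([[1.0, 0.0], [1.0, 4.0]], index=["a", "b"], columns=["x", "y"])
    out = hellinger_transform(CommunityTable(ab)).values()
    assert out[0].tolist() == [1.0, 0.0]
    assert out[1] == pytest.approx([math.sqrt(0.2), math.sqrt(0.8)], abs=1e-4)
    assert np.allclose((out**2).sum(axis=1), 1.0)


def test_hellinger_rejects_zero_row():
    ab = pd.DataFrame([[0.0, 0.0]], index=["a"], columns=["x", "y"])
    with pytest.raises(ValueError, match="all-zero"):
        hellinger_transform(CommunityTable(ab))


@given(
    data=st.lists(
        st.lists(st.integers(0, 50), min_size=4, max_size=4),
        min_size=2, max_size=6,
    )
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_transform_invariants_under_column_permutation(data):
    arr = np.asarray(data, dtype=float)
    arr[:, 0] += 1  # positive row sums
    perm = [2, 0, 3, 1]
    t = CommunityTable(pd.DataFrame(arr, columns=list("wxyz")))
    tp = CommunityTable(pd.DataFrame(arr[:, perm], columns=list("wxyz")))
    h = hellinger_transform(t).values()
    hp = hellinger_transform(tp).values()
    assert np.allclose(np.sort(h, axis=1), np.sort(hp, axis=1))
    bc = bray_curtis(t).d
    bcp = bray_curtis(tp).d
    assert np.allclose(bc, bcp)
    assert (bc >= 0).all() and (bc <= 1 + 1e-12).all()


def test_bray_curtis_values():
    ab = pd.DataFrame(
        [[2.0, 2.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]],
        index=list("abcd"), columns=["x", "y"],
    )
    d = bray_curtis(CommunityTable(ab)).d
    assert d[0, 1] == pytest.approx(1 / 3)
    assert d[2, 3] == pytest.approx(1.0)
    assert d[0, 0] == 0.0


def test_euclidean_distance_345():
    d = euclidean_distance(np.array([[0.0, 0.0], [3.0, 4.0]])).d
    assert d[0, 1] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# Diversity and rarefaction
# ---------------------------------------------------------------------------

def test_diversity_values():
    ab = pd.DataFrame([[10.0, 0.0, 0.0], [1.0, 1.0, 0.0]], index=["a", "b"],
                      columns=["x", "y", "z"])
    div = diversity(CommunityTable(ab))
    assert div.loc["a", "richness"] == 1
    assert div.loc["a", "shannon"] == pytest.approx(0.0)
    assert div.loc["b", "richness"] == 2
    assert div.loc["b", "shannon"] == pytest.approx(math.log(2))
    div2 = diversity(CommunityTable(ab), base=2)
    assert div2.loc["b", "shannon"] == pytest.approx(1.0)


def test_mao_tau_two_sample_example():
    ab = pd.DataFrame([[1.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["A", "B"])
    curve = mao_tau(CommunityTable(ab))
    assert curve.tau[0] == pytest.approx(1.5)
    assert curve.tau[-1] == pytest.approx(2.0)


def test_mao_tau_matches_exhaustive_subset_oracle(rng):
    """tau(h) equals the brute-force mean richness over all h-subsets."""
    for H in (3, 5, 8):
        pres = rng.random((H, 12)) < 0.4
        ab = pd.DataFrame(pres.astype(float), columns=[f"p{j}" for j in range(12)])
        curve = mao_tau(CommunityTable(ab))
        for h in range(1, H + 1):
            assert curve.tau[h - 1] == pytest.approx(
                exhaustive_rarefaction(pres, h), abs=1e-10
            )
        assert np.all(np.diff(curve.tau) >= -1e-12)  # non-decreasing
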