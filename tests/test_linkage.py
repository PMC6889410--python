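"""Duplicate removal, barcode merging, molecule calling, filters and
10x conversion, with brute-force oracles for the merge rule."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from blrkit import (
    PipelineParams,
    call_molecules,
    filter_droplets,
    merge_barcodes,
    remove_duplicates,
    strip_low_count,
    tenx_convert,
)
from blrkit.linkage import assign_groups, shared_proximal_pairs


def make_aln(rows):
    """rows: (read_id, bx, chrom, pos1, pos2[, sumq])"""
    recs = []
    for r in rows:
        read_id, bx, chrom, pos1, pos2 = r[:5]
        sumq = r[5] if len(r) > 5 else 8000
        recs.append((read_id, bx, chrom, pos1, pos2, "FR", sumq, 100))
    df = pd.DataFrame(
        recs,
        columns=["read_id", "bx", "chrom", "pos1", "pos2", "orientation", "sumq", "read_length"],
    )
    return df.sort_values(["chrom", "pos1", "read_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# duplicates


def test_same_barcode_same_coordinates_deduplicated():
    aln = make_aln([("a", "B1", "chr1", 100, 300, 7000), ("b", "B1", "chr1", 100, 300, 8000)])
    out, n = remove_duplicates(aln)
    assert n == 1
    kept = out[~out["duplicate"]]
    assert list(kept["read_id"]) == ["b"]  # higher summed quality wins


def test_duplicate_tie_keeps_first():
    aln = make_aln([("a", "B1", "chr1", 100, 300), ("b", "B1", "chr1", 100, 300)])
    out, n = remove_duplicates(aln)
    assert list(out[~out["duplicate"]]["read_id"]) == ["a"]


def test_different_barcode_or_position_not_duplicates():
    aln = make_aln(
        [
            ("a", "B1", "chr1", 100, 300),
            ("b", "B2", "chr1", 100, 300),
            ("c", "B1", "chr1", 101, 300),
        ]
    )
    out, n = remove_duplicates(aln)
    assert n == 0


def test_unsorted_input_rejected():
    aln = make_aln([("a", "B1", "chr1", 100, 300), ("b", "B1", "chr1", 50, 300)])
    aln = aln.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError):
        remove_duplicates(aln)


# ---------------------------------------------------------------------------
# merging


def brute_force_groups(aln, params):
    """O(n^2) oracle: test every barcode pair with a maximum bipartite
    matching of proximal read-pair pairings, then take connected
    components."""
    use = aln[aln["bx"].notna()]
    pos = {
        bx: {c: np.sort(s["pos1"].to_numpy()) for c, s in sub.groupby("chrom")}
        for bx, sub in use.groupby("bx")
    }
    g = nx.Graph()
    g.add_nodes_from(pos)
    for b1, b2 in itertools.combinations(sorted(pos), 2):
        shared = 0
        for chrom in pos[b1].keys() & pos[b2].keys():
            bip = nx.Graph()
            a_nodes = [("a", i) for i in range(len(pos[b1][chrom]))]
            b_nodes = [("b", i) for i in range(len(pos[b2][chrom]))]
            bip.add_nodes_from(a_nodes, bipartite=0)
            bip.add_nodes_from(b_nodes, bipartite=1)
            for (ka, i), (kb, j) in itertools.product(a_nodes, b_nodes):
                if abs(int(pos[b1][chrom][i]) - int(pos[b2][chrom][j])) < params.merge_proximity:
                    bip.add_edge(("a", i), ("b", j))
            matching = nx.bipartite.maximum_matching(bip, top_nodes=a_nodes)
            shared += len(matching) // 2
        if shared >= params.merge_min_shared_pairs:
            g.add_edge(b1, b2)
    return sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )


def test_two_shared_proximal_pairs_merge():
    aln = make_aln(
        [
            ("a1", "A", "chr1", 1000, 1300),
            ("a2", "A", "chr1", 50_000, 50_300),
            ("b1", "B", "chr1", 2000, 2300),
            ("b2", "B", "chr1", 60_000, 60_300),
        ]
    )
    groups, mapping = merge_barcodes(aln, PipelineParams())
    assert len(groups) == 1
    assert mapping["A"] == mapping["B"]


def test_one_shared_pair_does_not_merge():
    aln = make_aln(
        [
            ("a1", "A", "chr1", 1000, 1300),
            ("a2", "A", "chr1", 500_000, 500_300),
            ("b1", "B", "chr1", 2000, 2300),
            ("b2", "B", "chr1", 900_000, 900_300),
        ]
    )
    groups, mapping = merge_barcodes(aln, PipelineParams())
    assert len(groups) == 2


def test_proximity_boundary_is_strict():
    """Distance must be < 100 kb: exactly 100,000 does not count."""
    base = [
        ("a1", "A", "chr1", 0, 300),
        ("a2", "A", "chr1", 1_000_000, 1_000_300),
        ("b2", "B", "chr1", 1_000_000, 1_000_300),
    ]
    at = make_aln(base + [("b1", "B", "chr1", 100_000, 100_300)])
    groups, _ = merge_barcodes(at, PipelineParams())
    assert len(groups) == 2
    within = make_aln(base + [("b1", "B", "chr1", 99_999, 100_299)])
    groups, _ = merge_barcodes(within, PipelineParams())
    assert len(groups) == 1


def test_transitive_chain_forms_single_group():
    rows = []
    for bx, off in (("A", 0), ("B", 50_000), ("C", 100_000)):
        rows += [(f"{bx}1", bx, "chr1", off, off + 300), (f"{bx}2", bx, "chr1", off + 10_000, off + 10_300)]
    # A-B and B-C within 100 kb; A-C pairs are 100 kb apart -> no direct link
    aln = make_aln(rows)
    groups, mapping = merge_barcodes(aln, PipelineParams())
    assert len(groups) == 1
    assert mapping["A"] == mapping["C"]
    assert brute_force_groups(aln, PipelineParams()) == [frozenset("ABC")]


@pytest.mark.parametrize("trial", range(12))
def test_merge_matches_brute_force_oracle(trial):
    """Greedy binned implementation equals the O(n^2) all-pairs +
    maximum-matching + connected-components oracle on random instances."""
    rng = np.random.default_rng(300 + trial)
    n_bc = int(rng.integers(5, 40))
    rows = []
    rid = 0
    for b in range(n_bc):
        bx = f"BC{b:03d}"
        for _ in range(int(rng.integers(1, 7))):
            chrom = f"chr{int(rng.integers(1, 3))}"
            p = int(rng.integers(0, 600_000))
            rows.append((f"r{rid}", bx, chrom, p, p + 300))
            rid += 1
    params = PipelineParams(merge_proximity=50_000, merge_min_shared_pairs=2)
    aln = make_aln(rows)
    groups, _ = merge_barcodes(aln, params)
    got = sorted((g.barcodes for g in groups), key=min)
    assert got == brute_force_groups(aln, params)


def test_greedy_pairing_matches_maximum_matching():
    """Two-pointer greedy nearest pairing attains the maximum bipartite
    matching size for points on a line with a fixed tolerance."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        a = np.sort(rng.integers(0, 2000, size=rng.integers(1, 10)))
        b = np.sort(rng.integers(0, 2000, size=rng.integers(1, 10)))
        prox = int(rng.integers(1, 500))
        bip = nx.Graph()
        bip.add_nodes_from([("a", i) for i in range(len(a))], bipartite=0)
        bip.add_nodes_from([("b", j) for j in range(len(b))], bipartite=1)
        for i in range(len(a)):
            for j in range(len(b)):
                if abs(int(a[i]) - int(b[j])) < prox:
                    bip.add_edge(("a", i), ("b", j))
        want = len(nx.bipartite.maximum_matching(bip, top_nodes=[("a", i) for i in range(len(a))])) // 2
        assert shared_proximal_pairs(a, b, prox) == want


# ---------------------------------------------------------------------------
# molecules


def grouped(rows, params=None):
    aln = make_aln(rows)
    aln["duplicate"] = False
    groups, mapping = merge_barcodes(aln, params or PipelineParams())
    return assign_groups(aln, mapping)


def test_close_reads_form_one_molecule():
    aln = grouped(
        [("a", "A", "chr1", 0, 300), ("b", "A", "chr1", 10_000, 10_300), ("c", "A", "chr1", 20_000, 20_300)]
    )
    mols, aln = call_molecules(aln)
    assert len(mols) == 1
    m = mols.iloc[0]
    assert (m["start"], m["end"], m["read_pair_count"]) == (0, 20_400, 3)


def test_gap_above_threshold_splits():
    aln = grouped([("a", "A", "chr1", 0, 300), ("b", "A", "chr1", 40_000, 40_300)])
    mols, _ = call_molecules(aln)
    assert len(mols) == 2


def test_gap_of_exactly_30kb_is_inclusive():
    """Reads exactly 30,000 bases apart stay in one molecule; 30,001 splits."""
    aln = grouped([("a", "A", "chr1", 0, 300), ("b", "A", "chr1", 30_000, 30_300)])
    assert len(call_molecules(aln)[0]) == 1
    aln = grouped([("a", "A", "chr1", 0, 300), ("b", "A", "chr1", 30_001, 30_301)])
    assert len(call_molecules(aln)[0]) == 2


def test_molecules_split_per_chromosome():
    aln = grouped([("a", "A", "chr1", 0, 300), ("b", "A", "chr2", 0, 300)])
    mols, tagged = call_molecules(aln)
    assert len(mols) == 2
    assert tagged["mi"].notna().all()


# ---------------------------------------------------------------------------
# filters


def synthetic_group(n_molecules, bx="A", pairs_per_molecule=1):
    rows = []
    rid = 0
    for m in range(n_molecules):
        base = m * 100_000  # separate molecules by > 30 kb
        for k in range(pairs_per_molecule):
            rows.append((f"r{rid}", bx, "chr1", base + k * 100, base + k * 100 + 300))
            rid += 1
    return rows


def test_droplet_filter_boundary_260_261():
    params = PipelineParams()
    for n, expect_stripped in ((261, True), (260, False)):
        aln = grouped(synthetic_group(n), params)
        mols, aln = call_molecules(aln, params)
        assert len(mols) == n
        out, kept, stripped = filter_droplets(aln, mols, params)
        if expect_stripped:
            assert stripped and out["bx"].isna().all()
        else:
            assert not stripped and out["bx"].notna().all()


def test_low_count_boundary_3_4():
    params = PipelineParams()
    for n, expect_stripped in ((3, True), (4, False)):
        rows = [(f"r{i}", "A", "chr1", i * 100, i * 100 + 300) for i in range(n)]
        aln = grouped(rows, params)
        out, kept, stripped = strip_low_count(aln, params)
        assert bool(stripped) == expect_stripped
        assert out["bx"].isna().all() == expect_stripped


def test_empty_group_set_filters_are_noops():
    aln = make_aln([])
    aln["duplicate"] = pd.Series(dtype=bool)
    aln["group"] = pd.Series(dtype="Int64")
    mols = pd.DataFrame(columns=["molecule_id", "group_id", "chrom", "start", "end", "read_pair_count", "length"])
    out, kept, stripped = filter_droplets(aln, mols, PipelineParams())
    assert kept == [] and stripped == []
    out, kept, stripped = strip_low_count(out, PipelineParams())
    assert kept == [] and stripped == []


def test_filters_never_resurrect_stripped_barcodes():
    """Applying the droplet filter then the low-count strip leaves every
    previously stripped read barcode-less."""
    params = PipelineParams(max_molecules_per_droplet=2, min_read_pairs_per_group=2)
    rows = synthetic_group(3, bx="A") + [("x", "B", "chr2", 0, 300)]
    aln = grouped(rows, params)
    mols, aln = call_molecules(aln, params)
    aln, _, stripped_d = filter_droplets(aln, mols, params)
    assert stripped_d  # A exceeded 2 molecules
    aln, _, stripped_l = strip_low_count(aln, params)
    assert stripped_l  # B has a single pair
    assert aln["bx"].isna().all()
    assert aln["stripped"].all()


# ---------------------------------------------------------------------------
# 10x conversion


def test_tenx_mapping_is_injective_and_deterministic():
    mapping = tenx_convert([5, 3, 9])
    again = tenx_convert([9, 5, 3])
    assert mapping == again
    assert len(set(mapping.values())) == 3
    assert all(len(b) == 16 and set(b) <= set("ACGT") for b in mapping.values())


def test_tenx_limit_enforced():
    with pytest.raises(ValueError, match="limit of 10"):
        tenx_convert(range(11), limit=10)
    assert len(tenx_convert(range(10), limit=10)) == 10
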