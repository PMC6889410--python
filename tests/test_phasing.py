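"""Phaser behavior: block construction, switch-error metrics, the
exhaustive-orientation oracle, and exactness on error-free molecules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from blrkit import evaluate_phasing, phase_variants, phase_with_truth_molecules
from blrkit.phasing import PhaseResult, allele_observations


def variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "hap_with_alt": [0] * len(positions),
        }
    )


def obs(rows):
    return pd.DataFrame(rows, columns=["mi", "var_idx", "allele"])


def test_one_molecule_two_snvs_one_block():
    var = variants([100, 200])
    result = phase_variants(var, obs([(0, 0, 1), (0, 1, 1)]))
    assert len(result.phased_blocks) == 1
    b = result.phased_blocks[0]
    assert b.n_variants == 2
    # equal alleles on one molecule -> same haplotype parity
    assert b.variants[0][2] == b.variants[1][2]


def test_trans_molecule_gives_opposite_parity():
    var = variants([100, 200])
    result = phase_variants(var, obs([(0, 0, 1), (0, 1, 0)]))
    (b,) = result.phased_blocks
    assert b.variants[0][2] != b.variants[1][2]


def test_unlinked_snvs_are_singleton_blocks_counted_unphased():
    var = variants([100, 200])
    result = phase_variants(var, obs([(0, 0, 1), (1, 1, 1)]))
    assert result.phased_blocks == []
    assert len(result.blocks) == 2
    assert result.n_unphased == 2
    metrics = evaluate_phasing(result, var)
    assert metrics["phased_fraction"] == 0.0
    assert metrics["n50_phase_block"] == 0


def test_conflicting_zero_net_weight_leaves_unphased():
    var = variants([100, 200])
    conflicting = obs([(0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 0)])
    result = phase_variants(var, conflicting)
    assert result.phased_blocks == []


def test_switch_error_counts_flip_points():
    """One flipped variant inside a 10-variant block creates 2 switch
    points (entering and leaving the flipped stretch)."""
    positions = [100 * (i + 1) for i in range(10)]
    var = variants(positions)
    rows = []
    for i in range(9):  # chain of cis molecules
        rows += [(i, i, 1), (i, i + 1, 1)]
    result = phase_variants(var, obs(rows))
    (block,) = result.phased_blocks
    truth = var.copy()
    base = [p for _v, _pos, p in block.variants]
    truth["hap_with_alt"] = base  # perfect agreement
    assert evaluate_phasing(result, truth)["switch_errors"] == 0
    flipped = list(base)
    flipped[4] ^= 1
    truth["hap_with_alt"] = flipped
    assert evaluate_phasing(result, truth)["switch_errors"] == 2
    # flipped at the block edge: a single switch point
    edge = list(base)
    edge[9] ^= 1
    truth["hap_with_alt"] = edge
    assert evaluate_phasing(result, truth)["switch_errors"] == 1


def test_switch_error_invariant_under_block_flip():
    """Haplotype labels are arbitrary: flipping every parity in a block
    leaves the switch error unchanged."""
    rng = np.random.default_rng(1)
    positions = [100 * (i + 1) for i in range(8)]
    var = variants(positions)
    rows = []
    for i in range(7):
        a = int(rng.integers(0, 2))
        b = int(rng.integers(0, 2))
        rows += [(i, i, a), (i, i + 1, b)]
    result = phase_variants(var, obs(rows))
    truth = var.copy()
    truth["hap_with_alt"] = rng.integers(0, 2, size=8)
    before = evaluate_phasing(result, truth)["switch_errors"]
    flipped = PhaseResult(
        blocks=[
            type(b)(b.block_id, b.chrom, [(v, p, parity ^ 1) for v, p, parity in b.variants])
            for b in result.blocks
        ],
        assignments={v: (bid, par ^ 1) for v, (bid, par) in result.assignments.items()},
        n_variants=result.n_variants,
        n_unphased=result.n_unphased,
    )
    assert evaluate_phasing(flipped, truth)["switch_errors"] == before


def exhaustive_best_score(edges, nodes):
    """Oracle: maximize satisfied cis/trans evidence over all 2^k
    orientations."""
    best = -np.inf
    nodes = sorted(nodes)
    for bits in itertools.product([0, 1], repeat=len(nodes)):
        parity = dict(zip(nodes, bits))
        score = 0
        for (u, v), w in edges.items():
            score += w if parity[u] == parity[v] else -w
        best = max(best, score)
    return best


def forest_score(result, edges):
    score = 0
    for (u, v), w in edges.items():
        pu = result.assignments[u][1]
        pv = result.assignments[v][1]
        score += w if pu == pv else -w
    return score


@pytest.mark.parametrize("trial", range(10))
def test_forest_orientation_matches_exhaustive_enumeration(trial):
    """On consistent (error-free molecule) instances with <= 12 variants,
    the spanning-forest orientation attains the exhaustive optimum."""
    rng = np.random.default_rng(500 + trial)
    k = int(rng.integers(4, 13))
    positions = [100 * (i + 1) for i in range(k)]
    var = variants(positions)
    truth_parity = rng.integers(0, 2, size=k)
    rows = []
    mi = 0
    for _ in range(k * 2):  # random error-free molecules over variant runs
        a = int(rng.integers(0, k - 1))
        b = int(rng.integers(a + 1, k + 1))
        hap = int(rng.integers(0, 2))
        for v in range(a, b):
            allele = 1 if truth_parity[v] == hap else 0
            rows.append((mi, v, allele))
        mi += 1
    result = phase_variants(var, obs(rows))
    edges = {}
    o = obs(rows)
    for mi_, sub in o.groupby("mi"):
        s = sub.sort_values("var_idx")
        for (u, au), (v, av) in zip(
            s[["var_idx", "allele"]].itertuples(index=False),
            s[["var_idx", "allele"]].iloc[1:].itertuples(index=False),
        ):
            key = (u, v)
            edges[key] = edges.get(key, 0) + (1 if au == av else -1)
    assert forest_score(result, edges) == exhaustive_best_score(edges, range(k))


def test_single_block_n50_is_its_span():
    var = variants([100, 500, 900])
    rows = [(0, 0, 1), (0, 1, 1), (0, 2, 0)]
    result = phase_variants(var, obs(rows))
    metrics = evaluate_phasing(result, var)
    assert metrics["n50_phase_block"] == 801
    assert metrics["longest_block"] == 801


def test_error_free_simulation_phases_without_switch_errors(clean_lib):
    """With error-free inserts and true-fragment molecule tags, every
    phased variant is correct (switch error 0) and the phased set equals
    the molecule-linked set."""
    from blrkit import TrimParams, extract_read_pairs
    from blrkit.extract import library_pairs

    params = TrimParams(design=clean_lib.design)
    pairs = extract_read_pairs(library_pairs(clean_lib), params).extracted
    out = phase_with_truth_molecules(clean_lib, pairs)
    metrics = out["metrics"]
    assert metrics["switch_errors"] == 0
    # molecule-linked variants: covered together with >= 1 other variant
    linked = set()
    for _mi, sub in out["observations"].groupby("mi"):
        if sub["var_idx"].nunique() >= 2:
            linked.update(int(v) for v in sub["var_idx"])
    phased = {v for b in out["result"].phased_blocks for v, _p, _q in b.variants}
    assert phased == linked
    assert metrics["n_phased"] == len(linked)


def test_phased_fraction_monotone_in_molecule_coverage():
    """More molecules can only phase more variants (nested datasets)."""
    rng = np.random.default_rng(3)
    k = 20
    var = variants([1000 * (i + 1) for i in range(k)])
    truth_parity = rng.integers(0, 2, size=k)
    rows = []
    fractions = []
    for mi in range(30):  # error-free molecules from either haplotype
        a = int(rng.integers(0, k - 1))
        b = min(k, a + int(rng.integers(2, 6)))
        hap = int(rng.integers(0, 2))
        for v in range(a, b):
            rows.append((mi, v, 1 if truth_parity[v] == hap else 0))
        result = phase_variants(var, obs(rows))
        fractions.append(evaluate_phasing(result, var)["n_phased"])
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))


def test_allele_observations_reads_both_mates():
    var = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [5, 105], "ref": ["A", "A"], "alt": ["C", "C"]}
    )
    tagged = pd.DataFrame(
        [(0, "chr1", 0, "AAAAACAAAA", 100, "AAAAAAAAAA")],
        columns=["mi", "chrom", "pos1", "seq1", "pos2", "seq2"],
    )
    o = allele_observations(tagged, var)
    got = dict(zip(o["var_idx"], o["allele"]))
    assert got == {0: 1, 1: 0}
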