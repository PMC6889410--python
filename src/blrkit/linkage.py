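"""Droplet deconvolution from barcode-tagged alignments.

The stages mirror the linked-read data-processing chain:

1. barcode-aware duplicate removal (identical coordinates AND barcode);
2. merging of barcodes that share at least ``merge_min_shared_pairs``
   proximal (< ``merge_proximity`` bases apart on the same chromosome)
   read pairs into droplet groups (connected components, so merging is
   transitive);
3. molecule calling within each group: same-chromosome read pairs are
   split wherever consecutive leftmost positions are more than
   ``molecule_max_gap`` apart (a gap of exactly the threshold does not
   split);
4. stripping barcodes from abnormally large droplets (> 260 molecules by
   default) and from groups with too few read pairs (< 4 by default);
5. deterministic translation of surviving groups to 16-base barcodes for
   10x-style downstream tools (which cap the whitelist at 4.8 M barcodes).

Alignments are handled as a pandas table with one row per read pair:
``read_id, bx, chrom, pos1, pos2, orientation, sumq, read_length`` (mate
leftmost positions, 0-based). Reads are never deleted: duplicates are
flagged and stripped reads keep a null barcode, so conservation identities
hold at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PipelineParams:
    """Thresholds of the deconvolution chain (defaults as used for human
    whole-genome libraries; fully configurable for toy genomes)."""

    merge_proximity: int = 100_000
    merge_min_shared_pairs: int = 2
    molecule_max_gap: int = 30_000
    max_molecules_per_droplet: int = 260
    min_read_pairs_per_group: int = 4
    tenx_barcode_limit: int = 4_800_000
    overlap_window: int = 250_000

    def __post_init__(self) -> None:
        for name in (
            "merge_proximity",
            "merge_min_shared_pairs",
            "molecule_max_gap",
            "max_molecules_per_droplet",
            "min_read_pairs_per_group",
            "tenx_barcode_limit",
            "overlap_window",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class DropletGroup:
    """Union of canonical barcodes inferred to share one emulsion droplet."""

    group_id: int
    barcodes: frozenset


# ---------------------------------------------------------------------------
# duplicate removal


def remove_duplicates(aln: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Flag barcode-aware duplicates on a coordinate-sorted alignment table.

    Among read pairs with identical (barcode, chrom, mate leftmost
    positions, orientation) exactly one is retained: the highest summed
    base quality, first-in-file on ties. Pairs without a barcode are passed
    through untouched. Raises on unsorted input.
    """
    pos_sorted = aln.groupby("chrom", sort=False)["pos1"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    )
    if not bool(pos_sorted.all()):
        raise ValueError("alignments must be coordinate-sorted (chrom, pos1)")
    aln = aln.reset_index(drop=True).copy()
    aln["duplicate"] = False
    tagged = aln[aln["bx"].notna()]
    if len(tagged):
        keep = tagged.groupby(
            ["bx", "chrom", "pos1", "pos2", "orientation"], sort=False
        )["sumq"].idxmax()
        dup_idx = tagged.index.difference(keep)
        aln.loc[dup_idx, "duplicate"] = True
    return aln, int(aln["duplicate"].sum())


# ---------------------------------------------------------------------------
# barcode merging into droplet groups


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def shared_proximal_pairs(a: np.ndarray, b: np.ndarray, proximity: int) -> int:
    """Count shared proximal read pairs between two sorted position arrays.

    Greedy nearest pairing: walk both sorted lists with two pointers and
    match the current heads when they lie within ``proximity`` of each
    other; each read pair participates in at most one match. For matching
    points on a line with a fixed tolerance this greedy scheme attains the
    maximum matching size.
    """
    i = j = n = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if -proximity < d < proximity:
            n += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return n


def _barcode_positions(aln: pd.DataFrame) -> dict:
    """barcode -> {chrom -> sorted pair-leftmost positions} over retained,
    barcoded read pairs."""
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    use = aln[aln["bx"].notna() & ~dup]
    out: dict = {}
    for (bx, chrom), sub in use.groupby(["bx", "chrom"], sort=True):
        out.setdefault(bx, {})[chrom] = np.sort(sub["pos1"].to_numpy())
    return out


def barcodes_linked(
    pos_a: dict, pos_b: dict, params: PipelineParams
) -> bool:
    """Spec of one link: >= merge_min_shared_pairs shared proximal read
    pairs, summed over chromosomes (distance is undefined across
    chromosomes)."""
    total = 0
    for chrom in pos_a.keys() & pos_b.keys():
        total += shared_proximal_pairs(pos_a[chrom], pos_b[chrom], params.merge_proximity)
        if total >= params.merge_min_shared_pairs:
            return True
    return False


def merge_barcodes(
    aln: pd.DataFrame, params: PipelineParams | None = None
) -> tuple[list[DropletGroup], dict]:
    """Merge barcodes sharing proximal read pairs into droplet groups.

    Returns the groups (connected components of the link graph; singleton
    barcodes form singleton groups) and a barcode -> group_id map. Group
    ids are assigned in sorted order of each group's smallest barcode, so
    the output is independent of traversal order.
    """
    params = params or PipelineParams()
    positions = _barcode_positions(aln)
    barcodes = sorted(positions)
    dsu = _DSU(barcodes)

    # candidate pairs: barcodes co-occurring in the same or adjacent
    # proximity-sized genome bins (any linked pair must co-occur this way)
    bins: dict = {}
    for bx, per_chrom in positions.items():
        for chrom, pos in per_chrom.items():
            for b in np.unique(pos // params.merge_proximity):
                bins.setdefault((chrom, int(b)), set()).add(bx)
    for (chrom, b), members in sorted(bins.items(), key=lambda kv: kv[0]):
        adjacent = members | bins.get((chrom, b + 1), set())
        for b1, b2 in combinations(sorted(adjacent), 2):
            if dsu.find(b1) == dsu.find(b2):
                continue  # already merged; link test cannot change the result
            if barcodes_linked(positions[b1], positions[b2], params):
                dsu.union(b1, b2)

    comps: dict = {}
    for bx in barcodes:
        comps.setdefault(dsu.find(bx), []).append(bx)
    groups = [
        DropletGroup(group_id=i, barcodes=frozenset(members))
        for i, members in enumerate(sorted(comps.values(), key=lambda m: min(m)))
    ]
    bx_to_group = {bx: g.group_id for g in groups for bx in g.barcodes}
    return groups, bx_to_group


def assign_groups(aln: pd.DataFrame, bx_to_group: dict) -> pd.DataFrame:
    """Add a nullable ``group`` column mapping each read's barcode to its
    droplet group."""
    aln = aln.copy()
    aln["group"] = aln["bx"].map(bx_to_group).astype("Int64")
    return aln


# ---------------------------------------------------------------------------
# molecule calling


def call_molecules(
    aln: pd.DataFrame, params: PipelineParams | None = None, group_col: str = "group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call molecules within every droplet group.

    Per (group, chromosome), read-pair leftmost positions are sorted and
    split where consecutive positions differ by more than
    ``molecule_max_gap`` (a gap of exactly the threshold stays in one
    molecule). A molecule spans from its first pair's leftmost position to
    its last pair's rightmost mate plus the read length (the fragment's
    true right end is unobservable).

    Returns ``(molecules, aln)`` where molecules has one row per molecule
    (molecule_id, group_id, chrom, start, end, read_pair_count, length)
    and ``aln`` gains a nullable ``mi`` molecule-id column. Unmapped or
    barcode-stripped reads are skipped (their count is in the caller's
    hands: they simply keep a null ``mi``).
    """
    params = params or PipelineParams()
    aln = aln.reset_index(drop=True).copy()
    aln["mi"] = pd.array([pd.NA] * len(aln), dtype="Int64")
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    use = aln[aln[group_col].notna() & ~dup]
    rows = []
    mi = 0
    mi_col = np.full(len(aln), -1, dtype=np.int64)
    for (gid, chrom), sub in use.groupby([group_col, "chrom"], sort=True):
        order = sub.sort_values(["pos1", "read_id"], kind="stable")
        pos = order["pos1"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > params.molecule_max_gap)[0] + 1
        for run in np.split(np.arange(len(pos)), breaks):
            idx = order.index[run]
            start = int(pos[run[0]])
            rl = int(aln.loc[idx, "read_length"].iloc[0])
            end = int(aln.loc[idx, "pos2"].max()) + rl
            rows.append((mi, gid, chrom, start, end, len(run), end - start))
            mi_col[idx] = mi
            mi += 1
    mask = mi_col >= 0
    aln.loc[mask, "mi"] = mi_col[mask]
    molecules = pd.DataFrame(
        rows,
        columns=["molecule_id", "group_id", "chrom", "start", "end", "read_pair_count", "length"],
    )
    return molecules, aln


# ---------------------------------------------------------------------------
# droplet / group filters


def filter_droplets(
    aln: pd.DataFrame,
    molecules: pd.DataFrame,
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, list, list]:
    """Strip barcodes from droplet groups with more molecules than
    ``max_molecules_per_droplet`` (reads are retained, barcode-less).

    Returns ``(aln, kept_group_ids, stripped_group_ids)``.
    """
    params = params or PipelineParams()
    per_group = molecules.groupby("group_id").size()
    stripped = sorted(per_group[per_group > params.max_molecules_per_droplet].index)
    kept = sorted(set(aln["group"].dropna().unique()) - set(stripped))
    aln = _strip_groups(aln, stripped)
    return aln, kept, stripped


def strip_low_count(
    aln: pd.DataFrame, params: PipelineParams | None = None
) -> tuple[pd.DataFrame, list, list]:
    """Strip barcodes from groups with fewer than
    ``min_read_pairs_per_group`` retained read pairs."""
    params = params or PipelineParams()
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    counts = aln[aln["group"].notna() & ~dup].groupby("group").size()
    stripped = sorted(counts[counts < params.min_read_pairs_per_group].index)
    kept = sorted(set(counts.index) - set(stripped))
    aln = _strip_groups(aln, stripped)
    return aln, kept, stripped


def _strip_groups(aln: pd.DataFrame, group_ids) -> pd.DataFrame:
    aln = aln.copy()
    if "stripped" not in aln:
        aln["stripped"] = pd.Series(False, index=aln.index, dtype=bool)
    if len(aln) == 0:
        return aln
    mask = aln["group"].isin(group_ids)
    aln.loc[mask, "stripped"] = True
    aln.loc[mask, "bx"] = None
    aln.loc[mask, "group"] = pd.NA
    aln.loc[mask, "mi"] = pd.NA if "mi" in aln else None
    return aln


# ---------------------------------------------------------------------------
# 10x-style conversion


def tenx_barcode(index: int) -> str:
    """Deterministic injective 16-mer for a whitelist index (base-4 digits)."""
    bases = "ACGT"
    out = []
    for _ in range(16):
        out.append(bases[index % 4])
        index //= 4
    return "".join(reversed(out))


def tenx_convert(group_ids, limit: int = 4_800_000) -> dict:
    """Assign each surviving droplet group a distinct 16-base barcode.

    The assignment is deterministic (groups in sorted order, base-4
    encoded index) and fails explicitly when the group count exceeds the
    downstream whitelist limit.
    """
    group_ids = sorted(group_ids)
    if len(group_ids) > limit:
        raise ValueError(
            f"{len(group_ids)} droplet groups exceed the 10x barcode limit of {limit}"
        )
    return {gid: tenx_barcode(i) for i, gid in enumerate(group_ids)}


# ---------------------------------------------------------------------------
# conservation


def read_conservation(aln: pd.DataFrame) -> dict:
    """Read-pair bookkeeping: pairs in = retained + duplicates; stripped
    pairs are retained but barcode-less."""
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    stripped = aln["stripped"] if "stripped" in aln else pd.Series(False, index=aln.index)
    return {
        "pairs_in": int(len(aln)),
        "duplicates": int(dup.sum()),
        "retained": int((~dup).sum()),
        "barcode_stripped": int(stripped.sum()),
        "barcoded_retained": int((aln["bx"].notna() & ~dup).sum()),
    }
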