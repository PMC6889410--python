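"""Library statistics: coupling efficiency, molecule length summaries,
N50, and barcode-overlap window matrices for structural-variant evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def coupling_efficiency(summary: pd.DataFrame) -> float:
    """Base-weighted coupling efficiency estimate.

    ``summary`` has one row per sequenced read pair with columns
    ``bases`` (sequenced bases of the pair), ``has_barcode`` (a valid
    barcode was extracted) and ``mapped`` (the genomic insert mapped).
    The estimate is the fraction of all sequenced bases belonging to
    pairs with both a valid barcode and a mapped insert — an operational,
    base-weighted definition of the assay's coupling efficiency.
    """
    total = int(summary["bases"].sum())
    if total == 0:
        raise ValueError("zero sequenced bases")
    good = int(summary.loc[summary["has_barcode"] & summary["mapped"], "bases"].sum())
    return good / total


def coupling_summary(lib, extracted_ids, mapped_ids=None) -> pd.DataFrame:
    """Build the per-pair summary for :func:`coupling_efficiency` from a
    simulated library: raw sequenced bases per pair, extraction success,
    and insert mapping status (all simulated reads map unless told
    otherwise)."""
    reads = lib.reads
    bases = reads["r1"].str.len() + reads["r2"].str.len()
    has_bc = reads["read_id"].isin(set(extracted_ids))
    mapped = (
        reads["read_id"].isin(set(mapped_ids)) if mapped_ids is not None else True
    )
    return pd.DataFrame(
        {"read_id": reads["read_id"], "bases": bases, "has_barcode": has_bc, "mapped": mapped}
    )


def molecule_stats(
    lengths, thresholds: tuple[int, int] = (20_000, 100_000)
) -> dict:
    """Mean molecule length and the fractions strictly above 20 kb and
    100 kb (configurable thresholds)."""
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no molecules")
    lo, hi = thresholds
    return {
        "n_molecules": int(lengths.size),
        "mean_molecule_length": float(lengths.mean()),
        f"fraction_gt_{lo // 1000}kb": float((lengths > lo).mean()),
        f"fraction_gt_{hi // 1000}kb": float((lengths > hi).mean()),
    }


def n50(lengths) -> int:
    """Smallest length L such that elements of length >= L sum to at least
    half the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of empty length set")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


@dataclass
class OverlapMatrix:
    """Barcode-overlap counts between genomic windows of one region."""

    chrom: str
    start: int
    end: int
    window: int
    #: window boundaries, half-open: windows[i] = (start_i, end_i)
    windows: list = field(default_factory=list)
    #: symmetric count matrix; diagonal = distinct barcodes per window
    matrix: np.ndarray = None
    barcode_sets: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{self.chrom}:{s}-{e}" for s, e in self.windows]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def barcode_overlap_matrix(
    aln: pd.DataFrame, chrom: str, start: int, end: int, window: int = 250_000
) -> OverlapMatrix:
    """Tile ``chrom:start-end`` into half-open windows and count shared
    barcodes between every window pair.

    Entry (i, j) is the number of distinct barcodes with at least one
    retained read pair in both windows; the diagonal is each window's
    distinct barcode count. A window larger than the region yields a
    single-window matrix; the last partial window is retained.
    """
    if end <= start:
        raise ValueError("empty region")
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    use = aln[
        aln["bx"].notna()
        & ~dup
        & (aln["chrom"] == chrom)
        & (aln["pos1"] >= start)
        & (aln["pos1"] < end)
    ]
    bounds = list(range(start, end, window))
    windows = [(s, min(s + window, end)) for s in bounds]
    n = len(windows)
    sets = [set() for _ in range(n)]
    widx = ((use["pos1"] - start) // window).astype(int)
    for bx, w in zip(use["bx"], widx):
        sets[w].add(bx)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        mat[i, i] = len(sets[i])
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = len(sets[i] & sets[j])
    return OverlapMatrix(
        chrom=chrom, start=start, end=end, window=window,
        windows=windows, matrix=mat, barcode_sets=sets,
    )
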