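"""Greedy abundance-ordered barcode error clustering.

Sequencing errors scatter each true barcode into a cloud of low-count
variants. Within each subset, observed barcodes are sorted by read count
(descending, ties broken lexicographically) and processed greedily: a
barcode joins the earliest-seeded cluster whose canonical sequence lies
within the Hamming radius implied by the identity threshold, otherwise it
seeds a new cluster. With an identity threshold of 0.9 on a 20-mer the
radius is floor(0.1 * 20) = 2 mismatches.

This is a direct-comparison equivalent of word-filtered greedy clustering
tools at fixed barcode length and desk scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .design import codes_to_str, str_to_codes

DEFAULT_IDENTITY = 0.9


@dataclass
class BarcodeCluster:
    """One error-collapsed barcode."""

    canonical: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


def hamming_radius(identity_threshold: float, length: int) -> int:
    """Mismatches allowed at a given identity threshold and barcode length:
    floor((1 - identity) * length), guarded against binary-float droop
    (0.1 * 20 must allow exactly 2)."""
    return int(np.floor((1.0 - identity_threshold) * length + 1e-9))


def cluster_barcodes(
    counts: dict[str, int] | Counter,
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[BarcodeCluster]:
    """Cluster observed barcodes of one subset.

    Parameters
    ----------
    counts
        Observed barcode -> read count. All barcodes must share one length.
    identity_threshold
        Fractional identity cutoff in (0, 1]; 0.9 allows 2 mismatches on a
        20-mer.
    """
    if not counts:
        raise ValueError("empty barcode subset")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    lengths = {len(b) for b in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths in subset: {sorted(lengths)}")
    (length,) = lengths
    radius = hamming_radius(identity_threshold, length)

    # abundance order with the documented lexicographic tie-break
    order = sorted(counts, key=lambda b: (-counts[b], b))
    codes = np.stack([str_to_codes(b) for b in order])

    clusters: list[BarcodeCluster] = []
    canon_mat = np.empty((len(order), length), dtype=np.uint8)
    n_canon = 0
    for i, bc in enumerate(order):
        if n_canon:
            d = (canon_mat[:n_canon] != codes[i]).sum(axis=1)
            hits = np.nonzero(d <= radius)[0]
        else:
            hits = ()
        if len(hits):
            clusters[hits[0]].members[bc] = counts[bc]
        else:
            canon_mat[n_canon] = codes[i]
            n_canon += 1
            clusters.append(BarcodeCluster(canonical=bc, members={bc: counts[bc]}))
    return clusters


def cluster_subsets(
    subset_counts: list[dict[str, int]],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[BarcodeCluster]:
    """Cluster each (non-empty) subset independently and concatenate."""
    clusters: list[BarcodeCluster] = []
    for counts in subset_counts:
        if counts:
            clusters.extend(cluster_barcodes(counts, identity_threshold))
    return clusters


def correction_map(clusters: list[BarcodeCluster]) -> dict[str, str]:
    """Observed barcode -> canonical barcode of its cluster."""
    out: dict[str, str] = {}
    for cl in clusters:
        for member in cl.members:
            out[member] = cl.canonical
    return out


def correct_reads(reads, clusters: list[BarcodeCluster]):
    """Set ``corrected_barcode`` on every extracted read pair.

    Reads whose raw barcode is absent from every cluster (impossible when
    the clusters were built from the same reads) are left uncorrected and
    counted.
    """
    cmap = correction_map(clusters)
    unclustered = 0
    out = []
    for pair in reads:
        canonical = cmap.get(pair.raw_barcode)
        if canonical is None:
            unclustered += 1
        else:
            pair.corrected_barcode = canonical
        out.append(pair)
    return out, unclustered
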