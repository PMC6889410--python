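"""Read trimming and barcode extraction.

R1 of a coupled amplicon is expected to read handle-barcode-handle-insert.
Both flanking handles are located by mismatch-tolerant ungapped alignment
(Hamming mismatch fraction <= ``similarity_threshold``, default 0.20, with
a bounded +/-3 base shift search); the intervening bases must conform to
the barcode design pattern. Reads failing any of these checks are rejected
and omitted from downstream analysis. Extracted barcodes are split into 8
subsets keyed on their first two bases before error clustering.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pysam

from .design import IUPAC, BarcodeDesign

#: shift offsets tried for each handle, nearest first (deterministic order)
_SHIFTS = (0, -1, 1, -2, 2, -3, 3)

#: rejection reason codes
TOO_SHORT = "too_short"
UPSTREAM_HANDLE = "upstream_handle_mismatch"
BARCODE_PATTERN = "barcode_pattern_mismatch"
DOWNSTREAM_HANDLE = "downstream_handle_mismatch"
NON_ACGT_KEY = "non_acgt_subset_key"

N_SUBSETS = 8

_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]
#: lexicographic pairing of the 16 dinucleotides onto 8 subset labels
#: (AA,AC -> 0; AG,AT -> 1; ...); deterministic and surjective
DINUC_SUBSET = {d: i // 2 for i, d in enumerate(_DINUCS)}


@dataclass(frozen=True)
class TrimParams:
    """Handle matching tolerance and the construct design."""

    design: BarcodeDesign
    similarity_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_threshold < 1.0:
            raise ValueError("similarity_threshold must be in [0, 1)")


@dataclass
class BarcodedReadPair:
    """One read pair surviving extraction; the pipeline's atom."""

    read_id: str
    r1: str  # genomic insert after handle/barcode removal
    q1: str
    r2: str
    q2: str
    raw_barcode: str | None = None
    corrected_barcode: str | None = None


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, early exit past limit."""
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def locate_handle(seq: str, handle: str, offset: int, threshold: float) -> int | None:
    """Find ``handle`` in ``seq`` near ``offset`` by ungapped comparison.

    Tries shifts 0, -1, +1, ... +/-3 around the expected offset and returns
    the end position (exclusive) of the best placement whose mismatch
    fraction is <= threshold, preferring fewer mismatches and then the
    smaller shift in the fixed search order. Returns None if no placement
    qualifies.
    """
    h = len(handle)
    limit = int(threshold * h + 1e-9)
    best = None  # (mismatches, end)
    for s in _SHIFTS:
        start = offset + s
        if start < 0 or start + h > len(seq):
            continue
        m = _mismatches(seq[start : start + h], handle, limit)
        if m <= limit and (best is None or m < best[0]):
            best = (m, start + h)
            if m == 0:
                break
    return None if best is None else best[1]


def _pattern_ok(barcode: str, pattern: str) -> bool:
    return all(b in IUPAC[p] for b, p in zip(barcode, pattern))


def extract_barcode(
    read_id: str,
    r1: str,
    q1: str,
    r2: str,
    q2: str,
    params: TrimParams,
) -> BarcodedReadPair | Rejection:
    """Extract the barcode from one raw read pair, or reject it.

    On success the returned pair's ``r1`` is the genomic insert with the
    upstream handle, barcode and downstream handle removed (and a trailing
    insert handle trimmed when present).
    """
    design = params.design
    min_len = design.construct_length + 1
    if len(r1) < min_len:
        return Rejection(read_id, TOO_SHORT)

    up_end = locate_handle(r1, design.upstream_handle, 0, params.similarity_threshold)
    if up_end is None:
        return Rejection(read_id, UPSTREAM_HANDLE)

    bc = r1[up_end : up_end + design.barcode_length]
    if len(bc) < design.barcode_length or not _pattern_ok(bc, design.pattern):
        return Rejection(read_id, BARCODE_PATTERN)

    down_end = locate_handle(
        r1, design.downstream_handle, up_end + design.barcode_length, params.similarity_threshold
    )
    if down_end is None:
        return Rejection(read_id, DOWNSTREAM_HANDLE)

    insert = r1[down_end:]
    iq = q1[down_end:]
    insert, iq = trim_insert_handle(insert, iq, design.insert_handle, params.similarity_threshold)
    return BarcodedReadPair(read_id, insert, iq, r2, q2, raw_barcode=bc)


def trim_insert_handle(
    seq: str, qual: str, handle: str, threshold: float, min_overlap: int = 8
) -> tuple[str, str]:
    """Trim the insert handle where its prefix overlaps the 3' end of the read.

    Overlap lengths from the full handle down to ``min_overlap`` bases are
    tried, longest first; a candidate is trimmed when its mismatch fraction
    is within the threshold. Interior handle placements (read-through far
    past the insert) are not searched.
    """
    for k in range(min(len(handle), len(seq)), min_overlap - 1, -1):
        limit = int(threshold * k + 1e-9)
        if _mismatches(seq[-k:], handle[:k], limit) <= limit:
            return seq[:-k], qual[:-k]
    return seq, qual


def split_subsets(barcodes, design: BarcodeDesign | None = None):
    """Partition barcode strings into 8 disjoint subsets by leading dinucleotide.

    Returns ``(subsets, rejects)`` where ``subsets`` is a list of 8 lists and
    ``rejects`` holds barcodes whose leading bases are not plain ACGT.
    The dinucleotide map is the documented lexicographic pairing
    (AA,AC -> 0; AG,AT -> 1; ...; TG,TT -> 7).
    """
    key_len = design.subset_key_length if design is not None else 2
    subsets: list[list[str]] = [[] for _ in range(N_SUBSETS)]
    rejects: list[str] = []
    for bc in barcodes:
        key = bc[:key_len][:2]
        sub = DINUC_SUBSET.get(key)
        if sub is None:
            rejects.append(bc)
        else:
            subsets[sub].append(bc)
    return subsets, rejects


@dataclass
class ExtractionResult:
    """All outputs of running extraction over a read-pair stream."""

    extracted: list[BarcodedReadPair]
    rejected: list[Rejection]
    summary: dict

    @property
    def barcode_counts(self) -> Counter:
        return Counter(p.raw_barcode for p in self.extracted)


def extract_read_pairs(
    pairs, params: TrimParams, rejects_path: str | Path | None = None
) -> ExtractionResult:
    """Run :func:`extract_barcode` over an iterable of raw read pairs.

    ``pairs`` yields ``(read_id, r1, q1, r2, q2)`` tuples. When
    ``rejects_path`` is given, rejected pairs are also written there as
    interleaved gzipped FASTQ with the reason in the header.
    """
    extracted: list[BarcodedReadPair] = []
    rejected: list[Rejection] = []
    reasons: Counter = Counter()
    total = 0
    rej_fh = gzip.open(rejects_path, "wt") if rejects_path else None
    for read_id, r1, q1, r2, q2 in pairs:
        total += 1
        res = extract_barcode(read_id, r1, q1, r2, q2, params)
        if isinstance(res, Rejection):
            rejected.append(res)
            reasons[res.reason] += 1
            if rej_fh is not None:
                rej_fh.write(f"@{read_id}/1 {res.reason}\n{r1}\n+\n{q1}\n")
                rej_fh.write(f"@{read_id}/2 {res.reason}\n{r2}\n+\n{q2}\n")
        else:
            extracted.append(res)
    if rej_fh is not None:
        rej_fh.close()
    summary = {
        "reads_in": total,
        "extracted": len(extracted),
        "rejected": len(rejected),
        "rejected_by_reason": dict(reasons),
    }
    return ExtractionResult(extracted, rejected, summary)


# ---------------------------------------------------------------------------
# FASTQ plumbing


def iter_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Yield (read_id, r1, q1, r2, q2) from paired FASTQ (optionally gzipped)."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            if e1.name != e2.name:
                raise ValueError(f"mate name mismatch: {e1.name} vs {e2.name}")
            yield e1.name, e1.sequence, e1.quality or "", e2.sequence, e2.quality or ""


def library_pairs(lib) -> list[tuple[str, str, str, str, str]]:
    """Adapter: in-memory simulated library -> extraction input tuples."""
    return list(lib.reads.itertuples(index=False, name=None))


def write_extracted_fastq(result: ExtractionResult, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write trimmed read pairs with the raw barcode tagged as ``BX:<seq>``
    in the read header."""
    out_prefix = Path(out_prefix)
    p1 = out_prefix.with_name(out_prefix.name + "_trimmed_R1.fastq.gz")
    p2 = out_prefix.with_name(out_prefix.name + "_trimmed_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for p in result.extracted:
            bc = p.corrected_barcode or p.raw_barcode
            f1.write(f"@{p.read_id}_BX:{bc}\n{p.r1}\n+\n{p.q1}\n")
            f2.write(f"@{p.read_id}_BX:{bc}\n{p.r2}\n+\n{p.q2}\n")
    return p1, p2
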