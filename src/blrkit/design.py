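"""Barcode construct design: the semi-randomized barcode pattern and its flanking handles.

A sequenced R1 of a coupled amplicon reads, 5'->3':

    [upstream handle][barcode][downstream handle][genomic insert]

The barcode pattern is an IUPAC string: fixed bases constrain the designed
positions, degenerate codes (``N``, ``V``, ...) mark randomized positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: uint8 base codes 0..3 -> ASCII
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Tn5 mosaic-end sequence: the tagmentation-inserted handle downstream of
# genomic inserts.
MOSAIC_END = "AGATGTGTATAAGAGACAG"


def _check_handle(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class BarcodeDesign:
    """The barcode construct used both to simulate and to extract reads.

    Parameters
    ----------
    pattern
        IUPAC string defining the barcode: fixed positions are literal
        bases, degenerate codes are drawn uniformly from their allowed set.
        The default is a fully randomized 20-mer, a stand-in for assay
        specific semi-random designs.
    upstream_handle, downstream_handle
        Universal PCR handles flanking the barcode on R1.
    insert_handle
        Handle downstream of the genomic insert (read through only when the
        insert is shorter than the read); defaults to the Tn5 mosaic end.
    subset_key_length
        Number of leading barcode bases used to split barcodes into subsets
        before clustering (default 2).
    """

    pattern: str = "N" * 20
    upstream_handle: str = "CAGTTGATCATCAGCAGGTA"
    downstream_handle: str = "CATGACCTCTTGGAACTGTC"
    insert_handle: str = MOSAIC_END
    subset_key_length: int = 2

    def __post_init__(self) -> None:
        if len(self.pattern) < self.subset_key_length:
            raise ValueError("pattern shorter than subset_key_length")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"pattern contains non-IUPAC characters: {sorted(bad)}")
        _check_handle("upstream_handle", self.upstream_handle)
        _check_handle("downstream_handle", self.downstream_handle)
        _check_handle("insert_handle", self.insert_handle)

    @property
    def barcode_length(self) -> int:
        return len(self.pattern)

    @property
    def construct_length(self) -> int:
        """Bases of R1 consumed by handles + barcode (insert excluded)."""
        return (
            len(self.upstream_handle)
            + self.barcode_length
            + len(self.downstream_handle)
        )

    def matches(self, barcode: str) -> bool:
        """True iff ``barcode`` conforms to the pattern (length and every
        position's allowed base set)."""
        if len(barcode) != len(self.pattern):
            return False
        return all(b in IUPAC[p] for b, p in zip(barcode, self.pattern))

    def sample_barcodes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` barcodes as a (n, barcode_length) uint8 code matrix."""
        out = np.empty((n, len(self.pattern)), dtype=np.uint8)
        for j, p in enumerate(self.pattern):
            allowed = np.array([BASE_INDEX[b] for b in IUPAC[p]], dtype=np.uint8)
            out[:, j] = allowed[rng.integers(0, len(allowed), size=n)]
        return out


def codes_to_str(codes: np.ndarray) -> str:
    """uint8 base codes -> DNA string."""
    return BASE_BYTES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    """DNA string -> uint8 base codes (raises on non-ACGT)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if (codes == 255).any():
        raise ValueError(f"non-ACGT base in sequence {seq!r}")
    return codes


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
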