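"""Emulsion-droplet linked-read library simulator with a full truth channel.

The generative model follows the assay: a diploid genome with heterozygous
SNVs; high molecular weight (HMW) fragments sampled from either haplotype
with lognormal lengths; droplets loaded with a Poisson number of fragments
and a Poisson number of distinct barcode oligos; read pairs sampled along
each fragment at a fixed density; each read pair coupled to one of its
droplet's barcodes with probability ``coupling_probability`` (uncoupled
amplicons are emitted as plain genomic read pairs, with no barcode
construct); substitution errors applied independently to barcode bases and
to genomic insert bases.

Optionally, large heterozygous deletions can be placed on haplotype 1 to
generate structural-variant barcode-overlap signal.

Every emitted read pair is recorded in a truth table (droplet, barcode,
fragment, haplotype, mate mapping positions) so each downstream stage can
be scored exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .design import BarcodeDesign, codes_to_str

#: sentinel barcode for uncoupled read pairs
NO_BARCODE = "."

_QUAL_CHAR = "I"  # constant Phred 40


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library.

    Defaults describe a desk-scale library: a 2 Mb diploid toy genome with
    1 het SNV per kb, 2,000 droplets and on the order of 200k read pairs,
    with HMW fragment lengths lognormal around a 40 kb mean and a coupling
    probability of 0.75 (the assay couples roughly three quarters of its
    output to a barcode).
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    het_snv_rate: float = 0.001
    fragment_length_mean: float = 40_000.0
    fragment_length_shape: float = 0.8
    n_droplets: int = 2_000
    fragments_per_droplet_mean: float = 3.5
    barcodes_per_droplet_mean: float = 2.0
    read_pairs_per_kb: float = 0.7
    read_length: int = 100
    insert_size_mean: int = 350
    coupling_probability: float = 0.75
    barcode_error_rate: float = 0.01
    insert_error_rate: float = 0.002
    rng_seed: int = 0
    #: heterozygous deletions on haplotype 1: (chrom_name, ref_start, ref_end)
    deletions: tuple = ()

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.fragment_length_mean <= 0:
            raise ValueError("fragment_length_mean must be positive")
        if not 0.0 <= self.coupling_probability <= 1.0:
            raise ValueError("coupling_probability must be in [0, 1]")
        for name in (
            "het_snv_rate",
            "fragment_length_shape",
            "fragments_per_droplet_mean",
            "barcodes_per_droplet_mean",
            "read_pairs_per_kb",
            "barcode_error_rate",
            "insert_error_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedLibrary:
    """In-memory result of :func:`simulate_library`."""

    config: SimConfig
    design: BarcodeDesign
    #: read_id, r1, q1, r2, q2
    reads: pd.DataFrame
    #: one row per read pair: read_id, droplet_id, true_barcode, fragment_id,
    #: chrom, fragment_start, fragment_end, haplotype, coupled, pos1, pos2
    truth: pd.DataFrame
    #: chrom, pos (0-based), ref, alt, hap_with_alt
    variants: pd.DataFrame
    #: fragment_id, droplet_id, chrom, start, end, haplotype (ref coords)
    fragments: pd.DataFrame
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def n_read_pairs(self) -> int:
        return len(self.reads)

    @property
    def coupled_fraction(self) -> float:
        if len(self.truth) == 0:
            return 0.0
        return float(self.truth["coupled"].mean())


class _HapCoords:
    """Monotone haplotype->reference coordinate transform for a chromosome
    with deletions removed from the haplotype."""

    def __init__(self, chrom_length: int, deletions: list[tuple[int, int]]):
        dels = sorted(deletions)
        for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
            if e1 > s2:
                raise ValueError("overlapping deletions on one chromosome")
        seg_starts_hap = [0]
        shifts = [0]
        removed = 0
        for s, e in dels:
            if not (0 <= s < e <= chrom_length):
                raise ValueError(f"deletion ({s}, {e}) outside chromosome")
            removed += e - s
            seg_starts_hap.append(s - (removed - (e - s)))
            shifts.append(removed)
        self.hap_length = chrom_length - removed
        self._starts = np.asarray(seg_starts_hap, dtype=np.int64)
        self._shifts = np.asarray(shifts, dtype=np.int64)
        self.deletions = dels

    def to_ref(self, pos):
        """Map haplotype coordinates (scalar or array) to reference."""
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(self._starts, pos, side="right") - 1
        return pos + self._shifts[idx]


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _split_lengths(total: int, n: int) -> list[int]:
    base = total // n
    if base == 0:
        raise ValueError("genome_length too small for n_chromosomes")
    out = [base] * n
    out[-1] = total - base * (n - 1)
    return out


def _apply_substitutions(arr: np.ndarray, n_err: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_err`` (with replacement) positions of a base-code array."""
    if n_err == 0:
        return arr
    arr = arr.copy()
    pos = rng.integers(0, arr.size, size=n_err)
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_err)) % 4
    return arr


def simulate_library(config: SimConfig, design: BarcodeDesign | None = None) -> SimulatedLibrary:
    """Simulate one linked-read library.

    The same ``config.rng_seed`` always yields byte-identical output.
    """
    if design is None:
        design = BarcodeDesign()
    rng = np.random.default_rng(config.rng_seed)

    names = _chrom_names(config.n_chromosomes)
    lengths = _split_lengths(config.genome_length, config.n_chromosomes)
    chrom_lengths = dict(zip(names, lengths))

    dels_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for chrom, s, e in config.deletions:
        if chrom not in dels_by_chrom:
            raise ValueError(f"deletion on unknown chromosome {chrom!r}")
        dels_by_chrom[chrom].append((int(s), int(e)))

    # --- genome and heterozygous SNVs -------------------------------------
    ref: list[np.ndarray] = []
    var_rows = []
    hap_seqs: list[list[np.ndarray]] = []  # [chrom][hap]
    coords: list[list[_HapCoords]] = []
    for ci, (name, length) in enumerate(zip(names, lengths)):
        seq = rng.integers(0, 4, size=length, dtype=np.uint8)
        n_snv = rng.poisson(length * config.het_snv_rate)
        pos = np.unique(rng.integers(0, length, size=n_snv)) if n_snv else np.empty(0, np.int64)
        alt = (seq[pos] + rng.integers(1, 4, size=pos.size, dtype=np.uint8)) % 4
        hap_with_alt = rng.integers(0, 2, size=pos.size, dtype=np.int8)
        ref.append(seq)
        for p, a, h in zip(pos, alt, hap_with_alt):
            var_rows.append((name, int(p), int(seq[p]), int(a), int(h)))

        hap0 = seq.copy()
        m0 = hap_with_alt == 0
        hap0[pos[m0]] = alt[m0]
        hap1_full = seq.copy()
        m1 = hap_with_alt == 1
        hap1_full[pos[m1]] = alt[m1]
        tr1 = _HapCoords(length, dels_by_chrom[name])
        if tr1.deletions:
            keep = np.ones(length, dtype=bool)
            for s, e in tr1.deletions:
                keep[s:e] = False
            hap1 = hap1_full[keep]
        else:
            hap1 = hap1_full
        hap_seqs.append([hap0, hap1])
        coords.append([_HapCoords(length, []), tr1])

    from .design import BASE_BYTES

    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt", "hap_with_alt"])
    if len(variants):
        variants["ref"] = [chr(BASE_BYTES[c]) for c in variants["ref"]]
        variants["alt"] = [chr(BASE_BYTES[c]) for c in variants["alt"]]
    else:
        variants = variants.astype({"chrom": str, "pos": np.int64, "ref": str, "alt": str, "hap_with_alt": np.int8})

    # --- droplet loading ---------------------------------------------------
    n_frag_per_drop = rng.poisson(config.fragments_per_droplet_mean, size=config.n_droplets)
    n_bc_per_drop = rng.poisson(config.barcodes_per_droplet_mean, size=config.n_droplets)
    total_bc = int(n_bc_per_drop.sum())
    bc_codes = design.sample_barcodes(total_bc, rng)
    bc_offset = np.concatenate([[0], np.cumsum(n_bc_per_drop)])
    # enforce distinct barcodes within a droplet (collisions are vanishingly
    # rare for randomized designs; constrained patterns may need resampling)
    for d in range(config.n_droplets):
        lo, hi = bc_offset[d], bc_offset[d + 1]
        for _ in range(100):
            seqs = [codes_to_str(bc_codes[i]) for i in range(lo, hi)]
            if len(set(seqs)) == hi - lo:
                break
            bc_codes[lo:hi] = design.sample_barcodes(hi - lo, rng)
    bc_strings = [codes_to_str(bc_codes[i]) for i in range(total_bc)]

    # --- fragments ---------------------------------------------------------
    F = int(n_frag_per_drop.sum())
    frag_droplet = np.repeat(np.arange(config.n_droplets), n_frag_per_drop)
    frag_hap = rng.integers(0, 2, size=F, dtype=np.int8)
    hap_len = np.array([[coords[c][h].hap_length for c in range(config.n_chromosomes)] for h in (0, 1)], dtype=np.float64)
    cum = np.cumsum(hap_len, axis=1)
    cum = cum / cum[:, -1:]
    u = rng.random(F)
    frag_chrom = np.argmax(u[:, None] < cum[frag_hap], axis=1)

    mu = np.log(config.fragment_length_mean) - config.fragment_length_shape**2 / 2.0
    frag_len = np.rint(rng.lognormal(mu, config.fragment_length_shape, size=F)).astype(np.int64)
    chrom_cap = hap_len[frag_hap, frag_chrom].astype(np.int64)
    frag_len = np.clip(frag_len, 1, chrom_cap)
    frag_start = np.floor(rng.random(F) * (chrom_cap - frag_len + 1)).astype(np.int64)

    # --- read pairs --------------------------------------------------------
    L1 = design.construct_length + config.read_length  # total R1 cycles
    min_insert = max(L1, config.read_length)
    n_rp = rng.poisson(frag_len / 1000.0 * config.read_pairs_per_kb)
    n_rp[frag_len < min_insert] = 0
    R = int(n_rp.sum())

    frag_of = np.repeat(np.arange(F), n_rp)
    rd_droplet = frag_droplet[frag_of]
    rd_hap = frag_hap[frag_of]
    rd_chrom = frag_chrom[frag_of]

    ins_sd = max(1.0, config.insert_size_mean / 10.0)
    insert_len = np.rint(rng.normal(config.insert_size_mean, ins_sd, size=R)).astype(np.int64)
    insert_len = np.clip(insert_len, min_insert, frag_len[frag_of])
    istart = frag_start[frag_of] + np.floor(
        rng.random(R) * (frag_len[frag_of] - insert_len + 1)
    ).astype(np.int64)

    coupled = rng.random(R) < config.coupling_probability
    has_bc = n_bc_per_drop[rd_droplet] > 0
    # Coupled amplicons require a barcode oligo in the droplet; in its
    # absence they are removed by the post-emulsion enrichment and never
    # sequenced. Uncoupled carryover is emitted from any droplet, so the
    # coupled fraction of EMITTED pairs is coupling_probability whenever
    # barcode loading saturates.
    emit = np.logical_or(~coupled, has_bc)
    frag_of = frag_of[emit]
    rd_droplet = rd_droplet[emit]
    rd_hap = rd_hap[emit]
    rd_chrom = rd_chrom[emit]
    insert_len = insert_len[emit]
    istart = istart[emit]
    coupled = coupled[emit]
    R = int(emit.sum())
    bc_pick = rng.integers(0, np.maximum(n_bc_per_drop[rd_droplet], 1))
    bc_global = bc_offset[rd_droplet] + bc_pick

    n_err_bc = rng.binomial(design.barcode_length, config.barcode_error_rate, size=R)
    gl = np.where(coupled, config.read_length, L1)
    n_err_r1 = rng.binomial(gl, config.insert_error_rate)
    n_err_r2 = rng.binomial(config.read_length, config.insert_error_rate, size=R)

    # --- sequence assembly -------------------------------------------------
    uh, dh = design.upstream_handle, design.downstream_handle
    rl = config.read_length
    r1_list: list[str] = []
    r2_list: list[str] = []
    pos1 = np.empty(R, dtype=np.int64)
    pos2 = np.empty(R, dtype=np.int64)
    for i in range(R):
        seq = hap_seqs[rd_chrom[i]][rd_hap[i]]
        i0 = istart[i]
        iend = i0 + insert_len[i]
        g = gl[i]
        r1g = _apply_substitutions(seq[i0 : i0 + g], int(n_err_r1[i]), rng)
        r2c = _apply_substitutions((3 - seq[iend - rl : iend])[::-1], int(n_err_r2[i]), rng)
        if coupled[i]:
            bc = _apply_substitutions(bc_codes[bc_global[i]], int(n_err_bc[i]), rng)
            r1 = uh + codes_to_str(bc) + dh + codes_to_str(r1g)
        else:
            r1 = codes_to_str(r1g)
        r1_list.append(r1)
        r2_list.append(codes_to_str(r2c))
    # mate leftmost reference positions
    for c in range(config.n_chromosomes):
        for h in (0, 1):
            m = (rd_chrom == c) & (rd_hap == h)
            if m.any():
                tr = coords[c][h]
                pos1[m] = tr.to_ref(istart[m])
                pos2[m] = tr.to_ref(istart[m] + insert_len[m] - rl)

    read_ids = [f"rp{i:08d}" for i in range(R)]
    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "r1": r1_list,
            "q1": [_QUAL_CHAR * len(s) for s in r1_list],
            "r2": r2_list,
            "q2": _QUAL_CHAR * rl,
        }
    )

    frag_start_ref = np.empty(F, dtype=np.int64)
    frag_end_ref = np.empty(F, dtype=np.int64)
    for c in range(config.n_chromosomes):
        for h in (0, 1):
            m = (frag_chrom == c) & (frag_hap == h)
            if m.any():
                tr = coords[c][h]
                frag_start_ref[m] = tr.to_ref(frag_start[m])
                frag_end_ref[m] = tr.to_ref(frag_start[m] + frag_len[m])

    chrom_name_arr = np.asarray(names)
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "droplet_id": rd_droplet,
            "true_barcode": [bc_strings[b] if c else NO_BARCODE for b, c in zip(bc_global, coupled)],
            "fragment_id": frag_of,
            "chrom": chrom_name_arr[rd_chrom],
            "fragment_start": frag_start_ref[frag_of],
            "fragment_end": frag_end_ref[frag_of],
            "haplotype": rd_hap,
            "coupled": coupled,
            "pos1": pos1,
            "pos2": pos2,
        }
    )
    fragments = pd.DataFrame(
        {
            "fragment_id": np.arange(F),
            "droplet_id": frag_droplet,
            "chrom": chrom_name_arr[frag_chrom],
            "start": frag_start_ref,
            "end": frag_end_ref,
            "haplotype": frag_hap,
        }
    )
    return SimulatedLibrary(
        config=config,
        design=design,
        reads=reads,
        truth=truth,
        variants=variants,
        fragments=fragments,
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# serialization


def write_fastq(lib: SimulatedLibrary, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the paired reads as gzipped FASTQ (R1 carries the construct)."""
    out_prefix = Path(out_prefix)
    p1 = out_prefix.with_name(out_prefix.name + "_R1.fastq.gz")
    p2 = out_prefix.with_name(out_prefix.name + "_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for row in lib.reads.itertuples(index=False):
            f1.write(f"@{row.read_id}\n{row.r1}\n+\n{row.q1}\n")
            f2.write(f"@{row.read_id}\n{row.r2}\n+\n{row.q2}\n")
    return p1, p2


def write_truth(lib: SimulatedLibrary, out_prefix: str | Path) -> dict[str, Path]:
    """Write ground truth: reads TSV, phased variants VCF, fragments BED."""
    if len(lib.truth) == 0:
        raise ValueError("empty truth table")
    out_prefix = Path(out_prefix)
    paths = {
        "reads": out_prefix.with_name(out_prefix.name + "_truth_reads.tsv"),
        "variants": out_prefix.with_name(out_prefix.name + "_truth_variants.vcf"),
        "fragments": out_prefix.with_name(out_prefix.name + "_truth_fragments.bed"),
    }
    t = lib.truth.copy()
    t["coupled"] = t["coupled"].astype(int)
    t.to_csv(paths["reads"], sep="\t", index=False)
    write_truth_vcf(lib.variants, lib.chrom_lengths, paths["variants"])
    lib.fragments[["chrom", "start", "end", "fragment_id", "droplet_id", "haplotype"]].to_csv(
        paths["fragments"], sep="\t", index=False, header=False
    )
    return paths


def write_truth_vcf(variants: pd.DataFrame, chrom_lengths: dict, path: str | Path) -> Path:
    """Phased truth VCF: GT is 1|0 when haplotype 0 carries the alt allele."""
    header = pysam.VariantHeader()
    for name, length in chrom_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("sim")
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                stop=int(row.pos) + 1,
                alleles=(row.ref, row.alt),
            )
            rec.samples["sim"]["GT"] = (1, 0) if row.hap_with_alt == 0 else (0, 1)
            rec.samples["sim"].phased = True
            vcf.write(rec)
    return path


def read_truth_reads(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    t["coupled"] = t["coupled"].astype(bool)
    return t


def read_truth_vcf(path: str | Path) -> pd.DataFrame:
    """Read a phased VCF back into the variants-table layout."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            gt = rec.samples[sample]["GT"]
            rows.append(
                (rec.contig, rec.start, rec.ref, rec.alts[0], 0 if gt == (1, 0) else 1)
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "hap_with_alt"])


def alignments_from_truth(
    truth: pd.DataFrame,
    barcode_map: dict[str, str] | None = None,
    read_length: int = 100,
) -> pd.DataFrame:
    """Build a coordinate-sorted alignment table from the truth channel.

    Read mapping is outside this package's scope; simulated reads are
    "aligned" at their true positions. ``barcode_map`` translates each
    read_id to its corrected barcode (e.g. after extraction + clustering);
    if omitted, true barcodes are used. Reads absent from the map get a
    null barcode.
    """
    aln = pd.DataFrame(
        {
            "read_id": truth["read_id"],
            "bx": truth["true_barcode"].where(truth["coupled"], other=None),
            "chrom": truth["chrom"],
            "pos1": truth["pos1"],
            "pos2": truth["pos2"],
            "orientation": "FR",
            "sumq": 2 * read_length * 40,
            "read_length": read_length,
        }
    )
    if barcode_map is not None:
        aln["bx"] = aln["read_id"].map(barcode_map)
    aln["bx"] = aln["bx"].astype(object).where(pd.notna(aln["bx"]), None)
    return aln.sort_values(["chrom", "pos1", "read_id"], kind="stable").reset_index(drop=True)
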