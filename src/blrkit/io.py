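"""File-format plumbing: tagged SAM, molecule BED, cluster and barcode
translation tables, stats JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam


def write_tagged_sam(
    aln: pd.DataFrame,
    chrom_lengths: dict,
    path: str | Path,
    sequences: dict | None = None,
) -> Path:
    """Write an alignment table as a paired-end SAM with BX/MI/DI tags.

    Each read pair becomes two proper-pair records (R1 forward at pos1,
    R2 reverse at pos2). ``sequences`` optionally maps read_id ->
    (r1_seq, r2_seq); otherwise SEQ is omitted.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in chrom_lengths.items()],
        }
    )
    path = Path(path)
    order = aln.sort_values(["chrom", "pos1"], kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in order.itertuples(index=False):
            rl = int(row.read_length)
            for mate, pos in ((1, int(row.pos1)), (2, int(row.pos2))):
                a = pysam.AlignedSegment(header)
                a.query_name = row.read_id
                a.flag = 99 if mate == 1 else 147
                if getattr(row, "duplicate", False):
                    a.flag |= 0x400
                a.reference_name = row.chrom
                a.reference_start = pos
                a.mapping_quality = 60
                if sequences and row.read_id in sequences:
                    seq = sequences[row.read_id][mate - 1]
                    a.query_sequence = seq
                    a.cigarstring = f"{len(seq)}M"
                else:
                    a.cigarstring = f"{rl}M"
                a.next_reference_name = row.chrom
                a.next_reference_start = int(row.pos2) if mate == 1 else int(row.pos1)
                tags = []
                if row.bx is not None and not pd.isna(row.bx):
                    tags.append(("BX", str(row.bx)))
                mi = getattr(row, "mi", None)
                if mi is not None and not pd.isna(mi):
                    tags.append(("MI", int(mi)))
                gid = getattr(row, "group", None)
                if gid is not None and not pd.isna(gid):
                    tags.append(("DI", int(gid)))
                a.set_tags(tags)
                out.write(a)
    return path


def read_tagged_sam(path: str | Path) -> pd.DataFrame:
    """Read a tagged paired SAM/BAM back into the alignment-table layout."""
    pairs: dict = {}
    with pysam.AlignmentFile(str(path)) as f:
        for rec in f:
            if rec.is_unmapped:
                continue
            entry = pairs.setdefault(
                rec.query_name,
                {
                    "read_id": rec.query_name,
                    "bx": rec.get_tag("BX") if rec.has_tag("BX") else None,
                    "chrom": rec.reference_name,
                    "pos1": None,
                    "pos2": None,
                    "orientation": "FR",
                    "sumq": 0,
                    "read_length": rec.query_length or rec.reference_length,
                    "duplicate": rec.is_duplicate,
                    "mi": rec.get_tag("MI") if rec.has_tag("MI") else pd.NA,
                    "group": rec.get_tag("DI") if rec.has_tag("DI") else pd.NA,
                },
            )
            key = "pos1" if rec.is_read1 else "pos2"
            entry[key] = rec.reference_start
            if rec.query_qualities is not None:
                entry["sumq"] += int(np.sum(rec.query_qualities))
    rows = [p for p in pairs.values() if p["pos1"] is not None and p["pos2"] is not None]
    df = pd.DataFrame(rows)
    if len(df):
        df["mi"] = df["mi"].astype("Int64")
        df["group"] = df["group"].astype("Int64")
        df = df.sort_values(["chrom", "pos1", "read_id"], kind="stable").reset_index(drop=True)
    return df


def write_molecule_bed(molecules: pd.DataFrame, path: str | Path) -> Path:
    """Molecules as BED: chrom, start, end, group_id, read_pair_count."""
    path = Path(path)
    molecules[["chrom", "start", "end", "group_id", "read_pair_count"]].to_csv(
        path, sep="\t", index=False, header=False
    )
    return path


def write_cluster_tsv(clusters, path: str | Path) -> Path:
    """Barcode clusters as TSV: canonical, member, count."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("canonical\tmember\tcount\n")
        for cl in clusters:
            for member, count in sorted(cl.members.items()):
                f.write(f"{cl.canonical}\t{member}\t{count}\n")
    return path


def read_cluster_tsv(path: str | Path):
    from .cluster import BarcodeCluster

    df = pd.read_csv(path, sep="\t")
    out = []
    for canonical, sub in df.groupby("canonical", sort=True):
        out.append(
            BarcodeCluster(
                canonical=canonical,
                members=dict(zip(sub["member"], sub["count"].astype(int))),
            )
        )
    return out


def write_barcode_translation(tenx_map: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        f.write("group_id\ttenx_barcode\n")
        for gid in sorted(tenx_map):
            f.write(f"{gid}\t{tenx_map[gid]}\n")
    return path


def write_tenx_fastq(
    pairs, aln: pd.DataFrame, tenx_map: dict, path: str | Path
) -> Path:
    """Interleaved gzipped FASTQ with translated 16-base barcodes.

    ``pairs`` are extracted read pairs; each read's droplet group (from
    ``aln``) is translated through ``tenx_map`` and carried as a
    ``BX:Z:`` header comment, the shape 10x-style tools consume. Reads
    whose group was stripped or unmapped are emitted without a barcode.
    """
    import gzip

    group_of = aln.set_index("read_id")["group"]
    path = Path(path)
    with gzip.open(path, "wt") as f:
        for p in pairs:
            gid = group_of.get(p.read_id)
            bx = tenx_map.get(int(gid)) if gid is not None and not pd.isna(gid) else None
            tag = f" BX:Z:{bx}" if bx else ""
            f.write(f"@{p.read_id}/1{tag}\n{p.r1}\n+\n{p.q1}\n")
            f.write(f"@{p.read_id}/2{tag}\n{p.r2}\n+\n{p.q2}\n")
    return path


def write_stats_json(stats: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        json.dump(stats, f, indent=2, default=_jsonify)
        f.write("\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
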