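"""Simplified barcode-graph phasing of heterozygous SNVs.

Reads carrying molecule (``MI``) tags observe alleles at het SNV
positions. For each molecule the observations are collapsed per variant
(majority vote, ties dropped), and every pair of consecutive variants
covered by one molecule contributes evidence: +1 to the pair's edge
weight when the molecule sees equal alleles (the variants' ALT alleles
sit on the same haplotype, cis) and -1 otherwise (trans). Variants are
then oriented along a maximum-weight spanning forest of the evidence
graph; each connected component is one phase block. Variants with no
(net) molecule linkage stay unphased; singleton blocks count as
unphased.

This is a deliberately simple, deterministic stand-in for production
phasers: with error-free, single-haplotype molecules every edge is
consistent and the forest orientation is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import pysam

from .design import revcomp


@dataclass
class PhaseBlock:
    """A maximal set of jointly oriented het SNVs on one chromosome."""

    block_id: int
    chrom: str
    #: (variant_index, position, parity) sorted by position; parity is the
    #: haplotype index assigned to the variant's ALT allele (labels within a
    #: block are arbitrary up to a global flip)
    variants: list = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.variants[0][1]

    @property
    def end(self) -> int:
        return self.variants[-1][1] + 1

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class PhaseResult:
    blocks: list
    #: variant index -> (block_id, parity)
    assignments: dict
    n_variants: int
    n_unphased: int

    @property
    def phased_blocks(self) -> list:
        """Blocks with at least two variants (singletons are unphased)."""
        return [b for b in self.blocks if b.n_variants >= 2]


def forward_strand_reads(pairs, aln: pd.DataFrame) -> pd.DataFrame:
    """Combine extracted read pairs with their alignments into a table of
    forward-strand sequences for allele lookup.

    ``pairs`` are extracted reads (``r1`` is the forward genomic insert,
    ``r2`` the reverse-strand mate); ``aln`` supplies coordinates and
    molecule tags. Pairs without a molecule tag are dropped.
    """
    seqs = {p.read_id: (p.r1, revcomp(p.r2)) for p in pairs}
    dup = aln["duplicate"] if "duplicate" in aln else pd.Series(False, index=aln.index)
    use = aln[aln["mi"].notna() & ~dup]
    rows = []
    for row in use.itertuples(index=False):
        s = seqs.get(row.read_id)
        if s is None:
            continue
        rows.append((int(row.mi), row.chrom, int(row.pos1), s[0], int(row.pos2), s[1]))
    return pd.DataFrame(rows, columns=["mi", "chrom", "pos1", "seq1", "pos2", "seq2"])


def allele_observations(tagged_reads: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Per-(molecule, variant) allele calls.

    ``tagged_reads`` columns: mi, chrom, pos1, seq1, pos2, seq2 with both
    sequences on the forward strand starting at their positions. Bases
    matching neither REF nor ALT are discarded; within a molecule each
    variant is called by majority, ties dropped.
    """
    var = variants.reset_index(drop=True)
    by_chrom = {
        chrom: (sub["pos"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in var.groupby("chrom")
    }
    ref = var["ref"].to_numpy()
    alt = var["alt"].to_numpy()
    votes: dict = {}
    for row in tagged_reads.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos_arr, idx_arr = entry
        for p, seq in ((row.pos1, row.seq1), (row.pos2, row.seq2)):
            lo = np.searchsorted(pos_arr, p)
            hi = np.searchsorted(pos_arr, p + len(seq))
            for k in range(lo, hi):
                base = seq[pos_arr[k] - p]
                vi = int(idx_arr[k])
                if base == ref[vi]:
                    a = 0
                elif base == alt[vi]:
                    a = 1
                else:
                    continue
                key = (int(row.mi), vi)
                votes[key] = votes.get(key, [0, 0])
                votes[key][a] += 1
    rows = []
    for (mi, vi), (n0, n1) in votes.items():
        if n0 == n1:
            continue
        rows.append((mi, vi, 0 if n0 > n1 else 1))
    return pd.DataFrame(rows, columns=["mi", "var_idx", "allele"])


def phase_variants(variants: pd.DataFrame, observations: pd.DataFrame) -> PhaseResult:
    """Build the evidence graph and orient haplotypes along a
    maximum-weight spanning forest.

    ``observations`` is the output of :func:`allele_observations`. Edges
    with zero net cis-trans weight are dropped; a variant left with no
    edges becomes a singleton (unphased) block.
    """
    var = variants.reset_index(drop=True)
    order = {int(i): (row.chrom, int(row.pos)) for i, row in var.iterrows()}

    weights: dict = {}
    for mi, sub in observations.groupby("mi"):
        sub = sub.set_index("var_idx")["allele"]
        idx = sorted(sub.index, key=lambda v: order[v])
        for u, v in zip(idx, idx[1:]):
            w = 1 if sub[u] == sub[v] else -1
            key = (u, v) if u < v else (v, u)
            weights[key] = weights.get(key, 0) + w

    G = nx.Graph()
    G.add_nodes_from(range(len(var)))
    for (u, v), w in sorted(weights.items()):
        if w != 0:
            G.add_edge(u, v, weight=abs(w), sign=1 if w > 0 else -1)

    forest = nx.Graph()
    forest.add_nodes_from(G.nodes)
    forest.add_edges_from(
        (u, v, d) for u, v, d in nx.maximum_spanning_edges(G, algorithm="kruskal", data=True)
    )

    assignments: dict = {}
    blocks: list[PhaseBlock] = []
    for comp in sorted(nx.connected_components(forest), key=min):
        root = min(comp)
        parity = {root: 0}
        for u, v in nx.bfs_edges(forest, root):
            parity[v] = parity[u] ^ (0 if forest[u][v]["sign"] > 0 else 1)
        members = sorted(comp, key=lambda v: order[v])
        chrom = order[members[0]][0]
        block = PhaseBlock(
            block_id=len(blocks),
            chrom=chrom,
            variants=[(v, order[v][1], parity[v]) for v in members],
        )
        blocks.append(block)
        for v in members:
            assignments[v] = (block.block_id, parity[v])
    return PhaseResult(
        blocks=blocks,
        assignments=assignments,
        n_variants=len(var),
        n_unphased=sum(b.n_variants for b in blocks if b.n_variants < 2),
    )


def evaluate_phasing(result: PhaseResult, truth_variants: pd.DataFrame) -> dict:
    """Score inferred blocks against haplotype-resolved truth.

    Metrics: fraction of het SNVs phased (in a >= 2-variant block), switch
    error rate (haplotype flips between consecutive variants within blocks,
    invariant to each block's arbitrary global orientation), N50 and
    longest phase-block span.
    """
    truth = truth_variants.reset_index(drop=True)["hap_with_alt"].to_numpy()
    switches = 0
    comparisons = 0
    phased = 0
    spans = []
    for block in result.phased_blocks:
        phased += block.n_variants
        spans.append(block.span)
        d = [parity ^ int(truth[vi]) for vi, _pos, parity in block.variants]
        switches += sum(a != b for a, b in zip(d, d[1:]))
        comparisons += len(d) - 1
    n_var = result.n_variants
    return {
        "n_het_variants": n_var,
        "n_phased": phased,
        "phased_fraction": phased / n_var if n_var else 0.0,
        "switch_errors": switches,
        "switch_comparisons": comparisons,
        "switch_error_rate": switches / comparisons if comparisons else 0.0,
        "n50_phase_block": _n50(spans) if spans else 0,
        "longest_block": max(spans) if spans else 0,
        "n_blocks": len(result.phased_blocks),
    }


def _n50(lengths) -> int:
    from .stats import n50

    return n50(lengths)


def result_from_phased_vcf(path) -> tuple[pd.DataFrame, PhaseResult]:
    """Reconstruct variants + a :class:`PhaseResult` from a phased VCF
    (PS groups variants into blocks; GT 1|0 means parity 0)."""
    rows = []
    phase: list = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            s = rec.samples[sample]
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0]))
            ps = s.get("PS") if s.phased else None
            parity = None
            if s.phased and s["GT"] in ((1, 0), (0, 1)):
                parity = 0 if s["GT"] == (1, 0) else 1
            phase.append((ps, parity))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    blocks: dict = {}
    for vi, ((ps, parity), row) in enumerate(zip(phase, rows)):
        if ps is None or parity is None:
            blocks.setdefault(("singleton", vi), []).append((vi, row[1], 0))
        else:
            blocks.setdefault((row[0], ps), []).append((vi, row[1], parity))
    out_blocks = []
    assignments = {}
    for key in sorted(blocks, key=lambda k: str(k)):
        members = sorted(blocks[key], key=lambda t: t[1])
        chrom = variants.loc[members[0][0], "chrom"]
        b = PhaseBlock(block_id=len(out_blocks), chrom=chrom, variants=members)
        out_blocks.append(b)
        for vi, _pos, parity in members:
            assignments[vi] = (b.block_id, parity)
    result = PhaseResult(
        blocks=out_blocks,
        assignments=assignments,
        n_variants=len(variants),
        n_unphased=sum(b.n_variants for b in out_blocks if b.n_variants < 2),
    )
    return variants, result


def write_phased_vcf(
    variants: pd.DataFrame, result: PhaseResult, chrom_lengths: dict, path
):
    """Phased VCF with GT 0|1 / 1|0 and PS set to the block's first
    position (1-based); unphased variants get an unphased 0/1."""
    header = pysam.VariantHeader()
    for name, length in chrom_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set")
    header.add_sample("sample")
    var = variants.reset_index(drop=True)
    block_start = {b.block_id: b.start + 1 for b in result.blocks}
    phased_ids = {b.block_id for b in result.phased_blocks}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for vi in var.sort_values(["chrom", "pos"]).index:
            row = var.loc[vi]
            rec = vcf.new_record(
                contig=row["chrom"],
                start=int(row["pos"]),
                stop=int(row["pos"]) + 1,
                alleles=(row["ref"], row["alt"]),
            )
            assignment = result.assignments.get(int(vi))
            if assignment is not None and assignment[0] in phased_ids:
                block_id, parity = assignment
                rec.samples["sample"]["GT"] = (1, 0) if parity == 0 else (0, 1)
                rec.samples["sample"].phased = True
                rec.samples["sample"]["PS"] = block_start[block_id]
            else:
                rec.samples["sample"]["GT"] = (0, 1)
                rec.samples["sample"].phased = False
            vcf.write(rec)
    return path
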