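# Methods

This note documents the models, parameters and numerical choices behind
`blrkit`, and what the synthetic-data tests do and do not demonstrate.

## 1. Generative model of an emulsion-barcoded linked-read library

**Genome.** A uniform-random diploid genome of `genome_length` bases is
split evenly across `n_chromosomes`. Heterozygous SNVs are placed at
rate `het_snv_rate` (default 10⁻³/bp, a human-like het density); each
SNV's alternate allele is assigned to haplotype 0 or 1 uniformly, giving
a phased truth VCF. Optional large heterozygous deletions are removed
from haplotype 1; haplotype coordinates are mapped back to reference
coordinates through a monotone segment transform, so reads and fragments
right of a deletion report reference positions.

**Droplets and fragments.** Each of `n_droplets` droplets draws
`Poisson(fragments_per_droplet_mean)` HMW fragments (default 3.5) and
`Poisson(barcodes_per_droplet_mean)` distinct barcode oligos (default
2.0). Zero-occupancy droplets therefore occur naturally. Fragment
lengths are lognormal, parameterized by arithmetic mean
(`fragment_length_mean`, default 40 kb) and log-scale shape
(`fragment_length_shape`, default 0.8): a long-tailed law consistent
with tagmented HMW DNA, under which roughly 60% of fragments exceed
20 kb and ~10% exceed 100 kb. Fragments sample a haplotype uniformly and
a chromosome proportional to length.

**Read pairs.** Along each fragment, `Poisson(length/1kb ×
read_pairs_per_kb)` read pairs (default 0.7/kb, matching the
reads-per-molecule economy of published linked-read datasets) are placed
uniformly with insert sizes `Normal(insert_size_mean, insert_size_mean/10)`
truncated to the fragment and to the R1 cycle count. R1 of a *coupled*
pair reads `upstream handle – barcode – downstream handle – genomic`;
R2 is the reverse-complemented insert end. All R1s have equal cycle
counts: an uncoupled R1 is pure genomic sequence of the same length, so
base-weighted and pair-weighted coupling fractions coincide.

**Coupling.** Each sampled pair is designated coupled with probability
`coupling_probability` (default 0.75, the order of published assay
coupling efficiencies). A coupled designee requires a barcode oligo in
its droplet; without one its amplicon is removed by the post-emulsion
enrichment and never sequenced. Uncoupled carryover is emitted from any
fragment-bearing droplet — so `barcodes_per_droplet_mean = 0` yields an
entirely uncoupled library, and the coupled fraction of *emitted* pairs
equals `coupling_probability` exactly when barcode loading saturates and
falls below it at sparse loading.

**Errors.** Substitutions only, at `barcode_error_rate` (default 1%/bp)
inside the barcode copy and `insert_error_rate` (default 0.2%/bp) in
genomic bases. Handles are emitted error-free; handle matching tolerance
downstream exists for real data, and keeping handles clean keeps the
extraction oracle exact. Indels, PCR duplicates and amplification bias
are not modeled (see Limitations).

Identical `rng_seed` gives byte-identical output; every emitted pair is
recorded in a truth table (droplet, barcode, fragment, haplotype, mate
positions).

## 2. Extraction

Handles are located by ungapped Hamming comparison at the expected
offset with a ±3-base shift search; a placement passes when its mismatch
fraction is ≤ `similarity_threshold` (default 0.20, applied per handle).
Mismatch limits are computed as `floor(threshold × length)` with a 10⁻⁹
guard against binary-float droop (0.1 × 20 must allow exactly 2). The
intervening bases must match the barcode design pattern (IUPAC). Reads
failing any check are rejected with a distinct reason code and never
deleted — conservation identities count them. A trailing insert-handle
overlap (≥ 8 bases) is trimmed from the 3' end; interior placements are
not searched.

Extracted barcodes are split into 8 subsets by the documented
lexicographic dinucleotide pairing (AA,AC→0; AG,AT→1; …; TG,TT→7).
Consequence worth knowing: a barcode error in either of the two key
bases usually routes the read to the wrong subset, where it cannot
rejoin its true cluster. At a 1% per-base error rate this caps
pipeline-level barcode recovery near 98.3%; the clustering operation
itself, measured on pooled counts, corrects ≥ 99% of reads. Both numbers
are asserted in the test suite.

## 3. Barcode clustering

Observed barcodes are sorted by count (descending; lexicographic
tie-break for determinism) and processed greedily: a barcode joins the
earliest-seeded cluster whose canonical is within
`floor((1 − identity) × length)` mismatches (identity 0.9 → radius 2 on
a 20-mer), else seeds a new cluster. This replaces word-filtered greedy
clustering heuristics with direct comparison — equivalent at fixed
barcode length and desk scale. On instances whose error variants lie
within the radius of their true barcode (the regime the error model
produces), the greedy result coincides with the Hamming-radius connected
components, which the tests verify against an independent
scipy-components oracle; adversarial chains of variants could split
components and are out of scope.

## 4. Deconvolution

* **Duplicates**: read pairs identical in (corrected barcode, chrom,
  both mate leftmost positions, orientation) are collapsed to the
  highest summed base quality (first wins ties). The simulator does not
  generate PCR duplicates, so this stage is exercised by constructed
  fixtures.
* **Merging**: barcodes link iff ≥ `merge_min_shared_pairs` (2) of their
  read pairs lie within `merge_proximity` (100 kb, strict) on the same
  chromosome, counted by greedy nearest pairing over the two sorted
  position lists — which attains the maximum bipartite matching for
  points on a line, as the tests check against networkx matching —
  summed per chromosome (cross-chromosome distance is undefined). Groups
  are connected components (union-find; candidate pairs from
  proximity-sized genome bins; already-merged pairs are skipped since
  re-testing cannot change the component). Group ids are assigned by
  each group's smallest barcode, making output order-independent.
* **Molecules**: within a (group, chromosome), read-pair leftmost
  positions are sorted and split where consecutive positions differ by
  **more than** `molecule_max_gap` (30 kb; a gap of exactly 30,000 stays
  together). A molecule spans first leftmost to last rightmost mate plus
  the read length — the fragment's true right end is unobservable, so
  spans are accurate only when sampling is dense enough that end gaps
  (~ Exp(density⁻¹) per barcode) are small; the recovery test uses
  25 pairs/kb with limiting-dilution barcode loading for exactly this
  reason.
* **Filters**: droplet groups with > `max_molecules_per_droplet` (260)
  molecules, then groups with < `min_read_pairs_per_group` (4) retained
  pairs, have barcodes stripped from their reads (reads are kept,
  counted, and can never be resurrected). Survivors are mapped
  injectively to 16-base barcodes by base-4 encoding of their rank, with
  an explicit error past the 4.8 M whitelist limit.

**Scale caveat.** The 100 kb / 2-pair merge rule presumes fragment
coverage sparse enough that unrelated molecules rarely colocate within
100 kb — true for human-scale genomes, false for megabase toy genomes at
high coverage, where proximity chains collapse whole chromosomes into
one group and the droplet filter then strips them. Tests and the
acceptance script therefore use the dense 2 Mb configuration for
throughput and conservation properties, and sparse large-genome
configurations (e.g. 200 Mb, 80 droplets, fragment coverage ≈ 0.03×)
whenever group composition, molecules or phasing are the quantity of
interest. Defaults stay at the human-scale values and are fully
configurable.

## 5. Phasing

Reads carrying molecule tags observe REF/ALT alleles at het SNV
positions (per-molecule majority vote; ties dropped). Consecutive
variants covered by one molecule contribute +1 (equal alleles, cis) or
−1 (opposite, trans) to an edge. Variants are oriented along a
maximum-weight spanning forest (Kruskal on |weight|); each component is
a phase block; zero-net-weight edges are dropped and singleton blocks
count as unphased. This deterministic simplification is not an
MEC-optimal phaser and does not claim equivalence with production
pipelines: on conflict-free evidence (error-free, single-haplotype
molecules) it is exact, and the tests verify the forest orientation
attains the exhaustive 2^k optimum on ≤ 12-variant instances of that
regime; frustrated cycles from chimeric molecules can make the forest
suboptimal.

Evaluation: phased fraction (variants in ≥ 2-variant blocks / all het
variants), switch errors (haplotype-disagreement flips between
consecutive block variants; invariant under each block's arbitrary
global flip), N50 and longest block over block spans.

## 6. Statistics

* **Coupling efficiency** is operationalized as a base-weighted
  fraction: bases in read pairs with a valid extracted barcode *and* a
  mapped insert over all sequenced bases. This is a documented stand-in
  for assay-specific definitions; with equal cycle counts it reduces to
  the coupled pair fraction times the mapping rate.
* **Molecule statistics**: mean length and fractions strictly greater
  than 20 kb / 100 kb.
* **N50**: smallest length whose ≥-tail covers half the total.
* **Overlap matrices**: a region is tiled into half-open windows (last
  partial window kept); entry (i,j) counts barcodes with retained reads
  in both windows. Symmetry and diagonal maximality are invariants. A
  heterozygous deletion makes breakpoint-flanking windows adjacent on
  one haplotype, elevating their overlap above distance-matched control
  pairs — the simulated 50 kb deletion shows this at one-sided
  Wilcoxon p < 0.001 over 20 seeds.

## 7. Problem sizes and determinism

The default `SimConfig` (2 Mb, 2,000 droplets, ≈ 176k read pairs) runs
the full pipeline in about a minute on one CPU; the sparse haplotyping
configuration (200 Mb, 80 droplets, ≈ 3k pairs) in ~15 s. All
stochastic tests fix seeds; hypothesis-based property tests are bounded
and derandomized by the library's example database. `--seed` is the only
entropy source of `scripts/acceptance.py`.

## 8. Known limitations

* Substitution-only error model; no indels, so extraction and clustering
  oracles are exact by construction.
* No PCR duplicate or amplification-bias model; the duplicate remover is
  validated on fixtures only.
* Uncoupled reads are emitted with no construct at all; partial or
  chimeric constructs are not modeled.
* Reads "align" at their simulator-truth coordinates; mapping error,
  repeats and mappability are outside scope, so real-data extraction and
  phasing rates will be lower than the synthetic ones.
* The phaser is a deliberately simple stand-in (see §5).
* Passing synthetic tests demonstrates the pipeline's internal
  correctness and its behavior under the stated generative model, not
  performance on real libraries.
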