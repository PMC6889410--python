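"""End-to-end driver: simulate -> extract -> cluster -> deconvolve ->
molecules -> filter -> 10x conversion -> phase -> statistics.

Each stage's counts are kept so read-conservation identities can be
checked: reads are only ever rejected, flagged duplicate or
barcode-stripped — never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import cluster as bc_cluster
from . import linkage, phasing, stats
from .design import BarcodeDesign
from .extract import TrimParams, extract_read_pairs, library_pairs, split_subsets
from .simulate import SimConfig, SimulatedLibrary, alignments_from_truth, simulate_library


@dataclass
class PipelineResult:
    lib: SimulatedLibrary
    extraction: dict
    clusters: list
    aln: pd.DataFrame
    groups: list
    bx_to_group: dict
    molecules: pd.DataFrame
    surviving_groups: list
    tenx_map: dict
    coupling: float
    phase_metrics: dict = field(default_factory=dict)
    extracted_pairs: list = field(default_factory=list)
    phase_result: object = None
    phase_observations: pd.DataFrame | None = None

    # -- conservation -------------------------------------------------------

    def conservation(self) -> list[tuple[str, int, int, bool]]:
        """Stage-by-stage read bookkeeping identities as
        (name, lhs, rhs, holds) tuples."""
        n_pairs = self.lib.n_read_pairs
        ex = self.extraction
        cluster_total = sum(c.total_count for c in self.clusters)
        cons = linkage.read_conservation(self.aln)
        checks = [
            ("truth_rows_eq_read_pairs", len(self.lib.truth), n_pairs),
            ("extracted_plus_rejected_eq_input", ex["extracted"] + ex["rejected"], n_pairs),
            ("cluster_members_eq_extracted", cluster_total, ex["extracted"]),
            ("alignment_rows_eq_read_pairs", cons["pairs_in"], n_pairs),
            ("retained_plus_duplicates_eq_input", cons["retained"] + cons["duplicates"], n_pairs),
        ]
        return [(name, lhs, rhs, lhs == rhs) for name, lhs, rhs in checks]

    def conservation_ok(self) -> bool:
        return all(ok for *_ignored, ok in self.conservation())

    # -- reporting ----------------------------------------------------------

    def report(self) -> dict:
        cons = linkage.read_conservation(self.aln)
        rep = {
            "read_pairs": self.lib.n_read_pairs,
            "coupled_read_pairs": int(self.lib.truth["coupled"].sum()),
            "extraction": self.extraction,
            "barcode_clusters": len(self.clusters),
            "duplicates": cons["duplicates"],
            "droplet_groups": len(self.groups),
            "surviving_groups": len(self.surviving_groups),
            "molecules": int(len(self.molecules)),
            "barcode_stripped_pairs": cons["barcode_stripped"],
            "coupling_efficiency": self.coupling,
            "conservation": [
                {"identity": n, "lhs": l, "rhs": r, "ok": ok}
                for n, l, r, ok in self.conservation()
            ],
        }
        if len(self.molecules):
            surviving = self.molecules[self.molecules["group_id"].isin(self.surviving_groups)]
            source = surviving if len(surviving) else self.molecules
            rep["molecule_stats"] = stats.molecule_stats(source["length"])
        if self.phase_metrics:
            rep["phasing"] = self.phase_metrics
        return rep


def run_pipeline(
    config: SimConfig,
    design: BarcodeDesign | None = None,
    params: linkage.PipelineParams | None = None,
    run_phasing: bool = True,
) -> PipelineResult:
    """Run the whole chain on a freshly simulated library."""
    design = design or BarcodeDesign()
    params = params or linkage.PipelineParams()

    lib = simulate_library(config, design)

    # barcode extraction
    trim = TrimParams(design=design)
    ex = extract_read_pairs(library_pairs(lib), trim)

    # subset split + clustering + correction
    raw_counts = Counter(p.raw_barcode for p in ex.extracted)
    subsets, subset_rejects = split_subsets(raw_counts.keys(), design)
    subset_counts = [{b: raw_counts[b] for b in sub} for sub in subsets]
    # non-ACGT keyed barcodes (subset_rejects) stay uncorrected by design
    clusters = bc_cluster.cluster_subsets(subset_counts)
    corrected, n_unclustered = bc_cluster.correct_reads(ex.extracted, clusters)
    barcode_map = {p.read_id: p.corrected_barcode for p in corrected if p.corrected_barcode}

    # alignment table (simulated reads align at their true coordinates)
    aln = alignments_from_truth(lib.truth, barcode_map, read_length=config.read_length)
    aln, _n_dup = linkage.remove_duplicates(aln)

    # droplet deconvolution and molecules
    groups, bx_to_group = linkage.merge_barcodes(aln, params)
    aln = linkage.assign_groups(aln, bx_to_group)
    molecules, aln = linkage.call_molecules(aln, params)

    # filters and 10x conversion
    aln, _kept_d, stripped_d = linkage.filter_droplets(aln, molecules, params)
    aln, kept_l, stripped_l = linkage.strip_low_count(aln, params)
    surviving = sorted(set(kept_l) - set(stripped_d))
    tenx_map = linkage.tenx_convert(surviving, params.tenx_barcode_limit)

    # statistics
    summary = stats.coupling_summary(lib, [p.read_id for p in ex.extracted])
    coupling = stats.coupling_efficiency(summary)

    phase_metrics: dict = {}
    phase_result = None
    obs = None
    if run_phasing and len(lib.variants):
        tagged = phasing.forward_strand_reads(corrected, aln)
        obs = phasing.allele_observations(tagged, lib.variants)
        phase_result = phasing.phase_variants(lib.variants, obs)
        phase_metrics = phasing.evaluate_phasing(phase_result, lib.variants)

    return PipelineResult(
        lib=lib,
        extraction=ex.summary,
        clusters=clusters,
        aln=aln,
        groups=groups,
        bx_to_group=bx_to_group,
        molecules=molecules,
        surviving_groups=surviving,
        tenx_map=tenx_map,
        coupling=coupling,
        phase_metrics=phase_metrics,
        extracted_pairs=corrected,
        phase_result=phase_result,
        phase_observations=obs,
    )


def phase_with_truth_molecules(lib: SimulatedLibrary, extracted_pairs) -> dict:
    """Phase using the simulator's true fragment ids as molecule tags.

    This isolates the phaser from the deconvolution stages: every molecule
    is a true single-haplotype fragment, so with error-free inserts the
    switch error must be zero. Returns the evaluation metrics and the raw
    result.
    """
    truth = lib.truth.set_index("read_id")
    aln = alignments_from_truth(lib.truth, read_length=lib.config.read_length)
    aln["duplicate"] = False
    aln["mi"] = aln["read_id"].map(truth["fragment_id"]).astype("Int64")
    tagged = phasing.forward_strand_reads(extracted_pairs, aln)
    obs = phasing.allele_observations(tagged, lib.variants)
    result = phasing.phase_variants(lib.variants, obs)
    metrics = phasing.evaluate_phasing(result, lib.variants)
    return {"metrics": metrics, "result": result, "observations": obs}
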