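"""Droplet deconvolution: merge barcodes, call molecules, apply filters.

Uses a sparse genome (200 Mb, 80 droplets) so that proximity-based
merging reflects shared droplets rather than chance colocation — the
regime the <100 kb / >= 2 shared-pairs rule is designed for.
"""

from blrkit import SimConfig, run_pipeline
from blrkit.stats import molecule_stats

cfg = SimConfig(
    genome_length=200_000_000,
    n_chromosomes=2,
    n_droplets=80,
    fragments_per_droplet_mean=2.0,
    barcodes_per_droplet_mean=2.0,
    rng_seed=11,
)
res = run_pipeline(cfg, run_phasing=False)

print(f"read pairs              : {res.lib.n_read_pairs}")
print(f"barcode clusters        : {len(res.clusters)}")
print(f"droplet groups          : {len(res.groups)}")
print(f"groups after filters    : {len(res.surviving_groups)}")
print(f"molecules called        : {len(res.molecules)}")
print("molecule stats          :", molecule_stats(res.molecules["length"]))
print("conservation            :", res.conservation_ok())

# Groups approximate true droplets: several barcode oligos from one
# droplet tag the same fragments, so their reads share many proximal
# positions and merge; molecules are same-group read runs split at >30 kb
# gaps. Oversized droplets (>260 molecules) and groups under 4 read pairs
# are barcode-stripped, and survivors map to 16-base 10x-style barcodes.
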