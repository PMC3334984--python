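"""Simulate a small array-design study: genome, panel, call tables.

The generator produces an 8-chromosome genome with genic/repeat structure,
a 56-accession detection panel at heterogeneous low coverage, true SNPs
with uniform MAF, and per-accession raw call tables.
"""

from snparray import simdata

cfg = simdata.SimConfig(seed=42, chromosome_length=200_000, n_snps=1500)
genome, annotation, repeats = simdata.simulate_genome(cfg)
panel = simdata.simulate_panel(genome, annotation, cfg)
calls = simdata.simulate_callsets(panel, cfg)

print(f"genome: {len(genome.chromosomes)} chromosomes + "
      f"{len(genome.unanchored)} scaffolds, {genome.total_length:,} bp total")
print(f"annotation: {len(annotation)} genes; repeat intervals: {len(repeats)}")
print(f"panel: {len(panel.accessions)} accessions in "
      f"{panel.accessions['pool'].nunique()} pools, "
      f"coverage {panel.accessions['coverage'].min():.2f}-"
      f"{panel.accessions['coverage'].max():.2f}x")
print(f"true SNPs: {len(panel.snps)}, MAF "
      f"{panel.snps['maf'].min():.3f}-{panel.snps['maf'].max():.3f}")
rows = sum(len(t) for t in calls.values())
print(f"call tables: {rows:,} records across the panel")
# Each record is one accession's read support at one true SNP; low-coverage
# accessions cover only a fraction of the sites, as in real resequencing.
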