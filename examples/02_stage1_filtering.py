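"""Stage-1 variant filtering under both regimes, plus cross-lab concordance.

Regime A: inclusive quality >= 25, coverage 30..2.5x mean, >= 5 minor-allele
reads, repeat-track exclusion. Regime B: strict quality > 30, per-allele
ceiling at mean + 3 SD, >= 5 minor-allele reads, flank k-mer copy number < 2.
"""

import dataclasses

from snparray import detection, simdata

cfg = simdata.SimConfig(seed=42, chromosome_length=200_000, n_snps=1500)
genome, annotation, repeats = simdata.simulate_genome(cfg)
panel = simdata.simulate_panel(genome, annotation, cfg)
calls = simdata.simulate_callsets(panel, cfg)

for params in (detection.Stage1Params.regime_a(cov_min=10),
               detection.Stage1Params.regime_b(cov_min=10)):
    counts: dict = {}
    cand = detection.filter_stage1(
        calls, params, genome=genome, repeats=repeats, counts_out=counts
    )
    removed = ", ".join(f"{k}={v}" for k, v in counts.items())
    print(f"regime {params.regime}: {len(cand)} candidates (removed: {removed})")

# concordance between two independent resequencings of one accession,
# as done for accessions sequenced in two laboratories
cfg2 = dataclasses.replace(cfg, seed=43)
calls2 = simdata.simulate_callsets(panel, cfg2)
low = panel.accessions[panel.accessions["platform"] == "longread"].iloc[0]
acc = low["id"]  # a ~0.2x long-read accession
positions = list(zip(panel.snps["chrom"], panel.snps["pos"]))
rep = detection.compare_callsets(calls[acc], calls2[acc], positions)
print(f"\nconcordance for {acc} ({low['coverage']}x, two independent runs):")
print(f"  comparable: {rep.n_comparable}/{rep.n_candidates} "
      f"({rep.comparable_fraction:.1%}) - most positions lack coverage in one run")
print(f"  identical genotype: {rep.identical_fraction:.1%}, "
      f"share one allele: {rep.partial_fraction:.1%}, "
      f"no shared allele: {rep.no_share_fraction:.1%}")
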