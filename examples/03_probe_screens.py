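"""Infinium probe candidacy screens: assay type, tail uniqueness, merging.

Type-I SNPs (A/T, C/G) need two bead types and are dropped; a probe whose
25-bp tail recurs in the genome (either strand) cross-hybridises and is
dropped; candidate sets from the two detection regimes are merged with
same-position allele conflicts excluded.
"""

from snparray import detection, probedesign, simdata
from snparray.kmers import KmerIndex

cfg = simdata.SimConfig(seed=42, chromosome_length=200_000, n_snps=1500)
genome, annotation, repeats = simdata.simulate_genome(cfg)
panel = simdata.simulate_panel(genome, annotation, cfg)
calls = simdata.simulate_callsets(panel, cfg)

cand_a = detection.filter_stage1(
    calls, detection.Stage1Params.regime_a(cov_min=10), genome=genome,
    repeats=repeats,
)
cand_b = detection.filter_stage1(
    calls, detection.Stage1Params.regime_b(cov_min=10), genome=genome
)
merged, conflicts = probedesign.merge_dedup([cand_a, cand_b])
print(f"merged {len(cand_a)} + {len(cand_b)} -> {len(merged)} unique candidates "
      f"({len(conflicts)} allele conflicts dropped)")

tail_index = KmerIndex(genome, 25)
annotated = probedesign.annotate_candidates(
    merged, genome, annotation, tail_index=tail_index
)
n_type1 = (annotated["infinium_type"] == "I").sum()
n_tail = annotated["tail_duplicated"].sum()
print(f"assay types: {n_type1} type I removed "
      f"({n_type1 / len(annotated):.0%}; ~2 of 6 allele pairs are type I)")
print(f"probe tails duplicated in genome: {n_tail} "
      f"(sites inside duplicated repeat blocks)")

screened = probedesign.remove_infinium_i(annotated)
screened = screened[~screened["tail_duplicated"]]
print(f"candidates surviving probe screens: {len(screened)}")
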