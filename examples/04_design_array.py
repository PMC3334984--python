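"""Stage-2 filtering and even-spacing selection into a fixed-size array.

Stage 2 keeps exonic, well-supported, chromosome-anchored candidates; the
selector pins pre-validated SNPs and fills the remaining slots on an ideal
physical grid per chromosome (total-distance-minimising assignment).
"""

from snparray import arrayselect, detection, evaluate, probedesign, simdata

cfg = simdata.SimConfig(seed=42, chromosome_length=200_000, n_snps=1500)
genome, annotation, repeats = simdata.simulate_genome(cfg)
panel = simdata.simulate_panel(genome, annotation, cfg)
calls = simdata.simulate_callsets(panel, cfg)
cand = detection.filter_stage1(
    calls, detection.Stage1Params.regime_a(cov_min=10), genome=genome,
    repeats=repeats,
)
cand = probedesign.remove_infinium_i(
    probedesign.annotate_candidates(cand, genome, annotation)
)

counts: dict = {}
stage2 = arrayselect.filter_stage2(cand, min_support=3, counts_out=counts)
print(f"stage 2: {len(cand)} -> {len(stage2)} "
      f"(removed per rule, in order: {counts})")

# pin two pre-validated SNPs, fill 40 slots total
pinned = stage2.iloc[[0, len(stage2) // 2]][["id", "chrom", "pos"]]
plan = arrayselect.SelectionPlan(total_slots=40, pinned=pinned)
print(f"selection ratio: {plan.selection_ratio(len(stage2))} "
      f"stage-2 candidates per available slot")

design = arrayselect.select_even_spacing(stage2, plan)
print(f"design: {len(design)} SNPs; per chromosome: "
      f"{design.per_chromosome_counts.to_dict()}")

gaps = evaluate.gap_statistics(design.positions_by_chromosome(), threshold_kb=15)
print(f"spacing: average gap {gaps.total['avg_gap_kb']:.1f} kb, "
      f"largest {gaps.total['largest_gap_kb']:.1f} kb, "
      f"{gaps.total['n_gaps_over']} gaps > 15 kb")

# manufacturing dropout: a fraction of bead types is lost in production
after = arrayselect.apply_manufacturing_dropout(design, rate=0.05, seed=1)
print(f"after 5% manufacturing dropout: {len(after)} SNPs remain on the array")
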