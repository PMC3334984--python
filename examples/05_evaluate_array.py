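"""Evaluate an array on two independent panels: QC, MAF spectra, overlap.

Genotype reports carry GenTrain/GenCall cluster scores and no-calls; QC
fails SNPs with GenTrain <= 0.4, GenCall-10% <= 0.2 or > 50% no-calls, the
rest split into monomorphic (MAF 0) and polymorphic.
"""

import dataclasses

from snparray import arrayselect, detection, evaluate, probedesign, simdata

cfg = simdata.SimConfig(seed=42, chromosome_length=200_000, n_snps=1500,
                        failure_fraction=0.05, null_allele_fraction=0.02)
genome, annotation, repeats = simdata.simulate_genome(cfg)
panel = simdata.simulate_panel(genome, annotation, cfg)
calls = simdata.simulate_callsets(panel, cfg)
cand = probedesign.remove_infinium_i(
    probedesign.annotate_candidates(
        detection.filter_stage1(
            calls, detection.Stage1Params.regime_a(cov_min=10),
            genome=genome, repeats=repeats,
        ),
        genome, annotation,
    )
)
stage2 = arrayselect.filter_stage2(cand, min_support=3)
design = arrayselect.select_even_spacing(
    stage2, arrayselect.SelectionPlan(total_slots=40)
)
manifest = design.manifest[["id", "chrom", "pos"]]

# two independent evaluation panels = two report realisations
rep_eu = simdata.simulate_genotype_report(manifest, panel, cfg)
rep_us = simdata.simulate_genotype_report(
    manifest, panel, dataclasses.replace(cfg, seed=4242)
)

cls_eu = evaluate.classify_snps(rep_eu)
cls_us = evaluate.classify_snps(rep_us)
for name, cls in (("EU-like", cls_eu), ("US-like", cls_us)):
    p = cls.proportions
    print(f"{name} panel: failed {p['failed']:.2f}, "
          f"monomorphic {p['monomorphic']:.2f}, polymorphic {p['polymorphic']:.2f}; "
          f"MAF>0.10 among polymorphic: {cls.maf_over(0.10):.0%}")

cmp = evaluate.compare_panels(cls_eu, cls_us)
print(f"polymorphic in both: {cmp.n_shared} of {cmp.n_union} "
      f"({cmp.shared_fraction_pct}%)")

maf_a = cls_eu.table["maf"].dropna()
maf_b = cls_us.table["maf"].dropna()
r = evaluate.maf_concordance(maf_a, maf_b)
print(f"MAF concordance between panels: r = {r:.3f} "
      f"(same germplasm genotyped twice, so high)")
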