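"""Re-derive the published peach 9K array summaries from the shipped
input tables: the design funnel, per-chromosome polymorphism rates,
sequencing coverage accounting, and validation summaries.
"""

import pandas as pd

from snparray import refdata
from snparray.arrayselect import SelectionPlan, filter_stage2
from snparray.evaluate import (
    compare_panels, coverage_accounting, polymorphism_rate,
    progeny_informativeness,
)
from snparray.utils import round_half_up

funnel = refdata.design_funnel()
print(f"Stage-1 SNPs: {funnel['stage1_pools_1_5']:,} + "
      f"{funnel['stage1_pools_6_12']:,} = "
      f"{funnel['stage1_pools_1_5'] + funnel['stage1_pools_6_12']:,}")

plan = SelectionPlan(
    total_slots=funnel["array_slots"],
    pinned=pd.DataFrame({"chrom": "x", "pos": range(funnel["prevalidated_pinned"])}),
)
n_stage2 = funnel["stage2_exonic"] - funnel["stage2_unanchored"]
print(f"Stage-2 SNPs: {funnel['stage2_exonic']:,} exonic - "
      f"{funnel['stage2_unanchored']:,} unanchored = {n_stage2:,}")
print(f"selection ratio: {plan.selection_ratio(n_stage2)} candidates per slot")
print(f"after manufacturing dropout: "
      f"{funnel['array_slots'] - funnel['manufacturing_dropout']:,} SNPs on array")

table = refdata.array_chromosome_summary()
rate = polymorphism_rate(
    int(table["polymorphic_snps"].sum()), int(table["array_snps"].sum())
)
print(f"\noverall polymorphism rate: {rate}% "
      f"({int(table['polymorphic_snps'].sum()):,} of "
      f"{int(table['array_snps'].sum()):,} array SNPs)")

panel = refdata.detection_panel()
total_bp = (panel["read_count_million"] * 1e6 * panel["read_length"]).sum()
genome_size = total_bp / panel["coverage"].sum()
_, agg = coverage_accounting(panel, genome_size=genome_size, min_reads_million=0.1)
print(f"\ndetection panel: {agg['total_reads_million']} M reads, "
      f"{agg['total_coverage']}x total coverage "
      f"(effective genome {round_half_up(genome_size / 1e6, 1)} Mb)")
print(f"platform means: short-read {agg['platform_mean_coverage']['shortread']}x "
      f"(excluding {agg['n_excluded_from_means']} low-yield run), "
      f"long-read {agg['platform_mean_coverage']['longread']}x")

shared = {f"s{i}" for i in range(funnel["shared_polymorphic"])}
eu = shared | {f"e{i}" for i in range(funnel["eu_only_polymorphic"])}
us = shared | {f"u{i}" for i in range(funnel["us_only_polymorphic"])}
cmp = compare_panels(eu, us)
print(f"\npolymorphic in both evaluation panels: {cmp.n_shared:,} of "
      f"{cmp.n_union:,} ({cmp.shared_fraction_pct}%)")

dist = refdata.progeny_distribution()
rows = []
for rec in dist.itertuples(index=False):
    rows.extend(
        [[True] * rec.n_progenies + [False] * (5 - rec.n_progenies)] * rec.n_snps
    )
flags = pd.DataFrame(rows, columns=[f"p{j}" for j in range(5)])
summary = progeny_informativeness(flags)
print(f"validation SNPs segregating in >= 1 breeding progeny: "
      f"{summary.any_progeny_pct:.0f}%")
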