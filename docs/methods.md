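# Methods

`snparray` implements the computational pipeline by which a fixed-content
Infinium-style SNP genotyping array is designed from low-coverage
whole-genome resequencing of a breeding panel, and evaluated after
manufacture. This note records the models, the parameters that matter, the
numerical conventions, and the limits of what the synthetic data can show.

## The pipeline

1. **Stage-1 filtering** (`detection.filter_stage1`) screens raw
   per-accession variant calls for callable, non-repetitive, well-supported
   sites.
2. **Probe screens** (`probedesign`) remove SNPs that cannot be assayed
   with a single bead type, whose probe tails are not unique in the genome,
   or whose flanking sequence scores poorly in assay design; candidate sets
   from different detection pipelines are merged.
3. **Stage-2 filtering** (`arrayselect.filter_stage2`) restricts to
   candidates supported by many accessions, in exons, on chromosome-scale
   pseudomolecules.
4. **Selection** (`arrayselect.select_even_spacing`) fills a fixed slot
   budget: pre-validated SNPs are pinned, the rest chosen for even physical
   spacing.
5. **Evaluation** (`evaluate`) computes QC partitions, MAF spectra,
   polymorphism rates, gap statistics and panel comparisons from array
   genotype reports.

## Stage-1 filtering regimes

Two regimes mirror the two caller/laboratory pipelines such studies use:

| rule | regime A | regime B |
| --- | --- | --- |
| caller quality | inclusive, `>= 25` | strict, `> 30` |
| minimum site coverage | 30 reads | 10 reads |
| coverage ceiling | `2.5 x` mean site coverage | per-allele reads `< mean + 3 SD` of per-SNP totals |
| minor-allele support | `>= 5` reads | `>= 5` reads |
| repetitiveness | repeat interval track | flank k-mer copy number `< 2` |

Conventions that the source protocols leave open, fixed here and
configurable:

- **Coverage** at a site is the read total summed over all accessions of
  the pool (a ~30-read minimum only makes sense pool-wise when individual
  accessions average ~2-3x).
- **Site quality** is the maximum caller quality among the accession
  records at the site (the best observation decides callability).
- The **minor allele** at a site is the allele with fewer supporting reads
  (ties go to the alternate allele); its read total must meet the support
  minimum. A site where one allele has no reads at all therefore fails,
  which is intentional: such a site carries no within-panel polymorphism
  evidence.
- The coverage-ceiling statistics (mean, SD) are computed from the input
  call tables themselves, not fixed constants — the published ceilings
  (161, 380 reads) were dataset-derived.
- **Genotype** at a position, for concordance purposes, is the set of
  alleles with at least one supporting read; coverages of 0.2-3x preclude
  confident diploid calls, so agreement is measured as allele-set identity
  / partial sharing / disjointness.

## Copy number and probe-tail uniqueness

Both screens use a genome-wide canonical k-mer index (`kmers.KmerIndex`): a
k-mer and its reverse complement count as one, so duplications on either
strand are found. Copy number at a site is the mean genome-wide occurrence
count of all k-mers (k = 31) in a +/-50 bp window: 1.0 in unique sequence,
2.0 inside a block duplicated exactly once. The Stage-1 regime-B rule
requires `< 2`. The probe-tail screen asks whether the 25-mer immediately
adjacent to the SNP — on either side, since the assay can probe either
strand — occurs more than once (k = 25). Whether reverse-complement hits
should count is not a settled convention; the index exposes
`count_revcomp=False` for a strand-naive screen, and the default counts
them (conservative). A flank too short to contain a full tail is flagged
duplicated, excluding the candidate conservatively. Windows of ambiguous
bases have undefined copy number (NaN), which the filter treats as failing.

## Even-spacing selection

The slot budget is `total_slots`; pre-validated SNPs that pass their own
(laxer) score filter are pinned first, including any on unanchored
scaffolds, which bypass the pseudomolecule rule. Remaining slots are
apportioned to chromosomes proportionally to their Stage-2 candidate
counts by largest-remainder rounding, so array density tracks candidate
density. Within a chromosome an ideal grid of targets spans the candidate
range; pinned SNPs consume their nearest grid points; the remaining
targets are served by the subset of candidates minimising the summed
distance of the j-th chosen candidate to the j-th target (an O(n x m)
order-preserving assignment dynamic program; ties resolve to the
lexicographically smallest subset, i.e. lower positions win). The exact
minimiser is used rather than a sequential nearest-candidate heuristic
because the two disagree on about 1% of small instances and only the
minimiser is a well-defined optimum that an exhaustive-search oracle can
verify.

A caution on spacing: selecting more SNPs does **not** guarantee a smaller
largest gap. When candidates are irregular, enlarging the grid can shift
targets across a candidate desert and the largest realised gap can grow by
a small amount. The guaranteed properties are weaker: every design gap is
a union of consecutive candidate gaps (so the largest design gap is never
below the largest candidate gap, and equals it at saturation), and
monotonicity holds when candidates are uniformly spaced.

## Evaluation statistics

- **QC**: a SNP fails iff GenTrain `<= 0.4` or GenCall-10% `<= 0.2` (keep
  rules are strict `>`) or it is no-call in more than 50% of samples. The
  no-call allowance is deliberately loose because null alleles —
  hybridisation failures in divergent germplasm — present as missing
  genotypes, not as bad clusters.
- **MAF** = `min(p, 1-p)` with `p` the B-allele fraction over called
  samples; undefined (NaN) when every sample is no-call, which QC already
  catches. Binned views: `<5%`, `5-10%`, `>10%` and the `>0.10` / `>0.20`
  fractions.
- **Polymorphism rates** can be quoted against the whole array or against
  the on-chromosome subset; both denominators are computed explicitly and
  labelled, since published tables mix them (84.3% vs 84.4% in the
  reference study).
- **Gap statistics**: a gap is the distance between successive array SNPs
  on one chromosome; the flank from position 1 to the first SNP is not a
  gap; chromosomes with fewer than two SNPs report no gaps.
- **Rounding**: proportions print at 2 dp, percentages at 1 dp, ties
  half-up (`utils.round_half_up`) to match how such tables are typeset;
  Python's default banker's rounding would flip several printed values.

## The synthetic-data generator

`simdata` emulates the study design: an 8-pseudomolecule genome (default
1 Mb each, a deliberately scaled-down toy; all sizes configurable) with
exact duplicated repeat blocks (so k-mer screens find them), Poisson gene
structure with exon/intron/UTR intervals, a 56-accession panel in 12 pools
(the last pool tagged long-read at 0.2x; the rest lognormal around ~2x,
clipped to 0.2-8x, matching the published panel's coverage range), true
SNP MAFs uniform on (0.05, 0.5], Hardy-Weinberg genotypes, per-site
Poisson read depth at the accession's coverage, per-read allele error
(default 1%), and truncated-normal caller qualities (mean 32, SD 6 —
spanning both Stage-1 thresholds so the quality rules are exercisable).
Array reports plant a configurable fraction of forced failures (low
cluster scores, heavy no-calls) and null-allele-like SNPs (elevated
no-call rates in a random half of samples). The depth and quality models
are free parameters of this package: aggregate coverages are the only
constraint the emulated protocol publishes, and Poisson-per-site is the
simplest model that reproduces the low-coverage missingness central to the
concordance analysis.

Determinism: one integer seed drives independent named child streams
(`SeedSequence` + CRC of the stage name), so identical configurations give
byte-identical FASTA/GFF3/TSV outputs across runs and platforms.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and pedigree structure
(genotypes are independent across accessions and sites), reference bias
and alignment artifacts, indels, caller-specific error models, batch
effects between laboratories, and ascertainment of the reference genome.
Results on synthetic data validate the pipeline's bookkeeping and rule
logic, not biological effect sizes.

## Degenerate inputs and error conventions

Empty call-table sets filter to empty candidate sets (not an error);
unknown chromosomes, out-of-range positions, invalid alleles, scores
outside [0, 1], pinned sets exceeding the slot budget, and dropout ids
absent from a design all raise typed exceptions. Same-position candidates
with different allele pairs are excluded and returned as conflicts rather
than arbitrated; there is no principled way to pick a winner without
re-examining reads. Concordance and classification report NaN fractions
over zero denominators instead of dividing by zero.

## Reference tables

`refdata` ships the published summary tables of the peach 9K array study
as package data (per-accession read counts, per-chromosome array counts,
validation outcomes, progeny segregation distribution, funnel counts).
They are *inputs*; every derived number — coverages, the 111.7x total,
the 2.16x/0.22x platform means, the ~227 Mb effective genome size, the
4.74 selection ratio, the 84.3%/84.4% polymorphism rates, the 86.9% panel
overlap, the 95% progeny informativeness — is recomputed by package
functions at run time (see `scripts/acceptance.py` and
`examples/06_published_summaries.py`).

## Problem sizes

Tests and the acceptance script run the synthetic pipeline at toy scale
(genomes of a few hundred kb, panels of 10-56 accessions, hundreds to a
few thousand SNPs) — sizes chosen so exhaustive oracles (full k-mer
censuses, subset enumeration, brute-force rule evaluation) remain feasible
alongside every run. The funnel arithmetic runs at the published scale
(10^6 candidate rows) since it is vectorised counting.
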