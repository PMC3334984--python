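# snparray

Design and evaluation of fixed-content SNP genotyping arrays from
low-coverage resequencing panels.

Moderate-density Infinium-style arrays — like the 9K array built for peach
(*Prunus persica*) breeding germplasm — are designed by funnelling roughly
a million sequencing-detected variants down to a few thousand assayable,
informative, evenly spaced markers. `snparray` implements that funnel as a
reusable, testable pipeline for anyone building or auditing such an array:

- **Stage-1 filtering** of per-accession variant calls under two regimes
  (caller quality, site-coverage band, >= 5 minor-allele reads, repeat
  exclusion by interval track or by flank k-mer copy number < 2);
- **probe candidacy screens**: Infinium type-I (A/T, C/G) removal, 50 bp
  probe context extraction, genome-wide uniqueness of the 25 bp probe tail
  (canonical k-mers, both strands), design-score thresholds, and
  multi-source merge with allele-conflict exclusion;
- **Stage-2 filtering** (support >= 5 accessions, exonic, on a
  pseudomolecule) and **even-spacing selection** into a fixed slot budget,
  with pre-validated SNPs pinned and per-chromosome slots allocated
  proportionally to candidate density;
- **array evaluation**: GenTrain/GenCall QC with a 50% no-call rule, MAF
  spectra (MAF = min(p, 1-p) over called samples), polymorphism
  classification, physical gap statistics, two-panel comparisons,
  validation cross-tabs, progeny informativeness, and sequencing-coverage
  accounting;
- a **synthetic-data generator** (genome with genic/repeat structure,
  Hardy-Weinberg panel, Poisson read depths, GenomeStudio-like reports
  with planted failures and null-allele-like no-calls) so the entire
  workflow runs end to end, deterministically, without external data.

The published summary tables of the peach 9K study ship as package data
(`snparray.refdata`) and every derived number is recomputed at run time.

## Worked example

`examples/` holds one short script per capability. Designing and spacing
an array from a simulated study (`examples/04_design_array.py`):

```text
stage 2: 952 -> 85 (removed per rule, in order: {'support': 2, 'exonic': 863, 'pseudomolecule': 2})
selection ratio: 2.24 stage-2 candidates per available slot
design: 40 SNPs; per chromosome: {'Pp01': 5, 'Pp02': 6, 'Pp03': 3, 'Pp04': 5, 'Pp05': 6, 'Pp06': 5, 'Pp07': 4, 'Pp08': 6}
spacing: average gap 38.8 kb, largest 111.1 kb, 26 gaps > 15 kb
after 5% manufacturing dropout: 38 SNPs remain on the array
```

Of 952 screened candidates, 85 survive the design-level rules (the exonic
restriction dominates, as it does at full scale); 40 slots are filled with
per-chromosome counts tracking candidate density, and the gap statistics
quantify the evenness the selector achieved. Re-deriving the published
study summaries from the shipped tables
(`examples/06_published_summaries.py`):

```text
Stage-1 SNPs: 943,549 + 78,805 = 1,022,354
Stage-2 SNPs: 41,800 exonic - 1,006 unanchored = 40,794
selection ratio: 4.74 candidates per slot
after manufacturing dropout: 8,144 SNPs on array

overall polymorphism rate: 84.3% (6,869 of 8,144 array SNPs)

detection panel: 279.7 M reads, 111.7x total coverage (effective genome 227.2 Mb)
platform means: short-read 2.16x (excluding 1 low-yield run), long-read 0.22x

polymorphic in both evaluation panels: 5,967 of 6,869 (86.9%)
validation SNPs segregating in >= 1 breeding progeny: 95%
```

The same stages are runnable from a shell (`snparray simulate | detect |
design | genotype | evaluate | report`), each step logging per-rule
removal counts so the whole selection funnel can be reconstructed:

```sh
snparray simulate -c config.yaml -o run/
snparray detect -i run/ --regime B -o run/cand.vcf --log run/stage1.log
snparray design --candidates run/cand.vcf -i run/ --slots 9000 -o run/manifest.csv
```

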