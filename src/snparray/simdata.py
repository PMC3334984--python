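"""Synthetic genomes, resequencing panels, call tables and array reports.

The generator emulates the data a SNP-array design study consumes: a small
multi-chromosome plant genome with genic/intergenic/repeat structure, a
detection panel of a few dozen accessions resequenced at heterogeneous
low coverage (0.2-8x) on two platforms, true biallelic SNPs with a stated
minor-allele-frequency distribution, per-accession read depths and caller
quality scores, and GenomeStudio-style genotype reports with cluster-quality
scores, no-calls and null-allele-like failures.

Everything is driven by a single integer seed through independent child
streams per stage, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    Chromosome,
    Gene,
    GeneAnnotation,
    GenomeAssembly,
    InvalidConfigError,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the structure of the emulated study at toy scale:
    8 pseudomolecules, a detection panel of 56 accessions in 12 pools
    (pools 1-11 short-read at ~0.2-8x, pool 12 long-read at ~0.2x), SNP
    minor allele frequencies uniform on (0.05, 0.5], and caller quality
    scores spanning both Stage-1 thresholds (25 and 30).
    """

    seed: int = 0

    # genome
    n_chromosomes: int = 8
    chromosome_length: int = 1_000_000
    n_unanchored: int = 2
    unanchored_length: int = 50_000
    gene_density: float = 0.30       # fraction of genome covered by gene spans
    mean_exon_length: int = 250
    mean_intron_length: int = 400
    mean_exons_per_gene: int = 4
    utr_length: int = 300            # per side, within 2 kb of start/stop codons
    repeat_fraction: float = 0.05    # fraction of genome inside duplicated blocks
    repeat_block_length: int = 2_000

    # detection panel
    n_accessions: int = 56
    n_pools: int = 12
    n_snps: int = 2_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    coverage_log_mean: float = 0.6   # lognormal for short-read accessions
    coverage_log_sd: float = 0.7
    coverage_min: float = 0.2
    coverage_max: float = 8.0
    longread_coverage: float = 0.2   # pool-12 accessions

    # read-level model
    error_rate: float = 0.01         # per-read allele flip probability
    quality_mean: float = 32.0       # truncated-normal caller quality
    quality_sd: float = 6.0
    quality_max: float = 45.0

    # array report model
    nocall_rate: float = 0.02
    failure_fraction: float = 0.05   # SNPs forced to fail clustering
    null_allele_fraction: float = 0.0  # SNPs with null-allele-like no-calls
    null_allele_nocall_rate: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "gene_density", "repeat_fraction", "error_rate",
            "nocall_rate", "failure_fraction", "null_allele_fraction",
            "null_allele_nocall_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.n_chromosomes < 1:
            raise InvalidConfigError("at least one chromosome required")
        if self.chromosome_length < 1 or self.unanchored_length < 1:
            raise InvalidConfigError("zero-length chromosome requested")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise InvalidConfigError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.coverage_min < 0 or self.longread_coverage < 0:
            raise InvalidConfigError("negative coverage")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream for a named stage."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return np.random.default_rng(ss)


@dataclass
class TruePanel:
    """Ground truth: accessions, true SNPs and true diploid genotypes.

    ``genotypes[i, j]`` is the alternate-allele dosage (0/1/2) of accession
    i at SNP j, drawn under Hardy-Weinberg proportions from the SNP's
    population MAF (the alternate allele is the minor one).
    """

    accessions: pd.DataFrame   # id, pool, platform, coverage
    snps: pd.DataFrame         # id, chrom, pos, ref, alt, maf
    genotypes: np.ndarray      # n_accessions x n_snps int8

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.accessions), len(self.snps)):
            raise InvalidConfigError("genotype matrix shape mismatch")
        if len(self.snps) and not (
            (self.snps["maf"] > 0) & (self.snps["maf"] <= 0.5)
        ).all():
            raise InvalidConfigError("true MAF outside (0, 0.5]")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _place_repeats(
    rng: np.random.Generator,
    chroms: dict[str, np.ndarray],
    config: SimConfig,
) -> list[tuple[str, int, int]]:
    """Copy exact blocks within the genome; return all repeat intervals
    (1-based inclusive), sources and destinations alike."""
    total = sum(len(s) for s in chroms.values())
    target_bp = int(round(config.repeat_fraction * total))
    block = config.repeat_block_length
    intervals: list[tuple[str, int, int]] = []
    used: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chroms}
    ids = list(chroms)

    def free(cid: str, start0: int) -> bool:
        end0 = start0 + block
        if end0 > len(chroms[cid]):
            return False
        return all(end0 <= s or start0 >= e for s, e in used[cid])

    placed = 0
    attempts = 0
    # each placement duplicates one block: source + destination both repeat
    while placed + 2 * block <= target_bp and attempts < 10_000:
        attempts += 1
        src_c, dst_c = rng.choice(ids), rng.choice(ids)
        src0 = int(rng.integers(0, max(1, len(chroms[src_c]) - block)))
        dst0 = int(rng.integers(0, max(1, len(chroms[dst_c]) - block)))
        if not (free(src_c, src0) and free(dst_c, dst0)):
            continue
        if src_c == dst_c and not (dst0 + block <= src0 or dst0 >= src0 + block):
            continue
        chroms[dst_c][dst0 : dst0 + block] = chroms[src_c][src0 : src0 + block]
        used[src_c].append((src0, src0 + block))
        used[dst_c].append((dst0, dst0 + block))
        intervals.append((src_c, src0 + 1, src0 + block))
        intervals.append((dst_c, dst0 + 1, dst0 + block))
        placed += 2 * block
    intervals.sort()
    return intervals


def _annotate_chromosome(
    rng: np.random.Generator, chrom_id: str, length: int, config: SimConfig
) -> list[Gene]:
    """Tile genes left to right with exponential intergenic gaps sized so the
    expected genic fraction matches ``gene_density``."""
    if config.gene_density <= 0:
        return []
    genes: list[Gene] = []
    n_ex = config.mean_exons_per_gene
    mean_gene = (
        2 * config.utr_length
        + n_ex * config.mean_exon_length
        + (n_ex - 1) * config.mean_intron_length
    )
    mean_gap = mean_gene * (1 - config.gene_density) / config.gene_density
    pos = 1 + int(rng.exponential(mean_gap))
    gi = 0
    while True:
        utr5 = config.utr_length
        n_exons = max(1, int(rng.poisson(n_ex)))
        exon_lens = np.maximum(30, rng.poisson(config.mean_exon_length, n_exons))
        intron_lens = np.maximum(50, rng.poisson(config.mean_intron_length, max(0, n_exons - 1)))
        start = pos
        cur = start + utr5
        exons = []
        for i, el in enumerate(exon_lens):
            exons.append((cur, cur + int(el) - 1))
            cur += int(el)
            if i < len(intron_lens):
                cur += int(intron_lens[i])
        end = cur - 1 + config.utr_length
        if end > length:
            break
        utrs = ((start, start + utr5 - 1), (end - config.utr_length + 1, end))
        gi += 1
        genes.append(
            Gene(
                id=f"{chrom_id}.g{gi}",
                chrom=chrom_id,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                exons=tuple(exons),
                utrs=utrs,
            )
        )
        pos = end + 1 + int(rng.exponential(mean_gap))
        if pos >= length:
            break
    return genes


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeAssembly, GeneAnnotation, list[tuple[str, int, int]]]:
    """Generate a genome, gene annotation and repeat track.

    Repeat intervals are exact duplicated sequence blocks, so k-mer
    copy-number estimation recovers them; with ``repeat_fraction=0`` every
    k-mer of a (not absurdly large) random genome is unique.
    """
    rng = config.rng("genome")
    chrom_ids = [f"Pp{i + 1:02d}" for i in range(config.n_chromosomes)]
    scaf_ids = [f"scaffold_{i + 1}" for i in range(config.n_unanchored)]
    arrays = {cid: _random_sequence(rng, config.chromosome_length) for cid in chrom_ids}
    arrays.update(
        {sid: _random_sequence(rng, config.unanchored_length) for sid in scaf_ids}
    )
    repeats = _place_repeats(rng, arrays, config)
    genome = GenomeAssembly(
        chromosomes=[Chromosome(cid, "".join(arrays[cid])) for cid in chrom_ids],
        unanchored=[Chromosome(sid, "".join(arrays[sid])) for sid in scaf_ids],
    )
    genes: list[Gene] = []
    for chrom in genome:
        genes.extend(_annotate_chromosome(rng, chrom.id, chrom.length, config))
    return genome, GeneAnnotation(genes), repeats


def simulate_panel(
    genome: GenomeAssembly, annotation: GeneAnnotation, config: SimConfig
) -> TruePanel:
    """Draw a detection panel and its true SNPs.

    Accessions cycle through ``n_pools`` pools; the last pool is tagged as
    the long-read platform at fixed low coverage, the rest draw a lognormal
    short-read coverage clipped to [coverage_min, coverage_max]. SNP
    positions are uniform over the genome (pseudomolecules and unanchored
    scaffolds alike), MAFs uniform on [maf_low, maf_high], genotypes
    Hardy-Weinberg.
    """
    rng = config.rng("panel")
    if config.n_accessions < 1:
        raise InvalidConfigError("n_accessions must be >= 1")
    if config.n_snps > genome.total_length // 10:
        raise InvalidConfigError("requested SNP density exceeds genome size")

    pools = [(i % config.n_pools) + 1 for i in range(config.n_accessions)]
    platforms = [
        "longread" if p == config.n_pools and config.n_pools > 1 else "shortread"
        for p in pools
    ]
    coverage = np.where(
        np.array(platforms) == "longread",
        config.longread_coverage,
        np.clip(
            rng.lognormal(config.coverage_log_mean, config.coverage_log_sd,
                          config.n_accessions),
            config.coverage_min,
            config.coverage_max,
        ),
    )
    accessions = pd.DataFrame(
        {
            "id": [f"acc{i + 1:02d}" for i in range(config.n_accessions)],
            "pool": pools,
            "platform": platforms,
            "coverage": np.round(coverage, 3),
        }
    )

    chrom_list = list(genome)
    lengths = np.array([c.length for c in chrom_list], dtype=float)
    if config.n_snps == 0:
        snps = pd.DataFrame(columns=["id", "chrom", "pos", "ref", "alt", "maf"])
        return TruePanel(accessions, snps,
                         np.zeros((config.n_accessions, 0), dtype=np.int8))

    records = []
    seen: set[tuple[str, int]] = set()
    while len(records) < config.n_snps:
        ci = rng.choice(len(chrom_list), p=lengths / lengths.sum())
        chrom = chrom_list[ci]
        pos = int(rng.integers(1, chrom.length + 1))
        if (chrom.id, pos) in seen:
            continue
        ref = chrom.sequence[pos - 1]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        seen.add((chrom.id, pos))
        records.append((chrom.id, pos, ref, alt))
    records.sort()
    snps = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    snps.insert(0, "id", snps["chrom"] + "_" + snps["pos"].astype(str))
    snps["maf"] = rng.uniform(config.maf_low, config.maf_high, len(snps))

    p = snps["maf"].to_numpy()  # alternate (minor) allele frequency
    u = rng.random((config.n_accessions, len(snps)))
    hom_ref = (1 - p) ** 2
    het = 2 * p * (1 - p)
    genotypes = np.select(
        [u < hom_ref, u < hom_ref + het], [0, 1], default=2
    ).astype(np.int8)
    return TruePanel(accessions, snps, genotypes)


def simulate_callsets(panel: TruePanel, config: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-accession raw call tables at the panel's true SNP positions.

    Depth at a site is Poisson with mean equal to the accession's coverage;
    each read reports the alternate allele with probability
    ``dosage/2 * (1-e) + (1-dosage/2) * e`` for per-read error rate ``e``.
    Caller quality is truncated-normal. Sites with zero depth are absent
    from the table (the caller saw nothing there).
    """
    rng = config.rng("callsets")
    tables: dict[str, pd.DataFrame] = {}
    n_snps = len(panel.snps)
    cols = ["accession", "chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "qual"]
    for i, acc in panel.accessions.iterrows():
        if n_snps == 0 or acc["coverage"] <= 0:
            tables[acc["id"]] = pd.DataFrame(columns=cols)
            continue
        depth = rng.poisson(acc["coverage"], n_snps)
        dosage = panel.genotypes[i].astype(float)
        p_alt = (dosage / 2) * (1 - config.error_rate) + (1 - dosage / 2) * config.error_rate
        alt_depth = rng.binomial(depth, p_alt)
        qual = np.clip(
            rng.normal(config.quality_mean, config.quality_sd, n_snps),
            0.0,
            config.quality_max,
        )
        mask = depth > 0
        tables[acc["id"]] = pd.DataFrame(
            {
                "accession": acc["id"],
                "chrom": panel.snps["chrom"].to_numpy()[mask],
                "pos": panel.snps["pos"].to_numpy()[mask],
                "ref": panel.snps["ref"].to_numpy()[mask],
                "alt": panel.snps["alt"].to_numpy()[mask],
                "ref_depth": (depth - alt_depth)[mask],
                "alt_depth": alt_depth[mask],
                "qual": np.round(qual[mask], 2),
            }
        )
    return tables


def simulate_genotype_report(
    design: pd.DataFrame, panel: TruePanel, config: SimConfig
):
    """GenomeStudio-like genotype report for the SNPs of an array design.

    ``design`` needs columns id/chrom/pos; rows absent from the panel must
    carry a truthy ``decoy`` column (they genotype as monomorphic AA).
    A ``failure_fraction`` of SNPs is forced to fail (low cluster scores and
    mostly no-calls); a ``null_allele_fraction`` of the remainder shows
    elevated no-call rates in a random half of the samples, emulating null
    alleles. Returns an :class:`~snparray.evaluate.GenotypeMatrix`.
    """
    from .evaluate import GenotypeMatrix

    rng = config.rng("report")
    snp_index = {
        (c, p): j for j, (c, p) in enumerate(zip(panel.snps["chrom"], panel.snps["pos"]))
    }
    has_decoy = "decoy" in design.columns
    n_samples = len(panel.accessions)
    calls = {}
    gentrain = {}
    gencall10 = {}
    n = len(design)
    failed = rng.random(n) < config.failure_fraction
    nullish = (~failed) & (rng.random(n) < config.null_allele_fraction)
    for r, (_, row) in enumerate(design.iterrows()):
        key = (row["chrom"], row["pos"])
        if key not in snp_index:
            if has_decoy and bool(row["decoy"]):
                dosage = np.zeros(n_samples, dtype=np.int8)
            else:
                raise InvalidConfigError(
                    f"design SNP {row['id']} absent from panel and not a decoy"
                )
        else:
            dosage = panel.genotypes[:, snp_index[key]]
        geno = np.array(["AA", "AB", "BB"])[dosage]
        if failed[r]:
            nc = rng.random(n_samples) < 0.8
            gentrain[row["id"]] = round(float(rng.uniform(0.0, 0.35)), 4)
            gencall10[row["id"]] = round(float(rng.uniform(0.0, 0.15)), 4)
        else:
            rate = np.full(n_samples, config.nocall_rate)
            if nullish[r]:
                rate[rng.random(n_samples) < 0.5] = config.null_allele_nocall_rate
            nc = rng.random(n_samples) < rate
            gentrain[row["id"]] = round(float(rng.uniform(0.55, 1.0)), 4)
            gencall10[row["id"]] = round(float(rng.uniform(0.35, 1.0)), 4)
        geno = geno.copy()
        geno[nc] = "NC"
        calls[row["id"]] = geno
    calls_df = pd.DataFrame(calls, index=panel.accessions["id"].to_numpy())
    scores = pd.DataFrame(
        {"gentrain": pd.Series(gentrain), "gencall10": pd.Series(gencall10)}
    )
    samples = panel.accessions.set_index("id")
    return GenotypeMatrix(calls=calls_df, snp_scores=scores, samples=samples)
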