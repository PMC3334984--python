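"""Stage-1 variant filtering and cross-laboratory call-set concordance.

Two filtering regimes are supported, mirroring the two caller/laboratory
pipelines of the emulated study:

* **regime A** (CLC-style): inclusive quality threshold (default >=25),
  minimum total site coverage (default 30 reads), maximum coverage a
  multiple of the mean site coverage (default 2.5x), minimum minor-allele
  read support (default 5), and exclusion of sites inside a repeat interval
  track.
* **regime B** (SoapSNP-style): strict quality threshold (default >30),
  minimum total coverage 10 reads, maximum per-allele read count below the
  mean plus k standard deviations (default k=3) of per-SNP read totals,
  minimum minor-allele read support 5, and mean flanking k-mer copy number
  below a ceiling (default 2, i.e. unique sequence).

"Coverage" at a site is the total read count summed over all accessions in
the pool, and the site quality is the best caller quality among the
accession records; both conventions are configurable at the call sites
that need something else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import CoordinateError, GenomeAssembly, InvalidConfigError
from .kmers import KmerIndex

CALL_COLUMNS = [
    "accession", "chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "qual",
]

CANDIDATE_COLUMNS = [
    "id", "chrom", "pos", "ref", "alt", "n_support", "support_accessions",
    "maf", "source",
]


@dataclass
class Stage1Params:
    """Thresholds of the Stage-1 filter for one regime."""

    regime: str = "A"                 # "A" or "B"
    q_min: float = 25.0
    q_inclusive: bool = True          # regime A: >=; regime B uses strict >
    cov_min: int = 30
    cov_max_rule: str = "multiple_of_mean"  # or "mean_plus_sd"
    cov_max_factor: float = 2.5       # multiple_of_mean
    cov_max_k: float = 3.0            # mean_plus_sd
    minor_allele_min_reads: int = 5
    copy_number_max: float = 2.0      # regime B flank uniqueness ceiling
    flank_bp: int = 50
    kmer_k: int = 31

    def __post_init__(self) -> None:
        if self.regime not in ("A", "B"):
            raise InvalidConfigError(f"unknown regime {self.regime!r}")
        if self.q_min < 0:
            raise InvalidConfigError("q_min must be >= 0")
        if self.minor_allele_min_reads < 1:
            raise InvalidConfigError("minor_allele_min_reads must be >= 1")
        if self.cov_max_factor <= 0 or self.cov_max_k <= 0:
            raise InvalidConfigError("coverage-ceiling factor/k must be > 0")

    @classmethod
    def regime_a(cls, **kw) -> "Stage1Params":
        defaults = dict(regime="A", q_min=25.0, q_inclusive=True, cov_min=30,
                        cov_max_rule="multiple_of_mean")
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def regime_b(cls, **kw) -> "Stage1Params":
        defaults = dict(regime="B", q_min=30.0, q_inclusive=False, cov_min=10,
                        cov_max_rule="mean_plus_sd")
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class ConcordanceReport:
    """Agreement between two call sets of the same accession over a
    candidate position list."""

    n_candidates: int
    n_not_covered: int
    n_comparable: int
    n_identical: int
    n_partial: int
    n_no_share: int

    @property
    def comparable_fraction(self) -> float:
        return self.n_comparable / self.n_candidates if self.n_candidates else math.nan

    def _frac(self, n: int) -> float:
        return n / self.n_comparable if self.n_comparable else math.nan

    @property
    def identical_fraction(self) -> float:
        return self._frac(self.n_identical)

    @property
    def partial_fraction(self) -> float:
        return self._frac(self.n_partial)

    @property
    def no_share_fraction(self) -> float:
        return self._frac(self.n_no_share)


def _concat_calls(calls: Mapping[str, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    nonempty = [t for t in calls.values() if len(t)]
    if not nonempty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(nonempty, ignore_index=True)


def _in_intervals(
    chrom: np.ndarray, pos: np.ndarray, intervals: Iterable[tuple[str, int, int]]
) -> np.ndarray:
    """Membership of 1-based positions in 1-based inclusive intervals."""
    mask = np.zeros(len(pos), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c, ivs in by_chrom.items():
        sel = chrom == c
        if not sel.any():
            continue
        p = pos[sel]
        hit = np.zeros(len(p), dtype=bool)
        for s, e in ivs:
            hit |= (p >= s) & (p <= e)
        mask[sel] = hit
    return mask


def estimate_copy_number(
    genome: GenomeAssembly,
    chrom: str,
    pos: int,
    flank_bp: int = 50,
    k: int = 31,
    index: KmerIndex | None = None,
) -> float:
    """Mean genome-wide occurrence count of the k-mers in the +/-flank window
    around a position (canonical, both strands).

    1.0 means the flanking sequence is unique; 2.0 means it lies in a block
    duplicated exactly once elsewhere. The window is truncated at chromosome
    ends. A window with no valid k-mer (all N) returns NaN; a flank window
    shorter than k raises :class:`CoordinateError`.
    """
    chrom_obj = genome.chromosome(chrom)
    if not 1 <= pos <= chrom_obj.length:
        raise CoordinateError(f"position {pos} outside {chrom}")
    window = genome.subsequence(chrom, pos - flank_bp, pos + flank_bp)
    if len(window) < k:
        raise CoordinateError(
            f"flank window ({len(window)} bp) shorter than k={k}"
        )
    if index is None:
        index = KmerIndex(genome, k)
    elif index.k != k:
        raise InvalidConfigError(f"index built with k={index.k}, requested k={k}")
    return index.window_mean_count(window)


def filter_stage1(
    calls: Mapping[str, pd.DataFrame] | pd.DataFrame,
    params: Stage1Params,
    genome: GenomeAssembly | None = None,
    repeats: Iterable[tuple[str, int, int]] | None = None,
    kmer_index: KmerIndex | None = None,
    counts_out: dict | None = None,
) -> pd.DataFrame:
    """Apply one Stage-1 regime to a set of per-accession call tables.

    Records are pooled per (chrom, pos, ref, alt) site. A site survives iff
    every rule of the chosen regime holds; see the module docstring for the
    rules. Returns a candidate table sorted by (chrom, pos) with
    per-site supporting-accession counts (accessions with at least one
    alternate-supporting read) and the detection-panel MAF computed from
    allele-presence genotypes. ``counts_out``, if given, receives the number
    of sites removed by each rule (applied in sequence).
    """
    df = _concat_calls(calls)
    if len(df) == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    df = df.copy()
    if genome is not None:
        for c in df["chrom"].unique():
            if c not in genome:
                raise CoordinateError(f"unknown chromosome {c!r} in call table")
    df["depth"] = df["ref_depth"] + df["alt_depth"]

    key = ["chrom", "pos", "ref", "alt"]
    grouped = df.groupby(key, sort=True)
    site = grouped.agg(
        total_reads=("depth", "sum"),
        total_ref=("ref_depth", "sum"),
        total_alt=("alt_depth", "sum"),
        qual=("qual", "max"),
        allele_max=("depth", "max"),  # placeholder, refined below
    ).reset_index()
    # max read count for either allele in any single accession
    per_rec_allele_max = df[["ref_depth", "alt_depth"]].max(axis=1)
    site["allele_max"] = (
        df.assign(_am=per_rec_allele_max).groupby(key)["_am"].max().to_numpy()
    )

    counts = {} if counts_out is None else counts_out
    keep = np.ones(len(site), dtype=bool)

    def apply_rule(name: str, ok: np.ndarray) -> None:
        removed = int((keep & ~ok).sum())
        counts[name] = removed
        np.logical_and(keep, ok, out=keep)

    # rule 1: caller quality
    if params.q_inclusive:
        apply_rule("quality", site["qual"].to_numpy() >= params.q_min)
    else:
        apply_rule("quality", site["qual"].to_numpy() > params.q_min)

    # rule 2: coverage band
    totals = site["total_reads"].to_numpy(dtype=float)
    apply_rule("min_coverage", totals >= params.cov_min)
    if params.cov_max_rule == "multiple_of_mean":
        cov_max = params.cov_max_factor * totals.mean()
        apply_rule("max_coverage", totals <= cov_max)
    elif params.cov_max_rule == "mean_plus_sd":
        cov_max = totals.mean() + params.cov_max_k * totals.std(ddof=0)
        apply_rule("max_coverage", site["allele_max"].to_numpy() < cov_max)
    else:
        raise InvalidConfigError(f"unknown cov_max_rule {params.cov_max_rule!r}")

    # rule 3: minor-allele read support
    minor_reads = np.minimum(site["total_ref"], site["total_alt"]).to_numpy()
    apply_rule("minor_allele_reads", minor_reads >= params.minor_allele_min_reads)

    # rule 4: repetitiveness
    if params.regime == "A":
        if repeats is not None:
            in_rep = _in_intervals(
                site["chrom"].to_numpy(), site["pos"].to_numpy(), repeats
            )
            apply_rule("repeat_region", ~in_rep)
    else:
        if genome is None:
            raise InvalidConfigError("regime B needs the genome for copy number")
        if kmer_index is None:
            kmer_index = KmerIndex(genome, params.kmer_k)
        cn = np.array(
            [
                estimate_copy_number(
                    genome, c, int(p), params.flank_bp, params.kmer_k, kmer_index
                )
                if k_
                else np.nan
                for c, p, k_ in zip(site["chrom"], site["pos"], keep)
            ]
        )
        # NaN copy number (all-N window) fails conservatively
        apply_rule("copy_number", keep & (cn < params.copy_number_max))

    surv = site[keep].copy()
    if len(surv) == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    # supporting accessions and detection MAF from allele-presence genotypes
    df_alt = df[df["alt_depth"] > 0]
    support = (
        df_alt.groupby(key)["accession"].agg(lambda a: tuple(sorted(set(a))))
    )
    surv_keys = list(zip(surv["chrom"], surv["pos"], surv["ref"], surv["alt"]))
    surv["support_accessions"] = [support.get(kk, ()) for kk in surv_keys]
    surv["n_support"] = [len(s) for s in surv["support_accessions"]]

    dosage = df.assign(
        _d=np.select(
            [(df["ref_depth"] > 0) & (df["alt_depth"] > 0), df["alt_depth"] > 0],
            [1, 2],
            default=0,
        )
    ).groupby(key)["_d"].agg(["sum", "count"])
    p_alt = dosage["sum"] / (2 * dosage["count"])
    maf = np.minimum(p_alt, 1 - p_alt)
    surv["maf"] = [maf.get(kk, np.nan) for kk in surv_keys]

    surv["source"] = f"regime{params.regime}"
    surv["id"] = surv["chrom"] + "_" + surv["pos"].astype(str)
    surv = surv.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return surv[CANDIDATE_COLUMNS]


def genotype_from_calls(table: pd.DataFrame) -> dict[tuple[str, int], frozenset[str]]:
    """Allele-presence genotype at each covered position: the set of alleles
    with at least one supporting read (low coverage precludes confident
    diploid calls)."""
    geno: dict[tuple[str, int], set[str]] = {}
    for row in table.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        alleles = geno.setdefault(key, set())
        if row.ref_depth > 0:
            alleles.add(row.ref)
        if row.alt_depth > 0:
            alleles.add(row.alt)
    return {k: frozenset(v) for k, v in geno.items() if v}


def compare_callsets(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    candidate_positions: Iterable[tuple[str, int]],
) -> ConcordanceReport:
    """Classify candidate positions by agreement between two call sets of the
    same accession: not comparable (no coverage in at least one set), or
    comparable with identical / partially shared / disjoint allele sets."""
    ga = genotype_from_calls(calls_a)
    gb = genotype_from_calls(calls_b)
    positions = list(candidate_positions)
    n_nc = n_id = n_part = n_none = 0
    for key in positions:
        key = (key[0], int(key[1]))
        if key not in ga or key not in gb:
            n_nc += 1
            continue
        a, b = ga[key], gb[key]
        if a == b:
            n_id += 1
        elif a & b:
            n_part += 1
        else:
            n_none += 1
    return ConcordanceReport(
        n_candidates=len(positions),
        n_not_covered=n_nc,
        n_comparable=n_id + n_part + n_none,
        n_identical=n_id,
        n_partial=n_part,
        n_no_share=n_none,
    )
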