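"""Array-evaluation statistics.

Takes GenomeStudio-style genotype reports (calls in {AA, AB, BB, NC} with
per-SNP GenTrain and GenCall-10% cluster-quality scores) and computes the
quality-control partition, minor-allele-frequency spectra, polymorphism
classification, physical gap statistics, panel comparisons, validation
cross-tabulations, progeny informativeness and sequencing-coverage
accounting that together characterise a genotyping array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import InvalidConfigError
from .utils import round_half_up

CALL_STATES = ("AA", "AB", "BB", "NC")


class QCInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls plus per-SNP cluster-quality scores.

    ``calls`` values are ``AA``/``AB``/``BB``/``NC`` (no-call); ``snp_scores``
    has columns ``gentrain`` and ``gencall10`` indexed by SNP id; ``samples``
    carries per-sample metadata (panel, species group, progeny id, ...).
    """

    calls: pd.DataFrame
    snp_scores: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CALL_STATES)
        if len(self.calls.columns) and bad:
            raise InvalidConfigError(f"unknown call states {sorted(bad)}")
        missing = set(self.calls.columns) - set(self.snp_scores.index)
        if missing:
            raise QCInputError(f"{len(missing)} SNPs without cluster scores")
        for col in ("gentrain", "gencall10"):
            s = self.snp_scores[col]
            if len(s) and ((s < 0) | (s > 1)).any():
                raise QCInputError(f"{col} score outside [0, 1]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def nocall_fraction(self) -> pd.Series:
        if len(self.calls) == 0:
            return pd.Series(dtype=float)
        return (self.calls == "NC").mean(axis=0)


@dataclass
class SNPClassification:
    """Per-SNP outcome partition (failed / monomorphic / polymorphic) with
    MAF and its binned views."""

    table: pd.DataFrame  # index snp; columns: outcome, maf

    @property
    def counts(self) -> dict[str, int]:
        vc = self.table["outcome"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("failed", "monomorphic", "polymorphic")}

    @property
    def proportions(self) -> dict[str, float]:
        n = len(self.table)
        return {k: round_half_up(v / n, 2) if n else math.nan
                for k, v in self.counts.items()}

    def polymorphic_ids(self) -> set[str]:
        return set(self.table.index[self.table["outcome"] == "polymorphic"])

    def maf_bins(self) -> dict[str, int]:
        """Counts of polymorphic SNPs with MAF <5%, 5-10%, >10%."""
        maf = self.table.loc[self.table["outcome"] == "polymorphic", "maf"]
        return {
            "<5%": int((maf < 0.05).sum()),
            "5-10%": int(((maf >= 0.05) & (maf <= 0.10)).sum()),
            ">10%": int((maf > 0.10).sum()),
        }

    def maf_over(self, threshold: float) -> float:
        """Fraction of polymorphic SNPs with MAF above ``threshold``."""
        maf = self.table.loc[self.table["outcome"] == "polymorphic", "maf"]
        if len(maf) == 0:
            return math.nan
        return float((maf > threshold).mean())


def qc_genotypes(
    matrix: GenotypeMatrix,
    gentrain_min: float = 0.4,
    gencall10_min: float = 0.2,
    max_nocall_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Partition SNPs into (passed, failed).

    A SNP fails iff GenTrain <= ``gentrain_min`` or GenCall-10% <=
    ``gencall10_min`` (the keep rules are strict >) or it is no-call in more
    than ``max_nocall_fraction`` of samples.
    """
    scores = matrix.snp_scores
    nc = matrix.nocall_fraction()
    passed, failed = [], []
    for snp in matrix.snp_ids:
        if snp not in scores.index or pd.isna(scores.loc[snp, "gentrain"]):
            raise QCInputError(f"missing scores for {snp}")
        ok = (
            scores.loc[snp, "gentrain"] > gentrain_min
            and scores.loc[snp, "gencall10"] > gencall10_min
            and nc.get(snp, 0.0) <= max_nocall_fraction
        )
        (passed if ok else failed).append(snp)
    return passed, failed


def compute_maf(calls: Sequence[str] | pd.Series) -> float:
    """Minor allele frequency from diploid calls: with p the B-allele
    fraction over called samples, MAF = min(p, 1-p). All-NC input is
    undefined (NaN); such a SNP must already have failed QC."""
    arr = np.asarray(calls)
    called = arr[arr != "NC"]
    if len(called) == 0:
        return math.nan
    n_b = 2 * (called == "BB").sum() + (called == "AB").sum()
    p = n_b / (2 * len(called))
    return float(min(p, 1 - p))


def classify_snps(
    matrix: GenotypeMatrix,
    gentrain_min: float = 0.4,
    gencall10_min: float = 0.2,
    max_nocall_fraction: float = 0.5,
) -> SNPClassification:
    """QC partition plus polymorphism classification: failed (QC), passed
    and MAF 0 (monomorphic), passed and MAF > 0 (polymorphic)."""
    passed, failed = qc_genotypes(
        matrix, gentrain_min, gencall10_min, max_nocall_fraction
    )
    rows = {}
    for snp in matrix.snp_ids:
        if snp in set(failed):
            rows[snp] = ("failed", math.nan)
        else:
            maf = compute_maf(matrix.calls[snp])
            rows[snp] = ("polymorphic" if maf > 0 else "monomorphic", maf)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["outcome", "maf"])
    return SNPClassification(table)


def polymorphism_rate(n_polymorphic: int, n_on_array: int) -> float:
    """Percentage of array SNPs found polymorphic, 1 dp, half-up."""
    if n_on_array <= 0:
        raise InvalidConfigError("n_on_array must be > 0")
    return round_half_up(100.0 * n_polymorphic / n_on_array, 1)


@dataclass
class GapStats:
    """Physical spacing of array SNPs: per-chromosome and genome-wide gap
    summaries (gap = distance between successive SNPs on a chromosome)."""

    per_chromosome: pd.DataFrame  # n_snps, n_gaps, avg_gap_kb, largest_gap_kb, n_gaps_over
    total: dict


def gap_statistics(
    positions_by_chrom: Mapping[str, Sequence[int]],
    threshold_kb: float = 150.0,
) -> GapStats:
    """Gap summaries of a design. Chromosomes with fewer than two SNPs have
    no gaps and report NaN averages. The distance from the chromosome start
    to the first SNP is not a gap."""
    rows = {}
    all_gaps = []
    for chrom, pos in positions_by_chrom.items():
        p = np.sort(np.asarray(pos))
        if len(p) != len(np.unique(p)):
            raise InvalidConfigError(f"duplicate positions on {chrom}")
        gaps = np.diff(p) / 1000.0  # kb
        all_gaps.append(gaps)
        rows[chrom] = {
            "n_snps": len(p),
            "n_gaps": len(gaps),
            "avg_gap_kb": float(gaps.mean()) if len(gaps) else math.nan,
            "largest_gap_kb": float(gaps.max()) if len(gaps) else math.nan,
            "n_gaps_over": int((gaps > threshold_kb).sum()),
        }
    per = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    flat = np.concatenate(all_gaps) if all_gaps else np.array([])
    total = {
        "n_snps": int(per["n_snps"].sum()) if len(per) else 0,
        "n_gaps": len(flat),
        "avg_gap_kb": float(flat.mean()) if len(flat) else math.nan,
        "largest_gap_kb": float(flat.max()) if len(flat) else math.nan,
        "n_gaps_over": int((flat > threshold_kb).sum()),
    }
    return GapStats(per_chromosome=per, total=total)


@dataclass
class PanelComparison:
    n_shared: int
    n_only_a: int
    n_only_b: int

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_only_a + self.n_only_b

    @property
    def shared_fraction_pct(self) -> float:
        """Shared polymorphic SNPs as a percentage of the union, 1 dp."""
        if self.n_union == 0:
            return math.nan
        return round_half_up(100.0 * self.n_shared / self.n_union, 1)


def compare_panels(
    class_a: SNPClassification | set[str],
    class_b: SNPClassification | set[str],
) -> PanelComparison:
    """Shared and panel-specific polymorphic SNPs between two evaluation
    panels genotyped on the same array."""
    if isinstance(class_a, SNPClassification) and isinstance(class_b, SNPClassification):
        if set(class_a.table.index) != set(class_b.table.index):
            raise InvalidConfigError("panels classified over different SNP sets")
        a, b = class_a.polymorphic_ids(), class_b.polymorphic_ids()
    else:
        a = class_a.polymorphic_ids() if isinstance(class_a, SNPClassification) else set(class_a)
        b = class_b.polymorphic_ids() if isinstance(class_b, SNPClassification) else set(class_b)
    return PanelComparison(
        n_shared=len(a & b), n_only_a=len(a - b), n_only_b=len(b - a)
    )


def crosstab_validation(
    snps: pd.DataFrame,
    categories: Sequence[str],
    outcome_col: str = "outcome",
    maf_col: str = "maf",
) -> pd.DataFrame:
    """Validation cross-tabulation: for each value of each category column,
    the SNP count and the proportions (2 dp) failed / monomorphic /
    polymorphic, plus the polymorphic MAF bins <5% / 5-10% / >10%.

    Every SNP must carry an outcome; ``maf`` is used only for polymorphic
    SNPs. Rows' MAF-bin proportions sum to the polymorphic proportion up to
    rounding.
    """
    if snps[outcome_col].isna().any():
        raise InvalidConfigError("SNP without outcome label")
    rows = []
    for cat in categories:
        if snps[cat].isna().any():
            raise InvalidConfigError(f"SNP without label in category {cat!r}")
        for value, g in snps.groupby(cat, sort=False):
            n = len(g)
            poly = g[g[outcome_col] == "polymorphic"]
            maf = poly[maf_col]
            rows.append(
                {
                    "parameter": cat,
                    "value": value,
                    "total": n,
                    "failed": round_half_up((g[outcome_col] == "failed").sum() / n, 2),
                    "monomorphic": round_half_up(
                        (g[outcome_col] == "monomorphic").sum() / n, 2
                    ),
                    "polymorphic": round_half_up(len(poly) / n, 2),
                    "maf_lt5": round_half_up((maf < 0.05).sum() / n, 2),
                    "maf_5_10": round_half_up(
                        ((maf >= 0.05) & (maf <= 0.10)).sum() / n, 2
                    ),
                    "maf_gt10": round_half_up((maf > 0.10).sum() / n, 2),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProgenySummary:
    per_progeny: dict[str, float]      # fraction of polymorphic SNPs segregating
    any_progeny_fraction: float        # fraction segregating in >= 1 progeny
    distribution: dict[int, int]       # n progenies -> n SNPs

    @property
    def any_progeny_pct(self) -> float:
        return round_half_up(100.0 * self.any_progeny_fraction, 0)


def progeny_informativeness(flags: pd.DataFrame) -> ProgenySummary:
    """Informativeness of polymorphic SNPs in breeding progenies.

    ``flags`` is SNPs x progenies boolean (does the SNP segregate in that
    progeny). Reports per-progeny segregating fractions, the fraction
    segregating in at least one progeny, and the distribution of SNPs by
    the number of progenies they segregate in.
    """
    n = len(flags)
    if n == 0:
        return ProgenySummary({}, math.nan, {})
    per = {c: float(flags[c].mean()) for c in flags.columns}
    counts = flags.sum(axis=1)
    dist = counts.value_counts().to_dict()
    return ProgenySummary(
        per_progeny=per,
        any_progeny_fraction=float((counts >= 1).mean()),
        distribution={int(k): int(v) for k, v in sorted(dist.items())},
    )


def coverage_accounting(
    records: pd.DataFrame,
    genome_size: float,
    min_reads_million: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sequencing-coverage bookkeeping for a detection panel.

    ``records`` needs columns ``accession``, ``pool``, ``platform``,
    ``read_count_million`` and ``read_length``; per-row coverage is
    read count x read length / genome size. Aggregates report the summed
    panel coverage, per-pool sums, and per-platform means; rows with fewer
    than ``min_reads_million`` reads are excluded from the platform means
    (flagged low-yield runs), never from the sums.
    """
    if genome_size <= 0:
        raise InvalidConfigError("genome_size must be > 0")
    if (records["read_count_million"] < 0).any() or (records["read_length"] <= 0).any():
        raise InvalidConfigError("read counts must be >= 0 and lengths > 0")
    out = records.copy()
    out["coverage"] = (
        out["read_count_million"] * 1e6 * out["read_length"] / genome_size
    ).round(2)
    in_mean = (
        out["read_count_million"] >= min_reads_million
        if min_reads_million is not None
        else pd.Series(True, index=out.index)
    )
    agg = {
        "total_coverage": round_half_up(out["coverage"].sum(), 1),
        "total_reads_million": round_half_up(out["read_count_million"].sum(), 1),
        "per_pool_coverage": out.groupby("pool")["coverage"].sum().to_dict(),
        "platform_mean_coverage": {
            plat: round_half_up(g["coverage"].mean(), 2)
            for plat, g in out[in_mean].groupby("platform")
        },
        "n_excluded_from_means": int((~in_mean).sum()),
    }
    return out, agg


def maf_concordance(maf_a: pd.Series, maf_b: pd.Series) -> float:
    """Pearson correlation of per-SNP MAF between two sample groups over
    their shared polymorphic SNPs. Needs >= 3 shared SNPs; a constant
    vector has no defined correlation and returns NaN."""
    shared = maf_a.dropna().index.intersection(maf_b.dropna().index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared SNPs; need at least 3"
        )
    a = maf_a.loc[shared].to_numpy(dtype=float)
    b = maf_b.loc[shared].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(stats.pearsonr(a, b).statistic)


def maf_histogram(
    classification: SNPClassification, bin_width: float = 0.05
) -> pd.DataFrame:
    """Figure-ready MAF spectrum: counts of polymorphic SNPs per MAF bin."""
    maf = classification.table.loc[
        classification.table["outcome"] == "polymorphic", "maf"
    ]
    edges = np.arange(0, 0.5 + bin_width, bin_width)
    counts, _ = np.histogram(maf, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
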