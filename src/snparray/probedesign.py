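"""Infinium assay candidacy screening.

An Infinium II assay interrogates a SNP with a single 50-bp probe ending
immediately next to the variant base and distinguishes the two alleles by
colour channel; that only works when the alleles differ in colour, which
excludes A/T and C/G transversions (type I SNPs, which need two bead types
and cost two array slots). The screens here classify allele types, extract
probe context from the genome, check the probe tail (the 25 bases adjacent
to the SNP) for genome-wide uniqueness, filter on design scores, and merge
candidate sets from multiple detection pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CoordinateError, GenomeAssembly, InvalidConfigError
from .kmers import KmerIndex

TYPE_I_PAIRS = (frozenset("AT"), frozenset("CG"))


class InvalidAlleleError(ValueError):
    pass


class InvalidScoreError(ValueError):
    pass


@dataclass(frozen=True)
class ProbeCandidate:
    """Probe context of one SNP: 50 bp on each side, assay type, tail flag."""

    chrom: str
    pos: int
    ref: str
    alt: str
    upstream: str
    downstream: str
    infinium_type: str
    truncated: bool = False
    tail_duplicated: bool | None = None
    design_score: float | None = None


def classify_infinium(ref: str, alt: str) -> str:
    """Assay type of an allele pair: ``"I"`` for A/T and C/G transversions,
    ``"II"`` for the other four unordered pairs. Symmetric in allele order."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise InvalidAlleleError(f"non-ACGT allele in ({ref!r}, {alt!r})")
    if ref == alt:
        raise InvalidAlleleError(f"identical alleles {ref!r}")
    return "I" if frozenset((ref, alt)) in TYPE_I_PAIRS else "II"


def extract_probe_context(
    genome: GenomeAssembly, chrom: str, pos: int, flank: int = 50
) -> tuple[str, str, bool]:
    """Flanking probe sequences of a SNP: (upstream ``[pos-flank, pos-1]``,
    downstream ``[pos+1, pos+flank]``, truncated?). Near a chromosome end
    the short side is returned as-is and the truncated flag is set."""
    chrom_obj = genome.chromosome(chrom)
    if not 1 <= pos <= chrom_obj.length:
        raise CoordinateError(f"position {pos} outside {chrom}")
    upstream = genome.subsequence(chrom, pos - flank, pos - 1)
    downstream = genome.subsequence(chrom, pos + 1, pos + flank)
    truncated = len(upstream) < flank or len(downstream) < flank
    return upstream, downstream, truncated


def probe_tail_duplicated(
    index: KmerIndex,
    upstream: str,
    downstream: str,
    tail: int = 25,
) -> bool:
    """Whether the probe tail (the ``tail`` bases immediately adjacent to the
    SNP, on either side) occurs more than once in the genome.

    Both possible probe orientations are checked: the last ``tail`` bases of
    the upstream flank and the first ``tail`` bases of the downstream flank.
    With a canonical index, reverse-complement copies count as duplicates.
    A flank shorter than ``tail`` on both sides cannot be assessed and is
    flagged duplicated (conservative exclusion).
    """
    if index.k != tail:
        raise InvalidConfigError(f"index k={index.k} does not match tail={tail}")
    tails = []
    if len(upstream) >= tail:
        tails.append(upstream[-tail:])
    if len(downstream) >= tail:
        tails.append(downstream[:tail])
    if not tails:
        return True
    return any(index.count(t) > 1 for t in tails)


def apply_score_filter(
    candidates: pd.DataFrame,
    threshold: float,
    score_col: str = "design_score",
    failure_col: str = "failure_code",
) -> pd.DataFrame:
    """Keep candidates with design score >= threshold and no failure code.

    This implements the removal rule "score below threshold or any failure
    code"; a candidate exactly at the threshold is retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidScoreError(f"threshold {threshold} outside [0, 1]")
    if len(candidates) == 0:
        return candidates.copy()
    scores = candidates[score_col]
    if scores.isna().any():
        raise InvalidScoreError("candidate without a design score")
    if ((scores < 0) | (scores > 1)).any():
        raise InvalidScoreError("design score outside [0, 1]")
    keep = scores >= threshold
    if failure_col in candidates.columns:
        fc = candidates[failure_col]
        keep &= fc.isna() | (fc.astype(str).str.len() == 0) | (fc.astype(str) == "nan")
    return candidates[keep].reset_index(drop=True)


def _allele_key(ref: pd.Series, alt: pd.Series) -> pd.Series:
    r = ref.to_numpy(dtype=str)
    a = alt.to_numpy(dtype=str)
    lo = np.where(r <= a, r, a)
    hi = np.where(r <= a, a, r)
    return pd.Series(np.char.add(lo, hi), index=ref.index)


def merge_dedup(
    sources: list[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge candidate sets from several detection pipelines.

    Candidates identical in (chrom, pos, unordered allele pair) collapse to
    one record keeping the union of supporting accessions (or the maximum
    support count when accession identities are unavailable) and the joined
    source tags. Same-position records with *different* allele pairs are a
    conflict: all records at that position are excluded and returned
    separately.

    Returns ``(merged, conflicts)``, merged sorted by (chrom, pos).
    """
    frames = [s for s in sources if len(s)]
    if not frames:
        empty = (sources[0].iloc[0:0].copy() if sources
                 else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]))
        return empty, empty.copy()
    df = pd.concat(frames, ignore_index=True)
    df["_alleles"] = _allele_key(df["ref"], df["alt"])

    # positions carrying more than one distinct allele pair are conflicts
    n_pairs = df.groupby(["chrom", "pos"])["_alleles"].transform("nunique")
    conflicts = df[n_pairs > 1].drop(columns="_alleles").reset_index(drop=True)
    df = df[n_pairs == 1]
    if len(df) == 0:
        return df.drop(columns="_alleles").reset_index(drop=True), conflicts

    def _merge_group(g: pd.DataFrame) -> pd.Series:
        rec = g.iloc[0].copy()
        if "support_accessions" in g.columns:
            accs = sorted(set().union(*[set(a) for a in g["support_accessions"]]))
            rec["support_accessions"] = tuple(accs)
            if "n_support" in g.columns:
                rec["n_support"] = len(accs)
        elif "n_support" in g.columns:
            rec["n_support"] = g["n_support"].max()
        if "source" in g.columns:
            rec["source"] = "+".join(sorted(set(g["source"])))
        return rec

    dup_mask = df.duplicated(["chrom", "pos", "_alleles"], keep=False)
    unique_part = df[~dup_mask]
    merged_parts = [unique_part]
    if dup_mask.any():
        collapsed = [
            _merge_group(g)
            for _, g in df[dup_mask].groupby(["chrom", "pos", "_alleles"], sort=False)
        ]
        merged_parts.append(pd.DataFrame(collapsed))
    merged = pd.concat(merged_parts, ignore_index=True)
    merged = (
        merged.drop(columns="_alleles")
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return merged, conflicts


def annotate_candidates(
    candidates: pd.DataFrame,
    genome: GenomeAssembly,
    annotation=None,
    tail_index: KmerIndex | None = None,
    tail: int = 25,
) -> pd.DataFrame:
    """Attach the design-stage attributes the Stage-2 filter needs:
    ``infinium_type``, ``genic_class``, ``on_pseudomolecule``,
    ``tail_duplicated`` and probe sequences."""
    out = candidates.copy()
    if len(out) == 0:
        for c in ("infinium_type", "genic_class", "on_pseudomolecule",
                  "tail_duplicated", "probe_up", "probe_down"):
            out[c] = pd.Series(dtype=object)
        return out
    if tail_index is None:
        tail_index = KmerIndex(genome, tail)
    ups, downs, types, tails_dup = [], [], [], []
    for row in out.itertuples(index=False):
        up, down, _trunc = extract_probe_context(genome, row.chrom, int(row.pos))
        ups.append(up)
        downs.append(down)
        types.append(classify_infinium(row.ref, row.alt))
        tails_dup.append(probe_tail_duplicated(tail_index, up, down, tail))
    out["probe_up"] = ups
    out["probe_down"] = downs
    out["infinium_type"] = types
    out["tail_duplicated"] = tails_dup
    out["on_pseudomolecule"] = [
        genome.is_pseudomolecule(c) for c in out["chrom"]
    ]
    if annotation is not None:
        out["genic_class"] = [
            annotation.classify(c, int(p)) for c, p in zip(out["chrom"], out["pos"])
        ]
    return out


def remove_infinium_i(candidates: pd.DataFrame) -> pd.DataFrame:
    """Drop type-I (A/T, C/G) candidates; they cost two bead types."""
    if len(candidates) == 0:
        return candidates.copy()
    types = candidates.get("infinium_type")
    if types is None:
        types = [classify_infinium(r, a)
                 for r, a in zip(candidates["ref"], candidates["alt"])]
        types = pd.Series(types, index=candidates.index)
    return candidates[types == "II"].reset_index(drop=True)
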