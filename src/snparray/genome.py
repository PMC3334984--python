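"""Genome assemblies and gene annotations.

Coordinates are 1-based inclusive throughout the package (the VCF/GFF3
convention); BED input is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from intervaltree import IntervalTree

GENIC_CLASSES = ("exonic", "intronic", "utr", "intergenic")


class InvalidConfigError(ValueError):
    """Raised when a configuration or constructor argument is out of range."""


class CoordinateError(ValueError):
    """Raised when a position or interval falls outside its chromosome."""


@dataclass(frozen=True)
class Chromosome:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InvalidConfigError(f"chromosome {self.id!r} has zero length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """A set of chromosome-scale pseudomolecules plus unanchored scaffolds.

    ``chromosomes`` are the sequences candidate SNPs must lie on to pass the
    pseudomolecule restriction; ``unanchored`` scaffolds carry sequence but
    are flagged off-pseudomolecule.
    """

    chromosomes: list[Chromosome]
    unanchored: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes] + [c.id for c in self.unanchored]
        if len(ids) != len(set(ids)):
            raise InvalidConfigError("duplicate chromosome ids in assembly")
        self._by_id = {c.id: c for c in self.chromosomes}
        self._by_id.update({c.id: c for c in self.unanchored})
        self._pseudo = {c.id for c in self.chromosomes}

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self._by_id

    def __iter__(self) -> Iterator[Chromosome]:
        yield from self.chromosomes
        yield from self.unanchored

    def chromosome(self, chrom_id: str) -> Chromosome:
        try:
            return self._by_id[chrom_id]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom_id!r}") from None

    def is_pseudomolecule(self, chrom_id: str) -> bool:
        self.chromosome(chrom_id)
        return chrom_id in self._pseudo

    def base(self, chrom_id: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        chrom = self.chromosome(chrom_id)
        if not 1 <= pos <= chrom.length:
            raise CoordinateError(
                f"position {pos} outside {chrom_id} (length {chrom.length})"
            )
        return chrom.sequence[pos - 1]

    def subsequence(self, chrom_id: str, start: int, end: int) -> str:
        """1-based inclusive slice, clipped at chromosome ends."""
        chrom = self.chromosome(chrom_id)
        start = max(1, start)
        end = min(chrom.length, end)
        if start > end:
            return ""
        return chrom.sequence[start - 1 : end]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)


@dataclass(frozen=True)
class Gene:
    """A gene model: exons are CDS segments; UTR intervals flank the CDS
    (within the gene span, near the start/stop codons); everything else
    inside the span is intronic."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidConfigError(f"gene {self.id}: start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise InvalidConfigError(f"gene {self.id}: exon outside gene span")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise InvalidConfigError(f"gene {self.id}: overlapping exons")


class GeneAnnotation:
    """Position classifier over a set of gene models.

    Every genomic position maps to exactly one of ``exonic``, ``utr``,
    ``intronic`` or ``intergenic``; where intervals overlap, the precedence
    exonic > utr > intronic resolves the class.
    """

    def __init__(self, genes: list[Gene]):
        self.genes = list(genes)
        self._exons: dict[str, IntervalTree] = {}
        self._utrs: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for g in self.genes:
            # IntervalTree is half-open on integers; store [start, end+1)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1)
            for s, e in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)
            for s, e in g.utrs:
                self._utrs.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)

    def classify(self, chrom: str, pos: int) -> str:
        if chrom in self._exons and self._exons[chrom].overlaps_point(pos):
            return "exonic"
        if chrom in self._utrs and self._utrs[chrom].overlaps_point(pos):
            return "utr"
        if chrom in self._spans and self._spans[chrom].overlaps_point(pos):
            return "intronic"
        return "intergenic"

    def __len__(self) -> int:
        return len(self.genes)
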