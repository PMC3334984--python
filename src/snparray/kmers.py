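"""Canonical k-mer counting for copy-number and probe-uniqueness screens.

A k-mer and its reverse complement are collapsed to the lexicographically
smaller of the two (the canonical form), so a duplication on the opposite
strand is counted the same as one on the forward strand. Counting the
reverse complement can be switched off to emulate a strand-naive screen.
"""

from __future__ import annotations

from collections import Counter

from .genome import GenomeAssembly

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Occurrence counts of every k-mer of a genome (both strands by default).

    k-mers containing N are not indexed. Build once per genome and share
    between the copy-number filter (k=31) and the probe-tail screen (k=25).
    """

    def __init__(self, genome: GenomeAssembly, k: int, count_revcomp: bool = True):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.count_revcomp = count_revcomp
        counts: Counter[str] = Counter()
        for chrom in genome:
            seq = chrom.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                counts[canonical(kmer) if count_revcomp else kmer] += 1
        self._counts = counts

    def count(self, kmer: str) -> int:
        """Genome-wide occurrence count of ``kmer`` (0 if absent or len != k)."""
        if len(kmer) != self.k or "N" in kmer:
            return 0
        key = canonical(kmer) if self.count_revcomp else kmer
        return self._counts.get(key, 0)

    def window_mean_count(self, seq: str) -> float:
        """Mean occurrence count over all k-mers of ``seq``; NaN if none valid."""
        n, total = 0, 0
        for i in range(len(seq) - self.k + 1):
            kmer = seq[i : i + self.k]
            if "N" in kmer:
                continue
            total += self.count(kmer)
            n += 1
        if n == 0:
            return float("nan")
        return total / n
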