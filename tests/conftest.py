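import numpy as np
import pandas as pd
import pytest

from snparray import simdata
from snparray.genome import Chromosome, Gene, GeneAnnotation, GenomeAssembly


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=11,
        n_chromosomes=2,
        chromosome_length=100_000,
        n_unanchored=1,
        unanchored_length=20_000,
        n_snps=300,
        n_accessions=12,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome, annotation, repeats, panel and call tables at toy scale."""
    genome, annotation, repeats = simdata.simulate_genome(small_config)
    panel = simdata.simulate_panel(genome, annotation, small_config)
    calls = simdata.simulate_callsets(panel, small_config)
    return genome, annotation, repeats, panel, calls


@pytest.fixture()
def toy_genome() -> GenomeAssembly:
    """Hand-built 2-chromosome genome with one exact duplicated block:
    chr A positions 101-160 equal chr B positions 41-100."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    seq_a = "".join(bases[rng.integers(0, 4, 300)])
    seq_b = "".join(bases[rng.integers(0, 4, 200)])
    block = seq_a[100:160]
    seq_b = seq_b[:40] + block + seq_b[100:]
    return GenomeAssembly(
        chromosomes=[Chromosome("chrA", seq_a), Chromosome("chrB", seq_b)]
    )


@pytest.fixture()
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(
        [
            Gene(
                id="g1",
                chrom="chrA",
                strand="+",
                start=10,
                end=120,
                exons=((30, 60), (80, 100)),
                utrs=((10, 29), (101, 120)),
            )
        ]
    )


def make_calls(rows: list[tuple]) -> pd.DataFrame:
    """Call-table helper: rows of
    (accession, chrom, pos, ref, alt, ref_depth, alt_depth, qual)."""
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "chrom", "pos", "ref", "alt",
            "ref_depth", "alt_depth", "qual",
        ],
    )
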