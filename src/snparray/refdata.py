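"""Published summary tables of the peach 9K array study, shipped as inputs.

These are the printed inputs of the study this pipeline generalises: the
56-accession detection panel with per-accession read counts (Illumina-style
short reads in pools 1-11, 454-style long reads in pool 12), the
per-chromosome Stage-2/array/polymorphic SNP counts of the released array,
the 96-SNP GoldenGate validation outcomes by genic class, the
breeding-progeny segregation distribution of the 55 panel-polymorphic
validation SNPs, and the scalar counts of the design funnel. All derived
quantities (coverages, rates, proportions) are recomputed by the package,
never read from here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("snparray.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def detection_panel() -> pd.DataFrame:
    """Per-accession sequencing yields: pool, accession, platform,
    read_length (bp), read_count_million, and the published coverage."""
    return _read("detection_panel.tsv")


def array_chromosome_summary() -> pd.DataFrame:
    """Per-chromosome Stage-2, on-array and polymorphic SNP counts of the
    released array (plus the unanchored-scaffold row)."""
    return _read("array_chromosome_summary.tsv")


def validation_outcomes() -> pd.DataFrame:
    """GoldenGate validation outcome counts of the 96-SNP subset by genic
    class (failed / monomorphic / polymorphic)."""
    return _read("validation_outcomes.tsv")


def progeny_distribution() -> pd.DataFrame:
    """Distribution of the 55 panel-polymorphic validation SNPs by the
    number of six-seedling breeding progenies they segregate in (0-5)."""
    return _read("progeny_distribution.tsv")


def design_funnel() -> dict[str, int]:
    """Scalar counts of the design funnel (Stage-1 totals per pool group,
    Stage-2 cascade counts, slot budget, pinned SNPs, manufacturing dropout,
    and the evaluation-panel polymorphic overlap counts)."""
    df = _read("design_funnel.tsv")
    return dict(zip(df["key"], df["value"].astype(int)))
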