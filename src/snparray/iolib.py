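"""Readers and writers for the standard formats the pipeline touches.

Conventions: coordinates are 1-based inclusive internally (VCF/GFF3 style);
BED is 0-based half-open and converted at this boundary. All writers are
atomic (temp file + rename), so a crashed run never leaves a truncated
manifest behind.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detection import CALL_COLUMNS
from .evaluate import GenotypeMatrix
from .genome import Chromosome, Gene, GeneAnnotation, GenomeAssembly


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a temporary file in the target directory and rename on
    success; on error the target is left untouched."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- FASTA --------------------------------------------------------------

def write_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in genome
    ]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(
    path: str | Path, pseudomolecule_prefix: str = "Pp"
) -> GenomeAssembly:
    """Sequences whose id starts with ``pseudomolecule_prefix`` become
    chromosomes; the rest are unanchored scaffolds."""
    chroms, unanchored = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        target = chroms if rec.id.startswith(pseudomolecule_prefix) else unanchored
        target.append(Chromosome(rec.id, str(rec.seq).upper()))
    return GenomeAssembly(chromosomes=chroms, unanchored=unanchored)


# -- GFF3 ---------------------------------------------------------------

def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tsnparray\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\tsnparray\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.id}.cds{i};Parent={g.id}\n"
                )
            for i, (s, e) in enumerate(sorted(g.utrs), 1):
                fh.write(
                    f"{g.chrom}\tsnparray\tUTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.utr{i};Parent={g.id}\n"
                )


def read_gff3(path: str | Path) -> GeneAnnotation:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ParseError(f"{path}: malformed GFF3 record at line {lineno}")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gf in db.features_of_type("gene"):
        exons = tuple(
            (f.start, f.end) for f in db.children(gf, featuretype="CDS", order_by="start")
        )
        utrs = tuple(
            (f.start, f.end) for f in db.children(gf, featuretype="UTR", order_by="start")
        )
        genes.append(
            Gene(
                id=gf.id, chrom=gf.seqid, strand=gf.strand,
                start=gf.start, end=gf.end, exons=exons, utrs=utrs,
            )
        )
    return GeneAnnotation(genes)


# -- BED ----------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """0-based half-open BED intervals to 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: malformed BED record at line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer BED coordinate at line {lineno}"
                ) from None
            out.append((fields[0], start + 1, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for chrom, start1, end1 in intervals:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")


# -- candidate VCF ------------------------------------------------------

_INFO_FIELDS = [
    ("NS", "1", "Integer", "Number of supporting accessions"),
    ("MAF", "1", "Float", "Detection-panel minor allele frequency"),
    ("SRC", "1", "String", "Detection source tag"),
]


def write_candidates_vcf(
    candidates: pd.DataFrame, path: str | Path, genome: GenomeAssembly | None = None
) -> None:
    """Candidate SNP set as an uncompressed VCF with support, MAF and source
    in INFO."""
    header = pysam.VariantHeader()
    for fid, num, typ, desc in _INFO_FIELDS:
        header.info.add(fid, num, typ, desc)
    if genome is not None:
        for c in genome:
            header.contigs.add(c.id, length=c.length)
    else:
        for c in pd.unique(candidates["chrom"]):
            header.contigs.add(str(c))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    vf = pysam.VariantFile(str(tmp), "w", header=header)
    try:
        for row in candidates.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
                id=getattr(row, "id", None),
            )
            rec.info["NS"] = int(getattr(row, "n_support", 0))
            maf = getattr(row, "maf", None)
            if maf is not None and not pd.isna(maf):
                rec.info["MAF"] = float(maf)
            rec.info["SRC"] = str(getattr(row, "source", "."))
            vf.write(rec)
    finally:
        vf.close()
    os.replace(tmp, path)


def read_candidates_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                {
                    "id": rec.id,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "n_support": rec.info.get("NS", 0),
                    "maf": rec.info.get("MAF", float("nan")),
                    "source": rec.info.get("SRC", "."),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "ref", "alt", "n_support", "maf", "source"],
    )


# -- tabular formats ----------------------------------------------------

def write_calls_tsv(table: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as fh:
        table[CALL_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing call-table columns {sorted(missing)}")
    return df[CALL_COLUMNS]


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Design-score table: id, design_score, optional failure_code."""
    df = pd.read_csv(path, sep="\t", dtype={"failure_code": str})
    if "id" not in df.columns or "design_score" not in df.columns:
        raise ParseError(f"{path}: design-score TSV needs id and design_score")
    return df


def write_manifest_csv(manifest: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as fh:
        manifest.to_csv(fh, index=False)


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- genotype reports ---------------------------------------------------

def write_genotype_report(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Long-format GenomeStudio-like TSV: one row per SNP x sample with the
    call and the per-SNP cluster scores repeated."""
    with atomic_write(path) as fh:
        fh.write("snp\tsample\tcall\tgentrain\tgencall10\n")
        for snp in matrix.snp_ids:
            gt = matrix.snp_scores.loc[snp, "gentrain"]
            gc = matrix.snp_scores.loc[snp, "gencall10"]
            for sample, call in matrix.calls[snp].items():
                fh.write(f"{snp}\t{sample}\t{call}\t{gt}\t{gc}\n")


def read_genotype_report(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "sample", "call", "gentrain", "gencall10"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: genotype report needs columns {sorted(required)}")
    calls = df.pivot(index="sample", columns="snp", values="call")
    calls = calls[df["snp"].drop_duplicates().tolist()]  # preserve SNP order
    calls = calls.loc[df["sample"].drop_duplicates().tolist()]
    calls.columns.name = None
    calls.index.name = None
    scores = (
        df.drop_duplicates("snp").set_index("snp")[["gentrain", "gencall10"]]
    )
    scores.index.name = None
    return GenotypeMatrix(calls=calls, snp_scores=scores)


# -- configuration ------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Flat key-value configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a key-value mapping")
    return cfg


def write_stage_log(counts: dict, path: str | Path, stage: str) -> None:
    """Line-oriented machine-readable funnel log: stage<TAB>rule<TAB>count."""
    with atomic_write(path) as fh:
        for rule, count in counts.items():
            fh.write(f"{stage}\t{rule}\t{count}\n")


def read_stage_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["stage", "rule", "count"])
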