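"""Readers/writers for the standard formats the pipeline touches.

Everything is normalized to 0-based half-open coordinates at this boundary:
GTF (1-based inclusive) and VCF positions (1-based) are shifted on the way
in and restored on the way out.  BED is adopted unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import pandas as pd
from cyvcf2 import VCF

from .models import (
    MISSING,
    Cohort,
    FusionCall,
    GeneModel,
    GenomicInterval,
    Strand,
    TranscriptModel,
    VariantRecord,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _prevalidate_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}: malformed GTF line {lineno}: expected >=8 "
                    f"tab-separated fields, got {len(fields)}"
                )


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a Gencode-dialect GTF into :class:`GeneModel` objects.

    Exon order in each transcript follows transcription direction (reversed
    for minus-strand transcripts); coordinates become 0-based half-open.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # group exon / CDS features by transcript
    tx_exons: dict[str, list] = {}
    tx_cds: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, Strand]] = {}
    gene_names: dict[str, str] = {}

    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = feat.attributes.get("gene_id", [None])[0]
            if gid:
                gene_names[gid] = feat.attributes.get("gene_name", [gid])[0]
            continue
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ParseError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:"
                f"{feat.start} lacks transcript_id"
            )
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:"
                f"{feat.start} lacks gene_id"
            )
        tid = tids[0]
        strand = Strand(feat.strand) if feat.strand in "+-" else Strand.UNSTRANDED
        tx_meta.setdefault(tid, (gid, feat.seqid, strand))
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        (tx_exons if feat.featuretype == "exon" else tx_cds).setdefault(
            tid, []
        ).append(iv)
        gene_names.setdefault(gid, feat.attributes.get("gene_name", [gid])[0])

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        reverse = strand is Strand.MINUS
        exons = sorted(exons, key=lambda e: e.start, reverse=reverse)
        cds = sorted(tx_cds.get(tid, []), key=lambda e: e.start, reverse=reverse)
        genes.setdefault(gid, []).append(
            TranscriptModel(tid, gid, strand, exons, cds)
        )

    out = []
    for gid, transcripts in genes.items():
        transcripts.sort(key=lambda t: t.transcript_id)
        out.append(
            GeneModel(
                gene_id=gid,
                gene_name=gene_names.get(gid, gid),
                strand=transcripts[0].strand,
                chrom=transcripts[0].chrom,
                transcripts=transcripts,
            )
        )
    out.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return out


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "tandemchimera") -> None:
    """Write models as a Gencode-dialect GTF (gene/transcript/exon/CDS)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            span = g.span
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        g.strand.value,
                        ".",
                        _gtf_attrs(gene_id=g.gene_id, gene_name=g.gene_name),
                    ]
                )
                + "\n"
            )
            for t in g.transcripts:
                ts = t.span
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            source,
                            "transcript",
                            str(ts.start + 1),
                            str(ts.end),
                            ".",
                            g.strand.value,
                            ".",
                            _gtf_attrs(
                                gene_id=g.gene_id,
                                transcript_id=t.transcript_id,
                                gene_name=g.gene_name,
                            ),
                        ]
                    )
                    + "\n"
                )
                for ftype, pieces in (("exon", t.exons), ("CDS", t.cds)):
                    for iv in sorted(pieces, key=lambda e: e.start):
                        fh.write(
                            "\t".join(
                                [
                                    g.chrom,
                                    source,
                                    ftype,
                                    str(iv.start + 1),
                                    str(iv.end),
                                    ".",
                                    g.strand.value,
                                    ".",
                                    _gtf_attrs(
                                        gene_id=g.gene_id,
                                        transcript_id=t.transcript_id,
                                        gene_name=g.gene_name,
                                    ),
                                ]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_vcf(path: str | Path, sample_ids: Sequence[str]) -> list[VariantRecord]:
    """Read GT dosages for ``sample_ids``; multi-allelic sites are split into
    one record per alternative allele.  Phase separators are ignored."""
    vcf = VCF(str(path))
    present = set(vcf.samples)
    absent = [s for s in sample_ids if s not in present]
    if absent:
        raise ParseError(f"{path}: samples absent from VCF: {absent}")
    col = {s: i for i, s in enumerate(vcf.samples)}
    take = [col[s] for s in sample_ids]

    records: list[VariantRecord] = []
    for v in vcf:
        gts = v.genotypes  # [[a0, a1, phased], ...]
        for alt_idx, alt in enumerate(v.ALT, start=1):
            dosages: list[int] = []
            for i in take:
                a, b = gts[i][0], gts[i][1]
                if a < 0 or b < 0:
                    dosages.append(MISSING)
                else:
                    dosages.append(int(a == alt_idx) + int(b == alt_idx))
            vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            if len(v.ALT) > 1:
                vid = f"{vid}:{alt_idx}" if v.ID else vid
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    variant_id=vid,
                    ref=v.REF,
                    alt=alt,
                    dosages=dosages,
                    is_deletion=len(v.REF) > len(alt),
                )
            )
    return records


_GT_OF_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(records: Sequence[VariantRecord], sample_ids: Sequence[str],
              path: str | Path) -> None:
    """Write biallelic records as a minimal VCF 4.2 with GT only."""
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (chroms.index(r.chrom), r.pos)):
            if len(r.dosages) != len(sample_ids):
                raise ValueError(f"{r.variant_id}: dosage count != sample count")
            gts = "\t".join(_GT_OF_DOSAGE[d] for d in r.dosages)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.variant_id}\t{r.ref}\t{r.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6; coordinates adopted unchanged (already half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: BED line {lineno}: <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(
                    f"{path}: BED line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = Strand.UNSTRANDED
            if len(fields) > 5 and fields[5] in "+-":
                strand = Strand(fields[5])
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                f"{iv.strand.value if iv.strand is not Strand.UNSTRANDED else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Fusion TSV
# ---------------------------------------------------------------------------

@dataclass
class FusionTableColumns:
    """Column mapping for the fusion-call TSV (fusion-caller report dialects
    vary, so every column name is configurable).

    ``breakpoint_convention`` is either ``last_retained`` (bp1/bp2 are the
    last retained base of the 5' partner / first retained base of the 3'
    partner, the internal convention) or ``first_excluded`` (each breakpoint
    is shifted one base further in the partner's transcription direction;
    converting back requires gene strands from the annotation, assumed '+'
    when no annotation is given).
    """

    fusion_id: str = "FusionID"
    gene5: str = "Gene1"
    gene3: str = "Gene2"
    chrom5: str = "Chromosome1"
    chrom3: str = "Chromosome2"
    bp1: str = "Position1"
    bp2: str = "Position2"
    split_reads: str = "SplitReads"
    carriers: str = "Carriers"
    breakpoint_convention: str = "last_retained"


def parse_fusion_table(
    path: str | Path,
    columns: Optional[FusionTableColumns] = None,
    annotation: Optional[dict[str, GeneModel]] = None,
) -> list[FusionCall]:
    cols = columns or FusionTableColumns()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for needed in (cols.gene5, cols.gene3, cols.bp1, cols.bp2,
                   cols.split_reads, cols.carriers):
        if needed not in df.columns:
            raise ParseError(f"{path}: missing column {needed!r}")

    merged: dict[tuple, FusionCall] = {}
    for idx, row in df.iterrows():
        g5, g3 = row[cols.gene5], row[cols.gene3]
        bp1, bp2 = int(row[cols.bp1]), int(row[cols.bp2])
        if cols.breakpoint_convention == "first_excluded":
            s5 = annotation[g5].strand if annotation and g5 in annotation else Strand.PLUS
            s3 = annotation[g3].strand if annotation and g3 in annotation else Strand.PLUS
            bp1 += 1 if s5 is Strand.MINUS else -1
            bp2 += -1 if s3 is Strand.MINUS else 1
        carriers = frozenset(
            c for c in str(row[cols.carriers]).split(",") if c.strip()
        )
        flagged = False
        if annotation is not None:
            for g in (g5, g3):
                if g not in annotation:
                    warnings.warn(f"fusion row {idx}: unknown gene_id {g}")
                    flagged = True
        key = (g5, g3, bp1, bp2)
        call = FusionCall(
            fusion_id=(row[cols.fusion_id] if cols.fusion_id in df.columns
                       else f"FUS{idx:05d}"),
            gene5=g5,
            gene3=g3,
            chrom5=(row[cols.chrom5] if cols.chrom5 in df.columns else "."),
            chrom3=(row[cols.chrom3] if cols.chrom3 in df.columns else "."),
            bp1=bp1,
            bp2=bp2,
            split_reads=int(row[cols.split_reads]),
            carriers=carriers,
            flagged_unknown_gene=flagged,
        )
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                split_reads=max(prev.split_reads, call.split_reads),
                carriers=prev.carriers | call.carriers,
            )
        else:
            merged[key] = call
    return list(merged.values())


def write_fusion_table(calls: Sequence[FusionCall], path: str | Path,
                       columns: Optional[FusionTableColumns] = None) -> None:
    cols = columns or FusionTableColumns()
    header = [cols.fusion_id, cols.gene5, cols.gene3, cols.chrom5, cols.bp1,
              cols.chrom3, cols.bp2, cols.split_reads, cols.carriers]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.fusion_id, c.gene5, c.gene3, c.chrom5, str(c.bp1),
                        c.chrom3, str(c.bp2), str(c.split_reads),
                        ",".join(sorted(c.carriers)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RPKM table
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Transcript-level RPKM matrix plus transcript -> gene mapping."""

    values: pd.DataFrame  # index transcript_id, columns sample_id
    gene_of: pd.Series    # index transcript_id -> gene_id

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = self.values.index.difference(self.gene_of.index)
        if len(missing):
            raise ValueError(f"transcripts without gene mapping: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_rpkm_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "transcript_id" or df.columns[1] != "gene_id":
        raise ParseError(
            f"{path}: first two columns must be transcript_id, gene_id"
        )
    df = df.set_index("transcript_id")
    gene_of = df.pop("gene_id")
    return ExpressionTable(values=df.astype(float), gene_of=gene_of)


def write_rpkm_table(table: ExpressionTable, path: str | Path) -> None:
    df = table.values.copy()
    df.insert(0, "gene_id", table.gene_of)
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastqRead:
    name: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.name}: seq/qual length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Sequence[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# Cohort TSV
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise ParseError(f"{path}: need columns sample_id, population")
    return Cohort(
        populations=dict(zip(df["sample_id"], df["population"])),
        sample_order=list(df["sample_id"]),
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in cohort.sample_order:
            fh.write(f"{s}\t{cohort.populations[s]}\n")
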