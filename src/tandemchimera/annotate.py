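"""Custom chimeric annotation and expression aggregation.

Builds fused transcript models (5'-partner exons up to bp1 joined to
3'-partner exons from bp2, with intra-exon breakpoints truncating the exon),
emits them alongside the original models as a Gencode-dialect GTF for an
external quantifier, sums transcript RPKMs to gene level and compares
chimera vs partner-gene expression in carrier samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import boundary_status
from .io_formats import ExpressionTable
from .models import (
    BoundaryStatus,
    FusionCall,
    GeneModel,
    GenomicInterval,
    Strand,
    TranscriptModel,
    tx_key,
)
from .stats import KSResult, ks_two_sample

logger = logging.getLogger(__name__)


def fused_gene_id(gene5: str, gene3: str) -> str:
    return f"FUSION|{gene5}|{gene3}"


@dataclass
class ChimericTranscript:
    transcript_id: str
    gene_id: str
    strand: Strand
    exons: list[GenomicInterval]  # transcription order
    source_transcript5: str
    source_transcript3: str
    fusion_id: str
    truncated5: bool = False
    truncated3: bool = False

    def to_model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            strand=self.strand,
            exons=self.exons,
        )


def _snap_near_boundary(bp: int, transcript: TranscriptModel, side: str) -> int:
    """Snap a breakpoint 1-3 nt from an exon edge to the annotated edge of the
    retained side (exon end for the 5' partner, exon start for the 3')."""
    try:
        status, _ = boundary_status(bp, transcript)
    except ValueError:
        return bp
    if status is not BoundaryStatus.NEAR_BOUNDARY:
        return bp
    minus = transcript.strand is Strand.MINUS
    edges = []
    for e in transcript.exons:
        if side == "5":
            edges.append(e.start if minus else e.end - 1)  # last tx base
        else:
            edges.append(e.end - 1 if minus else e.start)  # first tx base
    return min(edges, key=lambda x: abs(x - bp))


def build_chimeric_transcripts(
    call: FusionCall,
    gene5: GeneModel,
    gene3: GeneModel,
    snap_near: bool = True,
) -> list[ChimericTranscript]:
    """One fused transcript per (transcript5, transcript3) combination.

    5'-partner exons transcriptionally beyond bp1 are dropped; an exon
    spanning bp1 is truncated to end at bp1 (flagged).  Symmetric rule at
    bp2.  All fused transcripts of a fusion share one new gene id.
    """
    if gene5.strand != gene3.strand:
        raise ValueError(f"{call.fusion_id}: partners must share a strand")
    strand = gene5.strand
    minus = strand is Strand.MINUS
    gid = fused_gene_id(call.gene5, call.gene3)
    out: list[ChimericTranscript] = []
    for t5 in gene5.transcripts:
        bp1 = _snap_near_boundary(call.bp1, t5, "5") if snap_near else call.bp1
        retained5: list[GenomicInterval] = []
        truncated5 = False
        for e in t5.exons:
            first = e.end - 1 if minus else e.start
            if tx_key(first, strand) > tx_key(bp1, strand):
                continue  # entirely beyond the breakpoint
            last = e.start if minus else e.end - 1
            if tx_key(last, strand) > tx_key(bp1, strand):
                e = GenomicInterval(
                    e.chrom,
                    bp1 if minus else e.start,
                    e.end if minus else bp1 + 1,
                    strand,
                )
                truncated5 = True
            retained5.append(e)
        if not retained5:
            logger.warning(
                "%s: bp1=%d upstream of %s; pair skipped",
                call.fusion_id, call.bp1, t5.transcript_id,
            )
            continue
        for t3 in gene3.transcripts:
            bp2 = _snap_near_boundary(call.bp2, t3, "3") if snap_near else call.bp2
            retained3: list[GenomicInterval] = []
            truncated3 = False
            for e in t3.exons:
                last = e.start if minus else e.end - 1
                if tx_key(last, strand) < tx_key(bp2, strand):
                    continue  # entirely before the junction
                first = e.end - 1 if minus else e.start
                if tx_key(first, strand) < tx_key(bp2, strand):
                    e = GenomicInterval(
                        e.chrom,
                        e.start if minus else bp2,
                        bp2 + 1 if minus else e.end,
                        strand,
                    )
                    truncated3 = True
                retained3.append(e)
            if not retained3:
                logger.warning(
                    "%s: bp2=%d beyond %s; pair skipped",
                    call.fusion_id, call.bp2, t3.transcript_id,
                )
                continue
            out.append(
                ChimericTranscript(
                    transcript_id=f"{gid}|{t5.transcript_id}|{t3.transcript_id}",
                    gene_id=gid,
                    strand=strand,
                    exons=retained5 + retained3,
                    source_transcript5=t5.transcript_id,
                    source_transcript3=t3.transcript_id,
                    fusion_id=call.fusion_id,
                    truncated5=truncated5,
                    truncated3=truncated3,
                )
            )
    return out


def chimeric_gene_model(
    call: FusionCall, transcripts: Sequence[ChimericTranscript]
) -> GeneModel:
    models = [t.to_model() for t in transcripts]
    gid = transcripts[0].gene_id
    return GeneModel(
        gene_id=gid,
        gene_name=gid,
        strand=transcripts[0].strand,
        chrom=models[0].chrom,
        transcripts=models,
    )


def build_custom_annotation(
    calls: Sequence[FusionCall],
    annotation: Mapping[str, GeneModel],
    snap_near: bool = True,
) -> tuple[list[GeneModel], dict[str, list[ChimericTranscript]]]:
    """Original gene models plus one fused gene model per call."""
    genes = list(annotation.values())
    fused: dict[str, list[ChimericTranscript]] = {}
    for call in calls:
        cts = build_chimeric_transcripts(
            call, annotation[call.gene5], annotation[call.gene3], snap_near
        )
        if not cts:
            logger.warning("%s: no compatible transcript pair; skipped", call.fusion_id)
            continue
        fused[call.fusion_id] = cts
        genes.append(chimeric_gene_model(call, cts))
    return genes, fused


def aggregate_gene_rpkm(expression: ExpressionTable) -> pd.DataFrame:
    """Gene-level RPKM = sum of the gene's transcript RPKMs, per sample."""
    orphans = expression.gene_of[expression.gene_of.isna()]
    if len(orphans):
        raise ValueError(f"orphan transcripts: {list(orphans.index)[:5]}")
    return expression.values.groupby(expression.gene_of).sum()


@dataclass
class ExpressionComparison:
    ks: KSResult
    chimera_median: float
    partner_median: float
    n_chimera_values: int
    n_partner_values: int
    skipped_fusions: list[str]


def compare_chimera_expression(
    gene_rpkm: pd.DataFrame,
    calls: Sequence[FusionCall],
    carrier_map: Optional[Mapping[str, frozenset[str]]] = None,
) -> ExpressionComparison:
    """Pool fused-gene and partner-gene RPKMs over carrier samples only,
    across fusions, and compare the two distributions."""
    chimera_vals: list[float] = []
    partner_vals: list[float] = []
    skipped: list[str] = []
    for call in calls:
        carriers = (
            carrier_map[call.fusion_id] if carrier_map is not None else call.carriers
        )
        samples = [s for s in carriers if s in gene_rpkm.columns]
        if not samples:
            logger.warning("%s: no carriers with expression; skipped", call.fusion_id)
            skipped.append(call.fusion_id)
            continue
        fid = fused_gene_id(call.gene5, call.gene3)
        if fid not in gene_rpkm.index:
            logger.warning("%s: fused gene %s absent from RPKM; skipped",
                           call.fusion_id, fid)
            skipped.append(call.fusion_id)
            continue
        chimera_vals.extend(gene_rpkm.loc[fid, samples].tolist())
        for g in (call.gene5, call.gene3):
            partner_vals.extend(gene_rpkm.loc[g, samples].tolist())
    ks = ks_two_sample(chimera_vals, partner_vals)
    return ExpressionComparison(
        ks=ks,
        chimera_median=float(np.median(chimera_vals)),
        partner_median=float(np.median(partner_vals)),
        n_chimera_values=len(chimera_vals),
        n_partner_values=len(partner_vals),
        skipped_fusions=skipped,
    )
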