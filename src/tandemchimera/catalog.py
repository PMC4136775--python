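"""Build the filtered chimera catalog.

Orientation classes, split-read support and repeat filters, breakpoint
boundary status, breakpoint distances, per-population frequencies (with a
venn partition over populations), the expression-presence filter and the
novelty annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import (
    BoundaryStatus,
    Cohort,
    FusionCall,
    GeneModel,
    GenomicInterval,
    OrientationClass,
    TranscriptModel,
    tx_key,
)


def classify_orientation(
    call: FusionCall, annotation: Mapping[str, GeneModel]
) -> OrientationClass:
    """Orientation of the call relative to the annotation.

    Same-strand intra-chromosomal calls are TANDEM when the 5' partner is
    transcriptionally upstream of the 3' partner, INVERTED otherwise.
    """
    for g in (call.gene5, call.gene3):
        if g not in annotation:
            raise KeyError(f"unknown gene {g} in {call.fusion_id}")
    g5, g3 = annotation[call.gene5], annotation[call.gene3]
    if g5.chrom != g3.chrom:
        return OrientationClass.INTERCHROM
    if g5.strand != g3.strand:
        return OrientationClass.INTRACHROM_DIFF_STRAND
    if tx_key(g5.tss, g5.strand) < tx_key(g3.tss, g3.strand):
        return OrientationClass.TANDEM_SAME_STRAND
    return OrientationClass.SAME_STRAND_INVERTED


def annotate_orientation(
    calls: Iterable[FusionCall], annotation: Mapping[str, GeneModel]
) -> list[FusionCall]:
    return [
        replace(c, orientation=classify_orientation(c, annotation)) for c in calls
    ]


def apply_support_filter(
    calls: Iterable[FusionCall], min_split_reads: int = 2
) -> list[FusionCall]:
    """Keep calls with split_reads strictly greater than ``min_split_reads``."""
    if min_split_reads < 0:
        raise ValueError("min_split_reads must be >= 0")
    return [c for c in calls if c.split_reads > min_split_reads]


def apply_repeat_filter(
    calls: Iterable[FusionCall],
    repeats: Sequence[GenomicInterval],
    window: int = 0,
) -> list[FusionCall]:
    """Drop calls whose breakpoint (a point, optionally widened by
    ``window`` nt each side) falls inside any repeat interval (half-open)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)

    def hit(chrom: str, pos: int) -> bool:
        return any(
            r.start < pos + window + 1 and pos - window < r.end
            for r in by_chrom.get(chrom, ())
        )

    return [
        c
        for c in calls
        if not hit(c.chrom5, c.bp1) and not hit(c.chrom3, c.bp2)
    ]


def boundary_status(
    bp: int, transcript: TranscriptModel
) -> tuple[BoundaryStatus, Optional[int]]:
    """Status of a breakpoint relative to a transcript's exon structure.

    Returns (status, distance) where distance is the nt offset for
    NEAR_BOUNDARY (1-3) and None otherwise.
    """
    span = transcript.span
    if not span.contains(bp):
        raise ValueError(
            f"breakpoint {bp} outside transcript span "
            f"{span.chrom}:{span.start}-{span.end}"
        )
    edges = []
    inside = False
    for e in transcript.exons:
        edges.extend((e.start, e.end - 1))
        if e.contains(bp):
            inside = True
    if bp in edges:
        return BoundaryStatus.AT_BOUNDARY, None
    dist = min(abs(bp - edge) for edge in edges)
    if dist <= 3:
        return BoundaryStatus.NEAR_BOUNDARY, dist
    return (BoundaryStatus.INTRA_EXON if inside else BoundaryStatus.INTRONIC), None


def breakpoint_distance(call: FusionCall) -> int:
    if call.chrom5 != call.chrom3:
        raise ValueError(
            f"{call.fusion_id}: breakpoint distance undefined across chromosomes"
        )
    return abs(call.bp2 - call.bp1)


@dataclass
class PopulationFrequency:
    fusion_id: str
    carrier_counts: dict[str, int]
    population_sizes: dict[str, int]
    combined_frequency: float

    @property
    def populations_present(self) -> frozenset[str]:
        return frozenset(p for p, c in self.carrier_counts.items() if c > 0)


def population_frequencies(
    calls: Iterable[FusionCall], cohort: Cohort
) -> tuple[dict[str, PopulationFrequency], dict[frozenset[str], int]]:
    """Per-population carrier counts plus the venn partition: for each fusion
    the subset of populations with >=1 carrier, aggregated into counts."""
    pops = cohort.population_names
    sizes = {p: len(cohort.samples_of(p)) for p in pops}
    total = len(cohort)
    freqs: dict[str, PopulationFrequency] = {}
    venn: dict[frozenset[str], int] = {}
    for call in calls:
        counts = dict.fromkeys(pops, 0)
        for s in call.carriers:
            if s not in cohort.populations:
                raise KeyError(
                    f"{call.fusion_id}: carrier {s} has no population label"
                )
            counts[cohort.populations[s]] += 1
        pf = PopulationFrequency(
            fusion_id=call.fusion_id,
            carrier_counts=counts,
            population_sizes=sizes,
            combined_frequency=len(call.carriers) / total,
        )
        freqs[call.fusion_id] = pf
        if call.carriers:
            region = pf.populations_present
            venn[region] = venn.get(region, 0) + 1
    return freqs, venn


def expression_presence_filter(
    calls: Iterable[FusionCall],
    gene_rpkm: pd.DataFrame,
    cohort: Cohort,
) -> list[FusionCall]:
    """Keep a fusion iff each partner gene has RPKM > 0 in at least one
    sample of every population.  ``gene_rpkm`` is gene x sample."""
    pop_samples = {
        p: [s for s in cohort.samples_of(p) if s in gene_rpkm.columns]
        for p in cohort.population_names
    }

    def expressed_everywhere(gene: str) -> bool:
        if gene not in gene_rpkm.index:
            raise KeyError(f"gene {gene} missing from expression table")
        row = gene_rpkm.loc[gene]
        return all((row[ss] > 0).any() for ss in pop_samples.values())

    return [
        c
        for c in calls
        if expressed_everywhere(c.gene5) and expressed_everywhere(c.gene3)
    ]


def annotate_novelty(
    calls: Iterable[FusionCall], known_pairs: Iterable[tuple[str, str]]
) -> list[FusionCall]:
    """Order-sensitive lookup against a list of known (gene5, gene3) pairs."""
    known = set(known_pairs)
    return [replace(c, novel=(c.gene5, c.gene3) not in known) for c in calls]


@dataclass
class CatalogRow:
    call: FusionCall
    boundary5: BoundaryStatus
    boundary3: BoundaryStatus
    distance: Optional[int]
    frequency: PopulationFrequency


def _best_boundary(bp: int, gene: GeneModel, side: str) -> BoundaryStatus:
    """Most favourable boundary status over the gene's transcripts."""
    order = [
        BoundaryStatus.AT_BOUNDARY,
        BoundaryStatus.NEAR_BOUNDARY,
        BoundaryStatus.INTRA_EXON,
        BoundaryStatus.INTRONIC,
    ]
    best = None
    for t in gene.transcripts:
        try:
            status, _ = boundary_status(bp, t)
        except ValueError:
            continue
        if best is None or order.index(status) < order.index(best):
            best = status
    if best is None:
        raise ValueError(f"breakpoint {bp} outside all transcripts of {gene.gene_id}")
    return best


def build_catalog(
    calls: Sequence[FusionCall],
    annotation: Mapping[str, GeneModel],
    cohort: Cohort,
    repeats: Sequence[GenomicInterval] = (),
    min_split_reads: int = 2,
    known_pairs: Iterable[tuple[str, str]] = (),
    gene_rpkm: Optional[pd.DataFrame] = None,
) -> list[CatalogRow]:
    """Full catalog pipeline: orientation, support filter, repeat filter,
    optional expression-presence filter, novelty, boundary status,
    distances and population frequencies."""
    calls = annotate_orientation(calls, annotation)
    calls = apply_support_filter(calls, min_split_reads)
    calls = apply_repeat_filter(calls, repeats)
    if gene_rpkm is not None:
        calls = expression_presence_filter(calls, gene_rpkm, cohort)
    calls = annotate_novelty(calls, known_pairs)
    freqs, _ = population_frequencies(calls, cohort)
    rows = []
    for c in calls:
        rows.append(
            CatalogRow(
                call=c,
                boundary5=_best_boundary(c.bp1, annotation[c.gene5], "5"),
                boundary3=_best_boundary(c.bp2, annotation[c.gene3], "3"),
                distance=(breakpoint_distance(c) if c.chrom5 == c.chrom3 else None),
                frequency=freqs[c.fusion_id],
            )
        )
    return rows


def catalog_to_frame(rows: Sequence[CatalogRow]) -> pd.DataFrame:
    pops = sorted(
        {p for r in rows for p in r.frequency.carrier_counts}
    ) if rows else []
    records = []
    for r in rows:
        rec = {
            "fusion_id": r.call.fusion_id,
            "gene5": r.call.gene5,
            "gene3": r.call.gene3,
            "chrom5": r.call.chrom5,
            "chrom3": r.call.chrom3,
            "bp1": r.call.bp1,
            "bp2": r.call.bp2,
            "orientation": r.call.orientation.value if r.call.orientation else ".",
            "split_reads": r.call.split_reads,
            "boundary_status_5": r.boundary5.value,
            "boundary_status_3": r.boundary3.value,
            "distance": r.distance if r.distance is not None else "",
            "combined_frequency": r.frequency.combined_frequency,
            "novel": r.call.novel,
            "carriers": ",".join(sorted(r.call.carriers)),
        }
        for p in pops:
            rec[f"n_{p}"] = r.frequency.carrier_counts.get(p, 0)
        records.append(rec)
    return pd.DataFrame.from_records(records)
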