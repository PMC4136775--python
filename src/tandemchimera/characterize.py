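"""Structural characterization of tandem chimeras.

Assigns one of five structural classes per fusion, determines the junction
reading frame from CDS arithmetic, enumerates exon-exclusion patterns over
all transcript combinations, and collects breakpoint-flanking intron/exon
lengths against the background of the partner genes' other introns/exons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog import boundary_status
from .models import (
    BoundaryStatus,
    FusionCall,
    GeneModel,
    StructuralClass,
    TranscriptModel,
)
from .stats import KSResult, ks_two_sample

logger = logging.getLogger(__name__)

_STATUS_RANK = {
    BoundaryStatus.AT_BOUNDARY: 0,
    BoundaryStatus.NEAR_BOUNDARY: 1,
    BoundaryStatus.INTRA_EXON: 2,
    BoundaryStatus.INTRONIC: 3,
}


def _pair_rank(call: FusionCall, t5: TranscriptModel, t3: TranscriptModel) -> Optional[int]:
    """Worse of the two breakpoint boundary ranks; None if the pair is
    incompatible with the breakpoints (a breakpoint outside the transcript
    or leaving no retained exon)."""
    if t5.fusion_exon_index_5prime(call.bp1) is None:
        return None
    if t3.fusion_exon_index_3prime(call.bp2) is None:
        return None
    try:
        s5, _ = boundary_status(call.bp1, t5)
        s3, _ = boundary_status(call.bp2, t3)
    except ValueError:
        return None
    return max(_STATUS_RANK[s5], _STATUS_RANK[s3])


def select_transcript_pair(
    call: FusionCall, gene5: GeneModel, gene3: GeneModel
) -> tuple[TranscriptModel, TranscriptModel]:
    """Pick the transcript pair used for the single reported class: prefer
    pairs with both breakpoints at exon boundaries, break ties by longest
    combined CDS, then by transcript ids for determinism."""
    best = None
    for t5 in gene5.transcripts:
        for t3 in gene3.transcripts:
            rank = _pair_rank(call, t5, t3)
            if rank is None:
                continue
            key = (rank, -(t5.cds_length + t3.cds_length),
                   t5.transcript_id, t3.transcript_id)
            if best is None or key < best[0]:
                best = (key, t5, t3)
    if best is None:
        nearest = []
        for g in (gene5, gene3):
            for t in g.transcripts:
                s = t.span
                nearest.append(f"{t.transcript_id}:{s.start}-{s.end}")
        raise ValueError(
            f"{call.fusion_id}: no transcript pair compatible with breakpoints "
            f"bp1={call.bp1}, bp2={call.bp2}; transcript spans: {nearest}"
        )
    return best[1], best[2]


def junction_frame(
    call: FusionCall, t5: TranscriptModel, t3: TranscriptModel
) -> StructuralClass:
    """IN_FRAME iff retained 5'-partner coding length and excluded 3'-partner
    coding length agree modulo 3."""
    if t5.cds_length == 0 or t3.cds_length == 0:
        raise ValueError(
            f"{call.fusion_id}: junction_frame requires both partners coding"
        )
    l5 = t5.cds_retained_upstream(call.bp1)
    s3 = t3.cds_excluded_upstream(call.bp2)
    return (
        StructuralClass.IN_FRAME
        if l5 % 3 == s3 % 3
        else StructuralClass.OUT_OF_FRAME
    )


def classify_structure(
    call: FusionCall, gene5: GeneModel, gene3: GeneModel
) -> tuple[Optional[StructuralClass], TranscriptModel, TranscriptModel]:
    """Structural class on the selected transcript pair.

    Returns (class, t5, t3); class is None for fusions the five-class scheme
    cannot describe (no coding sequence on either side of the junction).
    """
    t5, t3 = select_transcript_pair(call, gene5, gene3)
    cds5, cds3 = t5.cds_length, t3.cds_length
    l5 = t5.cds_retained_upstream(call.bp1)
    s3 = t3.cds_excluded_upstream(call.bp2)
    retained3_complete = cds3 > 0 and s3 == 0
    retained5_complete = cds5 > 0 and l5 == cds5

    if retained5_complete and retained3_complete:
        return StructuralClass.GENUINE_READ_THROUGH, t5, t3
    if l5 == 0 and retained3_complete:
        return StructuralClass.PROMOTER_SWAP, t5, t3
    if retained5_complete and (cds3 == 0 or s3 == cds3):
        return StructuralClass.UTR3_SWAP, t5, t3
    if cds5 == 0 or cds3 == 0 or (l5 == 0 and s3 == cds3):
        logger.warning(
            "%s: unclassifiable junction (no CDS contribution)", call.fusion_id
        )
        return None, t5, t3
    return junction_frame(call, t5, t3), t5, t3


@dataclass(frozen=True)
class ExclusionPattern:
    k5: int  # excluded terminal exons of the 5' partner (from last)
    k3: int  # excluded leading exons of the 3' partner (from first)
    weight: float


def exon_exclusion_patterns(
    call: FusionCall, gene5: GeneModel, gene3: GeneModel
) -> list[ExclusionPattern]:
    """(k5, k3) over every transcript pair, weighted by pair counts."""
    counts: Counter[tuple[int, int]] = Counter()
    n_pairs = 0
    for t5 in gene5.transcripts:
        for t3 in gene3.transcripts:
            k5 = t5.exons_after(call.bp1)
            k3 = t3.exons_before(call.bp2)
            counts[(k5, k3)] += 1
            n_pairs += 1
    return [
        ExclusionPattern(k5=k5, k3=k3, weight=c / n_pairs)
        for (k5, k3), c in sorted(counts.items())
    ]


def aggregate_patterns(
    per_fusion: Sequence[Sequence[ExclusionPattern]],
) -> dict[tuple[int, int], float]:
    """Average the per-fusion weight distributions (each fusion contributes
    total weight 1 regardless of its isoform count)."""
    total: Counter[tuple[int, int]] = Counter()
    for patterns in per_fusion:
        for p in patterns:
            total[(p.k5, p.k3)] += p.weight
    n = len(per_fusion)
    return {k: v / n for k, v in sorted(total.items())}


@dataclass
class FlankingLengths:
    """Breakpoint-flanking intron/exon lengths pooled over transcript pairs,
    each distinct intron/exon counted once per transcript."""

    intron5: list[int] = field(default_factory=list)
    intron3: list[int] = field(default_factory=list)
    background_introns: list[int] = field(default_factory=list)
    exon5: list[int] = field(default_factory=list)
    exon3: list[int] = field(default_factory=list)
    background_exons: list[int] = field(default_factory=list)
    skipped_pairs: int = 0


def flanking_feature_lengths(
    call: FusionCall, gene5: GeneModel, gene3: GeneModel
) -> FlankingLengths:
    """Lengths of the intron following the 5'-partner fusion exon and the
    intron preceding the 3'-partner fusion exon, with all the partners'
    other introns as background (exons analogously)."""
    out = FlankingLengths()
    seen5: set[str] = set()
    seen3: set[str] = set()
    for t5 in gene5.transcripts:
        for t3 in gene3.transcripts:
            f5 = t5.fusion_exon_index_5prime(call.bp1)
            f3 = t3.fusion_exon_index_3prime(call.bp2)
            if f5 is None or f3 is None:
                out.skipped_pairs += 1
                continue
            if t5.transcript_id not in seen5:
                seen5.add(t5.transcript_id)
                introns = t5.introns()
                if f5 < len(introns):
                    out.intron5.append(len(introns[f5]))
                else:
                    logger.info(
                        "%s: fusion exon of %s is terminal; no downstream intron",
                        call.fusion_id, t5.transcript_id,
                    )
                out.background_introns.extend(
                    len(iv) for i, iv in enumerate(introns) if i != f5
                )
                out.exon5.append(len(t5.exons[f5]))
                out.background_exons.extend(
                    len(e) for i, e in enumerate(t5.exons) if i != f5
                )
            if t3.transcript_id not in seen3:
                seen3.add(t3.transcript_id)
                introns = t3.introns()
                if f3 >= 1:
                    out.intron3.append(len(introns[f3 - 1]))
                else:
                    logger.info(
                        "%s: fusion exon of %s is first; no upstream intron",
                        call.fusion_id, t3.transcript_id,
                    )
                out.background_introns.extend(
                    len(iv) for i, iv in enumerate(introns) if i != f3 - 1
                )
                out.exon3.append(len(t3.exons[f3]))
                out.background_exons.extend(
                    len(e) for i, e in enumerate(t3.exons) if i != f3
                )
    return out


def compare_length_distributions(
    foreground: Sequence[float], background: Sequence[float]
) -> tuple[KSResult, float, float]:
    """KS comparison plus medians (foreground, background)."""
    import numpy as np

    ks = ks_two_sample(foreground, background)
    return ks, float(np.median(foreground)), float(np.median(background))


@dataclass
class CharacterizationRow:
    fusion_id: str
    structural_class: Optional[StructuralClass]
    transcript5: str
    transcript3: str
    l5_mod3: Optional[int]
    s3_mod3: Optional[int]
    selected_pattern: tuple[int, int]
    modal_pattern: tuple[int, int]
    patterns: list[ExclusionPattern]
    flanking: FlankingLengths


def characterize_fusion(
    call: FusionCall, annotation: Mapping[str, GeneModel]
) -> CharacterizationRow:
    g5, g3 = annotation[call.gene5], annotation[call.gene3]
    cls, t5, t3 = classify_structure(call, g5, g3)
    l5 = t5.cds_retained_upstream(call.bp1) if t5.cds_length else None
    s3 = t3.cds_excluded_upstream(call.bp2) if t3.cds_length else None
    patterns = exon_exclusion_patterns(call, g5, g3)
    modal = max(patterns, key=lambda p: (p.weight, -p.k5, -p.k3))
    selected = (t5.exons_after(call.bp1), t3.exons_before(call.bp2))
    return CharacterizationRow(
        fusion_id=call.fusion_id,
        structural_class=cls,
        transcript5=t5.transcript_id,
        transcript3=t3.transcript_id,
        l5_mod3=(l5 % 3 if l5 is not None else None),
        s3_mod3=(s3 % 3 if s3 is not None else None),
        selected_pattern=selected,
        modal_pattern=(modal.k5, modal.k3),
        patterns=patterns,
        flanking=flanking_feature_lengths(call, g5, g3),
    )


def characterize_all(
    calls: Sequence[FusionCall], annotation: Mapping[str, GeneModel]
) -> list[CharacterizationRow]:
    return [characterize_fusion(c, annotation) for c in calls]
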