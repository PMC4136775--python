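"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open; input formats that use other
conventions (GTF, VCF) are converted at the parsing boundary.  Transcript
exons are stored in transcription order, i.e. reversed genomic order for
minus-strand transcripts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def tx_key(pos: int, strand: Strand) -> int:
    """Map a genomic position to a key increasing in transcription direction."""
    return pos if strand is not Strand.MINUS else -pos


@dataclass
class TranscriptModel:
    """A transcript: exons (and optional CDS pieces) in transcription order."""

    transcript_id: str
    gene_id: str
    strand: Strand
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self._validate()

    def _validate(self) -> None:
        keys = [tx_key(e.start if self.strand is not Strand.MINUS else e.end - 1,
                       self.strand) for e in self.exons]
        if keys != sorted(keys):
            raise ValueError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"CDS {c.start}-{c.end} of {self.transcript_id} "
                    "not contained in any exon"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in transcription order."""
        out: list[GenomicInterval] = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if a.start < b.start else (b.end, a.start)
            out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    # -- breakpoint arithmetic (transcription-order semantics) ------------
    def bases_at_or_before(self, pieces: Sequence[GenomicInterval], pos: int) -> int:
        """Number of bases of ``pieces`` at or 5' of ``pos`` (inclusive)."""
        total = 0
        for p in pieces:
            if self.strand is Strand.MINUS:
                lo = max(p.start, pos)
                total += max(0, p.end - lo)
            else:
                hi = min(p.end, pos + 1)
                total += max(0, hi - p.start)
        return total

    def bases_strictly_before(self, pieces: Sequence[GenomicInterval], pos: int) -> int:
        """Number of bases of ``pieces`` strictly 5' of ``pos``."""
        total = 0
        for p in pieces:
            if self.strand is Strand.MINUS:
                lo = max(p.start, pos + 1)
                total += max(0, p.end - lo)
            else:
                hi = min(p.end, pos)
                total += max(0, hi - p.start)
        return total

    def cds_retained_upstream(self, bp1: int) -> int:
        """CDS bases retained when the transcript is cut after ``bp1``."""
        return self.bases_at_or_before(self.cds, bp1)

    def cds_excluded_upstream(self, bp2: int) -> int:
        """CDS bases lost when the transcript is joined starting at ``bp2``."""
        return self.bases_strictly_before(self.cds, bp2)

    def exons_after(self, bp1: int) -> int:
        """Count exons entirely 3' of ``bp1`` (transcription order)."""
        n = 0
        for e in self.exons:
            first = e.start if self.strand is not Strand.MINUS else e.end - 1
            if tx_key(first, self.strand) > tx_key(bp1, self.strand):
                n += 1
        return n

    def exons_before(self, bp2: int) -> int:
        """Count exons entirely 5' of ``bp2`` (transcription order)."""
        n = 0
        for e in self.exons:
            last = e.end - 1 if self.strand is not Strand.MINUS else e.start
            if tx_key(last, self.strand) < tx_key(bp2, self.strand):
                n += 1
        return n

    def fusion_exon_index_5prime(self, bp1: int) -> Optional[int]:
        """Index (transcription order) of the last exon with a retained base
        under a cut at ``bp1``; None if the cut precedes the transcript."""
        idx = None
        for i, e in enumerate(self.exons):
            first = e.start if self.strand is not Strand.MINUS else e.end - 1
            if tx_key(first, self.strand) <= tx_key(bp1, self.strand):
                idx = i
        return idx

    def fusion_exon_index_3prime(self, bp2: int) -> Optional[int]:
        """Index of the first exon with a retained base when joining at
        ``bp2``; None if the junction lies past the transcript end."""
        for i, e in enumerate(self.exons):
            last = e.end - 1 if self.strand is not Strand.MINUS else e.start
            if tx_key(last, self.strand) >= tx_key(bp2, self.strand):
                return i
        return None


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    strand: Strand
    chrom: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError("transcript gene_id mismatch")
            if t.strand != self.strand or t.chrom != self.chrom:
                raise ValueError("transcript strand/chrom mismatch")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    @property
    def tss(self) -> int:
        """Transcriptional 5'-most base of the gene span."""
        s = self.span
        return s.start if self.strand is not Strand.MINUS else s.end - 1


class OrientationClass(str, enum.Enum):
    TANDEM_SAME_STRAND = "TANDEM_SAME_STRAND"
    SAME_STRAND_INVERTED = "SAME_STRAND_INVERTED"
    INTRACHROM_DIFF_STRAND = "INTRACHROM_DIFF_STRAND"
    INTERCHROM = "INTERCHROM"


class BoundaryStatus(str, enum.Enum):
    AT_BOUNDARY = "AT_BOUNDARY"
    NEAR_BOUNDARY = "NEAR_BOUNDARY"
    INTRA_EXON = "INTRA_EXON"
    INTRONIC = "INTRONIC"


class StructuralClass(str, enum.Enum):
    GENUINE_READ_THROUGH = "GENUINE_READ_THROUGH"
    PROMOTER_SWAP = "PROMOTER_SWAP"
    UTR3_SWAP = "UTR3_SWAP"
    IN_FRAME = "IN_FRAME"
    OUT_OF_FRAME = "OUT_OF_FRAME"


@dataclass
class FusionCall:
    """One chimeric-transcript call.

    ``bp1`` is the last retained base of the 5' partner and ``bp2`` the first
    retained base of the 3' partner (0-based, default input convention).
    """

    fusion_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    bp1: int
    bp2: int
    split_reads: int
    carriers: frozenset[str]
    orientation: Optional[OrientationClass] = None
    novel: Optional[bool] = None
    flagged_unknown_gene: bool = False

    def __post_init__(self) -> None:
        if self.split_reads < 0:
            raise ValueError("split_reads must be >= 0")
        if self.gene5 == self.gene3:
            raise ValueError(f"{self.fusion_id}: partner genes must differ")


MISSING = -1  # sentinel dosage for missing genotypes


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    variant_id: str
    ref: str
    alt: str
    dosages: "list[int]"  # per-sample 0/1/2 or MISSING
    is_deletion: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref == alt")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def point(self) -> int:
        """0-based genomic position of the variant start."""
        return self.pos - 1


@dataclass
class Cohort:
    """Sample -> population mapping with stable sample order."""

    populations: dict[str, str]  # sample_id -> population label
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_order:
            self.sample_order = list(self.populations)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_order:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s in self.sample_order if self.populations[s] == population]

    def __len__(self) -> int:
        return len(self.sample_order)


def build_gene_index(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    index: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in index:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        index[g.gene_id] = g
    return index
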