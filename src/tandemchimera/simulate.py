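"""Synthetic-study generator.

Produces a fully self-consistent cohort — gene annotation with tandem gene
pairs, fusion calls with known structural truth, genotypes with injected
causal intronic variants, transcript RPKMs, interval annotations and
poly(A)-selection reads — so that every analysis stage can be tested
end-to-end without external data.  Everything is a pure function of
(spec, seed).

Construction notes
------------------
* Each fused gene pair is planned first: structural class, exon-exclusion
  pattern (k5, k3), fusion-exon indices.  The intron following the 5'
  fusion exon and the intron preceding the 3' fusion exon are drawn from
  the foreground log-normal distribution, all other introns from the
  background one.
* The primary transcript (suffix ``.t0``) carries the truth: breakpoints
  sit exactly on its fusion-exon boundaries and the CDS is placed so the
  planned class holds on the primary pair.  Additional isoforms only trim
  the transcript's outer tips, so the pair-selection rule (boundary
  status, then longest combined CDS, then transcript id) always selects
  the primary pair.
* Fusion carrier status for "testable" fusions is coupled to one causal
  intronic variant: variant carrier probabilities in cases and controls
  are solved to achieve the requested carrier odds ratio at the requested
  allele frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from .io_formats import (
    ExpressionTable,
    FastqRead,
    write_bed,
    write_cohort,
    write_fastq,
    write_fusion_table,
    write_gtf,
    write_rpkm_table,
    write_vcf,
)
from .models import (
    Cohort,
    FusionCall,
    GeneModel,
    GenomicInterval,
    OrientationClass,
    Strand,
    StructuralClass,
    TranscriptModel,
    VariantRecord,
    build_gene_index,
)

_DEFAULT_POPS = {"CEU": 91, "FIN": 95, "GBR": 94, "TSI": 93, "YRI": 89}

# class mix proportional to the generator's default 10/28/11/15/17 split
_DEFAULT_CLASS_MIX = {
    StructuralClass.GENUINE_READ_THROUGH: 10,
    StructuralClass.PROMOTER_SWAP: 28,
    StructuralClass.UTR3_SWAP: 11,
    StructuralClass.IN_FRAME: 15,
    StructuralClass.OUT_OF_FRAME: 17,
}

# exon-exclusion pattern mix; (1,1) modal at ~45%
_DEFAULT_PATTERN_MIX = {
    (1, 1): 0.45,
    (2, 1): 0.16,
    (1, 2): 0.10,
    (2, 2): 0.07,
    (3, 1): 0.06,
    (1, 3): 0.05,
    (0, 1): 0.04,
    (1, 0): 0.04,
    (0, 0): 0.03,
}


@dataclass
class CohortSpec:
    population_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_POPS)
    )
    n_tandem_pairs: int = 240
    n_inverted: int = 8
    n_diff_strand: int = 6
    n_interchrom: int = 8
    n_background_genes: int = 30
    n_subthreshold: int = 18      # tandem calls with split_reads <= 2
    n_repeat_overlap: int = 10    # tandem calls dropped by the repeat filter
    n_testable: int = 6           # fusions with pooled frequency > 5%
    testable_frequency: tuple[float, float] = (0.15, 0.25)
    causal_or: float = 6.0
    causal_maf: float = 0.3
    n_null_variants: int = 99
    known_fraction: float = 0.85  # fraction of tandem fusions marked known
    fg_intron5_median: float = 2516.0
    fg_intron3_median: float = 3734.0
    bg_intron5_median: float = 1400.0
    bg_intron3_median: float = 1164.0
    intron_sigma: float = 0.6
    partner_rpkm_median: float = 5.45
    chimera_rpkm_median: float = 1.33
    rpkm_sigma: float = 0.8
    zero_expression_population: Optional[str] = None
    n_polya_reads: int = 200

    def validate(self) -> None:
        if any(v <= 0 for v in self.population_sizes.values()):
            raise ValueError("population sizes must be positive")
        if self.causal_or <= 0:
            raise ValueError("causal OR must be positive")
        dropped = self.n_subthreshold + self.n_repeat_overlap
        if dropped + self.n_testable > self.n_tandem_pairs:
            raise ValueError(
                "infeasible spec: subthreshold + repeat-overlap + testable "
                f"({dropped + self.n_testable}) exceeds n_tandem_pairs "
                f"({self.n_tandem_pairs})"
            )
        for m in (self.fg_intron5_median, self.fg_intron3_median,
                  self.bg_intron5_median, self.bg_intron3_median,
                  self.partner_rpkm_median, self.chimera_rpkm_median):
            if m <= 0:
                raise ValueError("medians must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.population_sizes.values())


@dataclass
class PairPlan:
    fusion_id: str
    chrom: str
    strand: Strand
    orientation: OrientationClass
    klass: Optional[StructuralClass]
    pattern: tuple[int, int]
    gene5_id: str
    gene3_id: str
    bp1: int = -1
    bp2: int = -1
    f5_index: int = -1   # fusion exon of the 5' primary transcript (tx order)
    b3_index: int = -1
    boundary5: str = "AT_BOUNDARY"
    boundary3: str = "AT_BOUNDARY"
    l5_mod3: Optional[int] = None
    s3_mod3: Optional[int] = None
    intron5_len: Optional[int] = None
    intron3_len: Optional[int] = None
    split_reads: int = 0
    subthreshold: bool = False
    repeat_overlap: bool = False
    testable: bool = False
    known: bool = True
    carriers: frozenset[str] = frozenset()
    causal_variant: Optional[str] = None

    @property
    def kept(self) -> bool:
        return self.split_reads > 2 and not self.repeat_overlap


@dataclass
class SyntheticStudy:
    spec: CohortSpec
    seed: int
    genes: list[GeneModel]
    annotation: dict[str, GeneModel]
    calls: list[FusionCall]
    plans: list[PairPlan]
    cohort: Cohort
    variants: list[VariantRecord]
    expression: ExpressionTable
    repeats: list[GenomicInterval]
    polya_sites: list[GenomicInterval]
    rbp_sites: list[GenomicInterval]
    reads: list[FastqRead]
    read_labels: dict[str, str]
    known_pairs: list[tuple[str, str]]
    truth: dict


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _lognormal_length(rng: np.random.Generator, median: float, sigma: float,
                      minimum: int = 30) -> int:
    return max(minimum, int(round(float(rng.lognormal(np.log(median), sigma)))))


def _build_gene(
    gene_id: str,
    chrom: str,
    strand: Strand,
    left_start: int,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    cds_range: Optional[tuple[int, int]],
    n_isoforms: int,
    rng: np.random.Generator,
) -> GeneModel:
    """Build a gene from transcription-order exon/intron lengths.

    ``cds_range`` is a half-open range in transcript (spliced) coordinates.
    Isoforms beyond the primary trim the transcript's outer tips only.
    """
    m = len(exon_lens)
    assert len(intron_lens) == m - 1
    minus = strand is Strand.MINUS
    order = list(reversed(range(m))) if minus else list(range(m))
    genomic: dict[int, tuple[int, int]] = {}
    cur = left_start
    for pos, i in enumerate(order):
        genomic[i] = (cur, cur + exon_lens[i])
        cur += exon_lens[i]
        if pos < m - 1:
            nxt = order[pos + 1]
            gap_idx = min(i, nxt)  # tx intron between exon j and j+1
            cur += intron_lens[gap_idx]

    def exon_iv(i: int) -> GenomicInterval:
        s, e = genomic[i]
        return GenomicInterval(chrom, s, e, strand)

    def cds_pieces(lo: int, hi: int,
                   exon_clip: dict[int, tuple[int, int]]) -> list[GenomicInterval]:
        pieces = []
        offset = 0
        for i in range(m):
            s, e = exon_clip.get(i, genomic[i])
            ln = e - s
            t0, t1 = offset, offset + ln
            a, b = max(lo, t0), min(hi, t1)
            if a < b:
                if minus:
                    pieces.append(GenomicInterval(chrom, e - (b - t0), e - (a - t0), strand))
                else:
                    pieces.append(GenomicInterval(chrom, s + (a - t0), s + (b - t0), strand))
            offset = t1
        return pieces

    transcripts: list[TranscriptModel] = []
    for j in range(n_isoforms):
        clip: dict[int, tuple[int, int]] = {}
        if j > 0:
            t_trim = int(rng.integers(3, 11))
            u_trim = int(rng.integers(3, 11))
            s0, e0 = genomic[0]
            clip[0] = (s0, e0 - t_trim) if minus else (s0 + t_trim, e0)
            sl, el = genomic[m - 1]
            if m - 1 in clip:  # single-exon gene: apply both trims
                s_prev, e_prev = clip[0]
                clip[0] = (s_prev + u_trim, e_prev) if minus else (s_prev, e_prev - u_trim)
            else:
                clip[m - 1] = (sl + u_trim, el) if minus else (sl, el - u_trim)
        # tx index order 0..m-1 is transcription order by construction
        tx_exons = [
            GenomicInterval(chrom, *clip.get(i, genomic[i]), strand)
            for i in range(m)
        ]
        cds = []
        if cds_range is not None:
            lo, hi = cds_range
            if j > 0:
                # the first-exon tip trim shifts all spliced coordinates
                if minus:
                    first_trim = genomic[0][1] - clip[0][1]
                else:
                    first_trim = clip[0][0] - genomic[0][0]
                lo = max(0, lo - first_trim)
                hi = max(lo, hi - first_trim)
            cds = cds_pieces(lo, hi, clip)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{j}",
                gene_id=gene_id,
                strand=strand,
                exons=tx_exons,
                cds=cds,
            )
        )
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        strand=strand,
        chrom=chrom,
        transcripts=transcripts,
    )


def _plan_pair_geometry(
    rng: np.random.Generator,
    spec: CohortSpec,
    klass: Optional[StructuralClass],
    pattern: tuple[int, int],
) -> dict:
    """Draw exon/intron lengths and CDS ranges realizing ``klass`` with
    exclusion pattern ``pattern`` on the primary transcript pair."""
    a, b = pattern
    # clamp patterns to what the class can realize
    if klass in (StructuralClass.PROMOTER_SWAP, StructuralClass.IN_FRAME,
                 StructuralClass.OUT_OF_FRAME):
        a = max(a, 1)
    if klass in (StructuralClass.UTR3_SWAP, StructuralClass.IN_FRAME,
                 StructuralClass.OUT_OF_FRAME):
        b = max(b, 1)

    m = a + int(rng.integers(4, 7))          # 5' partner exon count
    k = b + int(rng.integers(4, 7))          # 3' partner exon count
    e5 = [int(rng.integers(80, 260)) for _ in range(m)]
    e3 = [int(rng.integers(80, 260)) for _ in range(k)]
    f5 = m - 1 - a
    b3 = b

    def intron_set(n: int, fg_index: Optional[int], fg_median: float,
                   bg_median: float) -> list[int]:
        out = []
        for i in range(n):
            med = fg_median if i == fg_index else bg_median
            out.append(_lognormal_length(rng, med, spec.intron_sigma))
        return out

    i5 = intron_set(m - 1, f5 if a >= 1 else None,
                    spec.fg_intron5_median, spec.bg_intron5_median)
    i3 = intron_set(k - 1, b3 - 1 if b >= 1 else None,
                    spec.fg_intron3_median, spec.bg_intron3_median)

    E = np.concatenate([[0], np.cumsum(e5)])  # tx offsets of 5' exon starts
    j5 = int(E[f5 + 1])                       # junction offset (first excluded)
    etot5 = int(E[-1])
    l5_mod = s3_mod = None

    if klass is StructuralClass.PROMOTER_SWAP:
        cds5 = (j5 + 6, j5 + 6 + 3 * max(1, (etot5 - 12 - j5) // 3))
    elif klass in (StructuralClass.GENUINE_READ_THROUGH, StructuralClass.UTR3_SWAP):
        cs = e5[0]
        cds5 = (cs, cs + 3 * max(1, (j5 - 6 - cs) // 3))
    elif klass in (StructuralClass.IN_FRAME, StructuralClass.OUT_OF_FRAME):
        cs = e5[0]
        r1 = int(rng.integers(0, 3))
        e5[f5] += (r1 - (j5 - cs)) % 3
        E = np.concatenate([[0], np.cumsum(e5)])
        j5 = int(E[f5 + 1])
        etot5 = int(E[-1])
        cds5 = (cs, etot5 - 6)
        l5_mod = (j5 - cs) % 3
    else:  # non-coding 5' partner (unclassifiable control case)
        cds5 = None

    G = np.concatenate([[0], np.cumsum(e3)])
    j3 = int(G[b3])
    etot3 = int(G[-1])

    if klass in (StructuralClass.GENUINE_READ_THROUGH, StructuralClass.PROMOTER_SWAP):
        cds3 = (j3 + 9, j3 + 9 + 3 * max(1, (etot3 - 15 - j3) // 3))
    elif klass is StructuralClass.UTR3_SWAP:
        cds3 = (12, 12 + 3 * max(1, (j3 - 18) // 3))
    elif klass in (StructuralClass.IN_FRAME, StructuralClass.OUT_OF_FRAME):
        r2 = l5_mod if klass is StructuralClass.IN_FRAME else (
            (l5_mod + int(rng.integers(1, 3))) % 3
        )
        e3[b3 - 1] += (r2 - (j3 - 12)) % 3
        G = np.concatenate([[0], np.cumsum(e3)])
        j3 = int(G[b3])
        etot3 = int(G[-1])
        cds3 = (12, etot3 - 6)
        s3_mod = (j3 - 12) % 3
    else:
        cds3 = None

    return {
        "pattern": (a, b),
        "e5": e5, "i5": i5, "cds5": cds5, "f5": f5,
        "e3": e3, "i3": i3, "cds3": cds3, "b3": b3,
        "l5_mod3": l5_mod, "s3_mod3": s3_mod,
        "intron5_len": i5[f5] if a >= 1 else None,
        "intron3_len": i3[b3 - 1] if b >= 1 else None,
    }


# per-side breakpoint placement relative to the fusion exon boundary; the
# in-exon offsets are multiples of 3 so junction frame is unaffected, and
# intronic offsets never change CDS retention
_BOUNDARY_KINDS = ("AT_BOUNDARY", "NEAR_BOUNDARY", "INTRA_EXON", "INTRONIC")
_BOUNDARY_PROBS = (0.76, 0.08, 0.08, 0.08)
_IN_EXON_OFFSET = {"AT_BOUNDARY": 0, "NEAR_BOUNDARY": 3, "INTRA_EXON": 6}
_INTRON_OFFSET = 8


def _primary_breakpoints(
    gene5: GeneModel, gene3: GeneModel, f5: int, b3: int,
    kind5: str = "AT_BOUNDARY", kind3: str = "AT_BOUNDARY",
) -> tuple[int, int]:
    """bp1 = last retained base of the 5' fusion exon (shifted per ``kind5``);
    bp2 = first retained base of the 3' fusion exon (per ``kind3``)."""
    t5 = gene5.transcripts[0]
    t3 = gene3.transcripts[0]
    e5 = t5.exons[f5]
    e3 = t3.exons[b3]
    minus = gene5.strand is Strand.MINUS
    if kind5 == "INTRONIC":
        bp1 = (e5.start - _INTRON_OFFSET) if minus else (e5.end - 1 + _INTRON_OFFSET)
    else:
        d = _IN_EXON_OFFSET[kind5]
        bp1 = (e5.start + d) if minus else (e5.end - 1 - d)
    if kind3 == "INTRONIC":
        bp2 = (e3.end - 1 + _INTRON_OFFSET) if minus else (e3.start - _INTRON_OFFSET)
    else:
        d = _IN_EXON_OFFSET[kind3]
        bp2 = (e3.end - 1 - d) if minus else (e3.start + d)
    return bp1, bp2


# ---------------------------------------------------------------------------
# [OP] generate_annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[GeneModel], list[PairPlan]]:
    """Gene models for all pairs plus background genes, and the pair plans
    (the truth fragment: class, pattern, breakpoints, flanking introns)."""
    spec.validate()

    class_labels = list(_DEFAULT_CLASS_MIX)
    class_probs = np.array(list(_DEFAULT_CLASS_MIX.values()), dtype=float)
    class_probs /= class_probs.sum()
    patterns = list(_DEFAULT_PATTERN_MIX)
    pattern_probs = np.array(list(_DEFAULT_PATTERN_MIX.values()))
    pattern_probs /= pattern_probs.sum()

    genes: list[GeneModel] = []
    plans: list[PairPlan] = []
    cursors = {"chrS1": 100_000, "chrS2": 100_000}
    chrom_cycle = ["chrS1", "chrS2"]
    gidx = 0

    def next_gene_id() -> str:
        nonlocal gidx
        gidx += 1
        return f"GENE{gidx:05d}"

    def place_pair(chrom: str, strand: Strand, geom: dict,
                   gene5_id: str, gene3_id: str,
                   rng: np.random.Generator) -> tuple[GeneModel, GeneModel]:
        """Place the 5' gene transcriptionally upstream of the 3' gene."""
        gap = int(rng.integers(5_000, 30_000))
        if rng.random() < 0.01:
            gap = int(rng.integers(200_000, 400_000))
        n_iso5 = int(rng.integers(1, 5))
        n_iso3 = int(rng.integers(1, 5))
        cur = cursors[chrom]
        if strand is Strand.MINUS:
            # genomic left-to-right: 3' gene first, then the 5' gene
            g3 = _build_gene(gene3_id, chrom, strand, cur,
                             geom["e3"], geom["i3"], geom["cds3"], n_iso3, rng)
            left_5 = g3.span.end + gap
            g5 = _build_gene(gene5_id, chrom, strand, left_5,
                             geom["e5"], geom["i5"], geom["cds5"], n_iso5, rng)
            cursors[chrom] = g5.span.end + int(rng.integers(30_000, 80_000))
        else:
            g5 = _build_gene(gene5_id, chrom, strand, cur,
                             geom["e5"], geom["i5"], geom["cds5"], n_iso5, rng)
            left_3 = g5.span.end + gap
            g3 = _build_gene(gene3_id, chrom, strand, left_3,
                             geom["e3"], geom["i3"], geom["cds3"], n_iso3, rng)
            cursors[chrom] = g3.span.end + int(rng.integers(30_000, 80_000))
        return g5, g3

    fusion_idx = 0

    def next_fusion_id() -> str:
        nonlocal fusion_idx
        fusion_idx += 1
        return f"FUS{fusion_idx:05d}"

    # --- tandem same-strand pairs -------------------------------------
    for i in range(spec.n_tandem_pairs):
        chrom = chrom_cycle[i % 2]
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        klass = class_labels[int(rng.choice(len(class_labels), p=class_probs))]
        pattern = patterns[int(rng.choice(len(patterns), p=pattern_probs))]
        geom = _plan_pair_geometry(rng, spec, klass, pattern)
        g5_id, g3_id = next_gene_id(), next_gene_id()
        g5, g3 = place_pair(chrom, strand, geom, g5_id, g3_id, rng)
        a, b = geom["pattern"]
        # off-boundary placements are safe only when the fusion exon is
        # internal (isoform tip-trims never move its edges)
        kind5 = (_BOUNDARY_KINDS[int(rng.choice(4, p=_BOUNDARY_PROBS))]
                 if a >= 1 else "AT_BOUNDARY")
        kind3 = (_BOUNDARY_KINDS[int(rng.choice(4, p=_BOUNDARY_PROBS))]
                 if b >= 1 else "AT_BOUNDARY")
        bp1, bp2 = _primary_breakpoints(g5, g3, geom["f5"], geom["b3"],
                                        kind5, kind3)
        genes.extend([g5, g3])
        plans.append(
            PairPlan(
                fusion_id=next_fusion_id(),
                chrom=chrom,
                strand=strand,
                orientation=OrientationClass.TANDEM_SAME_STRAND,
                klass=klass,
                pattern=geom["pattern"],
                gene5_id=g5_id,
                gene3_id=g3_id,
                bp1=bp1,
                bp2=bp2,
                f5_index=geom["f5"],
                b3_index=geom["b3"],
                boundary5=kind5,
                boundary3=kind3,
                l5_mod3=geom["l5_mod3"],
                s3_mod3=geom["s3_mod3"],
                intron5_len=geom["intron5_len"],
                intron3_len=geom["intron3_len"],
            )
        )

    # --- other orientations (cataloged, not characterized) ------------
    def other_pair(orientation: OrientationClass) -> None:
        geom = _plan_pair_geometry(
            rng, spec, StructuralClass.GENUINE_READ_THROUGH, (1, 1)
        )
        g5_id, g3_id = next_gene_id(), next_gene_id()
        if orientation is OrientationClass.INTERCHROM:
            s5 = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            s3 = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            g5 = _build_gene(g5_id, "chrS1", s5, cursors["chrS1"],
                             geom["e5"], geom["i5"], geom["cds5"],
                             int(rng.integers(1, 5)), rng)
            cursors["chrS1"] = g5.span.end + int(rng.integers(30_000, 80_000))
            g3 = _build_gene(g3_id, "chrS2", s3, cursors["chrS2"],
                             geom["e3"], geom["i3"], geom["cds3"],
                             int(rng.integers(1, 5)), rng)
            cursors["chrS2"] = g3.span.end + int(rng.integers(30_000, 80_000))
        elif orientation is OrientationClass.INTRACHROM_DIFF_STRAND:
            chrom = chrom_cycle[int(rng.integers(0, 2))]
            s5 = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            s3 = Strand.MINUS if s5 is Strand.PLUS else Strand.PLUS
            g5 = _build_gene(g5_id, chrom, s5, cursors[chrom],
                             geom["e5"], geom["i5"], geom["cds5"],
                             int(rng.integers(1, 5)), rng)
            g3 = _build_gene(g3_id, chrom, s3,
                             g5.span.end + int(rng.integers(5_000, 30_000)),
                             geom["e3"], geom["i3"], geom["cds3"],
                             int(rng.integers(1, 5)), rng)
            cursors[chrom] = g3.span.end + int(rng.integers(30_000, 80_000))
        else:  # SAME_STRAND_INVERTED: call's 5' partner is downstream
            chrom = chrom_cycle[int(rng.integers(0, 2))]
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            up, down = place_pair(chrom, strand, geom, g5_id, g3_id, rng)
            genes.extend([up, down])
            # the reported 5' partner is the transcriptionally downstream gene
            bp1, bp2 = _primary_breakpoints(down, up, geom["b3"], geom["f5"])
            plans.append(
                PairPlan(
                    fusion_id=next_fusion_id(),
                    chrom=chrom,
                    strand=strand,
                    orientation=orientation,
                    klass=None,
                    pattern=(0, 0),
                    gene5_id=g3_id,   # reported upstream partner = down gene
                    gene3_id=g5_id,
                    bp1=bp1,
                    bp2=bp2,
                )
            )
            return
        genes.extend([g5, g3])
        bp1, bp2 = _primary_breakpoints(g5, g3, geom["f5"], geom["b3"])
        plans.append(
            PairPlan(
                fusion_id=next_fusion_id(),
                chrom="." if orientation is OrientationClass.INTERCHROM else g5.chrom,
                strand=g5.strand,
                orientation=orientation,
                klass=None,
                pattern=(0, 0),
                gene5_id=g5_id,
                gene3_id=g3_id,
                bp1=bp1,
                bp2=bp2,
            )
        )

    for _ in range(spec.n_inverted):
        other_pair(OrientationClass.SAME_STRAND_INVERTED)
    for _ in range(spec.n_diff_strand):
        other_pair(OrientationClass.INTRACHROM_DIFF_STRAND)
    for _ in range(spec.n_interchrom):
        other_pair(OrientationClass.INTERCHROM)

    # --- unfused background genes -------------------------------------
    for _ in range(spec.n_background_genes):
        chrom = chrom_cycle[int(rng.integers(0, 2))]
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        m = int(rng.integers(3, 13))
        e = [int(rng.integers(80, 260)) for _ in range(m)]
        iv = [_lognormal_length(rng, spec.bg_intron5_median, spec.intron_sigma)
              for _ in range(m - 1)]
        etot = sum(e)
        cds = (e[0], e[0] + 3 * max(1, (etot - 6 - e[0]) // 3)) if m > 1 else None
        g = _build_gene(next_gene_id(), chrom, strand, cursors[chrom],
                        e, iv, cds, int(rng.integers(1, 5)), rng)
        cursors[chrom] = g.span.end + int(rng.integers(30_000, 80_000))
        genes.append(g)

    return genes, plans


# ---------------------------------------------------------------------------
# [OP] generate_fusion_truth
# ---------------------------------------------------------------------------

def generate_fusion_truth(
    spec: CohortSpec,
    plans: list[PairPlan],
    cohort: Cohort,
    rng: np.random.Generator,
) -> tuple[list[FusionCall], list[GenomicInterval]]:
    """Assign split-read support, carriers, repeat overlaps and novelty to
    the planned calls; returns the calls and the repeat BED intervals."""
    samples = np.array(cohort.sample_order)
    n = len(samples)
    tandem = [p for p in plans if p.orientation is OrientationClass.TANDEM_SAME_STRAND]

    idx = rng.permutation(len(tandem))
    sub_idx = set(idx[: spec.n_subthreshold].tolist())
    rep_idx = set(idx[spec.n_subthreshold: spec.n_subthreshold + spec.n_repeat_overlap].tolist())
    # testable fusions must survive both filters
    surviving = [i for i in range(len(tandem))
                 if i not in sub_idx and i not in rep_idx]
    test_idx = set(rng.permutation(np.array(surviving))[: spec.n_testable].tolist())

    repeats: list[GenomicInterval] = []
    for i, p in enumerate(tandem):
        p.subthreshold = i in sub_idx
        p.repeat_overlap = i in rep_idx
        p.testable = i in test_idx
        p.split_reads = (
            int(rng.integers(1, 3)) if p.subthreshold
            else 3 + int(rng.poisson(10))
        )
        p.known = bool(rng.random() < spec.known_fraction)
        if p.repeat_overlap:
            repeats.append(
                GenomicInterval(p.chrom, max(0, p.bp1 - 3), p.bp1 + 4,
                                name="simulated_repeat")
            )
        if p.testable:
            lo, hi = spec.testable_frequency
            count = int(round(float(rng.uniform(lo, hi)) * n))
        else:
            count = min(1 + int(rng.geometric(0.35)), 18)
        p.carriers = frozenset(
            rng.choice(samples, size=min(count, n), replace=False).tolist()
        )

    for p in plans:
        if p.orientation is not OrientationClass.TANDEM_SAME_STRAND:
            p.split_reads = 3 + int(rng.poisson(6))
            count = min(1 + int(rng.geometric(0.35)), 10)
            p.carriers = frozenset(
                rng.choice(samples, size=count, replace=False).tolist()
            )
            p.known = bool(rng.random() < 0.5)

    # decoy repeats away from any breakpoint
    breakpoints = {(p.chrom, p.bp1) for p in plans} | {(p.chrom, p.bp2) for p in plans}
    for _ in range(30):
        chrom = "chrS1" if rng.random() < 0.5 else "chrS2"
        start = int(rng.integers(1_000, 50_000))
        iv = GenomicInterval(chrom, start, start + int(rng.integers(100, 400)),
                             name="decoy_repeat")
        if not any(c == chrom and iv.contains(bp) for c, bp in breakpoints):
            repeats.append(iv)

    calls = [
        FusionCall(
            fusion_id=p.fusion_id,
            gene5=p.gene5_id,
            gene3=p.gene3_id,
            chrom5="chrS1" if p.orientation is OrientationClass.INTERCHROM else p.chrom,
            chrom3="chrS2" if p.orientation is OrientationClass.INTERCHROM else p.chrom,
            bp1=p.bp1,
            bp2=p.bp2,
            split_reads=p.split_reads,
            carriers=p.carriers,
        )
        for p in plans
    ]
    return calls, repeats


# ---------------------------------------------------------------------------
# [OP] generate_cohort_genotypes
# ---------------------------------------------------------------------------

def solve_carrier_probabilities(
    odds_ratio: float, maf: float, case_fraction: float
) -> tuple[float, float]:
    """Find (p_case, p_control) carrier probabilities with the requested
    carrier odds ratio whose mixture matches the Hardy-Weinberg carrier
    frequency of ``maf``."""
    if odds_ratio <= 0:
        raise ValueError("carrier OR unattainable: must be positive")
    if not (0.0 < maf < 0.5 + 1e-9) or not (0.0 < case_fraction < 1.0):
        raise ValueError(
            "carrier OR unattainable: need 0 < maf <= 0.5 and "
            "0 < case fraction < 1"
        )
    q = 1.0 - (1.0 - maf) ** 2

    def p_case_of(p_ctrl: float) -> float:
        o = odds_ratio * p_ctrl / (1.0 - p_ctrl)
        return o / (1.0 + o)

    def mix(p_ctrl: float) -> float:
        return case_fraction * p_case_of(p_ctrl) + (1 - case_fraction) * p_ctrl

    lo, hi = 1e-12, 1.0 - 1e-12
    if mix(lo) > q or mix(hi) < q:
        raise ValueError(
            f"carrier OR {odds_ratio} unattainable at MAF {maf} and case "
            f"fraction {case_fraction}; attainable carrier frequency range "
            f"is [{mix(lo):.4g}, {mix(hi):.4g}], target {q:.4g}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mix(mid) < q:
            lo = mid
        else:
            hi = mid
    p_ctrl = 0.5 * (lo + hi)
    return p_case_of(p_ctrl), p_ctrl


def _conditional_dosages(
    rng: np.random.Generator,
    is_case: np.ndarray,
    p_case: float,
    p_ctrl: float,
    maf: float,
) -> np.ndarray:
    """Sample dosages with carrier probability depending on case status;
    het/hom split among carriers follows Hardy-Weinberg proportions."""
    n = is_case.size
    p = np.where(is_case, p_case, p_ctrl)
    carrier = rng.random(n) < p
    hom = rng.random(n) < (maf / (2.0 - maf))
    return np.where(carrier, np.where(hom, 2, 1), 0).astype(int)


def generate_cohort_genotypes(
    spec: CohortSpec,
    plans: list[PairPlan],
    annotation: dict[str, GeneModel],
    cohort: Cohort,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Variants for every testable fusion's locus: one causal intronic
    variant tied to carrier status, null variants at Hardy-Weinberg, plus
    a few low-MAF variants and one deletion to exercise the scan filters."""
    samples = cohort.sample_order
    n = len(samples)
    variants: list[VariantRecord] = []
    bases = ["A", "C", "G", "T"]

    for p in plans:
        if not p.testable:
            continue
        g5 = annotation[p.gene5_id]
        g3 = annotation[p.gene3_id]
        t5 = g5.transcripts[0]
        is_case = np.array([s in p.carriers for s in samples])

        # causal variant in the intron adjacent to the 5' fusion exon
        introns = t5.introns()
        if p.f5_index < len(introns):
            intron = introns[p.f5_index]
        else:  # terminal fusion exon: fall back to the preceding intron
            intron = introns[-1]
        pos0 = (intron.start + intron.end) // 2
        p_case, p_ctrl = solve_carrier_probabilities(
            spec.causal_or, spec.causal_maf, float(is_case.mean())
        )
        dos = _conditional_dosages(rng, is_case, p_case, p_ctrl, spec.causal_maf)
        ref, alt = rng.choice(bases, size=2, replace=False).tolist()
        causal_id = f"var_{p.fusion_id}_causal"
        variants.append(
            VariantRecord(chrom=p.chrom, pos=pos0 + 1, variant_id=causal_id,
                          ref=ref, alt=alt, dosages=dos.tolist())
        )
        p.causal_variant = causal_id

        lo = min(g5.span.start, g3.span.start) - 150
        hi = max(g5.span.end, g3.span.end) + 150
        positions = sorted(
            rng.choice(np.arange(lo, hi), size=spec.n_null_variants + 3,
                       replace=False).tolist()
        )
        for j, q in enumerate(positions[: spec.n_null_variants]):
            f = float(rng.uniform(0.08, 0.5))
            dos = rng.binomial(2, f, size=n)
            ref, alt = rng.choice(bases, size=2, replace=False).tolist()
            variants.append(
                VariantRecord(chrom=p.chrom, pos=int(q) + 1,
                              variant_id=f"var_{p.fusion_id}_null{j:03d}",
                              ref=ref, alt=alt, dosages=dos.tolist())
            )
        # two sub-MAF variants and one deletion (filtered out by default)
        for j, q in enumerate(positions[spec.n_null_variants: spec.n_null_variants + 2]):
            dos = rng.binomial(2, 0.01, size=n)
            ref, alt = rng.choice(bases, size=2, replace=False).tolist()
            variants.append(
                VariantRecord(chrom=p.chrom, pos=int(q) + 1,
                              variant_id=f"var_{p.fusion_id}_rare{j}",
                              ref=ref, alt=alt, dosages=dos.tolist())
            )
        q = positions[-1]
        dos = rng.binomial(2, 0.2, size=n)
        variants.append(
            VariantRecord(chrom=p.chrom, pos=int(q) + 1,
                          variant_id=f"var_{p.fusion_id}_del",
                          ref="ACT", alt="A", dosages=dos.tolist(),
                          is_deletion=True)
        )
    return variants


# ---------------------------------------------------------------------------
# [OP] generate_expression_table
# ---------------------------------------------------------------------------

def generate_expression_table(
    spec: CohortSpec,
    genes: list[GeneModel],
    plans: list[PairPlan],
    annotation: dict[str, GeneModel],
    cohort: Cohort,
    rng: np.random.Generator,
) -> ExpressionTable:
    """Transcript RPKMs: log-normal partner/background genes (positive in
    every population), chimeric genes expressed in carriers only."""
    samples = cohort.sample_order
    n = len(samples)

    rows: list[tuple[str, str, np.ndarray]] = []
    for g in genes:
        vals = rng.lognormal(np.log(spec.partner_rpkm_median), spec.rpkm_sigma, size=n)
        weights = rng.dirichlet(np.ones(len(g.transcripts)))
        for t, w in zip(g.transcripts, weights):
            rows.append((t.transcript_id, g.gene_id, vals * w))

    kept_tandem = [
        p for p in plans
        if p.orientation is OrientationClass.TANDEM_SAME_STRAND and p.kept
    ]
    sample_index = {s: i for i, s in enumerate(samples)}
    for p in kept_tandem:
        call = FusionCall(
            fusion_id=p.fusion_id, gene5=p.gene5_id, gene3=p.gene3_id,
            chrom5=p.chrom, chrom3=p.chrom, bp1=p.bp1, bp2=p.bp2,
            split_reads=p.split_reads, carriers=p.carriers,
        )
        cts = annotate_mod.build_chimeric_transcripts(
            call, annotation[p.gene5_id], annotation[p.gene3_id]
        )
        gene_vals = np.zeros(n)
        carrier_idx = [sample_index[s] for s in p.carriers]
        gene_vals[carrier_idx] = rng.lognormal(
            np.log(spec.chimera_rpkm_median), spec.rpkm_sigma, size=len(carrier_idx)
        )
        weights = rng.dirichlet(np.ones(len(cts)))
        for ct, w in zip(cts, weights):
            rows.append((ct.transcript_id, ct.gene_id, gene_vals * w))

    if spec.zero_expression_population is not None and kept_tandem:
        pop_samples = cohort.samples_of(spec.zero_expression_population)
        target_gene = kept_tandem[0].gene5_id
        cols = [sample_index[s] for s in pop_samples]
        for tid, gid, vals in rows:
            if gid == target_gene:
                vals[cols] = 0.0

    values = pd.DataFrame(
        {tid: vals for tid, _, vals in rows}, index=samples
    ).T
    values.index.name = "transcript_id"
    gene_of = pd.Series({tid: gid for tid, gid, _ in rows}, name="gene_id")
    return ExpressionTable(values=values, gene_of=gene_of)


# ---------------------------------------------------------------------------
# [OP] generate_polyA_reads
# ---------------------------------------------------------------------------

def generate_polyA_reads(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[FastqRead], dict[str, str]]:
    """Labeled mixture of poly(A)-tailed, poly(T)-headed, untailed and
    low-complexity reads."""
    bases = np.array(list("ACGT"))
    no_a = np.array(list("CGT"))
    no_t = np.array(list("ACG"))
    reads: list[FastqRead] = []
    labels: dict[str, str] = {}

    def rand_seq(k: int, alphabet: np.ndarray) -> str:
        return "".join(rng.choice(alphabet, size=k).tolist())

    n_each = max(1, spec.n_polya_reads // 5)
    for i in range(n_each):
        stub = rand_seq(int(rng.integers(25, 60)), bases) + rand_seq(15, no_a)
        tail = "A" * int(rng.integers(10, 26))
        name = f"tailed_{i:04d}"
        reads.append(FastqRead(name, stub + tail, "I" * (len(stub) + len(tail))))
        labels[name] = "tailed"
    for i in range(n_each):
        stub = rand_seq(15, no_t) + rand_seq(int(rng.integers(25, 60)), bases)
        head = "T" * int(rng.integers(10, 26))
        name = f"headed_{i:04d}"
        reads.append(FastqRead(name, head + stub, "I" * (len(stub) + len(head))))
        labels[name] = "headed"
    for i in range(n_each):
        seq = rand_seq(int(rng.integers(40, 80)), bases) + rand_seq(10, no_a)
        name = f"plain_{i:04d}"
        reads.append(FastqRead(name, seq, "I" * len(seq)))
        labels[name] = "plain"
    for i in range(n_each):
        seq = "G" * int(rng.integers(30, 50)) + "A" * 15
        name = f"lowcomp_{i:04d}"
        reads.append(FastqRead(name, seq, "I" * len(seq)))
        labels[name] = "lowcomplexity"
    for i in range(n_each):
        seq = "A" * int(rng.integers(40, 60))
        name = f"alla_{i:04d}"
        reads.append(FastqRead(name, seq, "I" * len(seq)))
        labels[name] = "all_a"
    return reads, labels


# ---------------------------------------------------------------------------
# cohort / interval annotations / orchestration
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> Cohort:
    populations = {}
    order = []
    for pop, size in spec.population_sizes.items():
        for i in range(size):
            sid = f"{pop}{i:03d}"
            populations[sid] = pop
            order.append(sid)
    return Cohort(populations=populations, sample_order=order)


def _generate_interval_annotations(
    spec: CohortSpec,
    plans: list[PairPlan],
    annotation: dict[str, GeneModel],
    variants: list[VariantRecord],
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Poly(A) signal/site features at 5'-partner 3' ends, and RBP-binding
    intervals covering the causal variants (plus decoys)."""
    polya: list[GenomicInterval] = []
    tandem = [p for p in plans
              if p.orientation is OrientationClass.TANDEM_SAME_STRAND]
    for p in tandem:
        g5 = annotation[p.gene5_id]
        span = g5.span
        if g5.strand is Strand.MINUS:
            sig = GenomicInterval(g5.chrom, span.start, span.start + 6,
                                  name=f"{p.gene5_id}|signal")
            site = GenomicInterval(g5.chrom, max(0, span.start - 30),
                                   max(1, span.start - 10),
                                   name=f"{p.gene5_id}|site")
        else:
            sig = GenomicInterval(g5.chrom, span.end - 6, span.end,
                                  name=f"{p.gene5_id}|signal")
            site = GenomicInterval(g5.chrom, span.end + 10, span.end + 30,
                                   name=f"{p.gene5_id}|site")
        polya.extend([sig, site])

    rbp: list[GenomicInterval] = []
    for v in variants:
        if v.variant_id.endswith("_causal") and rng.random() < 0.7:
            rbp.append(
                GenomicInterval(v.chrom, max(0, v.point - 25), v.point + 25,
                                name="PABPC1")
            )
    for _ in range(20):
        chrom = "chrS1" if rng.random() < 0.5 else "chrS2"
        start = int(rng.integers(1_000, 2_000_000))
        rbp.append(GenomicInterval(chrom, start, start + 50, name="ELAVL1"))
    return polya, rbp


def _truth_dict(spec: CohortSpec, seed: int, plans: list[PairPlan],
                read_labels: dict[str, str]) -> dict:
    return {
        "seed": seed,
        "n_samples": spec.n_samples,
        "population_sizes": spec.population_sizes,
        "fusions": {
            p.fusion_id: {
                "gene5": p.gene5_id,
                "gene3": p.gene3_id,
                "orientation": p.orientation.value,
                "structural_class": p.klass.value if p.klass else None,
                "pattern": list(p.pattern),
                "boundary5": p.boundary5,
                "boundary3": p.boundary3,
                "l5_mod3": p.l5_mod3,
                "s3_mod3": p.s3_mod3,
                "bp1": p.bp1,
                "bp2": p.bp2,
                "split_reads": p.split_reads,
                "subthreshold": p.subthreshold,
                "repeat_overlap": p.repeat_overlap,
                "kept": p.kept,
                "testable": p.testable,
                "known": p.known,
                "carriers": sorted(p.carriers),
                "causal_variant": p.causal_variant,
                "causal_or": spec.causal_or if p.testable else None,
                "intron5_len": p.intron5_len,
                "intron3_len": p.intron3_len,
            }
            for p in plans
        },
        "read_labels": read_labels,
    }


def simulate_study(spec: Optional[CohortSpec] = None, seed: int = 0) -> SyntheticStudy:
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    genes, plans = generate_annotation(spec, rng)
    annotation = build_gene_index(genes)
    cohort = generate_cohort(spec)
    calls, repeats = generate_fusion_truth(spec, plans, cohort, rng)
    variants = generate_cohort_genotypes(spec, plans, annotation, cohort, rng)
    expression = generate_expression_table(spec, genes, plans, annotation, cohort, rng)
    polya_sites, rbp_sites = _generate_interval_annotations(
        spec, plans, annotation, variants, rng
    )
    reads, read_labels = generate_polyA_reads(spec, rng)
    known_pairs = [
        (p.gene5_id, p.gene3_id) for p in plans if p.known
    ]
    return SyntheticStudy(
        spec=spec,
        seed=seed,
        genes=genes,
        annotation=annotation,
        calls=calls,
        plans=plans,
        cohort=cohort,
        variants=variants,
        expression=expression,
        repeats=repeats,
        polya_sites=polya_sites,
        rbp_sites=rbp_sites,
        reads=reads,
        read_labels=read_labels,
        known_pairs=known_pairs,
        truth=_truth_dict(spec, seed, plans, read_labels),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "fusions": outdir / "fusions.tsv",
        "genotypes": outdir / "genotypes.vcf",
        "rpkm": outdir / "rpkm.tsv",
        "repeats": outdir / "repeats.bed",
        "polya_sites": outdir / "polya_sites.bed",
        "rbp_sites": outdir / "rbp_sites.bed",
        "reads": outdir / "reads.fastq",
        "cohort": outdir / "cohort.tsv",
        "known": outdir / "known_chimeras.tsv",
        "truth": outdir / "truth.json",
    }
    write_gtf(study.genes, paths["annotation"])
    write_fusion_table(study.calls, paths["fusions"])
    write_vcf(study.variants, study.cohort.sample_order, paths["genotypes"])
    write_rpkm_table(study.expression, paths["rpkm"])
    write_bed(study.repeats, paths["repeats"])
    write_bed(study.polya_sites, paths["polya_sites"])
    write_bed(study.rbp_sites, paths["rbp_sites"])
    write_fastq(study.reads, paths["reads"])
    write_cohort(study.cohort, paths["cohort"])
    with open(paths["known"], "w") as fh:
        fh.write("gene5\tgene3\n")
        for g5, g3 in study.known_pairs:
            fh.write(f"{g5}\t{g3}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# focused association locus (for power/type-I studies)
# ---------------------------------------------------------------------------

def simulate_association_locus(
    n_samples: int = 462,
    fusion_frequency: float = 0.2,
    causal_or: Optional[float] = 6.0,
    causal_maf: float = 0.3,
    n_null_variants: int = 99,
    seed: int = 0,
) -> tuple[FusionCall, list[VariantRecord], Cohort]:
    """A single fusion with carriers plus variants for scan studies.

    ``causal_or=None`` yields a pure-null locus (no causal variant,
    ``n_null_variants + 1`` nulls so the family size stays comparable).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    cohort = Cohort(populations={s: "POP" for s in samples})
    n_carriers = int(round(fusion_frequency * n_samples))
    carrier_idx = rng.choice(n_samples, size=n_carriers, replace=False)
    carriers = frozenset(samples[i] for i in carrier_idx)
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[carrier_idx] = True

    variants: list[VariantRecord] = []
    if causal_or is not None:
        p_case, p_ctrl = solve_carrier_probabilities(
            causal_or, causal_maf, fusion_frequency
        )
        dos = _conditional_dosages(rng, is_case, p_case, p_ctrl, causal_maf)
        variants.append(
            VariantRecord(chrom="chrS1", pos=500_000, variant_id="causal",
                          ref="G", alt="A", dosages=dos.tolist())
        )
    n_null = n_null_variants + (0 if causal_or is not None else 1)
    for j in range(n_null):
        f = float(rng.uniform(0.08, 0.5))
        dos = rng.binomial(2, f, size=n_samples)
        variants.append(
            VariantRecord(chrom="chrS1", pos=510_000 + j * 100,
                          variant_id=f"null{j:03d}", ref="C", alt="T",
                          dosages=dos.tolist())
        )
    call = FusionCall(
        fusion_id="FUS_LOCUS", gene5="GENEA", gene3="GENEB",
        chrom5="chrS1", chrom3="chrS1", bp1=400_000, bp2=450_000,
        split_reads=10, carriers=carriers,
    )
    return call, variants, cohort
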