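"""Case/control association of chimera presence with genetic variants.

Per fusion: carriers are cases, all other cohort samples controls.  Variants
in the partner-gene loci (+/- a flank) with MAF above threshold are tested
with the Cochran-Armitage trend test; Bonferroni correction uses the number
of variants tested for that fusion.  Also: interval annotation of variants
(RBP sites, poly(A) features) and poly(A)-read selection from FASTQ.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import PopulationFrequency
from .io_formats import FastqRead
from .models import (
    MISSING,
    Cohort,
    FusionCall,
    GeneModel,
    GenomicInterval,
    VariantRecord,
)
from .stats import (
    OddsRatioResult,
    TrendTable,
    bonferroni_adjust,
    carrier_odds_ratio,
    cochran_armitage_trend,
    minor_allele_frequency,
)

logger = logging.getLogger(__name__)


def select_testable_fusions(
    frequencies: Mapping[str, PopulationFrequency], min_freq: float = 0.05
) -> list[str]:
    """Fusions with pooled carrier frequency strictly above ``min_freq``."""
    return [
        fid
        for fid, pf in frequencies.items()
        if pf.combined_frequency > min_freq
    ]


def variants_in_fusion_interval(
    call: FusionCall,
    annotation: Mapping[str, GeneModel],
    variants: Sequence[VariantRecord],
    flank: int = 200,
) -> list[VariantRecord]:
    """Variants inside either partner-gene span extended by ``flank`` nt."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    spans = []
    for g in (call.gene5, call.gene3):
        s = annotation[g].span
        spans.append((s.chrom, max(0, s.start - flank), s.end + flank))
    return [
        v
        for v in variants
        if any(c == v.chrom and lo <= v.point < hi for c, lo, hi in spans)
    ]


@dataclass
class AssociationResult:
    fusion_id: str
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    raw_p: float
    adjusted_p: float
    statistic: float
    or_result: OddsRatioResult
    n_cases: int
    n_controls: int
    tested_m: int
    maf: float
    significant: bool


def _trend_and_or(
    dosages: np.ndarray, is_case: np.ndarray
) -> tuple[TrendTable, OddsRatioResult]:
    ok = dosages != MISSING
    case_d = dosages[ok & is_case]
    ctrl_d = dosages[ok & ~is_case]
    table = TrendTable(
        *(int((case_d == k).sum()) for k in (0, 1, 2)),
        *(int((ctrl_d == k).sum()) for k in (0, 1, 2)),
    )
    orr = carrier_odds_ratio(
        a=int((case_d >= 1).sum()),
        b=int((case_d == 0).sum()),
        c=int((ctrl_d >= 1).sum()),
        d=int((ctrl_d == 0).sum()),
    )
    return table, orr


def fusion_case_control_scan(
    call: FusionCall,
    variants: Sequence[VariantRecord],
    cohort: Cohort,
    maf_min: float = 0.05,
    include_indels: bool = False,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Trend-test every eligible variant against carrier status of the call.

    MAF filter is strict (> maf_min); the Bonferroni family is the set of
    variants actually tested for this fusion.
    """
    samples = cohort.sample_order
    is_case = np.array([s in call.carriers for s in samples])

    eligible: list[tuple[VariantRecord, np.ndarray, float]] = []
    for v in variants:
        if not include_indels and not v.is_snv:
            continue
        d = np.asarray(v.dosages)
        if (d == MISSING).all():
            logger.warning("%s: all genotypes missing; skipped", v.variant_id)
            continue
        maf = minor_allele_frequency(v.dosages)
        if maf <= maf_min:
            continue
        eligible.append((v, d, maf))

    m = len(eligible)
    results: list[AssociationResult] = []
    for v, d, maf in eligible:
        table, orr = _trend_and_or(d, is_case)
        stat, raw_p = cochran_armitage_trend(table)
        adj = bonferroni_adjust(raw_p, m)
        results.append(
            AssociationResult(
                fusion_id=call.fusion_id,
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                raw_p=raw_p,
                adjusted_p=adj,
                statistic=stat,
                or_result=orr,
                n_cases=table.n_cases,
                n_controls=table.n_controls,
                tested_m=m,
                maf=maf,
                significant=adj < alpha,
            )
        )
    return results


def top_variant_per_fusion(
    results: Iterable[AssociationResult],
) -> dict[str, AssociationResult]:
    """Most significant variant per fusion; ties broken by genomic position
    then variant id."""
    best: dict[str, AssociationResult] = {}
    for r in sorted(results, key=lambda r: (r.raw_p, r.pos, r.variant_id)):
        best.setdefault(r.fusion_id, r)
    return best


def overlap_variants_with_features(
    variants: Sequence[VariantRecord],
    features: Sequence[GenomicInterval],
) -> dict[str, list[str]]:
    """Labels of all feature intervals containing each variant's position
    (half-open)."""
    out: dict[str, list[str]] = {}
    for v in variants:
        labels = [
            f.name or f"{f.chrom}:{f.start}-{f.end}"
            for f in features
            if f.chrom == v.chrom and f.contains(v.point)
        ]
        out[v.variant_id] = labels
    return out


@dataclass
class PolyAVariantHit:
    gene_id: str
    feature: GenomicInterval
    feature_type: str
    variant: VariantRecord
    maf: float
    is_deletion: bool


@dataclass
class PolyAScreenReport:
    hits: list[PolyAVariantHit] = field(default_factory=list)
    genes_without_features: list[str] = field(default_factory=list)


def polyA_variant_screen(
    gene5_ids: Sequence[str],
    variants: Sequence[VariantRecord],
    polyA_features: Sequence[GenomicInterval],
    fusion_frequency_of_gene: Mapping[str, float],
) -> PolyAScreenReport:
    """Deletions/SNPs in each 5'-partner gene's poly(A) features, keeping only
    variants with MAF at or above that fusion's pooled frequency.

    Feature intervals carry names "<gene_id>|<feature_type>".
    """
    report = PolyAScreenReport()
    by_gene: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for f in polyA_features:
        if f.name and "|" in f.name:
            gid, ftype = f.name.split("|", 1)
        else:
            gid, ftype = (f.name or ""), "site"
        by_gene.setdefault(gid, []).append((f, ftype))

    for gid in gene5_ids:
        feats = by_gene.get(gid)
        if not feats:
            report.genes_without_features.append(gid)
            continue
        freq = fusion_frequency_of_gene.get(gid, 0.0)
        for f, ftype in feats:
            for v in variants:
                if v.chrom != f.chrom or not f.contains(v.point):
                    continue
                maf = minor_allele_frequency(v.dosages)
                if maf < freq:
                    continue
                report.hits.append(
                    PolyAVariantHit(
                        gene_id=gid,
                        feature=f,
                        feature_type=ftype,
                        variant=v,
                        maf=maf,
                        is_deletion=v.is_deletion,
                    )
                )
    return report


# ---------------------------------------------------------------------------
# poly(A)-read selection
# ---------------------------------------------------------------------------

def _longest_tail(seq: str, base: str, from_end: bool, max_other_fraction: float) -> int:
    """Longest run at one end of ``seq`` made of ``base`` with at most
    ``max_other_fraction`` other characters, ending in ``base`` itself."""
    it = reversed(seq) if from_end else iter(seq)
    best = 0
    others = 0
    for i, ch in enumerate(it, start=1):
        if ch != base:
            others += 1
        if others > max_other_fraction * i:
            break
        if ch == base:
            best = i
    return best


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) over overlapping dinucleotides."""
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def polyA_read_selection(
    reads: Sequence[FastqRead],
    min_tail: int = 8,
    max_other_fraction: float = 0.1,
    complexity_threshold: float = 1.0,
    min_stub: int = 20,
) -> list[FastqRead]:
    """Keep reads with a 3' poly(A) tail or a 5' poly(T) head; trim the
    tail/head and drop reads whose remainder is short or low-complexity."""
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    out: list[FastqRead] = []
    for r in reads:
        tail = _longest_tail(r.seq, "A", from_end=True,
                             max_other_fraction=max_other_fraction)
        head = _longest_tail(r.seq, "T", from_end=False,
                             max_other_fraction=max_other_fraction)
        if tail >= min_tail and tail >= head:
            stub_seq, stub_qual = r.seq[:-tail], r.qual[:-tail]
        elif head >= min_tail:
            stub_seq, stub_qual = r.seq[head:], r.qual[head:]
        else:
            continue
        if len(stub_seq) < min_stub:
            continue
        if dinucleotide_entropy(stub_seq) < complexity_threshold:
            continue
        out.append(FastqRead(r.name, stub_seq, stub_qual))
    return out
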