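"""Shared test helpers: tiny hand-built gene models and independent oracles.

The oracles here deliberately use brute-force / position-enumeration logic so
they stay independent of the package's interval arithmetic.
"""

from __future__ import annotations

import math

import numpy as np

from tandemchimera.models import (
    GeneModel,
    GenomicInterval,
    Strand,
    TranscriptModel,
)


def make_transcript(tid, gid, strand, exons, cds=(), chrom="chrT"):
    """exons/cds are (start, end) tuples given in transcription order."""
    s = Strand(strand)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        strand=s,
        exons=[GenomicInterval(chrom, a, b, s) for a, b in exons],
        cds=[GenomicInterval(chrom, a, b, s) for a, b in cds],
    )


def make_gene(gid, strand, exons, cds=(), chrom="chrT", name=None):
    t = make_transcript(f"{gid}.t0", gid, strand, exons, cds, chrom)
    return GeneModel(
        gene_id=gid, gene_name=name or gid, strand=Strand(strand),
        chrom=chrom, transcripts=[t],
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_ks_d(x, y):
    """sup |ECDF_x - ECDF_y| over all pooled sample points."""
    pts = sorted(set(x) | set(y))
    n, m = len(x), len(y)
    return max(
        abs(sum(v <= t for v in x) / n - sum(v <= t for v in y) / m)
        for t in pts
    )


def textbook_trend_stat(r, s, w=(0.0, 1.0, 2.0)):
    """Trend chi-square via the standard proportions-form formula (a different
    algebraic arrangement from the packaged implementation)."""
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    w = np.asarray(w, float)
    n = r + s
    big_r, big_s = r.sum(), s.sum()
    big_n = big_r + big_s
    if big_r == 0 or big_s == 0 or (n > 0).sum() < 2:
        return 0.0
    t = (w * r).sum() - big_r * (w * n).sum() / big_n
    denom = (
        (big_r / big_n) * (big_s / big_n)
        * ((w**2 * n).sum() - (w * n).sum() ** 2 / big_n)
    )
    return 0.0 if denom <= 0 else float(t * t / denom)


def exact_trend_distribution(n0, n1, n2, big_r):
    """Exact permutation distribution of the trend statistic given fixed
    dosage-column margins: [(stat, probability), ...]."""
    big_n = n0 + n1 + n2
    out = []
    for r0 in range(min(n0, big_r) + 1):
        for r1 in range(min(n1, big_r - r0) + 1):
            r2 = big_r - r0 - r1
            if r2 < 0 or r2 > n2:
                continue
            prob = (
                math.comb(n0, r0) * math.comb(n1, r1) * math.comb(n2, r2)
                / math.comb(big_n, big_r)
            )
            stat = textbook_trend_stat(
                (r0, r1, r2), (n0 - r0, n1 - r1, n2 - r2)
            )
            out.append((stat, prob))
    return out


def _tx_sorted_positions(intervals, strand):
    pos = []
    for iv in intervals:
        pos.extend(range(iv.start, iv.end))
    pos.sort(reverse=(Strand(strand) is Strand.MINUS))
    return pos


def fused_sequence_frame_oracle(t5, t3, bp1, bp2):
    """Build the fused coding sequence base by base and check whether the
    retained 3'-partner bases keep their native codon phase."""

    def key(p, strand):
        return p if Strand(strand) is not Strand.MINUS else -p

    cds5 = _tx_sorted_positions(t5.cds, t5.strand)
    retained5 = [p for p in cds5 if key(p, t5.strand) <= key(bp1, t5.strand)]
    cds3 = _tx_sorted_positions(t3.cds, t3.strand)
    retained3 = [p for p in cds3 if key(p, t3.strand) >= key(bp2, t3.strand)]
    if not retained3:
        raise ValueError("no 3' CDS retained; frame undefined")
    # fused index of the first retained 3' base vs its native CDS index
    fused_index = len(retained5)
    native_index = cds3.index(retained3[0])
    return "IN_FRAME" if fused_index % 3 == native_index % 3 else "OUT_OF_FRAME"


def brute_exclusion_pattern(t5, t3, bp1, bp2):
    """(k5, k3) by scanning every exon base: an exon is excluded iff all of
    its bases lie beyond bp1 (5' side) / before bp2 (3' side) in
    transcription order."""

    def key(p, strand):
        return p if Strand(strand) is not Strand.MINUS else -p

    k5 = sum(
        1
        for e in t5.exons
        if all(key(p, t5.strand) > key(bp1, t5.strand)
               for p in range(e.start, e.end))
    )
    k3 = sum(
        1
        for e in t3.exons
        if all(key(p, t3.strand) < key(bp2, t3.strand)
               for p in range(e.start, e.end))
    )
    return k5, k3
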