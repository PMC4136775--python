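import numpy as np
import pytest

from tandemchimera import characterize as ch
from tandemchimera.models import (
    FusionCall,
    GeneModel,
    Strand,
    StructuralClass,
)
from util import (
    brute_exclusion_pattern,
    fused_sequence_frame_oracle,
    make_gene,
    make_transcript,
)


def call(bp1, bp2, gene5="GA", gene3="GB", fid="F1"):
    return FusionCall(fid, gene5, gene3, "chrT", "chrT", bp1, bp2, 5,
                      frozenset({"s1"}))


EXONS5 = [(0, 100), (200, 300), (400, 500), (600, 700)]
EXONS3 = [(10_000, 10_100), (10_200, 10_300), (10_400, 10_500)]


def _pair(cds5, cds3):
    return (
        make_gene("GA", "+", EXONS5, cds=cds5),
        make_gene("GB", "+", EXONS3, cds=cds3),
    )


class TestClassifyStructure:
    def test_promoter_swap(self):
        # 5' CDS wholly beyond the breakpoint; 3' CDS fully retained
        g5, g3 = _pair([(600, 690)], [(10_210, 10_300)])
        cls, _, _ = ch.classify_structure(call(299, 10_200), g5, g3)
        assert cls is StructuralClass.PROMOTER_SWAP

    def test_genuine_read_through(self):
        g5, g3 = _pair([(210, 291)], [(10_210, 10_300)])
        cls, _, _ = ch.classify_structure(call(299, 10_200), g5, g3)
        assert cls is StructuralClass.GENUINE_READ_THROUGH

    def test_utr3_swap(self):
        g5, g3 = _pair([(210, 291)], [(10_010, 10_070)])
        cls, _, _ = ch.classify_structure(call(299, 10_200), g5, g3)
        assert cls is StructuralClass.UTR3_SWAP

    def test_truncated_both_uses_frame(self):
        g5, g3 = _pair([(200, 300), (400, 500)],
                       [(10_050, 10_100), (10_200, 10_260)])
        c = call(298, 10_201)  # L5 = 99, S3 = 51: both 0 mod 3
        cls, t5, t3 = ch.classify_structure(c, g5, g3)
        assert cls is StructuralClass.IN_FRAME
        assert cls.value == fused_sequence_frame_oracle(t5, t3, c.bp1, c.bp2)

    def test_noncoding_5prime_complete_3prime_is_promoter_swap(self):
        g5, g3 = _pair([], [(10_210, 10_300)])
        cls, _, _ = ch.classify_structure(call(299, 10_200), g5, g3)
        assert cls is StructuralClass.PROMOTER_SWAP

    def test_both_noncoding_unclassifiable(self):
        g5, g3 = _pair([], [])
        cls, _, _ = ch.classify_structure(call(299, 10_200), g5, g3)
        assert cls is None

    def test_incompatible_breakpoints_error(self):
        g5, g3 = _pair([(210, 291)], [(10_210, 10_300)])
        bad = call(9_000_000, 9_000_001)
        with pytest.raises(ValueError, match="no transcript pair"):
            ch.classify_structure(bad, g5, g3)


class TestJunctionFrame:
    def _single_exon_pair(self):
        g5 = make_gene("GA", "+", [(0, 400)], cds=[(50, 400)])
        g3 = make_gene("GB", "+", [(1000, 1400)], cds=[(1044, 1344)])
        return g5.transcripts[0], g3.transcripts[0]

    def test_in_frame_l5_303_s3_6(self):
        t5, t3 = self._single_exon_pair()
        c = call(352, 1050)
        assert t5.cds_retained_upstream(352) == 303
        assert t3.cds_excluded_upstream(1050) == 6
        assert ch.junction_frame(c, t5, t3) is StructuralClass.IN_FRAME
        assert fused_sequence_frame_oracle(t5, t3, 352, 1050) == "IN_FRAME"

    def test_out_of_frame_l5_304_s3_6(self):
        t5, t3 = self._single_exon_pair()
        c = call(353, 1050)
        assert t5.cds_retained_upstream(353) == 304
        assert ch.junction_frame(c, t5, t3) is StructuralClass.OUT_OF_FRAME
        assert fused_sequence_frame_oracle(t5, t3, 353, 1050) == "OUT_OF_FRAME"

    def test_identity_junction(self):
        t5, t3 = self._single_exon_pair()
        c = call(49, 1044)  # L5 = 0, S3 = 0
        assert ch.junction_frame(c, t5, t3) is StructuralClass.IN_FRAME

    def test_noncoding_partner_error(self):
        t5, _ = self._single_exon_pair()
        t3 = make_transcript("t3", "GB", "+", [(1000, 1400)])
        with pytest.raises(ValueError):
            ch.junction_frame(call(352, 1050), t5, t3)

    def test_agrees_with_fused_sequence_oracle_random(self):
        """1,000 random CDS pairs: interval arithmetic vs explicit base-level
        fused-sequence construction."""
        rng = np.random.default_rng(9)

        def random_transcript(tid, left, strand):
            n = int(rng.integers(2, 6))
            lens = rng.integers(30, 90, size=n)
            gaps = rng.integers(20, 50, size=n - 1)
            # build in transcription order
            tx_exons = []
            cur = left
            coords = []
            for i in range(n):
                coords.append((cur, cur + int(lens[i])))
                cur += int(lens[i]) + (int(gaps[i]) if i < n - 1 else 0)
            if strand == "-":
                # mirror so transcription order has descending coordinates
                hi = cur
                coords = [(left + hi - b, left + hi - a) for a, b in coords]
            total = int(lens.sum())
            lo = int(rng.integers(0, total - 9))
            hi_c = int(rng.integers(lo + 3, total))
            # map spliced CDS range back to genomic pieces
            cds = []
            off = 0
            s = Strand(strand)
            for a, b in coords:
                ln = b - a
                x, y = max(lo, off), min(hi_c, off + ln)
                if x < y:
                    if s is Strand.MINUS:
                        cds.append((b - (y - off), b - (x - off)))
                    else:
                        cds.append((a + (x - off), a + (y - off)))
                off += ln
            return make_transcript(tid, tid, strand, coords, cds)

        def random_breakpoint(t):
            e = t.exons[int(rng.integers(0, len(t.exons)))]
            return int(rng.integers(e.start, e.end))

        checked = 0
        while checked < 1000:
            strand = "+" if rng.random() < 0.5 else "-"
            t5 = random_transcript("t5", 0, strand)
            t3 = random_transcript("t3", 100_000, strand)
            bp1, bp2 = random_breakpoint(t5), random_breakpoint(t3)
            try:
                want = fused_sequence_frame_oracle(t5, t3, bp1, bp2)
            except ValueError:
                continue  # no 3' CDS retained; frame undefined
            c = call(bp1, bp2)
            assert ch.junction_frame(c, t5, t3).value == want
            checked += 1


class TestExclusionPatterns:
    def test_penultimate_and_second(self):
        g5, g3 = _pair([], [])
        pats = ch.exon_exclusion_patterns(call(499, 10_200), g5, g3)
        assert [(p.k5, p.k3, p.weight) for p in pats] == [(1, 1, 1.0)]

    def test_nothing_excluded(self):
        g5, g3 = _pair([], [])
        pats = ch.exon_exclusion_patterns(call(699, 10_000), g5, g3)
        assert [(p.k5, p.k3, p.weight) for p in pats] == [(0, 0, 1.0)]

    def test_multi_isoform_weights_match_brute_force(self):
        t5a = make_transcript("t5a", "GA", "+", EXONS5)
        t5b = make_transcript("t5b", "GA", "+", EXONS5[:3])
        g5 = GeneModel("GA", "GA", Strand.PLUS, "chrT", [t5a, t5b])
        t3s = [
            make_transcript("t3a", "GB", "+", EXONS3),
            make_transcript("t3b", "GB", "+", EXONS3[1:]),
            make_transcript("t3c", "GB", "+", EXONS3[:2]),
        ]
        g3 = GeneModel("GB", "GB", Strand.PLUS, "chrT", t3s)
        c = call(299, 10_400)
        pats = ch.exon_exclusion_patterns(c, g5, g3)
        assert sum(p.weight for p in pats) == pytest.approx(1.0, abs=1e-12)
        from collections import Counter

        want = Counter()
        for t5 in g5.transcripts:
            for t3 in g3.transcripts:
                want[brute_exclusion_pattern(t5, t3, c.bp1, c.bp2)] += 1
        got = {(p.k5, p.k3): p.weight for p in pats}
        assert got == {k: v / 6 for k, v in want.items()}

    def test_aggregate_is_distribution(self, mini_study):
        truth = mini_study.truth["fusions"]
        calls = [
            c for c in mini_study.calls
            if truth[c.fusion_id]["orientation"] == "TANDEM_SAME_STRAND"
        ]
        rows = ch.characterize_all(calls, mini_study.annotation)
        agg = ch.aggregate_patterns([r.patterns for r in rows])
        assert sum(agg.values()) == pytest.approx(1.0, abs=1e-12)


class TestFlankingLengths:
    def test_hand_arithmetic(self):
        g5 = make_gene("GA", "+", [(0, 100), (200, 300), (5000, 5100)])
        g3 = make_gene("GB", "+", [(10_000, 10_100), (10_150, 10_250)])
        fl = ch.flanking_feature_lengths(call(299, 10_150), g5, g3)
        assert fl.intron5 == [4700]
        assert fl.intron3 == [50]
        assert sorted(fl.background_introns) == [100]
        assert fl.exon5 == [100] and fl.exon3 == [100]

    def test_single_intron_background_empty(self):
        g5 = make_gene("GA", "+", [(0, 100), (200, 300)])
        g3 = make_gene("GB", "+", [(10_000, 10_100), (10_150, 10_250)])
        fl = ch.flanking_feature_lengths(call(99, 10_150), g5, g3)
        assert fl.intron5 == [100] and fl.intron3 == [50]
        assert fl.background_introns == []

    def test_terminal_fusion_exon_skipped(self):
        g5 = make_gene("GA", "+", [(0, 100), (200, 300)])
        g3 = make_gene("GB", "+", [(10_000, 10_100), (10_150, 10_250)])
        fl = ch.flanking_feature_lengths(call(299, 10_000), g5, g3)
        assert fl.intron5 == [] and fl.intron3 == []

    def test_length_conservation_identity(self, mini_study):
        for g in mini_study.genes[:40]:
            for t in g.transcripts:
                span = t.span
                assert t.exonic_length + sum(len(i) for i in t.introns()) == \
                    len(span)


class TestCompareLengths:
    def test_identical(self):
        ks, mf, mb = ch.compare_length_distributions([1, 2, 3], [1, 2, 3])
        assert ks.d == 0 and mf == mb

    def test_degenerate_single_values(self):
        ks, _, _ = ch.compare_length_distributions([5], [5])
        assert ks.d == 0.0
        ks, _, _ = ch.compare_length_distributions([1], [5])
        assert ks.d == 1.0

    def test_enrichment_detected_across_seeds(self):
        """Foreground drawn longer than background: median order recovered in
        >= 95% of seeds."""
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fg = rng.lognormal(np.log(2516), 0.6, 150)
            bg = rng.lognormal(np.log(1400), 0.6, 400)
            _, mf, mb = ch.compare_length_distributions(fg, bg)
            wins += mf > mb
        assert wins >= 38


class TestClosedLoop:
    def test_truth_recovery(self, mini_study):
        truth = mini_study.truth["fusions"]
        calls = [
            c for c in mini_study.calls
            if truth[c.fusion_id]["orientation"] == "TANDEM_SAME_STRAND"
        ]
        for r in ch.characterize_all(calls, mini_study.annotation):
            t = truth[r.fusion_id]
            got = r.structural_class.value if r.structural_class else None
            assert got == t["structural_class"]
            assert list(r.selected_pattern) == t["pattern"]
            assert r.transcript5.endswith(".t0")
            assert r.transcript3.endswith(".t0")
            if t["l5_mod3"] is not None:
                assert r.l5_mod3 == t["l5_mod3"]
                assert r.s3_mod3 == t["s3_mod3"]
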