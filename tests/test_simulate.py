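import filecmp
import json

import numpy as np
import pytest

from tandemchimera import associate as assoc
from tandemchimera import simulate as sim


SMALL = dict(n_tandem_pairs=20, n_testable=2, n_subthreshold=3,
             n_repeat_overlap=2, n_background_genes=4, n_inverted=2,
             n_diff_strand=2, n_interchrom=2)


class TestSpecValidation:
    def test_defaults_are_462_samples(self):
        spec = sim.CohortSpec()
        assert spec.n_samples == 462
        assert spec.population_sizes == {
            "CEU": 91, "FIN": 95, "GBR": 94, "TSI": 93, "YRI": 89
        }

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sim.CohortSpec(n_tandem_pairs=5, n_subthreshold=3,
                           n_repeat_overlap=3).validate()

    def test_bad_medians_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortSpec(partner_rpkm_median=0).validate()

    def test_bad_or_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortSpec(causal_or=-1).validate()


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        a = sim.write_study(sim.simulate_study(sim.CohortSpec(**SMALL), seed=4),
                            tmp_path / "a")
        b = sim.write_study(sim.simulate_study(sim.CohortSpec(**SMALL), seed=4),
                            tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_seed_changes_output(self, tmp_path):
        a = sim.write_study(sim.simulate_study(sim.CohortSpec(**SMALL), seed=4),
                            tmp_path / "a")
        b = sim.write_study(sim.simulate_study(sim.CohortSpec(**SMALL), seed=5),
                            tmp_path / "b")
        assert not filecmp.cmp(a["fusions"], b["fusions"], shallow=False)


class TestAnnotationShape:
    def test_model_invariants(self, mini_study):
        for g in mini_study.genes:
            assert 1 <= len(g.transcripts) <= 4
            primary = g.transcripts[0]
            assert 3 <= len(primary.exons) <= 12
            for t in g.transcripts:
                for c in t.cds:
                    assert any(e.start <= c.start and c.end <= e.end
                               for e in t.exons)

    def test_foreground_intron_median_calibrated(self, default_study):
        truth = default_study.truth["fusions"]
        fg5 = [t["intron5_len"] for t in truth.values()
               if t["intron5_len"] is not None]
        fg3 = [t["intron3_len"] for t in truth.values()
               if t["intron3_len"] is not None]
        spec = default_study.spec
        assert len(fg5) >= 200 and len(fg3) >= 200
        assert abs(np.median(fg5) - spec.fg_intron5_median) < \
            0.2 * spec.fg_intron5_median
        assert abs(np.median(fg3) - spec.fg_intron3_median) < \
            0.2 * spec.fg_intron3_median

    def test_breakpoints_inside_gene_spans(self, mini_study):
        for call in mini_study.calls:
            g5 = mini_study.annotation[call.gene5]
            g3 = mini_study.annotation[call.gene3]
            assert g5.span.start <= call.bp1 < g5.span.end or \
                abs(call.bp1 - g5.span.start) <= 8 or \
                abs(call.bp1 - (g5.span.end - 1)) <= 8
            assert g3.span.start <= call.bp2 < g3.span.end or \
                abs(call.bp2 - g3.span.start) <= 8 or \
                abs(call.bp2 - (g3.span.end - 1)) <= 8


class TestFusionTruth:
    def test_testable_fusions_above_threshold(self, mini_study):
        n = len(mini_study.cohort)
        for t in mini_study.truth["fusions"].values():
            if t["testable"]:
                assert len(t["carriers"]) / n > 0.05

    def test_subthreshold_split_reads(self, mini_study):
        for t in mini_study.truth["fusions"].values():
            if t["subthreshold"]:
                assert t["split_reads"] <= 2
            elif t["orientation"] == "TANDEM_SAME_STRAND":
                assert t["split_reads"] >= 3

    def test_repeat_overlap_consistency(self, mini_study):
        covered = mini_study.repeats
        for call in mini_study.calls:
            t = mini_study.truth["fusions"][call.fusion_id]
            hit = any(r.chrom == call.chrom5 and r.contains(call.bp1)
                      for r in covered)
            assert hit == t["repeat_overlap"]

    def test_frequency_spectrum_rare_skewed(self, default_study):
        counts = [len(t["carriers"])
                  for t in default_study.truth["fusions"].values()
                  if t["orientation"] == "TANDEM_SAME_STRAND"
                  and not t["testable"]]
        assert np.median(counts) <= 5


class TestGenotypes:
    def test_solve_carrier_probabilities_matches_or(self):
        for orr in (2.0, 5.0, 19.0):
            p_case, p_ctrl = sim.solve_carrier_probabilities(orr, 0.3, 0.2)
            realized = (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
            assert realized == pytest.approx(orr, rel=1e-6)
            mix = 0.2 * p_case + 0.8 * p_ctrl
            assert mix == pytest.approx(1 - 0.7**2, rel=1e-6)

    def test_unattainable_or_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            sim.solve_carrier_probabilities(0.0, 0.3, 0.2)
        with pytest.raises(ValueError, match="unattainable"):
            sim.solve_carrier_probabilities(2.0, 0.3, 1.0)

    def test_null_variants_independent_of_phenotype(self, mini_study):
        truth = mini_study.truth["fusions"]
        samples = mini_study.cohort.sample_order
        ok = total = 0
        for v in mini_study.variants:
            if "_null" not in v.variant_id:
                continue
            fid = v.variant_id.split("_")[1]
            carriers = set(truth[f"{fid}"]["carriers"])
            case = np.array([s in carriers for s in samples], dtype=float)
            d = np.array(v.dosages, dtype=float)
            r = abs(np.corrcoef(case, d)[0, 1])
            total += 1
            ok += r < 0.2
        assert total > 0 and ok / total >= 0.95

    def test_causal_or_realized_within_2se(self):
        """Realized carrier log-OR within 2 SE of target in >= 90% of seeds."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            call, variants, cohort = sim.simulate_association_locus(
                n_samples=462, causal_or=6.0, n_null_variants=0, seed=seed
            )
            res = assoc.fusion_case_control_scan(call, variants, cohort)
            r = next(x for x in res if x.variant_id == "causal")
            a, b, c, d = r.or_result.table
            se = np.sqrt(sum(1 / max(x, 0.5) for x in (a, b, c, d)))
            hits += abs(np.log(r.or_result.or_value) - np.log(6.0)) <= 2 * se
        assert hits / n_seeds >= 0.9

    def test_low_maf_and_deletion_variants_present(self, mini_study):
        ids = [v.variant_id for v in mini_study.variants]
        assert any(i.endswith("_del") for i in ids)
        assert any("_rare" in i for i in ids)
        dels = [v for v in mini_study.variants if v.variant_id.endswith("_del")]
        assert all(v.is_deletion for v in dels)


class TestExpression:
    def test_noncarriers_zero_carriers_positive(self, mini_study):
        from tandemchimera.annotate import aggregate_gene_rpkm

        gr = aggregate_gene_rpkm(mini_study.expression)
        truth = mini_study.truth["fusions"]
        for fid, t in truth.items():
            if t["orientation"] != "TANDEM_SAME_STRAND" or not t["kept"]:
                continue
            gid = f"FUSION|{t['gene5']}|{t['gene3']}"
            row = gr.loc[gid]
            carriers = set(t["carriers"])
            for s in mini_study.cohort.sample_order:
                if s in carriers:
                    assert row[s] > 0
                else:
                    assert row[s] == 0.0

    def test_partner_positive_in_all_populations(self, mini_study):
        from tandemchimera.annotate import aggregate_gene_rpkm

        gr = aggregate_gene_rpkm(mini_study.expression)
        cohort = mini_study.cohort
        for g in mini_study.genes:
            row = gr.loc[g.gene_id]
            for pop in cohort.population_names:
                assert (row[cohort.samples_of(pop)] > 0).any()

    def test_zero_expression_flag_exercises_filter(self):
        spec = sim.CohortSpec(**SMALL, zero_expression_population="YRI")
        study = sim.simulate_study(spec, seed=2)
        from tandemchimera import catalog as cat
        from tandemchimera.annotate import aggregate_gene_rpkm

        gr = aggregate_gene_rpkm(study.expression)
        truth = study.truth["fusions"]
        kept = [c for c in study.calls
                if truth[c.fusion_id]["kept"]
                and truth[c.fusion_id]["orientation"] == "TANDEM_SAME_STRAND"]
        filtered = cat.expression_presence_filter(kept, gr, study.cohort)
        assert len(filtered) == len(kept) - 1

    def test_aggregation_conserves_totals(self, mini_study):
        from tandemchimera.annotate import aggregate_gene_rpkm

        gr = aggregate_gene_rpkm(mini_study.expression)
        np.testing.assert_allclose(
            gr.sum(axis=0).values,
            mini_study.expression.values.sum(axis=0).values,
        )


class TestPolyAReads:
    def test_closed_loop_recovery(self, mini_study):
        kept = assoc.polyA_read_selection(mini_study.reads)
        kept_names = {r.name for r in kept}
        labels = mini_study.read_labels
        want = {n for n, l in labels.items() if l in ("tailed", "headed")}
        assert kept_names == want

    def test_label_counts_conserved(self, mini_study):
        kept = assoc.polyA_read_selection(mini_study.reads)
        dropped = len(mini_study.reads) - len(kept)
        assert len(kept) + dropped == len(mini_study.reads)
        assert len(mini_study.read_labels) == len(mini_study.reads)


def test_truth_json_consistent_with_files(default_study_dir):
    with open(default_study_dir["truth"]) as fh:
        truth = json.load(fh)
    assert truth["n_samples"] == 462
    from tandemchimera.io_formats import parse_fusion_table, read_cohort

    calls = {c.fusion_id: c for c in parse_fusion_table(default_study_dir["fusions"])}
    assert set(calls) == set(truth["fusions"])
    for fid, t in truth["fusions"].items():
        c = calls[fid]
        assert c.split_reads == t["split_reads"]
        assert sorted(c.carriers) == t["carriers"]
        assert (c.bp1, c.bp2) == (t["bp1"], t["bp2"])
    cohort = read_cohort(default_study_dir["cohort"])
    sizes = {p: len(cohort.samples_of(p)) for p in cohort.population_names}
    assert sizes == truth["population_sizes"]
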