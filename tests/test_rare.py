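"""Four-step rare-CNV cascade: step semantics, brute-force oracle, audit trail."""

import numpy as np
import pytest

from cnvcase.intervals import GenomicInterval, OverlapRule
from cnvcase.io import (
    CNVSegment,
    GeneAnnotation,
    PanelEntry,
    ReferencePanel,
)
from cnvcase.rare import (
    RareCNVReport,
    gene_list_screen,
    run_rare_pipeline,
    step1_case_exclusive,
    step2_population_frequency,
    step3_known_variant_filter,
    step4_caller_concordance,
)

RULE = OverlapRule("reciprocal", 0.5)
ANY = OverlapRule("any")


def seg(sample="S1", chrom="1", start=100, end=200, cn=1, caller="primary_caller", probes=30):
    return CNVSegment(sample, GenomicInterval(chrom, start, end), cn, probes, caller)


def entry(chrom="1", start=100, end=200, kind="loss", freq=None):
    return PanelEntry(GenomicInterval(chrom, start, end), kind, freq)


class TestStep1:
    def test_identical_control_call_removes(self):
        assert step1_case_exclusive([seg()], [seg("K1")], RULE) == []

    def test_type_mismatch_retains(self):
        case_loss = seg(cn=1)
        control_gain = seg("K1", start=150, end=300, cn=3)
        assert step1_case_exclusive([case_loss], [control_gain], RULE) == [case_loss]

    def test_reciprocal_vs_any_rule_sensitivity(self):
        case = seg(start=100, end=200)  # 101 bp
        control = seg("K1", start=150, end=400)  # shared 51 bp: 50.5% vs 20%
        assert step1_case_exclusive([case], [control], RULE) == [case]
        assert step1_case_exclusive([case], [control], ANY) == []


class TestStep2:
    def test_common_entry_removes(self):
        retained, _ = step2_population_frequency(
            [seg()], ReferencePanel("p", [entry(freq=0.05)]), 0.01, RULE
        )
        assert retained == []

    def test_subthreshold_entry_labels_below_one_percent(self):
        s = seg()
        retained, labels = step2_population_frequency(
            [s], ReferencePanel("p", [entry(freq=0.005)]), 0.01, RULE
        )
        assert retained == [s] and labels[s.key] == "< 1%"

    def test_no_match_labels_dash(self):
        s = seg()
        retained, labels = step2_population_frequency(
            [s], ReferencePanel("p", [entry(chrom="2", freq=0.5)]), 0.01, RULE
        )
        assert retained == [s] and labels[s.key] == "-"

    def test_frequency_free_panel_rejected(self):
        with pytest.raises(ValueError, match="step3"):
            step2_population_frequency([seg()], ReferencePanel("p", [entry()]), 0.01, RULE)


class TestStep3:
    def test_known_variant_removes(self):
        assert step3_known_variant_filter([seg()], ReferencePanel("d", [entry()]), RULE) == []

    def test_absent_chromosome_retains(self):
        s = seg(chrom="5")
        assert step3_known_variant_filter([s], ReferencePanel("d", [entry()]), RULE) == [s]

    def test_nested_small_segment_survives_reciprocal_rule(self):
        # 10% of the span of a huge common variant: reciprocal 50% fails
        small = seg(start=1000, end=1099)
        huge = entry(start=1, end=1000_0)
        assert step3_known_variant_filter(
            [small], ReferencePanel("d", [huge]), RULE
        ) == [small]
        assert step3_known_variant_filter(
            [small], ReferencePanel("d", [huge]), ANY
        ) == []


class TestStep4:
    def test_same_sample_replication_retains(self):
        s = seg()
        assert step4_caller_concordance([s], [seg(caller="secondary_caller")], RULE) == [s]

    def test_other_sample_replication_removes(self):
        s = seg()
        other = seg("S2", caller="secondary_caller")
        assert step4_caller_concordance([s], [other], RULE) == []

    def test_sample_absent_from_second_set_removes(self):
        assert step4_caller_concordance([seg()], [], RULE) == []

    def test_mislabeled_second_set_rejected(self):
        with pytest.raises(ValueError, match="secondary_caller"):
            step4_caller_concordance([seg()], [seg("S1")], RULE)


def brute_force_match(a_segments, b_entries, rule):
    """O(n*m) all-pairs same-type matcher: the oracle for every filter."""
    out = []
    for s in a_segments:
        hit = any(
            kind == s.cnv_type and rule.matches(s.interval, iv) for iv, kind in b_entries
        )
        out.append(hit)
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("rule", [RULE, ANY, OverlapRule("reciprocal", 0.8)])
    def test_filters_agree_with_all_pairs_scan(self, rule):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cases = [
                seg("S1", str(rng.integers(1, 4)), s, s + int(rng.integers(1, 400)),
                    int(rng.choice([1, 3])))
                for s in rng.integers(1, 3000, size=60)
            ]
            refs = [
                (GenomicInterval(str(rng.integers(1, 4)), s, s + int(rng.integers(1, 400))),
                 str(rng.choice(["loss", "gain"])))
                for s in rng.integers(1, 3000, size=60)
            ]
            controls = [
                CNVSegment("K1", iv, 1 if kind == "loss" else 3, 30) for iv, kind in refs
            ]
            expected = brute_force_match(cases, refs, rule)
            got = step1_case_exclusive(cases, controls, rule)
            assert got == [s for s, hit in zip(cases, expected) if not hit]
            panel = ReferencePanel("d", [PanelEntry(iv, kind) for iv, kind in refs])
            assert step3_known_variant_filter(cases, panel, rule) == got


class TestPipeline:
    def test_ground_truth_recovery_on_synthetic_cohort(self, default_cohort):
        cfg, samples, segs1, segs2, panels, truth = default_cohort
        case_ids = {s.sample_id for s in samples if s.is_case}
        report = run_rare_pipeline(
            [s for s in segs1 if s.sample_id in case_ids],
            [s for s in segs1 if s.sample_id not in case_ids],
            panels,
            segs2,
            cfg.overlap_rule,
        )
        gt = truth.segment_labels
        want = {
            (r.sample_id, r.chrom, r.start, r.end)
            for r in gt[gt.is_rare].itertuples()
        }
        got = {
            (s.sample_id, s.interval.chrom, s.interval.start, s.interval.end)
            for s in report.rare_segments
        }
        assert got == want  # sensitivity = specificity = 1

    def test_retained_sets_are_nested_and_reasons_partition(self, default_cohort):
        cfg, samples, segs1, segs2, panels, truth = default_cohort
        case_ids = {s.sample_id for s in samples if s.is_case}
        case_segs = [s for s in segs1 if s.sample_id in case_ids]
        report = run_rare_pipeline(
            case_segs,
            [s for s in segs1 if s.sample_id not in case_ids],
            panels,
            segs2,
            cfg.overlap_rule,
        )
        steps = [
            {s.key for s in report.input_segments},
            {s.key for s in report.step1_retained},
            {s.key for s in report.step2_retained},
            {s.key for s in report.step3_retained},
            {s.key for s in report.step4_retained},
        ]
        for outer, inner in zip(steps, steps[1:]):
            assert inner <= outer
        removed = steps[0] - steps[-1]
        assert set(report.removal_reason) == removed

    def test_step_order_independence_within_steps(self):
        cases = [seg("S1", start=s, end=s + 50) for s in (100, 500, 900)]
        controls = [seg("K1", start=100, end=150)]
        a = step1_case_exclusive(cases, controls, RULE)
        b = step1_case_exclusive(list(reversed(cases)), controls, RULE)
        assert {s.key for s in a} == {s.key for s in b}

    def test_empty_case_set_gives_zero_counts(self):
        report = run_rare_pipeline(
            [], [], {"frequency": ReferencePanel("f"), "known": ReferencePanel("d")}, []
        )
        assert all(v == 0 for v in report.counts.values())

    def test_passthrough_with_empty_panels_and_full_concordance(self):
        cases = [seg("S1"), seg("S1", start=1000, end=1100, cn=3)]
        caller2 = [
            CNVSegment(s.sample_id, s.interval, s.cn_state, s.n_probes, "secondary_caller")
            for s in cases
        ]
        report = run_rare_pipeline(
            cases,
            [],
            {"frequency": ReferencePanel("f"), "known": ReferencePanel("d")},
            caller2,
        )
        assert [s.key for s in report.rare_segments] == [s.key for s in cases]


class TestGeneScreen:
    GENE = GeneAnnotation("G2", GenomicInterval("1", 150, 180), 2)

    def test_relaxed_probe_threshold_recovers_small_call(self):
        loss16 = seg(probes=16)
        df = gene_list_screen([loss16], [self.GENE], min_probes=(15, 15))
        assert len(df) == 1 and df.iloc[0].gene_symbol == "G2"
        strict = gene_list_screen([loss16], [self.GENE], min_probes=(25, 50))
        assert strict.empty

    def test_non_overlapping_segment_absent(self):
        far = seg(start=5000, end=6000, probes=40)
        assert gene_list_screen([far], [self.GENE]).empty

    def test_loss_and_gain_hits_are_separate_rows(self):
        hits = [seg(probes=20), seg("S2", start=120, end=220, cn=3, probes=20)]
        df = gene_list_screen(hits, [self.GENE])
        assert len(df) == 2 and set(df.cnv_type) == {"loss", "gain"}


class TestCatalogReproduction:
    def test_report_writer_reproduces_printed_catalog(self, rare_catalog):
        """The final-table writer reproduces all 21 catalog rows verbatim."""
        segments, labels, spans = [], {}, {}
        for r in rare_catalog.itertuples(index=False):
            s = CNVSegment(
                r.sample_id,
                GenomicInterval(r.chrom, r.start, r.end),
                1 if r.cnv_type == "loss" else 3,
            )
            segments.append(s)
            labels[s.key] = r.pop_freq
            if r.genes != "-":
                for sym in r.genes.split(","):
                    chrom, lo, hi = spans.get(sym, (r.chrom, r.start, r.end))
                    spans[sym] = (chrom, min(lo, r.start), max(hi, r.end))
        gene_objs = [
            GeneAnnotation(sym, GenomicInterval(chrom, lo, hi), 1)
            for sym, (chrom, lo, hi) in spans.items()
        ]
        report = RareCNVReport(
            input_segments=segments,
            step1_retained=segments,
            step2_retained=segments,
            step3_retained=segments,
            step4_retained=segments,
            removal_reason={},
            pop_freq_label=labels,
        )
        table = report.table_frame(gene_objs)
        assert len(table) == 21
        for got, want in zip(table.itertuples(index=False), rare_catalog.itertuples(index=False)):
            assert got.location == f"chr{want.chrom}:{want.start}-{want.end}"
            assert got.type == ("Del" if want.cnv_type == "loss" else "Dup")
            assert got.size_kb == want.size_kb
            assert got.sample_id == want.sample_id
            assert got.pop_freq == want.pop_freq
            assert set(got.genes.split(",")) == set(want.genes.split(","))
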