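"""Burden summaries, adjusted burden regressions and per-chromosome tests."""

import numpy as np
import pytest
from scipy.special import expit

from cnvcase.burden import (
    compare_burden,
    per_chromosome_tests,
    size_range_histogram,
    summarize_burden,
)
from cnvcase.intervals import GenomicInterval
from cnvcase.io import CNVSegment, SampleRecord


def seg(sample, chrom="1", start=100, end=10_099, cn=1):
    return CNVSegment(sample, GenomicInterval(chrom, start, end), cn, 30)


def sample(sid, group="case", sex="F", anc=(0.3, 0.5, 0.2)):
    return SampleRecord(sid, group, sex, anc)


def make_cohort(rng, n_case, n_ctrl):
    out = []
    for i in range(n_case + n_ctrl):
        anc = rng.dirichlet((2.0, 6.0, 1.0))
        out.append(
            SampleRecord(
                f"S{i:04d}",
                "case" if i < n_case else "control",
                "F" if rng.random() < 0.8 else "M",
                tuple(anc / anc.sum()),
            )
        )
    return out


class TestSummaries:
    def test_mean_calls_from_fixed_totals(self):
        """447 calls over 23 subjects average to 19.4 per subject."""
        samples = [sample(f"P{i:02d}") for i in range(23)]
        segments = [seg(samples[i % 23].sample_id) for i in range(447)]
        burdens = summarize_burden(segments, samples)
        assert sum(b.n_total for b in burdens) == 447
        assert np.mean([b.n_total for b in burdens]) == pytest.approx(19.4, abs=0.05)

    def test_zero_call_sample_gets_all_zero_summary(self):
        samples = [sample("A"), sample("B")]
        (a, b) = summarize_burden([seg("A")], samples)
        assert b.n_total == b.size_total == 0 and b.chrom_counts == {}

    def test_orphan_sample_id_errors(self):
        with pytest.raises(ValueError, match="unknown sample"):
            summarize_burden([seg("ghost")], [sample("A")])

    def test_loss_gain_split_and_conservation(self):
        samples = [sample("A")]
        segments = [seg("A", cn=1), seg("A", cn=3, start=50_000, end=59_999)]
        (b,) = summarize_burden(segments, samples)
        assert b.n_del == b.n_dup == 1
        assert b.size_del == b.size_dup == 10_000
        assert b.n_total == b.n_del + b.n_dup
        assert sum(b.chrom_counts.values()) == b.n_total


class TestCompareBurden:
    def test_symmetric_groups_give_unit_odds_ratio(self):
        # identical covariates and mirrored measures in both groups
        samples = [
            sample(f"C{i}", "case", "F", (0.3, 0.5, 0.2)) for i in range(10)
        ] + [sample(f"K{i}", "control", "F", (0.3, 0.5, 0.2)) for i in range(10)]
        burdens = summarize_burden(
            [seg(s.sample_id) for s in samples for _ in range(3)], samples
        )
        res = compare_burden(burdens, samples, "n_total")
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_requires_two_per_group(self):
        samples = [sample("A", "case"), sample("B", "control"), sample("C", "control")]
        with pytest.raises(ValueError, match="2 samples per group"):
            compare_burden(summarize_burden([], samples), samples)

    def test_null_type_one_error_is_nominal(self):
        """With burden independent of status, p < 0.05 at ~5% over 500 nulls."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 500
        for _ in range(reps):
            samples = make_cohort(rng, 30, 30)
            segments = [
                seg(s.sample_id, start=1 + 100_000 * j, end=10_000 + 100_000 * j)
                for s in samples
                for j in range(rng.poisson(5))
            ]
            burdens = summarize_burden(segments, samples)
            res = compare_burden(burdens, samples, "n_total")
            rejections += res.p_value < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 2.5 * se

    def test_planted_duplication_deficit_recovered(self):
        """Dup-count OR 0.7 per call: CI coverage >=90% over 200 cohorts of 335."""
        rng = np.random.default_rng(1)
        beta = np.log(0.7)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 335
            counts = rng.poisson(8, size=n)
            status = rng.random(n) < expit(0.8 + beta * counts)
            ancs = rng.dirichlet((2.0, 6.0, 1.0), size=n)
            samples = [
                SampleRecord(
                    f"S{i}", "case" if status[i] else "control",
                    "F" if rng.random() < 0.8 else "M",
                    tuple(ancs[i] / ancs[i].sum()),
                )
                for i in range(n)
            ]
            if sum(status) < 2 or n - sum(status) < 2:
                continue
            segments = [
                CNVSegment(
                    f"S{i}",
                    GenomicInterval("1", 1 + 20_000 * j, 10_000 + 20_000 * j),
                    3,
                    60,
                )
                for i in range(n)
                for j in range(counts[i])
            ]
            burdens = summarize_burden(segments, samples)
            res = compare_burden(burdens, samples, "n_dup")
            covered += res.ci_low <= 0.7 <= res.ci_high
        assert covered / reps >= 0.90

    def test_large_sample_estimate_near_planted_value(self):
        rng = np.random.default_rng(2)
        n = 20_000
        counts = rng.poisson(8, size=n)
        status = rng.random(n) < expit(0.8 + np.log(0.7) * counts)
        ancs = rng.dirichlet((2.0, 6.0, 1.0), size=n)
        samples = [
            SampleRecord(
                f"S{i}", "case" if status[i] else "control",
                "F" if rng.random() < 0.8 else "M",
                tuple(ancs[i] / ancs[i].sum()),
            )
            for i in range(n)
        ]
        segments = [
            CNVSegment(f"S{i}", GenomicInterval("1", 1 + 20_000 * j, 10_000 + 20_000 * j), 3, 60)
            for i in range(n)
            for j in range(counts[i])
        ]
        res = compare_burden(summarize_burden(segments, samples), samples, "n_dup")
        assert res.ci_low < 0.7 < res.ci_high
        assert res.ci_high < 1.0  # deficit detected


class TestPerChromosome:
    def test_equal_group_means_give_zero_t(self):
        samples = [sample("A"), sample("B"), sample("C", "control"), sample("D", "control")]
        segments = [seg("A"), seg("B"), seg("B", start=200_000, end=210_000)] + [
            seg("C"),
            seg("D"),
            seg("D", start=200_000, end=210_000),
        ]
        table = per_chromosome_tests(summarize_burden(segments, samples), samples)
        row = table[(table.chrom == "1") & (table.measure == "calls")].iloc[0]
        assert row.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_chromosome_gives_na(self):
        samples = [sample("A"), sample("B"), sample("C", "control"), sample("D", "control")]
        table = per_chromosome_tests(summarize_burden([], samples), samples)
        assert table["t_statistic"].isna().all()

    def test_single_sample_group_errors(self):
        samples = [sample("A"), sample("B", "control"), sample("C", "control")]
        with pytest.raises(ValueError):
            per_chromosome_tests(summarize_burden([], samples), samples)

    def test_planted_chr14_shift_detected_only_there(self):
        rng = np.random.default_rng(3)
        samples = make_cohort(rng, 60, 60)
        segments = []
        for s in samples:
            for _ in range(rng.poisson(4)):
                chrom = str(rng.integers(1, 23))
                start = int(rng.integers(1, 10_000_000))
                segments.append(
                    CNVSegment(s.sample_id, GenomicInterval(chrom, start, start + 9_999), 1, 30)
                )
            if s.is_case:  # extra large chr14 burden in cases only
                for _ in range(3):
                    start = int(rng.integers(1, 10_000_000))
                    segments.append(
                        CNVSegment(
                            s.sample_id, GenomicInterval("14", start, start + 499_999), 1, 900
                        )
                    )
        table = per_chromosome_tests(summarize_burden(segments, samples), samples)
        size = table[table.measure == "size"].set_index("chrom")["p_value"]
        assert size["14"] < 1e-6
        assert (size.drop("14").dropna() > 0.001).mean() > 0.9


class TestHistogram:
    def test_counts_partition_segments(self):
        segments = [seg("A", end=100 + 9_999), seg("A", cn=3, end=100 + 299_999)]
        hist = size_range_histogram(segments)
        assert hist["count"].sum() == len(segments)

    def test_single_bin_concentration(self):
        segments = [seg("A"), seg("A", start=500, end=10_499)]
        hist = size_range_histogram(segments, bin_edges=(0, 1e6))
        loss = hist[hist.cnv_type == "loss"]
        assert loss["count"].tolist() == [2]

    def test_empty_input_gives_zero_table(self):
        hist = size_range_histogram([])
        assert hist["count"].sum() == 0

    def test_rejects_unsorted_edges(self):
        with pytest.raises(ValueError):
            size_range_histogram([], bin_edges=(10, 5))
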