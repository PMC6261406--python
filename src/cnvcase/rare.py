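"""Four-step rare-CNV identification with a per-step audit trail.

The cascade, applied to the case call set of the primary caller:

1. drop calls matching any same-type control call (case-exclusive calls);
2. drop calls matching a population-frequency panel entry at >= 1%;
3. drop calls matching a known-variant panel entry;
4. keep only calls replicated by a second caller in the same sample.

Matching is same-type and, by default, 50% reciprocal overlap.  Retained
sets are nested across steps and each removed segment carries the step that
removed it, so the cascade counts (e.g. 447 -> 88 -> 67 -> 49 -> 21) can be
audited directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, OverlapRule, interval_size_kb
from .io import (
    GAIN,
    LOSS,
    SECONDARY_CALLER,
    CNVSegment,
    GeneAnnotation,
    ReferencePanel,
    apply_probe_filter,
)

DEFAULT_MAX_FREQ = 0.01


class _TypedIndex:
    """(chrom, type)-keyed interval index over reference intervals."""

    def __init__(self, entries: Iterable[tuple[GenomicInterval, str, object]]) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for interval, cnv_type, payload in entries:
            tree = self._trees.setdefault((interval.chrom, cnv_type), IntervalTree())
            # closed 1-based -> half-open for the tree; payload rides along
            tree.addi(interval.start, interval.end + 1, (interval, payload))

    def matches(self, seg: CNVSegment, rule: OverlapRule):
        """Yield payloads of same-type entries matching ``seg`` under ``rule``."""
        tree = self._trees.get((seg.interval.chrom, seg.cnv_type))
        if tree is None:
            return
        for hit in tree.overlap(seg.interval.start, seg.interval.end + 1):
            interval, payload = hit.data
            if rule.matches(seg.interval, interval):
                yield payload


@dataclass
class RareCNVReport:
    """Audit trail of the cascade: nested retained sets and removal reasons."""

    input_segments: list[CNVSegment]
    step1_retained: list[CNVSegment]
    step2_retained: list[CNVSegment]
    step3_retained: list[CNVSegment]
    step4_retained: list[CNVSegment]
    removal_reason: dict[tuple, str]
    pop_freq_label: dict[tuple, str] = field(default_factory=dict)
    overlap_rule: OverlapRule = field(default_factory=OverlapRule)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "input": len(self.input_segments),
            "step1_case_exclusive": len(self.step1_retained),
            "step2_population_frequency": len(self.step2_retained),
            "step3_known_variants": len(self.step3_retained),
            "step4_dual_caller": len(self.step4_retained),
        }

    @property
    def rare_segments(self) -> list[CNVSegment]:
        return self.step4_retained

    def steps_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {
                "step": list(c),
                "retained": list(c.values()),
                "overlap_rule": self.overlap_rule.describe(),
            }
        )

    def table_frame(self, genes: Optional[Sequence[GeneAnnotation]] = None) -> pd.DataFrame:
        """Final rare-CNV table: location, genes, type, size kb, sample, pop-freq label."""
        rows = []
        for seg in sorted(
            self.step4_retained,
            key=lambda s: (_chrom_order(s.interval.chrom), s.interval.start),
        ):
            overlapping = (
                sorted(
                    {g.gene_symbol for g in genes if g.interval.overlap_bp(seg.interval) > 0}
                )
                if genes
                else []
            )
            rows.append(
                {
                    "location": str(seg.interval),
                    "genes": ",".join(overlapping) if overlapping else "-",
                    "type": "Del" if seg.cnv_type == LOSS else "Dup",
                    "size_kb": interval_size_kb(seg.interval),
                    "sample_id": seg.sample_id,
                    "pop_freq": self.pop_freq_label.get(seg.key, "-"),
                }
            )
        return pd.DataFrame(
            rows, columns=["location", "genes", "type", "size_kb", "sample_id", "pop_freq"]
        )


def _chrom_order(chrom: str) -> int:
    return 23 if chrom == "X" else int(chrom)


# ---------------------------------------------------------------------------
# individual steps


def step1_case_exclusive(
    case_segments: Sequence[CNVSegment],
    control_segments: Sequence[CNVSegment],
    overlap_rule: OverlapRule = OverlapRule(),
) -> list[CNVSegment]:
    """Retain case calls with no same-type control match under the rule."""
    index = _TypedIndex((c.interval, c.cnv_type, True) for c in control_segments)
    return [s for s in case_segments if next(index.matches(s, overlap_rule), None) is None]


def step2_population_frequency(
    segments: Sequence[CNVSegment],
    panel: ReferencePanel,
    max_freq: float = DEFAULT_MAX_FREQ,
    overlap_rule: OverlapRule = OverlapRule(),
) -> tuple[list[CNVSegment], dict[tuple, str]]:
    """Drop calls matching a panel entry at or above ``max_freq``.

    Calls matching only sub-threshold entries are retained and labeled
    ``"< 1%"``; calls matching nothing are labeled ``"-"``.  Returns the
    retained list and the label map.
    """
    if panel.entries and not panel.has_frequencies:
        raise ValueError(
            f"panel {panel.name!r} carries no frequencies; "
            "use step3_known_variant_filter for frequency-free panels"
        )
    index = _TypedIndex((e.interval, e.cnv_type, e.frequency) for e in panel.entries)
    retained = []
    labels: dict[tuple, str] = {}
    for seg in segments:
        freqs = [f for f in index.matches(seg, overlap_rule) if f is not None]
        if any(f >= max_freq for f in freqs):
            continue
        retained.append(seg)
        labels[seg.key] = f"< {max_freq:.0%}" if freqs else "-"
    return retained, labels


def step3_known_variant_filter(
    segments: Sequence[CNVSegment],
    dgv_panel: ReferencePanel,
    overlap_rule: OverlapRule = OverlapRule(),
) -> list[CNVSegment]:
    """Drop calls matching any same-type entry of a known-variant panel."""
    index = _TypedIndex((e.interval, e.cnv_type, True) for e in dgv_panel.entries)
    return [s for s in segments if next(index.matches(s, overlap_rule), None) is None]


def step4_caller_concordance(
    segments: Sequence[CNVSegment],
    second_caller_segments: Sequence[CNVSegment],
    overlap_rule: OverlapRule = OverlapRule(),
) -> list[CNVSegment]:
    """Keep calls replicated by the secondary caller in the same sample."""
    by_sample: dict[str, list[CNVSegment]] = {}
    for c in second_caller_segments:
        if c.caller_id != SECONDARY_CALLER:
            raise ValueError("second caller set must carry caller_id=secondary_caller")
        by_sample.setdefault(c.sample_id, []).append(c)
    indexes = {
        sid: _TypedIndex((c.interval, c.cnv_type, True) for c in calls)
        for sid, calls in by_sample.items()
    }
    retained = []
    for seg in segments:
        index = indexes.get(seg.sample_id)
        if index is not None and next(index.matches(seg, overlap_rule), None) is not None:
            retained.append(seg)
    return retained


def run_rare_pipeline(
    case_segments: Sequence[CNVSegment],
    control_segments: Sequence[CNVSegment],
    panels: dict[str, ReferencePanel],
    second_caller_segments: Sequence[CNVSegment],
    overlap_rule: OverlapRule = OverlapRule(),
    max_freq: float = DEFAULT_MAX_FREQ,
) -> RareCNVReport:
    """Apply steps 1-4 in order and assemble the audit report.

    ``panels`` must provide keys ``"frequency"`` (population-frequency panel)
    and ``"known"`` (known-variant panel).
    """
    s1 = step1_case_exclusive(case_segments, control_segments, overlap_rule)
    s2, labels = step2_population_frequency(s1, panels["frequency"], max_freq, overlap_rule)
    s3 = step3_known_variant_filter(s2, panels["known"], overlap_rule)
    s4 = step4_caller_concordance(s3, second_caller_segments, overlap_rule)

    reasons: dict[tuple, str] = {}
    sets = [
        set(s.key for s in case_segments),
        set(s.key for s in s1),
        set(s.key for s in s2),
        set(s.key for s in s3),
        set(s.key for s in s4),
    ]
    names = ["in_controls", "panel_common", "known_variant", "no_second_caller"]
    for prev, curr, name in zip(sets, sets[1:], names):
        for key in prev - curr:
            reasons[key] = name
    return RareCNVReport(
        input_segments=list(case_segments),
        step1_retained=s1,
        step2_retained=s2,
        step3_retained=s3,
        step4_retained=s4,
        removal_reason=reasons,
        pop_freq_label=labels,
        overlap_rule=overlap_rule,
    )


def gene_list_screen(
    segments: Sequence[CNVSegment],
    genes: Sequence[GeneAnnotation],
    min_probes: tuple[int, int] = (15, 15),
) -> pd.DataFrame:
    """Relaxed-threshold screen of calls over curated gene lists.

    Applies the relaxed probe filter (default 15 probes for both losses and
    gains, versus the 25/50 detection defaults) and reports every
    (gene, segment) overlap, tagged with the gene's list id.
    """
    screened = apply_probe_filter(segments, min_probes[0], min_probes[1])
    rows = []
    for g in genes:
        for seg in screened:
            if g.interval.overlap_bp(seg.interval) == 0:
                continue
            rows.append(
                {
                    "gene_symbol": g.gene_symbol,
                    "list_id": g.list_id,
                    "sample_id": seg.sample_id,
                    "location": str(seg.interval),
                    "cnv_type": seg.cnv_type,
                    "n_probes": seg.n_probes,
                    "size_kb": interval_size_kb(seg.interval),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "list_id",
            "sample_id",
            "location",
            "cnv_type",
            "n_probes",
            "size_kb",
        ],
    )
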