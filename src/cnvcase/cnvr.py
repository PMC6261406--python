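"""CNV regions: unions of overlapping same-type CNVs across subjects.

A CNVR is a connected component of the ≥1 bp overlap graph over segments of
one type (loss or gain) on one chromosome — the union-of-overlaps recurrence
definition.  Losses and gains are never merged.  Carrier frequencies per
region are compared between groups with an adjusted logistic model and an
unadjusted Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from ._stats import design_from_samples, fit_logit, status_vector
from .intervals import GenomicInterval
from .io import GAIN, LOSS, CNVSegment, GeneAnnotation, SampleRecord


@dataclass
class CNVR:
    """Union-of-overlaps region of one type with per-group carrier sets."""

    region_id: str
    interval: GenomicInterval
    cnvr_type: str
    members: list[CNVSegment]
    carriers_case: frozenset[str]
    carriers_control: frozenset[str]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers_case) + len(self.carriers_control)


@dataclass
class CNVRTestResult:
    region_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    fisher_odds_ratio: float
    fisher_p: float
    table: tuple[tuple[int, int], tuple[int, int]]  # [[case carriers, case rest], [ctrl...]]
    method: str
    separation: bool
    degenerate: bool = False
    notes: tuple[str, ...] = ()


def build_cnvrs(
    segments: Iterable[CNVSegment],
    samples: Sequence[SampleRecord],
    cnvr_type: Optional[str] = None,
) -> list[CNVR]:
    """Cluster same-type segments into CNVRs by transitive ≥1 bp overlap.

    ``cnvr_type`` restricts to ``"loss"`` or ``"gain"``; ``None`` builds
    both, separately.  Output is independent of input order: segments are
    sorted and region ids are assigned by genomic position.
    """
    group_of = {s.sample_id: s.is_case for s in samples}
    kinds = (cnvr_type,) if cnvr_type else (LOSS, GAIN)
    for kind in kinds:
        if kind not in (LOSS, GAIN):
            raise ValueError(f"unknown cnvr_type {kind!r}")
    regions: list[CNVR] = []
    segs = sorted(
        (s for s in segments if s.cnv_type in kinds),
        key=lambda s: (s.interval.chrom, s.cnv_type, s.interval.start, s.interval.end, s.sample_id),
    )
    # single left-to-right sweep per (chrom, type): a sorted segment joins the
    # open cluster iff it starts before the cluster's max end (1-based closed,
    # so start <= max_end means >=1 bp shared)
    cluster: list[CNVSegment] = []
    cluster_key = None
    max_end = -1

    def _close() -> None:
        if not cluster:
            return
        chrom = cluster[0].interval.chrom
        span = GenomicInterval(
            chrom,
            min(m.interval.start for m in cluster),
            max(m.interval.end for m in cluster),
        )
        carriers = {m.sample_id for m in cluster}
        for sid in carriers:
            if sid not in group_of:
                raise ValueError(f"segment references unknown sample {sid!r}")
        regions.append(
            CNVR(
                region_id="",
                interval=span,
                cnvr_type=cluster[0].cnv_type,
                members=list(cluster),
                carriers_case=frozenset(c for c in carriers if group_of[c]),
                carriers_control=frozenset(c for c in carriers if not group_of[c]),
            )
        )

    for seg in segs:
        key = (seg.interval.chrom, seg.cnv_type)
        if key != cluster_key or seg.interval.start > max_end:
            _close()
            cluster = [seg]
            cluster_key = key
            max_end = seg.interval.end
        else:
            cluster.append(seg)
            max_end = max(max_end, seg.interval.end)
    _close()

    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.cnvr_type))
    for i, r in enumerate(regions, start=1):
        prefix = "L" if r.cnvr_type == LOSS else "G"
        r.region_id = f"CNVR_{prefix}{i:04d}_chr{r.interval.chrom}"
    return regions


def test_cnvr(
    cnvr: CNVR,
    samples: Sequence[SampleRecord],
    ancestry_component: str = "afr",
) -> CNVRTestResult:
    """Carrier-status association for one region.

    Fits case status ~ carrier + sex + ancestry component, and also reports
    the Fisher exact test on the unadjusted carrier 2×2 table.
    """
    if cnvr.n_carriers == 0:
        raise ValueError("region has no carriers")
    carriers = cnvr.carriers_case | cnvr.carriers_control
    n_case = sum(1 for s in samples if s.is_case)
    n_ctrl = len(samples) - n_case
    a = len(cnvr.carriers_case)
    c = len(cnvr.carriers_control)
    table = ((a, n_case - a), (c, n_ctrl - c))
    fisher = stats.fisher_exact(table)
    degenerate = len(carriers) == len(samples)
    X = design_from_samples(samples, ancestry_component)
    X["carrier"] = [1.0 if s.sample_id in carriers else 0.0 for s in samples]
    y = status_vector(samples).loc[X.index].to_numpy()
    notes: list[str] = []
    if degenerate:
        notes.append("all samples are carriers; carrier indicator is constant")
    fit = fit_logit(X, y)
    ci_low, ci_high = fit.conf_int("carrier")
    return CNVRTestResult(
        region_id=cnvr.region_id,
        odds_ratio=fit.odds_ratio("carrier"),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(fit.pvalues["carrier"]),
        fisher_odds_ratio=float(fisher.statistic),
        fisher_p=float(fisher.pvalue),
        table=table,
        method=fit.method,
        separation=fit.separation,
        degenerate=degenerate,
        notes=tuple(notes + fit.notes),
    )


def annotate_cnvrs(
    cnvrs: Sequence[CNVR], genes: Sequence[GeneAnnotation]
) -> dict[str, list[tuple[str, str]]]:
    """Overlapping gene symbols per region, tagged "entire" or "partial".

    "entire" means the gene lies fully inside the region span; any other
    positive overlap is "partial".
    """
    out: dict[str, list[tuple[str, str]]] = {}
    for r in cnvrs:
        hits = []
        for g in genes:
            ov = r.interval.overlap_bp(g.interval)
            if ov == 0:
                continue
            hits.append((g.gene_symbol, "entire" if r.interval.contains(g.interval) else "partial"))
        out[r.region_id] = sorted(set(hits))
    return out


def cnvr_frame(
    cnvrs: Sequence[CNVR],
    tests: Optional[Sequence[CNVRTestResult]] = None,
    annotations: Optional[dict[str, list[tuple[str, str]]]] = None,
) -> pd.DataFrame:
    tests_by_id = {t.region_id: t for t in tests or []}
    rows = []
    for r in cnvrs:
        row = {
            "region_id": r.region_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "cnvr_type": r.cnvr_type,
            "n_members": len(r.members),
            "carriers_case": len(r.carriers_case),
            "carriers_control": len(r.carriers_control),
        }
        t = tests_by_id.get(r.region_id)
        if t is not None:
            row.update(
                odds_ratio=t.odds_ratio,
                ci_low=t.ci_low,
                ci_high=t.ci_high,
                p_adjusted_model=t.p_value,
                fisher_odds_ratio=t.fisher_odds_ratio,
                p_fisher=t.fisher_p,
                fit_method=t.method,
            )
        if annotations is not None:
            row["genes"] = ";".join(
                f"{sym}({kind})" for sym, kind in annotations.get(r.region_id, [])
            )
        rows.append(row)
    return pd.DataFrame(rows)
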