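"""Per-sample CNV burden summaries and case-control burden comparisons.

Burden measures (call counts and summed sizes, split by loss/gain) are
compared between groups with logistic regression of case status on the
measure adjusted for sex and one admixture proportion; per-chromosome
comparisons use two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import LogitFit, design_from_samples, fit_logit, status_vector
from .intervals import ALLOWED_CHROMS
from .io import GAIN, LOSS, CNVSegment, SampleRecord

BURDEN_MEASURES = ("n_total", "n_del", "n_dup", "size_total", "size_del", "size_dup")


@dataclass
class BurdenSummary:
    """CNV burden of one sample: counts, base-pair sums, per-chromosome splits."""

    sample_id: str
    n_total: int = 0
    n_del: int = 0
    n_dup: int = 0
    size_total: int = 0
    size_del: int = 0
    size_dup: int = 0
    chrom_counts: dict[str, int] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def mean_size_del(self) -> float:
        return self.size_del / self.n_del if self.n_del else 0.0

    @property
    def mean_size_dup(self) -> float:
        return self.size_dup / self.n_dup if self.n_dup else 0.0


@dataclass
class BurdenTestResult:
    """Logistic burden comparison: OR per unit of the measure, Wald 95% CI."""

    measure: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: tuple[str, ...]
    method: str = "mle"
    separation: bool = False
    notes: tuple[str, ...] = ()


def summarize_burden(
    segments: Iterable[CNVSegment], samples: Sequence[SampleRecord]
) -> list[BurdenSummary]:
    """One burden summary per sample; samples with zero calls get zeros."""
    known = {s.sample_id for s in samples}
    summaries = {s.sample_id: BurdenSummary(s.sample_id) for s in samples}
    for seg in segments:
        if seg.sample_id not in known:
            raise ValueError(f"segment references unknown sample {seg.sample_id!r}")
        b = summaries[seg.sample_id]
        size = seg.interval.size
        b.n_total += 1
        b.size_total += size
        if seg.cnv_type == LOSS:
            b.n_del += 1
            b.size_del += size
        else:
            b.n_dup += 1
            b.size_dup += size
        b.chrom_counts[seg.interval.chrom] = b.chrom_counts.get(seg.interval.chrom, 0) + 1
        b.chrom_sizes[seg.interval.chrom] = b.chrom_sizes.get(seg.interval.chrom, 0) + size
    return [summaries[s.sample_id] for s in samples]


def burden_frame(burdens: Iterable[BurdenSummary]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": b.sample_id,
            "n_total": b.n_total,
            "n_del": b.n_del,
            "n_dup": b.n_dup,
            "size_total": b.size_total,
            "size_del": b.size_del,
            "size_dup": b.size_dup,
            "mean_size_del": b.mean_size_del,
            "mean_size_dup": b.mean_size_dup,
        }
        for b in burdens
    ]
    return pd.DataFrame(rows)


def compare_burden(
    burdens: Sequence[BurdenSummary],
    samples: Sequence[SampleRecord],
    measure: str = "n_dup",
    ancestry_component: str = "afr",
) -> BurdenTestResult:
    """Case status ~ measure + sex + one ancestry proportion (ML logistic).

    The measure enters as a continuous covariate, so the odds ratio is per
    call (count measures) or per base pair (size measures).  Quasi-separated
    fits are flagged and re-estimated with a Firth penalty.
    """
    if measure not in BURDEN_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; pick one of {BURDEN_MEASURES}")
    n_case = sum(1 for s in samples if s.is_case)
    n_ctrl = len(samples) - n_case
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 samples per group")
    by_id = {b.sample_id: b for b in burdens}
    X = design_from_samples(samples, ancestry_component)
    X[measure] = [float(getattr(by_id[s.sample_id], measure)) for s in samples]
    y = status_vector(samples).loc[X.index].to_numpy()
    fit = fit_logit(X, y)
    ci_low, ci_high = fit.conf_int(measure)
    return BurdenTestResult(
        measure=measure,
        coefficient=float(fit.params[measure]),
        odds_ratio=fit.odds_ratio(measure),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(fit.pvalues[measure]),
        covariates=("sex", f"ancestry_{ancestry_component}"),
        method=fit.method,
        separation=fit.separation,
        notes=tuple(fit.notes),
    )


def per_chromosome_tests(
    burdens: Sequence[BurdenSummary],
    samples: Sequence[SampleRecord],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per chromosome for call count and summed size.

    Welch's correction is the default (unequal group sizes and variances);
    ``equal_var=True`` gives the classical pooled-variance Student test.
    No multiplicity correction is applied: per-chromosome p-values are raw.
    """
    groups = {s.sample_id: s.is_case for s in samples}
    if not any(groups.values()) or all(groups.values()):
        raise ValueError("both groups must be represented")
    if sum(groups.values()) < 2 or len(groups) - sum(groups.values()) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for chrom in ALLOWED_CHROMS:
        for measure, source in (("calls", "chrom_counts"), ("size", "chrom_sizes")):
            case_vals = np.array(
                [getattr(b, source).get(chrom, 0) for b in burdens if groups[b.sample_id]],
                dtype=float,
            )
            ctrl_vals = np.array(
                [getattr(b, source).get(chrom, 0) for b in burdens if not groups[b.sample_id]],
                dtype=float,
            )
            if case_vals.std() == 0 and ctrl_vals.std() == 0:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(case_vals, ctrl_vals, equal_var=equal_var)
            rows.append(
                {
                    "chrom": chrom,
                    "measure": measure,
                    "mean_case": case_vals.mean(),
                    "mean_control": ctrl_vals.mean(),
                    "t_statistic": t,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


DEFAULT_SIZE_BINS = (0, 50_000, 100_000, 250_000, 500_000, 1_000_000, np.inf)


def size_range_histogram(
    segments: Iterable[CNVSegment],
    bin_edges: Sequence[float] = DEFAULT_SIZE_BINS,
) -> pd.DataFrame:
    """Counts of losses and gains per size range."""
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    sizes = {LOSS: [], GAIN: []}
    for seg in segments:
        sizes[seg.cnv_type].append(seg.interval.size)
    rows = []
    for kind in (LOSS, GAIN):
        counts, _ = np.histogram(np.array(sizes[kind], dtype=float), bins=edges)
        for i, c in enumerate(counts):
            lo, hi = edges[i], edges[i + 1]
            label = f"{lo:.0f}-{hi:.0f}" if np.isfinite(hi) else f">={lo:.0f}"
            rows.append({"cnv_type": kind, "size_range_bp": label, "count": int(c)})
    return pd.DataFrame(rows)


def plot_size_histogram(hist: pd.DataFrame, path) -> None:
    """Bar-chart export of :func:`size_range_histogram`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    pivot = hist.pivot(index="size_range_bp", columns="cnv_type", values="count")
    pivot.plot.bar(ax=ax, color={"loss": "#c0392b", "gain": "#2980b9"})
    ax.set_xlabel("size range (bp)")
    ax.set_ylabel("CNV calls")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
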