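"""Target-specific copy-number quantification: qPCR ΔΔCT and droplet digital PCR.

qPCR: copy number relative to a diploid calibrator is ``2 * 2^(-ΔΔCt)``
with ΔCt the target-minus-reference mean cycle threshold and ΔΔCt its
offset from a known-diploid calibrator (perfect doubling per cycle).

ddPCR: droplet occupancy is Poisson, so target concentration follows from
the positive-droplet fraction as ``λ = -ln(1 - p̂)`` copies per droplet;
copy number is twice the target/reference concentration ratio.  Single-well
95% intervals come from the normal approximation on p̂ propagated through
the Poisson correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


class SaturationError(ValueError):
    """All droplets positive: concentration not estimable."""


@dataclass(frozen=True)
class CtMeasurement:
    """Triplicate cycle thresholds for one gene in one sample.

    Non-amplification is encoded as NaN.
    """

    sample_id: str
    gene_role: str  # target | reference
    cts: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.gene_role not in ("target", "reference"):
            raise ValueError(f"unknown gene_role {self.gene_role!r}")
        for ct in self.cts:
            if not math.isnan(ct) and not (0.0 < ct < 45.0):
                raise ValueError(f"Ct {ct} outside (0, 45)")

    @property
    def finite_cts(self) -> list[float]:
        return [c for c in self.cts if not math.isnan(c)]

    @property
    def non_amplified(self) -> bool:
        return len(self.finite_cts) == 0


@dataclass(frozen=True)
class DropletCount:
    """Positive/total droplet counts for one gene in one well."""

    sample_id: str
    gene_role: str
    positives: int
    total: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total droplets must be positive")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")


@dataclass
class QuantResult:
    """A copy-number estimate with its interval and integer call."""

    sample_id: str
    locus_id: str
    cn_estimate: float
    ci_low: float
    ci_high: float
    cn_integer: Optional[int]  # None = no-call (estimate too close to a half-integer)
    method: str  # qpcr_ddct | ddpcr
    flags: tuple[str, ...] = ()


#: half-width of the no-call band around half-integer copy numbers
NO_CALL_BAND = 0.15


def integer_call(cn_estimate: float, band: float = NO_CALL_BAND) -> Optional[int]:
    """Half-up integer copy number, or None inside the half-integer no-call band."""
    if cn_estimate < 0:
        raise ValueError("copy-number estimate must be >= 0")
    nearest_half = math.floor(cn_estimate) + 0.5
    if abs(cn_estimate - nearest_half) <= band:
        return None
    return int(math.floor(cn_estimate + 0.5))


def replicate_qc(
    cts: Sequence[float], max_range: float = 0.5
) -> tuple[Optional[float], str]:
    """Mean Ct after triplicate QC.

    If the replicate range is within ``max_range`` cycles the mean of all
    finite replicates is used; otherwise the replicate farthest from the
    median is dropped and the remaining two averaged.  Fewer than two finite
    replicates is a failure.  Returns ``(mean or None, action)``.
    """
    finite = [c for c in cts if not math.isnan(c)]
    if len(finite) < 2:
        return None, "failed: <2 finite replicates"
    rng = max(finite) - min(finite)
    if rng <= max_range:
        return float(np.mean(finite)), "mean_all"
    if len(finite) == 2:
        return None, "failed: 2 replicates disagree beyond max_range"
    med = float(np.median(finite))
    drop = max(range(len(finite)), key=lambda i: abs(finite[i] - med))
    kept = [c for i, c in enumerate(finite) if i != drop]
    return float(np.mean(kept)), f"outlier_trimmed (dropped {finite[drop]:.2f})"


def ddct_copy_number(
    target: CtMeasurement,
    reference: CtMeasurement,
    calibrator_dct: float = 0.0,
    locus_id: str = "target",
    max_range: float = 0.5,
) -> QuantResult:
    """ΔΔCT relative quantification against a known-diploid calibrator.

    ``cn = 2 * 2^(-ΔΔCt)`` with ``ΔΔCt = (mean Ct_target - mean Ct_ref) -
    calibrator ΔCt``.  Replicate scatter is propagated to a 95% interval on
    the estimate.  A non-amplifying target with an amplifying reference is a
    homozygous deletion (CN 0).
    """
    if target.sample_id != reference.sample_id:
        raise ValueError("target and reference measurements are from different samples")
    flags: list[str] = []
    if target.non_amplified:
        if reference.non_amplified:
            return QuantResult(
                target.sample_id, locus_id, math.nan, math.nan, math.nan, None,
                "qpcr_ddct", ("failed: no amplification in target or reference",),
            )
        return QuantResult(
            target.sample_id, locus_id, 0.0, 0.0, 0.0, 0, "qpcr_ddct",
            ("target non-amplified: homozygous deletion",),
        )
    mean_t, action_t = replicate_qc(target.cts, max_range)
    mean_r, action_r = replicate_qc(reference.cts, max_range)
    for role, action in (("target", action_t), ("reference", action_r)):
        if action != "mean_all":
            flags.append(f"{role}: {action}")
    if mean_t is None or mean_r is None:
        return QuantResult(
            target.sample_id, locus_id, math.nan, math.nan, math.nan, None,
            "qpcr_ddct", tuple(flags) or ("failed: replicate QC",),
        )
    ddct = (mean_t - mean_r) - calibrator_dct
    cn = 2.0 * 2.0 ** (-ddct)
    sd_t = float(np.std(target.finite_cts, ddof=1))
    sd_r = float(np.std(reference.finite_cts, ddof=1))
    se = math.sqrt(sd_t**2 / len(target.finite_cts) + sd_r**2 / len(reference.finite_cts))
    ci_low = 2.0 * 2.0 ** (-(ddct + Z95 * se))
    ci_high = 2.0 * 2.0 ** (-(ddct - Z95 * se))
    return QuantResult(
        target.sample_id,
        locus_id,
        cn,
        ci_low,
        ci_high,
        integer_call(cn),
        "qpcr_ddct",
        tuple(flags),
    )


# ---------------------------------------------------------------------------
# ddPCR


@dataclass
class Concentration:
    """Copies per µL with a single-well 95% interval."""

    copies_per_ul: float
    ci_low: float
    ci_high: float
    lam: float  # mean copies per droplet


def ddpcr_concentration(count: DropletCount) -> Concentration:
    """Poisson-corrected concentration from the positive-droplet fraction.

    ``λ = -ln(1 - p̂)`` copies/droplet, divided by droplet volume in µL.
    The 95% CI transforms the normal interval on p̂ through the same map;
    zero positives yield concentration 0 with an exact one-sided upper
    bound (p at which P(0 positives) = 5%).
    """
    v_ul = count.droplet_volume_nl * 1e-3
    n = count.total
    if count.positives == count.total:
        raise SaturationError(
            f"{count.sample_id}/{count.gene_role}: all {n} droplets positive"
        )
    p_hat = count.positives / n
    lam = -math.log1p(-p_hat)
    if count.positives == 0:
        p_upper = 1.0 - 0.05 ** (1.0 / n)
        return Concentration(0.0, 0.0, -math.log1p(-p_upper) / v_ul, 0.0)
    half = Z95 * math.sqrt(p_hat * (1.0 - p_hat) / n)
    p_lo = max(0.0, p_hat - half)
    p_hi = min(1.0 - 1e-12, p_hat + half)
    return Concentration(
        copies_per_ul=lam / v_ul,
        ci_low=-math.log1p(-p_lo) / v_ul,
        ci_high=-math.log1p(-p_hi) / v_ul,
        lam=lam,
    )


def ddpcr_copy_number(
    target: DropletCount, reference: DropletCount, locus_id: str = "target"
) -> QuantResult:
    """Copy number as twice the target/reference concentration ratio.

    The interval treats the two wells as independent Poisson estimates and
    propagates on the log-ratio scale (delta method):
    ``var(ln λ̂) = p̂ / ((1 - p̂) N λ̂²)``.
    """
    if target.sample_id != reference.sample_id:
        raise ValueError("target and reference wells are from different samples")
    conc_r = ddpcr_concentration(reference)
    if conc_r.copies_per_ul == 0:
        raise ValueError("reference concentration is zero")
    if target.positives == 0:
        upper = ddpcr_concentration(target).ci_high
        cn_hi = 2.0 * upper / conc_r.copies_per_ul
        return QuantResult(
            target.sample_id, locus_id, 0.0, 0.0, cn_hi, 0, "ddpcr",
            ("target well empty: homozygous deletion",),
        )
    conc_t = ddpcr_concentration(target)
    cn = 2.0 * conc_t.copies_per_ul / conc_r.copies_per_ul
    var_log = 0.0
    for count, conc in ((target, conc_t), (reference, conc_r)):
        p_hat = count.positives / count.total
        var_log += p_hat / ((1.0 - p_hat) * count.total * conc.lam**2)
    half = Z95 * math.sqrt(var_log)
    return QuantResult(
        target.sample_id,
        locus_id,
        cn,
        cn * math.exp(-half),
        cn * math.exp(half),
        integer_call(cn),
        "ddpcr",
    )


def reference_sample_check(
    run: Iterable[QuantResult], reference_sample_id: str
) -> tuple[bool, str]:
    """Run-level internal control: the known-diploid sample must call CN 2.

    Returns ``(passed, message)``; a missing reference sample invalidates
    the run, as does any of its calls not being 2.
    """
    ref_calls = [r for r in run if r.sample_id == reference_sample_id]
    if not ref_calls:
        return False, f"reference sample {reference_sample_id!r} missing: run invalid"
    bad = [r for r in ref_calls if r.cn_integer != 2]
    if bad:
        detail = "; ".join(f"{r.locus_id}: CN {r.cn_estimate:.2f}" for r in bad)
        return False, f"reference sample not diploid ({detail}): run invalid"
    return True, "reference sample diploid at all assayed loci"


# ---------------------------------------------------------------------------
# plate-level drivers


def call_qpcr_plate(
    plate: pd.DataFrame, calibrator_sample_id: Optional[str] = None, locus_id: str = "target"
) -> list[QuantResult]:
    """Call copy numbers for every sample on a triplicate qPCR plate.

    If ``calibrator_sample_id`` is given, its ΔCt anchors the ΔΔCt scale
    (that sample is assumed diploid); otherwise the calibrator ΔCt is 0,
    i.e. target and reference are assumed to amplify identically at CN 2.
    """
    meas: dict[str, dict[str, CtMeasurement]] = {}
    for row in plate.itertuples(index=False):
        m = CtMeasurement(
            str(row.sample_id),
            str(row.gene_role),
            (float(row.ct1), float(row.ct2), float(row.ct3)),
        )
        meas.setdefault(m.sample_id, {})[m.gene_role] = m
    calibrator_dct = 0.0
    if calibrator_sample_id is not None:
        pair = meas.get(calibrator_sample_id)
        if not pair or "target" not in pair or "reference" not in pair:
            raise ValueError(f"calibrator sample {calibrator_sample_id!r} not on plate")
        mt, _ = replicate_qc(pair["target"].cts)
        mr, _ = replicate_qc(pair["reference"].cts)
        if mt is None or mr is None:
            raise ValueError("calibrator sample failed replicate QC")
        calibrator_dct = mt - mr
    results = []
    for sid, pair in sorted(meas.items()):
        if "target" not in pair or "reference" not in pair:
            continue
        results.append(
            ddct_copy_number(pair["target"], pair["reference"], calibrator_dct, locus_id)
        )
    return results


def call_ddpcr_wells(wells: pd.DataFrame, locus_id: str = "target") -> list[QuantResult]:
    """Call copy numbers from a table of paired target/reference wells."""
    by_sample: dict[str, dict[str, DropletCount]] = {}
    for row in wells.itertuples(index=False):
        c = DropletCount(
            str(row.sample_id),
            str(row.gene_role),
            int(row.positives),
            int(row.total),
            float(row.droplet_volume_nl),
        )
        by_sample.setdefault(c.sample_id, {})[c.gene_role] = c
    results = []
    for sid, pair in sorted(by_sample.items()):
        if "target" not in pair or "reference" not in pair:
            continue
        results.append(ddpcr_copy_number(pair["target"], pair["reference"], locus_id))
    return results


def quant_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "locus_id": r.locus_id,
                "cn_estimate": r.cn_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "cn_integer": r.cn_integer,
                "method": r.method,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
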