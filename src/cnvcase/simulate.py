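"""Synthetic admixed case-control cohorts with known CNV ground truth.

The generator emulates an array-based CNV screen of a tri-hybrid
(African/European/Amerindian) cohort: overdispersed per-sample call counts,
loss-skewed call ratios with losses several-fold smaller than gains,
X-chromosome call enrichment, a second caller with partial concordance,
population-frequency and known-variant reference panels, planted two-locus
risk genotypes, and qPCR/ddPCR plates for assay validation.

Every emitted artifact is accompanied by ground truth.  Rarity labels are
*recomputed* from the emitted artifacts by brute-force all-pairs interval
matching (independent of the filtering pipeline's indexed implementation),
so a rare-CNV pipeline run with the same overlap rule must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GRCH37_LENGTHS
from .intervals import GenomicInterval, OverlapRule
from .io import (
    GAIN,
    LOSS,
    PRIMARY_CALLER,
    SECONDARY_CALLER,
    CNVSegment,
    PanelEntry,
    ReferencePanel,
    SampleRecord,
)

#: probe pitch used to convert segment size to a supporting probe count
PROBE_SPACING_BP = 600

JOINT_CATEGORIES = (
    "diploid_both",
    "del_A_only",
    "del_B_only",
    "del_both",
    "dup_A_only",
    "dup_B_only",
    "dup_both",
    "mixed",
)

#: control joint-genotype distribution for the two-locus synergy study
DEFAULT_JOINT_CONTROL_PROBS: dict[str, float] = {
    "diploid_both": 0.68,
    "del_A_only": 0.10,
    "del_B_only": 0.06,
    "del_both": 0.03,
    "dup_A_only": 0.05,
    "dup_B_only": 0.04,
    "dup_both": 0.02,
    "mixed": 0.02,
}

#: planted per-category odds ratios vs the diploid-at-both-loci reference
DEFAULT_JOINT_ORS: dict[str, float] = {
    "diploid_both": 1.0,
    "del_A_only": 3.6,
    "del_B_only": 1.8,
    "del_both": 5.9,
    "dup_A_only": 0.2,
    "dup_B_only": 0.5,
    "dup_both": 0.2,
    "mixed": 1.0,
}


@dataclass(frozen=True)
class RiskLocusSpec:
    """A locus where deletion/duplication carriership is planted with target ORs."""

    locus_id: str
    interval: GenomicInterval
    del_freq_control: float = 0.10
    dup_freq_control: float = 0.05
    target_or_del: float = 1.0
    target_or_dup: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.del_freq_control < 1 and 0 <= self.dup_freq_control < 1):
            raise ValueError("control carrier frequencies must be in [0, 1)")
        if self.del_freq_control + self.dup_freq_control >= 1:
            raise ValueError("del_freq + dup_freq must be < 1")
        if self.target_or_del <= 0 or self.target_or_dup <= 0:
            raise ValueError("target odds ratios must be positive")


def _default_risk_loci() -> list[RiskLocusSpec]:
    return [
        RiskLocusSpec(
            "FCGR3B",
            GenomicInterval("1", 161592986, 161601753),
            del_freq_control=0.10,
            dup_freq_control=0.08,
            target_or_del=3.6,
            target_or_dup=0.2,
        ),
        RiskLocusSpec(
            "ADAM3A",
            GenomicInterval("8", 39306013, 39442632),
            del_freq_control=0.12,
            dup_freq_control=0.05,
            target_or_del=1.6,
            target_or_dup=0.2,
        ),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the array-screen arm of the motivating study design:
    23 lupus-nephritis cases vs 110 healthy controls, ~19 calls per case and
    ~24 per control (overdispersed), 76%/62% losses among case/control calls,
    losses several-fold smaller than gains, and an X-enriched chromosome
    distribution.
    """

    n_cases: int = 23
    n_controls: int = 110
    seed: int = 0
    mean_calls_case: float = 19.4
    mean_calls_control: float = 24.1
    call_dispersion: float = 4.5  # NB size parameter; var = m + m^2/k
    del_fraction: float = 0.76  # losses among case calls
    del_fraction_control: Optional[float] = 0.62
    del_size_logmean: float = 10.3  # ln bp; median ~30 kb
    dup_size_logmean: float = 11.6  # ln bp; median ~110 kb
    size_logsd: float = 0.8
    x_enrichment: float = 10.0  # multiplier on X length weight
    risk_loci: list[RiskLocusSpec] = field(default_factory=_default_risk_loci)
    panel_overlap_fraction: float = 0.4
    caller2_concordance: float = 0.8
    caller2_noise_mean: float = 3.0
    ancestry_dirichlet: tuple[float, float, float] = (2.0, 6.0, 1.0)
    # planting rates for the four-step rare cascade, applied to case
    # background calls: P(shared with controls), then among case-exclusive
    # calls P(common in the frequency panel), then P(known variant).
    control_shared_fraction: float = 0.80
    panel_common_fraction: float = 0.24
    known_variant_fraction: float = 0.27
    female_fraction_case: float = 0.90
    female_fraction_control: float = 0.70
    min_probes_loss: int = 25
    min_probes_gain: int = 50
    overlap_rule: OverlapRule = field(default_factory=OverlapRule)

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        for name in (
            "mean_calls_case",
            "mean_calls_control",
            "call_dispersion",
            "x_enrichment",
            "caller2_noise_mean",
        ):
            if getattr(self, name) <= 0 and name != "caller2_noise_mean":
                raise ValueError(f"{name} must be positive")
        for name in (
            "del_fraction",
            "panel_overlap_fraction",
            "caller2_concordance",
            "control_shared_fraction",
            "panel_common_fraction",
            "known_variant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "risk_loci" in raw:
            raw["risk_loci"] = [
                RiskLocusSpec(
                    locus_id=r["locus_id"],
                    interval=GenomicInterval(r["chrom"], r["start"], r["end"]),
                    del_freq_control=r.get("del_freq_control", 0.0),
                    dup_freq_control=r.get("dup_freq_control", 0.0),
                    target_or_del=r.get("target_or_del", 1.0),
                    target_or_dup=r.get("target_or_dup", 1.0),
                )
                for r in raw["risk_loci"]
            ]
        if "ancestry_dirichlet" in raw:
            raw["ancestry_dirichlet"] = tuple(raw["ancestry_dirichlet"])
        if "overlap_rule" in raw:
            raw["overlap_rule"] = OverlapRule(**raw["overlap_rule"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["risk_loci"] = [
            {
                "locus_id": s.locus_id,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "del_freq_control": s.del_freq_control,
                "dup_freq_control": s.dup_freq_control,
                "target_or_del": s.target_or_del,
                "target_or_dup": s.target_or_dup,
            }
            for s in self.risk_loci
        ]
        raw["ancestry_dirichlet"] = list(self.ancestry_dirichlet)
        raw["overlap_rule"] = {
            "mode": self.overlap_rule.mode,
            "fraction": self.overlap_rule.fraction,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery tests."""

    genotypes: pd.DataFrame  # sample_id, locus_id, genotype
    segment_labels: pd.DataFrame  # per case caller-1 segment: category, is_rare
    planted_ors: dict[str, dict[str, float]]


# ---------------------------------------------------------------------------
# risk-locus genotypes


def case_genotype_probs(spec: RiskLocusSpec) -> dict[str, float]:
    """Case del/dup carrier probabilities from control frequencies and ORs.

    Per class the planted odds ratio is on carrier-vs-rest odds:
    ``odds_case = OR * p_ctrl / (1 - p_ctrl)``, inverted back to a
    probability.  Raises if the implied case probabilities are infeasible.
    """
    probs = {}
    for cls, p_ctrl, or_target in (
        ("del", spec.del_freq_control, spec.target_or_del),
        ("dup", spec.dup_freq_control, spec.target_or_dup),
    ):
        if p_ctrl == 0:
            probs[cls] = 0.0
            continue
        odds = or_target * p_ctrl / (1.0 - p_ctrl)
        probs[cls] = odds / (1.0 + odds)
    if probs["del"] + probs["dup"] >= 1.0:
        raise ValueError(
            f"locus {spec.locus_id}: case del+dup probability "
            f"{probs['del'] + probs['dup']:.3f} >= 1 (infeasible OR/frequency combination)"
        )
    return probs


def genotype_risk_loci(
    spec: RiskLocusSpec, n_cases: int, n_controls: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-sample genotypes in {del, diploid, dup} for one locus.

    Returns ``(case_genotypes, control_genotypes)`` as string arrays.
    """
    rng = np.random.default_rng(seed)
    return (
        _draw_genotypes(spec, n_cases, rng, group="case"),
        _draw_genotypes(spec, n_controls, rng, group="control"),
    )


def _draw_genotypes(spec: RiskLocusSpec, n: int, rng, group: str) -> np.ndarray:
    if group == "case":
        p = case_genotype_probs(spec)
        p_del, p_dup = p["del"], p["dup"]
    else:
        p_del, p_dup = spec.del_freq_control, spec.dup_freq_control
    u = rng.random(n)
    out = np.full(n, "diploid", dtype=object)
    out[u < p_del] = "del"
    out[(u >= p_del) & (u < p_del + p_dup)] = "dup"
    return out


def simulate_joint_cohort(
    n_cases: int,
    n_controls: int,
    seed: int,
    control_probs: Optional[Mapping[str, float]] = None,
    target_ors: Optional[Mapping[str, float]] = None,
    ancestry_dirichlet: Sequence[float] = (2.0, 6.0, 1.0),
    female_fraction_case: float = 0.9,
    female_fraction_control: float = 0.7,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Plant joint two-locus genotype categories with exact per-category ORs.

    Controls draw categories at ``control_probs``; cases draw from the
    odds-tilted distribution ``p_case(k) ∝ p_ctrl(k) * OR(k)``, which under
    case-control sampling makes the odds ratio of category *k* versus the
    reference exactly ``OR(k)``.  Covariates (sex, ancestry) are drawn
    independently of genotype, so adjusted and unadjusted ORs coincide in
    expectation.
    """
    q = dict(DEFAULT_JOINT_CONTROL_PROBS if control_probs is None else control_probs)
    ors = dict(DEFAULT_JOINT_ORS if target_ors is None else target_ors)
    cats = [c for c in JOINT_CATEGORIES if c in q]
    qv = np.array([q[c] for c in cats], dtype=float)
    if abs(qv.sum() - 1.0) > 1e-9:
        raise ValueError("control category probabilities must sum to 1")
    tilt = qv * np.array([ors.get(c, 1.0) for c in cats])
    pv = tilt / tilt.sum()

    rng = np.random.default_rng(seed)
    samples = _draw_samples(
        n_cases,
        n_controls,
        rng,
        ancestry_dirichlet,
        female_fraction_case,
        female_fraction_control,
    )
    rows = []
    case_draws = rng.choice(len(cats), size=n_cases, p=pv)
    ctrl_draws = rng.choice(len(cats), size=n_controls, p=qv)
    it_case = iter(case_draws)
    it_ctrl = iter(ctrl_draws)
    for s in samples:
        k = next(it_case) if s.is_case else next(it_ctrl)
        rows.append({"sample_id": s.sample_id, "category": cats[k]})
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_samples(
    n_cases, n_controls, rng, ancestry_dirichlet, female_case, female_control
) -> list[SampleRecord]:
    samples = []
    alphas = np.asarray(ancestry_dirichlet, dtype=float)
    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        sid = f"SLE{i + 1:03d}" if is_case else f"BRZ{i - n_cases + 1:03d}"
        anc = rng.dirichlet(alphas)
        anc = tuple(float(a) for a in anc / anc.sum())
        sex = "F" if rng.random() < (female_case if is_case else female_control) else "M"
        samples.append(SampleRecord(sid, "case" if is_case else "control", sex, anc))
    return samples


def _chrom_weights(x_enrichment: float) -> tuple[list[str], np.ndarray]:
    chroms = list(GRCH37_LENGTHS)
    w = np.array([GRCH37_LENGTHS[c] for c in chroms], dtype=float)
    w[chroms.index("X")] *= x_enrichment
    return chroms, w / w.sum()


def _draw_background_segment(
    rng, cfg: SimulationConfig, sample_id: str, is_loss: bool, chroms, weights
) -> CNVSegment:
    logmean = cfg.del_size_logmean if is_loss else cfg.dup_size_logmean
    min_probes = cfg.min_probes_loss if is_loss else cfg.min_probes_gain
    min_size = min_probes * PROBE_SPACING_BP
    size = 0
    for _ in range(200):
        size = int(rng.lognormal(logmean, cfg.size_logsd))
        if size >= min_size:
            break
    size = max(size, min_size)
    ci = rng.choice(len(chroms), p=weights)
    chrom = chroms[ci]
    length = GRCH37_LENGTHS[chrom]
    size = min(size, length - 1)
    start = int(rng.integers(1, length - size + 1))
    if is_loss:
        cn = 0 if rng.random() < 0.1 else 1
    else:
        cn = 4 if rng.random() < 0.1 else 3
    return CNVSegment(
        sample_id=sample_id,
        interval=GenomicInterval(chrom, start, start + size - 1),
        cn_state=cn,
        n_probes=max(1, size // PROBE_SPACING_BP),
        caller_id=PRIMARY_CALLER,
    )


def _as_secondary(seg: CNVSegment) -> CNVSegment:
    return CNVSegment(seg.sample_id, seg.interval, seg.cn_state, seg.n_probes, SECONDARY_CALLER)


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort.

    Returns ``(samples, segments_caller1, segments_caller2, panels,
    ground_truth)`` where ``panels`` is a dict with keys ``frequency``
    (population-frequency panel) and ``known`` (known-variant panel).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = _draw_samples(
        cfg.n_cases,
        cfg.n_controls,
        rng,
        cfg.ancestry_dirichlet,
        cfg.female_fraction_case,
        cfg.female_fraction_control,
    )
    cases = [s for s in samples if s.is_case]
    controls = [s for s in samples if not s.is_case]
    chroms, weights = _chrom_weights(cfg.x_enrichment)

    segs1: list[CNVSegment] = []
    segs2: list[CNVSegment] = []
    freq_entries: list[PanelEntry] = []
    known_entries: list[PanelEntry] = []
    intents: dict[tuple, str] = {}

    del_frac_control = (
        cfg.del_fraction if cfg.del_fraction_control is None else cfg.del_fraction_control
    )

    k = cfg.call_dispersion
    for s in samples:
        mean = cfg.mean_calls_case if s.is_case else cfg.mean_calls_control
        n_calls = int(rng.negative_binomial(k, k / (k + mean)))
        del_frac = cfg.del_fraction if s.is_case else del_frac_control
        for _ in range(n_calls):
            seg = _draw_background_segment(
                rng, cfg, s.sample_id, rng.random() < del_frac, chroms, weights
            )
            segs1.append(seg)
            if s.is_case:
                u = rng.random()
                if u < cfg.control_shared_fraction:
                    intent = "shared_with_controls"
                    host = controls[int(rng.integers(len(controls)))]
                    twin = CNVSegment(host.sample_id, seg.interval, seg.cn_state, seg.n_probes)
                    segs1.append(twin)
                    if rng.random() < cfg.caller2_concordance:
                        segs2.append(_as_secondary(twin))
                elif rng.random() < cfg.panel_common_fraction:
                    intent = "panel_common"
                    freq_entries.append(
                        PanelEntry(
                            seg.interval,
                            seg.cnv_type,
                            float(rng.uniform(0.01, 0.20)),
                        )
                    )
                elif rng.random() < cfg.known_variant_fraction:
                    intent = "known_variant"
                    known_entries.append(PanelEntry(seg.interval, seg.cnv_type, None))
                else:
                    intent = "candidate_rare"
                    if rng.random() < cfg.panel_overlap_fraction:
                        # rare but catalogued below the 1% threshold
                        freq_entries.append(
                            PanelEntry(
                                seg.interval,
                                seg.cnv_type,
                                float(rng.uniform(0.0005, 0.009)),
                            )
                        )
                intents[seg.key] = intent
            # second caller re-detects each call independently
            if rng.random() < cfg.caller2_concordance:
                segs2.append(_as_secondary(seg))

    # caller-2 private noise calls
    for s in samples:
        n_noise = int(rng.poisson(cfg.caller2_noise_mean))
        for _ in range(n_noise):
            seg = _draw_background_segment(
                rng, cfg, s.sample_id, rng.random() < 0.5, chroms, weights
            )
            segs2.append(_as_secondary(seg))

    # planted risk-locus genotypes: carriers get one whole-locus segment in
    # both call sets (validated large loci; both callers detect them)
    geno_rows = []
    planted_ors: dict[str, dict[str, float]] = {}
    for spec in cfg.risk_loci:
        locus_seed = int(rng.integers(0, 2**31 - 1))
        g_case, g_ctrl = genotype_risk_loci(spec, len(cases), len(controls), locus_seed)
        planted_ors[spec.locus_id] = {
            "del": spec.target_or_del,
            "dup": spec.target_or_dup,
        }
        for group_samples, genos in ((cases, g_case), (controls, g_ctrl)):
            for s, g in zip(group_samples, genos):
                geno_rows.append(
                    {"sample_id": s.sample_id, "locus_id": spec.locus_id, "genotype": g}
                )
                if g == "diploid":
                    continue
                cn = 1 if g == "del" else 3
                seg = CNVSegment(
                    s.sample_id,
                    spec.interval,
                    cn,
                    n_probes=max(1, spec.interval.size // PROBE_SPACING_BP),
                )
                segs1.append(seg)
                segs2.append(_as_secondary(seg))
                if s.is_case:
                    intents[seg.key] = "risk_locus"

    panels = {
        "frequency": ReferencePanel("population_frequency", freq_entries),
        "known": ReferencePanel("known_variants", known_entries),
    }
    case_ids = {s.sample_id for s in cases}
    labels = _brute_force_rare_labels(
        [s for s in segs1 if s.sample_id in case_ids],
        [s for s in segs1 if s.sample_id not in case_ids],
        panels["frequency"],
        panels["known"],
        segs2,
        cfg.overlap_rule,
        intents,
    )
    truth = GroundTruth(
        genotypes=pd.DataFrame(geno_rows),
        segment_labels=labels,
        planted_ors=planted_ors,
    )
    return samples, segs1, segs2, panels, truth


def _brute_force_rare_labels(
    case_segs: list[CNVSegment],
    control_segs: list[CNVSegment],
    freq_panel: ReferencePanel,
    known_panel: ReferencePanel,
    caller2_segs: list[CNVSegment],
    rule: OverlapRule,
    intents: Mapping[tuple, str],
    max_freq: float = 0.01,
) -> pd.DataFrame:
    """All-pairs evaluation of the four-step cascade (reference oracle)."""
    rows = []
    for seg in case_segs:
        category = "rare"
        if any(
            c.cnv_type == seg.cnv_type and rule.matches(seg.interval, c.interval)
            for c in control_segs
        ):
            category = "in_controls"
        elif any(
            e.cnv_type == seg.cnv_type
            and e.frequency is not None
            and e.frequency >= max_freq
            and rule.matches(seg.interval, e.interval)
            for e in freq_panel.entries
        ):
            category = "panel_common"
        elif any(
            e.cnv_type == seg.cnv_type and rule.matches(seg.interval, e.interval)
            for e in known_panel.entries
        ):
            category = "known_variant"
        elif not any(
            c.sample_id == seg.sample_id
            and c.cnv_type == seg.cnv_type
            and rule.matches(seg.interval, c.interval)
            for c in caller2_segs
        ):
            category = "no_second_caller"
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chrom": seg.interval.chrom,
                "start": seg.interval.start,
                "end": seg.interval.end,
                "cn_state": seg.cn_state,
                "intent": intents.get(seg.key, "background"),
                "category": category,
                "is_rare": category == "rare",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "cn_state",
            "intent",
            "category",
            "is_rare",
        ],
    )


# ---------------------------------------------------------------------------
# assay simulators


def simulate_qpcr_plate(
    true_cn: Mapping[str, int],
    efficiency: float = 2.0,
    ct_ref_mean: float = 25.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate Ct plate for a target gene against a diploid reference gene.

    With amplification efficiency *E* per cycle, a sample at copy number
    ``cn`` amplifies the target ``cn/2``-fold relative to the reference, so
    ``Ct_target = Ct_ref_mean - log_E(cn/2)`` plus replicate noise.  Copy
    number 0 yields non-amplifying target replicates (NaN sentinel).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, cn in true_cn.items():
        if cn < 0:
            raise ValueError("true_cn must be >= 0")
        ref = ct_ref_mean + rng.normal(0, noise_sd, size=3)
        if cn == 0:
            tgt = np.full(3, np.nan)
        else:
            shift = -np.log(cn / 2.0) / np.log(efficiency)
            tgt = ct_ref_mean + shift + rng.normal(0, noise_sd, size=3)
        rows.append({"sample_id": sid, "gene_role": "target",
                     "ct1": tgt[0], "ct2": tgt[1], "ct3": tgt[2]})
        rows.append({"sample_id": sid, "gene_role": "reference",
                     "ct1": ref[0], "ct2": ref[1], "ct3": ref[2]})
    return pd.DataFrame(rows)


def simulate_ddpcr_well(
    true_cn: int,
    droplets: int = 15000,
    ref_copies_per_droplet: float = 0.8,
    droplet_volume_nl: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """One target/reference ddPCR well pair for a sample at a known copy number.

    Droplet occupancy is Poisson, so the positive probability at mean
    occupancy λ is ``1 - exp(-λ)``; the target runs at ``λ_ref * cn / 2``.
    """
    if droplets <= 0 or ref_copies_per_droplet <= 0:
        raise ValueError("droplets and ref_copies_per_droplet must be positive")
    if true_cn < 0:
        raise ValueError("true_cn must be >= 0")
    rng = np.random.default_rng(seed)
    lam_ref = ref_copies_per_droplet
    lam_tgt = lam_ref * true_cn / 2.0
    pos_ref = int(rng.binomial(droplets, 1.0 - np.exp(-lam_ref)))
    pos_tgt = int(rng.binomial(droplets, 1.0 - np.exp(-lam_tgt))) if lam_tgt > 0 else 0
    return pd.DataFrame(
        [
            {"gene_role": "target", "positives": pos_tgt, "total": droplets,
             "droplet_volume_nl": droplet_volume_nl},
            {"gene_role": "reference", "positives": pos_ref, "total": droplets,
             "droplet_volume_nl": droplet_volume_nl},
        ]
    )
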