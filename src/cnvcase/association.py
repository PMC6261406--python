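"""Single- and joint two-locus copy-number association with ancestry adjustment.

Integer copy numbers are classified into del (CN < 2), diploid (CN = 2) and
dup (CN > 2).  For a locus pair, each sample falls into one of eight joint
categories; one logistic model with category indicators plus sex and one
admixture proportion estimates each category's odds ratio against the
diploid-at-both-loci reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import design_from_samples, fit_logit, status_vector
from .io import SampleRecord

log = logging.getLogger(__name__)

DEL, DIPLOID, DUP = "del", "diploid", "dup"

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


@dataclass(frozen=True)
class CopyNumberCall:
    """Per-sample integer copy number at one locus from one assay."""

    sample_id: str
    locus_id: str
    cn: int
    source: str = "array"  # array | qpcr | ddpcr

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")
        if self.source not in ("array", "qpcr", "ddpcr"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def cn_class(self) -> str:
        return classify_genotype(self.cn)


def classify_genotype(cn: int) -> str:
    """del for CN < 2, diploid for CN = 2, dup for CN > 2."""
    if cn < 0:
        raise ValueError(f"copy number must be >= 0, got {cn}")
    if cn < 2:
        return DEL
    if cn == 2:
        return DIPLOID
    return DUP


@dataclass(frozen=True)
class JointGenotype:
    sample_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in JOINT_CATEGORIES:
            raise ValueError(f"unknown joint category {self.category!r}")


def joint_genotype(call_A: CopyNumberCall, call_B: CopyNumberCall) -> JointGenotype:
    """Eight-way joint category of one sample's calls at loci A and B."""
    if call_A.sample_id != call_B.sample_id:
        raise ValueError("calls belong to different samples")
    if call_A.locus_id == call_B.locus_id:
        raise ValueError("joint genotype needs two distinct loci")
    a, b = call_A.cn_class, call_B.cn_class
    if a == DIPLOID and b == DIPLOID:
        cat = "diploid_both"
    elif a == DEL and b == DEL:
        cat = "del_both"
    elif a == DUP and b == DUP:
        cat = "dup_both"
    elif a == DEL and b == DIPLOID:
        cat = "del_A_only"
    elif a == DIPLOID and b == DEL:
        cat = "del_B_only"
    elif a == DUP and b == DIPLOID:
        cat = "dup_A_only"
    elif a == DIPLOID and b == DUP:
        cat = "dup_B_only"
    else:
        cat = "mixed"
    return JointGenotype(call_A.sample_id, cat)


def joint_genotypes_from_calls(
    calls: Iterable[CopyNumberCall], locus_a: str, locus_b: str
) -> list[JointGenotype]:
    """Pair calls per sample; samples missing either locus are logged and dropped."""
    by_sample: dict[str, dict[str, CopyNumberCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, {})[c.locus_id] = c
    out = []
    for sid, at in sorted(by_sample.items()):
        if locus_a not in at or locus_b not in at:
            log.info("sample %s lacks a call at %s or %s; excluded", sid, locus_a, locus_b)
            continue
        out.append(joint_genotype(at[locus_a], at[locus_b]))
    return out


@dataclass
class AssociationRow:
    category: str
    n_case: int
    n_control: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AssociationTable:
    """Per-category ORs against the reference category, one fitted model."""

    reference: str
    rows: list[AssociationRow]
    covariates: tuple[str, ...]
    method: str
    separation: bool
    excluded_categories: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "n_case": r.n_case,
                    "n_control": r.n_control,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "reference": self.reference,
                    "covariates": "+".join(self.covariates),
                    "fit_method": self.method,
                }
                for r in self.rows
            ]
        )

    def row(self, category: str) -> AssociationRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)


def fit_association(
    genotypes: Sequence[JointGenotype],
    samples: Sequence[SampleRecord],
    ancestry_component: str = "afr",
    reference: str = "diploid_both",
    include_mixed: bool = False,
) -> AssociationTable:
    """One logistic model: status ~ category dummies + sex + ancestry component.

    Samples in the ``mixed`` category (del at one locus, dup at the other)
    are excluded by default and reported in ``excluded_categories``; pass
    ``include_mixed=True`` to model them as their own dummy.  Empty
    categories yield NA rows.
    """
    by_id = {g.sample_id: g.category for g in genotypes}
    used = [s for s in samples if s.sample_id in by_id]
    excluded = []
    if not include_mixed:
        n_mixed = sum(1 for s in used if by_id[s.sample_id] == "mixed")
        if n_mixed:
            excluded.append("mixed")
        used = [s for s in used if by_id[s.sample_id] != "mixed"]
    counts = {
        cat: (
            sum(1 for s in used if s.is_case and by_id[s.sample_id] == cat),
            sum(1 for s in used if not s.is_case and by_id[s.sample_id] == cat),
        )
        for cat in JOINT_CATEGORIES
    }
    if counts[reference][0] == 0 or counts[reference][1] == 0:
        raise ValueError(f"reference category {reference!r} must be non-empty in both groups")

    modelled = [
        cat
        for cat in JOINT_CATEGORIES
        if cat != reference
        and sum(counts[cat]) > 0
        and (include_mixed or cat != "mixed")
    ]
    X = design_from_samples(used, ancestry_component)
    for cat in modelled:
        X[f"cat_{cat}"] = [1.0 if by_id[s.sample_id] == cat else 0.0 for s in used]
    y = status_vector(used).loc[X.index].to_numpy()
    fit = fit_logit(X, y)

    rows = [
        AssociationRow(reference, *counts[reference], 1.0, np.nan, np.nan, np.nan)
    ]
    for cat in JOINT_CATEGORIES:
        if cat == reference:
            continue
        if cat in modelled:
            name = f"cat_{cat}"
            lo, hi = fit.conf_int(name)
            rows.append(
                AssociationRow(
                    cat,
                    *counts[cat],
                    fit.odds_ratio(name),
                    lo,
                    hi,
                    float(fit.pvalues[name]),
                )
            )
        elif not include_mixed and cat == "mixed":
            continue
        else:
            rows.append(AssociationRow(cat, *counts[cat], np.nan, np.nan, np.nan, np.nan))
    return AssociationTable(
        reference=reference,
        rows=rows,
        covariates=("sex", f"ancestry_{ancestry_component}"),
        method=fit.method,
        separation=fit.separation,
        excluded_categories=tuple(excluded),
        notes=tuple(fit.notes),
    )


def genotype_frequency_table(
    calls: Iterable[CopyNumberCall], samples: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per-locus, per-group counts and proportions of CN classes and integer CN."""
    group_of = {s.sample_id: s.group for s in samples}
    rows = []
    df = pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "group": group_of[c.sample_id],
                "cn": c.cn,
                "cn_class": c.cn_class,
            }
            for c in calls
            if c.sample_id in group_of
        ]
    )
    if df.empty:
        raise ValueError("no calls for known samples")
    for (locus, group), sub in df.groupby(["locus_id", "group"]):
        n = len(sub)
        for cn, k in sub["cn"].value_counts().sort_index().items():
            rows.append(
                {
                    "locus_id": locus,
                    "group": group,
                    "cn": int(cn),
                    "cn_class": classify_genotype(int(cn)),
                    "count": int(k),
                    "proportion": k / n,
                }
            )
    return pd.DataFrame(rows)
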