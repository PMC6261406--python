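"""Readers, writers and validation for the tabular formats of the pipeline.

Every downstream module consumes only the domain types defined here:
:class:`CNVSegment`, :class:`SampleRecord`, :class:`ReferencePanel` and
:class:`GeneAnnotation`.  All on-disk formats are plain TSV with a header,
except BED4 (0-based half-open), which is converted to the internal 1-based
inclusive convention on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, interval_size_kb, normalize_chrom

log = logging.getLogger(__name__)

LOSS = "loss"
GAIN = "gain"
PRIMARY_CALLER = "primary_caller"
SECONDARY_CALLER = "secondary_caller"

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_state", "n_probes", "caller_id"]
PANEL_COLUMNS = ["chrom", "start", "end", "cnv_type", "frequency"]
GENE_COLUMNS = ["gene_symbol", "chrom", "start", "end", "list_id"]
MANIFEST_COLUMNS = ["sample_id", "group", "sex", "afr", "eur", "amr"]


class FormatError(ValueError):
    """The file is structurally wrong (missing columns, bad dialect)."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message names the row."""


def cnv_type_of(cn_state: int) -> str:
    if cn_state < 2:
        return LOSS
    if cn_state > 2:
        return GAIN
    raise ValidationError("cn_state 2 is diploid, not a CNV")


@dataclass(frozen=True)
class CNVSegment:
    """One called deletion/duplication interval in one sample from one caller."""

    sample_id: str
    interval: GenomicInterval
    cn_state: int
    n_probes: Optional[int] = None
    caller_id: str = PRIMARY_CALLER

    def __post_init__(self) -> None:
        if self.cn_state < 0:
            raise ValidationError(f"cn_state must be >= 0, got {self.cn_state}")
        if self.cn_state == 2:
            raise ValidationError(
                f"segment {self.sample_id} {self.interval}: cn_state 2 is not a CNV"
            )
        if self.n_probes is not None and self.n_probes < 1:
            raise ValidationError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.caller_id not in (PRIMARY_CALLER, SECONDARY_CALLER):
            raise ValidationError(f"unknown caller_id {self.caller_id!r}")

    @property
    def cnv_type(self) -> str:
        return cnv_type_of(self.cn_state)

    @property
    def key(self) -> tuple:
        """Identity used for set semantics and ground-truth matching."""
        return (
            self.sample_id,
            self.interval.chrom,
            self.interval.start,
            self.interval.end,
            self.cn_state,
            self.caller_id,
        )

    @property
    def size_kb(self) -> int:
        return interval_size_kb(self.interval)


@dataclass(frozen=True)
class SampleRecord:
    """Study subject: case/control label, sex, admixture proportions.

    Ancestry proportions (African, European, Amerindian) must sum to 1.
    """

    sample_id: str
    group: str
    sex: str
    ancestry: tuple[float, float, float]  # (afr, eur, amr)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValidationError(f"unknown group label {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        total = sum(self.ancestry)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"ancestry proportions of {self.sample_id} sum to {total:.4f}, not 1"
            )
        if any(a < 0 or a > 1 for a in self.ancestry):
            raise ValidationError(f"ancestry proportions of {self.sample_id} outside [0,1]")

    @property
    def is_case(self) -> bool:
        return self.group == "case"

    def ancestry_component(self, which: str) -> float:
        return dict(zip(("afr", "eur", "amr"), self.ancestry))[which]


@dataclass(frozen=True)
class PanelEntry:
    interval: GenomicInterval
    cnv_type: str
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cnv_type not in (LOSS, GAIN):
            raise ValidationError(f"unknown cnv_type {self.cnv_type!r}")
        if self.frequency is not None and not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(f"frequency {self.frequency} outside [0,1]")


@dataclass
class ReferencePanel:
    """Population-frequency or known-variant interval panel."""

    name: str
    entries: list[PanelEntry] = field(default_factory=list)

    @property
    def has_frequencies(self) -> bool:
        return any(e.frequency is not None for e in self.entries)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval assigned to one of the three curated lists.

    list 1: genes with CNVs previously associated with SLE; list 2: genes
    from SLE linkage/GWAS hits; list 3: autoimmunity genes.
    """

    gene_symbol: str
    interval: GenomicInterval
    list_id: int = 1

    def __post_init__(self) -> None:
        if self.list_id not in (1, 2, 3):
            raise ValidationError(f"list_id must be 1, 2 or 3, got {self.list_id}")


# ---------------------------------------------------------------------------
# segment I/O


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_segments(path, dialect: str = "chas_tsv", default_sample_id: str = "NA") -> list[CNVSegment]:
    """Read CNV segment calls.

    ``chas_tsv``: headered TSV with columns sample_id, chrom, start, end,
    cn_state, n_probes, caller_id (coordinates already 1-based inclusive).
    ``bed``: BED4 where the name column holds ``del``/``dup`` or
    ``<sample_id>:<del|dup>``; 0-based half-open starts are shifted to
    1-based inclusive on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "chas_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str}, comment="#")
        _require_columns(df, ["sample_id", "chrom", "start", "end", "cn_state"], path)
        segments = []
        for idx, row in enumerate(df.itertuples(index=False), start=2):
            try:
                n_probes = getattr(row, "n_probes", None)
                if n_probes is not None and pd.isna(n_probes):
                    n_probes = None
                seg = CNVSegment(
                    sample_id=str(row.sample_id),
                    interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    cn_state=int(row.cn_state),
                    n_probes=int(n_probes) if n_probes is not None else None,
                    caller_id=getattr(row, "caller_id", PRIMARY_CALLER),
                )
            except ValueError as exc:
                raise ValidationError(f"{path} line {idx}: {exc}") from exc
            segments.append(seg)
        return segments
    if dialect == "bed":
        segments = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(f"{path} line {lineno}: BED4 needs 4 columns")
                chrom, start0, end, name = fields[:4]
                sample_id, _, kind = name.rpartition(":")
                sample_id = sample_id or default_sample_id
                kind = kind.lower()
                if kind not in ("del", "dup"):
                    raise FormatError(f"{path} line {lineno}: name must end in del/dup")
                try:
                    seg = CNVSegment(
                        sample_id=sample_id,
                        interval=GenomicInterval(chrom, int(start0) + 1, int(end)),
                        cn_state=1 if kind == "del" else 3,
                    )
                except ValueError as exc:
                    raise ValidationError(f"{path} line {lineno}: {exc}") from exc
                segments.append(seg)
        return segments
    raise FormatError(f"unknown dialect {dialect!r}")


def segments_to_frame(segments: Iterable[CNVSegment]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "cn_state": s.cn_state,
            "n_probes": s.n_probes,
            "caller_id": s.caller_id,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(segments: Iterable[CNVSegment], path, dialect: str = "chas_tsv") -> None:
    path = Path(path)
    if dialect == "chas_tsv":
        df = segments_to_frame(segments)
        df.to_csv(path, sep="\t", index=False, na_rep="")
        return
    if dialect == "bed":
        with open(path, "w") as fh:
            for s in segments:
                kind = "del" if s.cnv_type == LOSS else "dup"
                fh.write(
                    f"chr{s.interval.chrom}\t{s.interval.start - 1}\t{s.interval.end}"
                    f"\t{s.sample_id}:{kind}\n"
                )
        return
    raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# manifest, panels, gene lists


def read_sample_manifest(path) -> list[SampleRecord]:
    """Read the subject manifest; ancestry triples off by <=1e-3 are renormalized."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    _require_columns(df, MANIFEST_COLUMNS, path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.sample_id)
        if sid in seen:
            raise ValidationError(f"{path} line {idx}: duplicate sample_id {sid!r}")
        seen.add(sid)
        triple = (float(row.afr), float(row.eur), float(row.amr))
        total = sum(triple)
        if abs(total - 1.0) > 1e-3:
            raise ValidationError(
                f"{path} line {idx}: ancestry proportions sum to {total:.4f}"
            )
        triple = tuple(a / total for a in triple)
        try:
            records.append(SampleRecord(sid, str(row.group), str(row.sex), triple))
        except ValueError as exc:
            raise ValidationError(f"{path} line {idx}: {exc}") from exc
    return records


def write_sample_manifest(samples: Iterable[SampleRecord], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "sex": s.sex,
            "afr": s.ancestry[0],
            "eur": s.ancestry[1],
            "amr": s.ancestry[2],
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path, name: Optional[str] = None) -> ReferencePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    _require_columns(df, ["chrom", "start", "end", "cnv_type"], path)
    entries = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        freq = getattr(row, "frequency", None)
        if freq is not None and pd.isna(freq):
            freq = None
        try:
            entries.append(
                PanelEntry(
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    str(row.cnv_type),
                    float(freq) if freq is not None else None,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path} line {idx}: {exc}") from exc
    return ReferencePanel(name or path.stem, entries)


def write_panel(panel: ReferencePanel, path) -> None:
    rows = [
        {
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "cnv_type": e.cnv_type,
            "frequency": e.frequency,
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False, na_rep="")


def read_gene_list(path) -> list[GeneAnnotation]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    _require_columns(df, GENE_COLUMNS, path)
    genes = []
    seen: set[tuple[str, int]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.gene_symbol), int(row.list_id))
        if key in seen:
            raise ValidationError(f"{path} line {idx}: duplicate gene {key}")
        seen.add(key)
        try:
            genes.append(
                GeneAnnotation(
                    str(row.gene_symbol),
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    int(row.list_id),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path} line {idx}: {exc}") from exc
    return genes


def write_gene_list(genes: Iterable[GeneAnnotation], path) -> None:
    rows = [
        {
            "gene_symbol": g.gene_symbol,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "list_id": g.list_id,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assay plates


def read_qpcr_plate(path) -> pd.DataFrame:
    """qPCR plate: sample_id, gene_role (target/reference), ct1, ct2, ct3.

    Non-amplification is encoded as an empty cell or ``NA`` and surfaces as
    NaN; the assay layer treats all-NaN target rows as copy number 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    _require_columns(df, ["sample_id", "gene_role", "ct1", "ct2", "ct3"], path)
    bad = ~df["gene_role"].isin(["target", "reference"])
    if bad.any():
        raise ValidationError(f"{path}: unknown gene_role values {df.loc[bad, 'gene_role'].unique()}")
    return df


def read_ddpcr_wells(path) -> pd.DataFrame:
    """ddPCR wells: sample_id, gene_role, positives, total, droplet_volume_nl."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    _require_columns(df, ["sample_id", "gene_role", "positives", "total", "droplet_volume_nl"], path)
    if (df["positives"] < 0).any() or (df["positives"] > df["total"]).any():
        raise ValidationError(f"{path}: positives must lie in [0, total]")
    return df


# ---------------------------------------------------------------------------
# filters


def apply_probe_filter(
    segments: Iterable[CNVSegment],
    min_probes_loss: int = 25,
    min_probes_gain: int = 50,
) -> list[CNVSegment]:
    """Keep losses/gains supported by at least the given probe counts.

    The array caller's defaults are 25 consecutive probes for deletions and
    50 for duplications; the relaxed gene-screen uses 15/15.  Segments that
    carry no probe count (synthetic or assay-derived calls) pass unfiltered
    with a warning.
    """
    if min_probes_loss < 1 or min_probes_gain < 1:
        raise ValueError("probe thresholds must be >= 1")
    kept = []
    n_unscored = 0
    for seg in segments:
        if seg.n_probes is None:
            n_unscored += 1
            kept.append(seg)
            continue
        threshold = min_probes_loss if seg.cnv_type == LOSS else min_probes_gain
        if seg.n_probes >= threshold:
            kept.append(seg)
    if n_unscored:
        log.warning("%d segments lack probe counts and bypass the probe filter", n_unscored)
    return kept
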