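"""Genomic interval primitives and overlap rules.

Coordinates are 1-based and inclusive on both ends (the convention of
GRCh37 array reports); ``size = end - start + 1``.  BED input/output is the
only place where 0-based half-open coordinates appear, and the conversion
is done explicitly at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Chromosomes the analysis covers: all autosomes plus X (no Y).
ALLOWED_CHROMS: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and validate against the allowed set."""
    chrom = str(label).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    chrom = chrom.upper() if chrom.upper() == "X" else chrom
    if chrom not in ALLOWED_CHROMS:
        raise ValueError(f"unsupported chromosome label {label!r}")
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval on an autosome or X."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on chrom {self.chrom}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # chr-prefixed, printed-table style
        return f"chr{self.chrom}:{self.start}-{self.end}"


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero upward (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def interval_size_kb(interval: GenomicInterval) -> int:
    """Interval size in kb, half-up rounded — the "Size (Kb)" convention."""
    return round_half_up(interval.size / 1000.0)


@dataclass(frozen=True)
class OverlapRule:
    """How two intervals are declared to match.

    mode ``"reciprocal"`` requires the shared span to cover at least
    ``fraction`` of *both* intervals (the standard CNV-matching criterion);
    mode ``"any"`` accepts a single shared base pair.
    """

    mode: str = "reciprocal"
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("reciprocal", "any"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")

    def matches(self, a: GenomicInterval, b: GenomicInterval) -> bool:
        ov = a.overlap_bp(b)
        if ov == 0:
            return False
        if self.mode == "any":
            return True
        return ov >= self.fraction * a.size and ov >= self.fraction * b.size

    def describe(self) -> str:
        if self.mode == "any":
            return "any-overlap (>=1 bp)"
        return f"reciprocal overlap >= {self.fraction:.0%}"
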