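"""Genomic intervals (1-based, inclusive) and interval arithmetic.

All internal coordinates in this package are 1-based inclusive, matching VCF
and the way positions are reported in the clinical genetics literature
("position 111,375,382").  BED I/O converts at the boundary (see
:mod:`linkmend.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one chromosome.

    ``start`` and ``end`` are 1-based and both included; a single base is
    represented as ``start == end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"negative-length interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def merge_intervals(regions: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Returns a sorted, disjoint list covering the same set of bases.
    """
    by_pos = sorted(regions)
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def total_span_bp(regions: Sequence[GenomicInterval]) -> int:
    """Total number of bases covered by the union of ``regions``."""
    return sum(iv.length for iv in merge_intervals(regions))


def total_span_mb(regions: Sequence[GenomicInterval]) -> float:
    """Union span in megabases (1 Mb = 10^6 bp)."""
    return total_span_bp(regions) / 1e6


def point_in_any(regions: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(iv.contains(chrom, pos) for iv in regions)
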