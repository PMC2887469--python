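"""Sequence variants and representation normalization.

Variants follow the VCF left-anchored convention: ``pos`` is the 1-based
position of the first reference base, and for indels ref and alt share a
leading anchor base.  Because the same indel can be written at several
positions in a repeat tract, every set comparison in the filter cascade runs
on *normalized* (left-aligned, anchor-trimmed-then-re-anchored) records so
that membership is representation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Protocol

_ALLELE_CHARS = set("ACGT")


class ReferenceLookup(Protocol):
    """Anything that can serve reference bases (see :class:`linkmend.io.SparseReference`)."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


@dataclass(frozen=True, order=True)
class Variant:
    """A genomic change: SNV or small indel, VCF-style."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference base touched (1-based, inclusive)."""
        return self.pos + len(self.ref) - 1


def trim_shared(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove bases shared at the right end, then at the left end.

    May return an empty ref or alt (a pure indel without its anchor base).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(variant: Variant, reference: ReferenceLookup) -> Variant:
    """Return the canonical left-aligned, minimal representation.

    Implements the standard normalization loop: trim shared flanking bases,
    then, while the alleles end with the same base and one of them would
    become empty, prepend the preceding reference base and retry.  SNVs are
    returned with flanks trimmed only.
    """
    pos, ref, alt = trim_shared(variant.pos, variant.ref, variant.alt)
    if len(ref) == len(alt):
        return Variant(variant.chrom, pos, ref, alt, variant.id)

    # pure indel: ref/alt of form anchor+inserted / anchor+deleted
    while True:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if ref and alt and ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1):
            if pos > 1:
                prev = reference.fetch(variant.chrom, pos - 1, pos - 1)
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
                changed = True
        if not changed:
            break
    pos2, ref, alt = trim_shared(pos, ref, alt)
    return Variant(variant.chrom, pos2, ref, alt, variant.id)


def normalized_key_set(
    variants: Iterable[Variant], reference: ReferenceLookup
) -> set[tuple[str, int, str, str]]:
    """Normalized (chrom, pos, ref, alt) keys for set-membership filtering."""
    return {left_align(v, reference).key for v in variants}
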