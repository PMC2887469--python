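"""Coding-DNA (``c.``) HGVS parsing and formatting.

Deliberately limited to the subset of the nomenclature needed for truncating
variants in a coding sequence: substitutions (``c.412C>T``), deletions
(``c.514_524del11``, ``c.514del``), insertions (``c.514_515insACGT``) and
deletion-insertions (``c.514_515delinsTT``).  Intronic offsets (``c.123+2``)
and protein-level notation are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class HgvsError(ValueError):
    """Malformed or internally inconsistent HGVS string."""


class ChangeKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELINS = "delins"


_BASES = re.compile(r"^[ACGT]+$")

_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del(\d+|[ACGT]+)?$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_DELINS_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")


@dataclass(frozen=True)
class HgvsCodingChange:
    """A change expressed in coding-DNA (CDS) coordinates, 1-based."""

    kind: ChangeKind
    cds_start: int
    cds_end: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.cds_start < 1:
            raise HgvsError(f"CDS position must be >= 1, got {self.cds_start}")
        if self.cds_end < self.cds_start:
            raise HgvsError(
                f"cds_end {self.cds_end} precedes cds_start {self.cds_start}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if allele and not _BASES.match(allele):
                raise HgvsError(f"allele {allele!r} is not an A/C/G/T string")

    @property
    def span(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def length_change(self) -> int:
        """Net change in CDS length (negative for deletions)."""
        if self.kind is ChangeKind.SUBSTITUTION:
            return 0
        if self.kind is ChangeKind.DELETION:
            return -self.span
        if self.kind is ChangeKind.INSERTION:
            return len(self.alt_allele)
        return len(self.alt_allele) - self.span


def parse_hgvs_c(text: str) -> HgvsCodingChange:
    """Parse a coding-DNA HGVS string.

    Raises :class:`HgvsError` on malformed input or when a declared deletion
    length contradicts the position span (e.g. ``c.10_12del5``).
    """
    text = text.strip()

    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        return HgvsCodingChange(
            ChangeKind.SUBSTITUTION, pos, pos, m.group(2), m.group(3)
        )

    m = _INS_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsError(
                f"insertion flanks must be adjacent positions: {text!r}"
            )
        return HgvsCodingChange(ChangeKind.INSERTION, start, end, "", m.group(3))

    m = _DELINS_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return HgvsCodingChange(ChangeKind.DELINS, start, end, "", m.group(3))

    m = _DEL_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        span = end - start + 1
        suffix = m.group(3) or ""
        ref = ""
        if suffix:
            if suffix.isdigit():
                if int(suffix) != span:
                    raise HgvsError(
                        f"declared deletion length {suffix} != span {span} in {text!r}"
                    )
            else:
                if len(suffix) != span:
                    raise HgvsError(
                        f"deleted sequence length {len(suffix)} != span {span} in {text!r}"
                    )
                ref = suffix
        return HgvsCodingChange(ChangeKind.DELETION, start, end, ref, "")

    raise HgvsError(f"unsupported or malformed HGVS c. string: {text!r}")


def format_hgvs_c(change: HgvsCodingChange) -> str:
    """Format a change back to its canonical ``c.`` string.

    ``parse_hgvs_c(format_hgvs_c(x)) == x`` for every supported kind (for
    deletions without a stored reference allele the declared numeric length is
    emitted, e.g. ``c.514_524del11``).
    """
    k = change.kind
    if k is ChangeKind.SUBSTITUTION:
        return f"c.{change.cds_start}{change.ref_allele}>{change.alt_allele}"
    if k is ChangeKind.INSERTION:
        return f"c.{change.cds_start}_{change.cds_end}ins{change.alt_allele}"
    pos = (
        f"{change.cds_start}"
        if change.cds_end == change.cds_start
        else f"{change.cds_start}_{change.cds_end}"
    )
    if k is ChangeKind.DELINS:
        return f"c.{pos}delins{change.alt_allele}"
    tail = change.ref_allele if change.ref_allele else str(change.span)
    return f"c.{pos}del{tail}"
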