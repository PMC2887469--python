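"""Confirmatory analyses for a candidate variant.

* co-segregation of carrier status with affection in a pedigree, tolerant of
  non-penetrant carriers (unaffected carriers are reported, never counted as
  incompatible);
* restriction-site (RFLP) assay design: which enzyme recognition sites a
  variant destroys or creates, so segregation can be followed by digestion
  of a PCR amplicon;
* a control-cohort screen counting truncating alleles in a target region;
* coverage assessment under the covered-base rule (>= 5 reads with a
  positive consensus score).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import Annotator, SEVERITY
from .intervals import GenomicInterval
from .io import SparseReference
from .pedigree import Affection, Pedigree
from .transcripts import TranscriptModel
from .variants import Variant


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Co-segregation
# ---------------------------------------------------------------------------

CARRIER = "carrier"
NON_CARRIER = "non-carrier"
MISSING = "missing"


@dataclass
class SegregationVerdict:
    compatible: bool
    nonpenetrant_carriers: list[str]
    incompatible_individuals: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "compatible": self.compatible,
                    "nonpenetrant_carriers": self.nonpenetrant_carriers,
                    "incompatible_individuals": self.incompatible_individuals,
                },
                indent=1,
            )
            + "\n"
        )


def cosegregation_test(
    pedigree: Pedigree,
    carrier_calls: dict[str, str],
    allow_phenocopies: bool = False,
) -> SegregationVerdict:
    """Does carrier status co-segregate with affection, allowing non-penetrance?

    Compatible iff every genotyped affected individual is a carrier (unless
    ``allow_phenocopies``) and every carrier's status is transmissible: a
    non-founder carrier needs a carrier parent or an untyped parent through
    whom an obligate-carrier path can run.  Unaffected carriers are listed as
    non-penetrant, never as incompatible.
    """
    for iid in carrier_calls:
        if iid not in pedigree:
            raise ValidationError(f"carrier call for unknown individual {iid!r}")
    for call in carrier_calls.values():
        if call not in (CARRIER, NON_CARRIER, MISSING):
            raise ValidationError(f"carrier call must be carrier/non-carrier/missing, got {call!r}")

    incompatible: list[str] = []
    nonpenetrant: list[str] = []

    def call(iid: str) -> str:
        return carrier_calls.get(iid, MISSING)

    for ind in pedigree.individuals:
        c = call(ind.id)
        if ind.affection is Affection.AFFECTED and c == NON_CARRIER:
            if not allow_phenocopies:
                incompatible.append(ind.id)
        if ind.affection is Affection.UNAFFECTED and c == CARRIER:
            nonpenetrant.append(ind.id)
        if c == CARRIER and not ind.is_founder:
            # transmission: some ancestor path must be able to supply the allele
            if not _transmissible(pedigree, ind.id, carrier_calls):
                incompatible.append(ind.id)

    incompatible = sorted(set(incompatible))
    return SegregationVerdict(
        compatible=not incompatible,
        nonpenetrant_carriers=sorted(set(nonpenetrant)),
        incompatible_individuals=incompatible,
    )


def _transmissible(
    pedigree: Pedigree, iid: str, calls: dict[str, str]
) -> bool:
    """Can individual iid have received the allele from some parent?

    A parent qualifies if called carrier, if untyped/missing (permissive:
    an obligate-carrier path may run through them), but not if called
    non-carrier.  Founders introduce the allele freely.
    """
    ind = pedigree[iid]
    for pid in (ind.father_id, ind.mother_id):
        parent_call = calls.get(pid, MISSING)
        if parent_call == CARRIER or parent_call == MISSING:
            return True
    return False


def read_carrier_table(path: str | Path) -> dict[str, str]:
    """TSV with columns: individual id, carrier call."""
    calls: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"line {lineno}: expected id<TAB>call")
        calls[fields[0]] = fields[1]
    return calls


def write_carrier_table(calls: dict[str, str], path: str | Path) -> None:
    lines = [f"{iid}\t{call}" for iid, call in sorted(calls.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Restriction assays
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC, 5'->3'
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValidationError(
                f"{self.name}: recognition sequence shorter than 4 bp"
            )
        if any(b not in _IUPAC for b in self.recognition):
            raise ValidationError(f"{self.name}: non-IUPAC base in recognition site")

    @property
    def is_palindromic(self) -> bool:
        rc = self.recognition.translate(_COMPLEMENT)[::-1]
        return rc == self.recognition

    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(f"[{_IUPAC[b]}]" for b in self.recognition)
        )


# a small library of common 4-6 bp cutters; RsaI is the one the RFLP assay
# in the motivating study used (its site GTAC is destroyed by the nonsense
# mutation followed there)
ENZYME_LIBRARY = {
    e.name: e
    for e in [
        RestrictionEnzyme("RsaI", "GTAC"),
        RestrictionEnzyme("AluI", "AGCT"),
        RestrictionEnzyme("HaeIII", "GGCC"),
        RestrictionEnzyme("TaqI", "TCGA"),
        RestrictionEnzyme("HinfI", "GANTC"),
        RestrictionEnzyme("EcoRI", "GAATTC"),
        RestrictionEnzyme("BamHI", "GGATCC"),
        RestrictionEnzyme("HindIII", "AAGCTT"),
    ]
}


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """(0-based offset, strand) of every recognition site, both strands.

    Minus-strand hits are reported at the offset of the site's plus-strand
    footprint, so palindromic enzymes yield the same positions on both
    strands.
    """
    seq = sequence.upper()
    pat = enzyme.regex()
    hits = [(m.start(), "+") for m in _finditer_overlapping(pat, seq)]
    rc = seq.translate(_COMPLEMENT)[::-1]
    L = len(seq)
    n = len(enzyme.recognition)
    hits += [
        (L - m.start() - n, "-") for m in _finditer_overlapping(pat, rc)
    ]
    return sorted(hits)


def _finditer_overlapping(pat: re.Pattern, seq: str):
    i = 0
    while True:
        m = pat.search(seq, i)
        if m is None:
            return
        yield m
        i = m.start() + 1


@dataclass
class SiteDiff:
    enzyme: str
    lost: list[int]  # 0-based offsets in the reference window
    gained: list[int]  # 0-based offsets in the mutated window


def restriction_site_diff(
    window_seq: str,
    window_start: int,
    variant: Variant,
    enzymes: Sequence[RestrictionEnzyme] = (ENZYME_LIBRARY["RsaI"],),
) -> list[SiteDiff]:
    """Recognition sites destroyed/created by a variant inside a window.

    ``window_start`` is the genomic position of the window's first base.
    Positions in the result are offsets into the respective sequence.
    """
    off = variant.pos - window_start
    if off < 0 or off + len(variant.ref) > len(window_seq):
        raise ValidationError("variant does not lie inside the window")
    if window_seq[off : off + len(variant.ref)].upper() != variant.ref:
        raise ValidationError(
            f"window sequence does not match variant ref at {variant.chrom}:{variant.pos}"
        )
    mutated = window_seq[:off] + variant.alt + window_seq[off + len(variant.ref) :]
    shift = len(variant.alt) - len(variant.ref)
    boundary = off + len(variant.ref)

    def back_map(p: int) -> int:
        # express a mutated-sequence offset in reference coordinates so that
        # sites merely displaced by an indel do not show up as lost + gained
        return p - shift if p >= boundary + shift and p > off else p

    out = []
    for enz in enzymes:
        before = {p for p, _ in find_sites(window_seq, enz)}
        after = {back_map(p) for p, _ in find_sites(mutated, enz)}
        out.append(
            SiteDiff(enz.name, sorted(before - after), sorted(after - before))
        )
    return out


# ---------------------------------------------------------------------------
# Control-cohort screen
# ---------------------------------------------------------------------------

def control_cohort_screen(
    control_variants: Sequence[Sequence[tuple[Variant, int]]],
    region: GenomicInterval,
    annotator: Annotator,
) -> int:
    """Count truncating alleles carried by controls inside ``region``.

    ``control_variants``: per control, (variant, allele count) pairs.  A zero
    count across a sizeable cohort supports pathogenicity of a truncating
    allele found only in cases.
    """
    touches = any(
        t.span.overlaps(region)
        for ts in annotator.by_chrom.values()
        for t in ts
    )
    if not touches:
        raise ValidationError("screen region overlaps no annotated transcript")
    total = 0
    for person in control_variants:
        for v, n_alleles in person:
            if not region.contains(v.chrom, v.pos):
                continue
            best = annotator.most_severe(v)
            if best.truncating:
                total += max(1, n_alleles)
    return total


# ---------------------------------------------------------------------------
# Coverage assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageRule:
    """A base is covered iff reads >= min_reads and score > min_consensus_score."""

    min_reads: int = 5
    min_consensus_score: int = 0  # exclusive bound

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")


@dataclass
class CoverageReport:
    fraction_covered: float
    mean_depth: float
    n_bases: int
    per_region: dict[str, float]  # region label -> fraction with depth > k
    depth_cutoff: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fraction_covered": self.fraction_covered,
                    "mean_depth": self.mean_depth,
                    "n_bases": self.n_bases,
                    "depth_cutoff": self.depth_cutoff,
                    "per_region": self.per_region,
                },
                indent=1,
            )
            + "\n"
        )


def coverage_assess(
    depth: pd.DataFrame,
    rule: CoverageRule = CoverageRule(),
    regions: Optional[Sequence[GenomicInterval]] = None,
    depth_cutoff: int = 10,
) -> CoverageReport:
    """Covered-base fraction and optional per-region depth report.

    ``depth_cutoff`` is exclusive (a base counts when reads > cutoff),
    matching the convention of reporting exonic coverage "at >10x".
    Requires the profile sorted by (chrom, pos).
    """
    for chrom, grp in depth.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValidationError("depth profile must be position-sorted")
    covered = (depth["reads"] >= rule.min_reads) & (
        depth["consensus_score"] > rule.min_consensus_score
    )
    per_region: dict[str, float] = {}
    if regions:
        for iv in regions:
            mask = (
                (depth["chrom"] == iv.chrom)
                & (depth["pos"] >= iv.start)
                & (depth["pos"] <= iv.end)
            )
            sub = depth.loc[mask, "reads"]
            label = f"{iv.chrom}:{iv.start}-{iv.end}"
            per_region[label] = (
                float((sub > depth_cutoff).mean()) if len(sub) else float("nan")
            )
    return CoverageReport(
        fraction_covered=float(covered.mean()) if len(depth) else float("nan"),
        mean_depth=float(depth["reads"].mean()) if len(depth) else float("nan"),
        n_bases=int(len(depth)),
        per_region=per_region,
        depth_cutoff=depth_cutoff,
    )
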