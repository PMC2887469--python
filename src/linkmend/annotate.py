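"""Coding-consequence prediction against transcript models.

Variants are projected into spliced CDS coordinates (strand-aware) and
classified as stop_gained, frameshift, inframe_indel, missense, synonymous,
splice_site or noncoding.  Protein truncation - the property the downstream
filter keeps - is stop_gained or frameshift.  For frameshifts, a downstream
scan translates the mutated CDS from the last intact codon boundary and
counts the novel codons before the first premature stop.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from Bio.Seq import Seq

from .hgvs import ChangeKind, HgvsCodingChange, format_hgvs_c
from .io import SparseReference
from .transcripts import STOP_CODONS, TranscriptModel
from .variants import Variant

SPLICE_WINDOW = 2  # intronic bp next to an exon treated as splice site


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    pass


class ConsequenceClass(str, Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


# most severe first; used to pick the representative consequence
SEVERITY = {
    ConsequenceClass.STOP_GAINED: 0,
    ConsequenceClass.FRAMESHIFT: 1,
    ConsequenceClass.SPLICE_SITE: 2,
    ConsequenceClass.MISSENSE: 3,
    ConsequenceClass.INFRAME_INDEL: 4,
    ConsequenceClass.SYNONYMOUS: 5,
    ConsequenceClass.NONCODING: 6,
}

TRUNCATING_CLASSES = {ConsequenceClass.STOP_GAINED, ConsequenceClass.FRAMESHIFT}


@dataclass
class Consequence:
    variant: Variant
    klass: ConsequenceClass
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    hgvs_c: Optional[HgvsCodingChange] = None
    novel_codons_before_stop: Optional[int] = None
    terminates: Optional[bool] = None

    @property
    def truncating(self) -> bool:
        return self.klass in TRUNCATING_CLASSES

    @property
    def hgvs_text(self) -> Optional[str]:
        return format_hgvs_c(self.hgvs_c) if self.hgvs_c else None


@dataclass
class FrameshiftScan:
    novel_codons: int
    terminates: bool


def frameshift_stop_scan(
    transcript: TranscriptModel,
    change: HgvsCodingChange,
    reference: SparseReference,
) -> FrameshiftScan:
    """Apply a frame-shifting CDS indel and count novel codons before a stop.

    Translation restarts at the last codon boundary unaffected by the change;
    ``terminates`` is False when the shifted frame runs off the transcript
    end without hitting a stop (reported, not an error).
    """
    if change.length_change % 3 == 0:
        raise AnnotationError(
            "frameshift_stop_scan requires an indel with length not divisible by 3"
        )
    cds = transcript.spliced_cds(reference)
    if change.kind is ChangeKind.DELETION:
        mutated = cds[: change.cds_start - 1] + cds[change.cds_end :]
        first_affected = change.cds_start
    elif change.kind is ChangeKind.INSERTION:
        mutated = cds[: change.cds_start] + change.alt_allele + cds[change.cds_start :]
        first_affected = change.cds_start + 1
    elif change.kind is ChangeKind.DELINS:
        mutated = (
            cds[: change.cds_start - 1] + change.alt_allele + cds[change.cds_end :]
        )
        first_affected = change.cds_start
    else:
        raise AnnotationError("substitutions cannot shift the reading frame")
    ci = (first_affected - 1) // 3  # 0-based index of first affected codon
    novel = 0
    for k in range(ci * 3, len(mutated) - 2, 3):
        if mutated[k : k + 3] in STOP_CODONS:
            return FrameshiftScan(novel, True)
        novel += 1
    return FrameshiftScan(novel, False)


# ---------------------------------------------------------------------------
# Annotation engine
# ---------------------------------------------------------------------------

class Annotator:
    """Annotates variants against a fixed transcript set + reference."""

    def __init__(
        self, transcripts: Sequence[TranscriptModel], reference: SparseReference
    ) -> None:
        self.reference = reference
        self.by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.span.start)):
            self.by_chrom.setdefault(t.chrom, []).append(t)
        self._starts = {
            c: [t.span.start for t in ts] for c, ts in self.by_chrom.items()
        }
        self._cds_cache: dict[str, str] = {}

    def _spliced(self, t: TranscriptModel) -> str:
        if t.transcript_id not in self._cds_cache:
            self._cds_cache[t.transcript_id] = t.spliced_cds(self.reference)
        return self._cds_cache[t.transcript_id]

    def _overlapping(self, v: Variant) -> list[TranscriptModel]:
        ts = self.by_chrom.get(v.chrom, [])
        out = []
        lo, hi = v.pos - SPLICE_WINDOW, v.end + SPLICE_WINDOW
        i = bisect_right(self._starts.get(v.chrom, []), hi)
        for t in ts[:i]:
            if t.span.end >= lo:
                out.append(t)
        return out

    def _check_reference(self, v: Variant) -> None:
        if self.reference.covers(v.chrom, v.pos, v.end):
            expected = self.reference.fetch(v.chrom, v.pos, v.end)
            if expected != v.ref:
                raise ReferenceMismatchError(
                    f"{v.chrom}:{v.pos} ref {v.ref!r} != reference {expected!r}"
                )

    def annotate(self, variant: Variant) -> list[Consequence]:
        """One consequence per overlapping transcript; noncoding if none.

        The returned list is ordered most-severe first; element 0 is the
        designated representative used by the filter cascade.
        """
        self._check_reference(variant)
        out = [
            self._annotate_one(variant, t) for t in self._overlapping(variant)
        ]
        out = [c for c in out if c is not None]
        if not out:
            out = [Consequence(variant, ConsequenceClass.NONCODING)]
        out.sort(key=lambda c: SEVERITY[c.klass])
        return out

    def most_severe(self, variant: Variant) -> Consequence:
        return self.annotate(variant)[0]

    # -- per-transcript logic ------------------------------------------
    def _annotate_one(
        self, v: Variant, t: TranscriptModel
    ) -> Optional[Consequence]:
        if v.is_snv:
            return self._annotate_snv(v, t)
        return self._annotate_indel(v, t)

    def _annotate_snv(self, v: Variant, t: TranscriptModel) -> Optional[Consequence]:
        span = t.span
        if not (span.start - SPLICE_WINDOW <= v.pos <= span.end + SPLICE_WINDOW):
            return None
        cpos = t.genomic_to_cds(v.pos)
        if cpos is None:
            d = t.intron_distance(v.pos)
            if d is not None and d <= SPLICE_WINDOW:
                return Consequence(v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id)
            return Consequence(v, ConsequenceClass.NONCODING, t.gene_id, t.transcript_id)
        cds = self._spliced(t)
        ref_t = v.ref if t.strand == "+" else str(Seq(v.ref).complement())
        alt_t = v.alt if t.strand == "+" else str(Seq(v.alt).complement())
        if cds[cpos - 1] != ref_t:
            raise ReferenceMismatchError(
                f"{t.transcript_id}: CDS position {cpos} is {cds[cpos - 1]}, "
                f"variant claims {ref_t}"
            )
        ci = (cpos - 1) // 3
        codon = cds[ci * 3 : ci * 3 + 3]
        mutated = codon[: (cpos - 1) % 3] + alt_t + codon[(cpos - 1) % 3 + 1 :]
        change = HgvsCodingChange(ChangeKind.SUBSTITUTION, cpos, cpos, ref_t, alt_t)
        if mutated in STOP_CODONS and codon not in STOP_CODONS:
            klass = ConsequenceClass.STOP_GAINED
        elif str(Seq(mutated).translate()) == str(Seq(codon).translate()):
            klass = ConsequenceClass.SYNONYMOUS
        else:
            klass = ConsequenceClass.MISSENSE
        return Consequence(v, klass, t.gene_id, t.transcript_id, change)

    def _annotate_indel(self, v: Variant, t: TranscriptModel) -> Optional[Consequence]:
        # left-anchored: changed bases start after the anchor for deletions
        if len(v.ref) > len(v.alt):  # deletion (possibly delins)
            lo, hi = v.pos + len(v.alt), v.end
        else:  # insertion: lands between pos and pos+1
            lo, hi = v.pos, v.pos + 1
        span = t.span
        if hi < span.start - SPLICE_WINDOW or lo > span.end + SPLICE_WINDOW:
            return None

        positions = list(range(lo, hi + 1))
        cds_hits = [t.genomic_to_cds(p) for p in positions]
        in_cds = [c is not None for c in cds_hits]
        if len(v.ref) > len(v.alt):
            if all(in_cds):
                return self._cds_deletion(v, t, positions, cds_hits)
            if any(in_cds):
                # spans a CDS/intron or CDS/UTR edge: deterministic splice call
                return Consequence(
                    v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id
                )
            dists = [t.intron_distance(p) for p in positions]
            if any(d is not None and d <= SPLICE_WINDOW for d in dists):
                return Consequence(
                    v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id
                )
            return Consequence(v, ConsequenceClass.NONCODING, t.gene_id, t.transcript_id)

        # insertion
        if all(in_cds):
            return self._cds_insertion(v, t, cds_hits)
        dists = [t.intron_distance(p) for p in positions]
        if any(d is not None and d <= SPLICE_WINDOW for d in dists) or any(in_cds):
            return Consequence(
                v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id
            )
        return Consequence(v, ConsequenceClass.NONCODING, t.gene_id, t.transcript_id)

    def _cds_deletion(
        self, v: Variant, t: TranscriptModel, positions, cds_hits
    ) -> Consequence:
        cstart, cend = min(cds_hits), max(cds_hits)
        if cend - cstart != len(positions) - 1:
            # deleted run crosses an intron inside the CDS
            return Consequence(v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id)
        removed = len(v.ref) - len(v.alt)
        cds = self._spliced(t)
        inserted = v.alt[1:]  # bases beyond the anchor (delins case)
        inserted_t = inserted if t.strand == "+" else str(Seq(inserted).reverse_complement())
        if inserted_t:
            change = HgvsCodingChange(
                ChangeKind.DELINS, cstart, cend, cds[cstart - 1 : cend], inserted_t
            )
        else:
            change = HgvsCodingChange(
                ChangeKind.DELETION, cstart, cend, cds[cstart - 1 : cend], ""
            )
        net = change.length_change
        if net % 3 != 0:
            scan = frameshift_stop_scan(t, change, self.reference)
            return Consequence(
                v,
                ConsequenceClass.FRAMESHIFT,
                t.gene_id,
                t.transcript_id,
                change,
                scan.novel_codons,
                scan.terminates,
            )
        return Consequence(v, ConsequenceClass.INFRAME_INDEL, t.gene_id, t.transcript_id, change)

    def _cds_insertion(self, v: Variant, t: TranscriptModel, cds_hits) -> Consequence:
        inserted = v.alt[len(v.ref) :]
        inserted_t = (
            inserted if t.strand == "+" else str(Seq(inserted).reverse_complement())
        )
        c1, c2 = sorted(cds_hits)
        if c2 != c1 + 1:
            return Consequence(v, ConsequenceClass.SPLICE_SITE, t.gene_id, t.transcript_id)
        change = HgvsCodingChange(ChangeKind.INSERTION, c1, c2, "", inserted_t)
        if len(inserted) % 3 != 0:
            scan = frameshift_stop_scan(t, change, self.reference)
            return Consequence(
                v,
                ConsequenceClass.FRAMESHIFT,
                t.gene_id,
                t.transcript_id,
                change,
                scan.novel_codons,
                scan.terminates,
            )
        return Consequence(v, ConsequenceClass.INFRAME_INDEL, t.gene_id, t.transcript_id, change)


def classify_truncating(consequences: Sequence[Consequence]) -> bool:
    """True iff the most severe consequence is stop_gained or frameshift.

    Classification is by class alone: a frameshift whose shifted frame never
    reaches a stop codon still counts as truncating (it is flagged via
    ``terminates``).
    """
    if not consequences:
        raise AnnotationError("no consequences supplied")
    best = min(consequences, key=lambda c: SEVERITY[c.klass])
    return best.truncating


def annotate_variants(
    variants: Sequence[Variant],
    transcripts: Sequence[TranscriptModel],
    reference: SparseReference,
) -> list[list[Consequence]]:
    ann = Annotator(transcripts, reference)
    return [ann.annotate(v) for v in variants]


def info_fields(consequences: Sequence[Consequence]) -> dict:
    """VCF INFO representation of a variant's most severe consequence."""
    best = consequences[0]
    return {
        "CLASS": best.klass.value,
        "HGVSC": best.hgvs_text,
        "NOVEL_CODONS": best.novel_codons_before_stop,
        "TRUNCATING": best.truncating,
        "GENE": best.gene_id,
    }
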