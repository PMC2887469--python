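"""Gene/transcript models and GFF3 I/O.

A :class:`TranscriptModel` is the minimal gene model needed to call coding
consequences: ordered exons, the CDS segments within them, and the strand.
CDS coordinates ("c." positions) are 1-based along the spliced coding
sequence in transcript orientation; on the minus strand the spliced CDS is
the reverse complement of the genomic segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .intervals import GenomicInterval
from .io import SparseReference


class TranscriptError(ValueError):
    pass


STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[GenomicInterval]  # sorted by genomic coordinate
    cds: list[GenomicInterval]  # sorted by genomic coordinate, within exons

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for name, ivs in (("exons", self.exons), ("CDS", self.cds)):
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise TranscriptError(
                        f"{self.transcript_id}: overlapping {name} segments"
                    )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise TranscriptError(
                    f"{self.transcript_id}: CDS segment outside exons"
                )

    # -- geometry ------------------------------------------------------
    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    def _cds_in_transcript_order(self) -> list[GenomicInterval]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based coding position of a genomic base, or None outside CDS."""
        offset = 0
        for seg in self._cds_in_transcript_order():
            if seg.start <= pos <= seg.end:
                within = (pos - seg.start) if self.strand == "+" else (seg.end - pos)
                return offset + within + 1
            offset += seg.length
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        """Genomic position of 1-based coding position ``cpos``."""
        offset = 0
        for seg in self._cds_in_transcript_order():
            if cpos <= offset + seg.length:
                within = cpos - offset - 1
                return seg.start + within if self.strand == "+" else seg.end - within
            offset += seg.length
        raise TranscriptError(
            f"{self.transcript_id}: CDS position {cpos} beyond CDS length {self.cds_length}"
        )

    def spliced_cds(self, reference: SparseReference) -> str:
        parts = [reference.fetch(self.chrom, iv.start, iv.end) for iv in self.cds]
        seq = "".join(parts)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def intron_distance(self, pos: int) -> Optional[int]:
        """For an intronic base, distance (>=1) to the nearest exon edge; None if exonic/outside."""
        if not (self.span.start <= pos <= self.span.end):
            return None
        for e in self.exons:
            if e.start <= pos <= e.end:
                return None
        dist = None
        for e in self.exons:
            for edge in (e.start, e.end):
                d = abs(pos - edge)
                if dist is None or d < dist:
                    dist = d
        return dist


def validate_transcript(t: TranscriptModel, reference: SparseReference) -> None:
    """Assert the CDS is a translatable ORF: length % 3 == 0, ATG...stop, no internal stop."""
    if t.cds_length % 3 != 0:
        raise TranscriptError(f"{t.transcript_id}: CDS length {t.cds_length} not divisible by 3")
    seq = t.spliced_cds(reference)
    if seq[:3] != "ATG":
        raise TranscriptError(f"{t.transcript_id}: CDS does not start with ATG")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        raise TranscriptError(f"{t.transcript_id}: CDS does not end with a stop codon")
    if any(c in STOP_CODONS for c in codons[:-1]):
        raise TranscriptError(f"{t.transcript_id}: internal stop codon")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.span.start)):
        s = t.span
        lines.append(
            f"{t.chrom}\tlinkmend\tgene\t{s.start}\t{s.end}\t.\t{t.strand}\t.\t"
            f"ID=gene:{t.gene_id}"
        )
        lines.append(
            f"{t.chrom}\tlinkmend\tmRNA\t{s.start}\t{s.end}\t.\t{t.strand}\t.\t"
            f"ID=transcript:{t.transcript_id};Parent=gene:{t.gene_id}"
        )
        for e in t.exons:
            lines.append(
                f"{t.chrom}\tlinkmend\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t"
                f"Parent=transcript:{t.transcript_id}"
            )
        # phase: number of bases to skip before the first full codon
        offset = 0
        phases: dict[GenomicInterval, int] = {}
        for seg in t._cds_in_transcript_order():
            phases[seg] = (3 - offset % 3) % 3
            offset += seg.length
        for c in t.cds:
            lines.append(
                f"{t.chrom}\tlinkmend\tCDS\t{c.start}\t{c.end}\t.\t{t.strand}\t{phases[c]}\t"
                f"Parent=transcript:{t.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Parse gene/mRNA/exon/CDS features into transcript models (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id.removeprefix("transcript:")
        parents = list(db.parents(mrna, featuretype="gene"))
        gid = (parents[0].id if parents else tid).removeprefix("gene:")
        exons = [
            GenomicInterval(f.seqid, f.start, f.end)
            for f in db.children(mrna, featuretype="exon")
        ]
        cds = [
            GenomicInterval(f.seqid, f.start, f.end)
            for f in db.children(mrna, featuretype="CDS")
        ]
        if not exons or not cds:
            raise TranscriptError(f"{tid}: mRNA without exon/CDS children")
        out.append(
            TranscriptModel(gid, tid, mrna.seqid, mrna.strand, exons, cds)
        )
    out.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return out
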