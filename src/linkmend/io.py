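"""Interchange-format readers and writers: VCF, BED, FASTA, depth tables.

VCF handling goes through pysam; BED and the depth TSV are trivial columnar
dialects written and parsed directly so that round-trips are byte-stable.

The reference sequence may be *sparse*: a FASTA whose records are windows of
chromosomes, with headers like ``chr12:105900001-105925000`` (1-based,
inclusive).  A plain ``chr12`` header is treated as a window starting at
base 1.  This lets a genome-scale simulation carry sequence only where genes
(and assay windows) live.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import GenomicInterval
from .variants import Variant


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive internally)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    regions: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 tab-separated columns")
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
        if end0 <= start0:
            raise FormatError(f"{path}:{lineno}: empty or negative BED interval")
        regions.append(GenomicInterval(fields[0], start0 + 1, end0))
    return regions


def write_bed(regions: Sequence[GenomicInterval], path: str | Path) -> None:
    lines = [f"{iv.chrom}\t{iv.start - 1}\t{iv.end}" for iv in regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA / sparse reference
# ---------------------------------------------------------------------------

_WINDOW_RE = re.compile(r"^(\S+?):(\d+)-(\d+)$")


@dataclass
class SparseReference:
    """Reference sequence stored as per-chromosome windows.

    ``windows`` maps chromosome -> list of (start, sequence), start 1-based,
    windows non-overlapping and sorted.
    """

    windows: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, seq: str) -> None:
        self.windows.setdefault(chrom, []).append((start, seq.upper()))
        self.windows[chrom].sort()
        prev_end = 0
        for s, q in self.windows[chrom]:
            if s <= prev_end:
                raise FormatError(f"overlapping reference windows on {chrom}")
            prev_end = s + len(q) - 1

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases start..end inclusive; raises if not fully inside one window."""
        for s, seq in self.windows.get(chrom, []):
            if s <= start and end <= s + len(seq) - 1:
                return seq[start - s : end - s + 1]
        raise KeyError(f"no reference window covering {chrom}:{start}-{end}")

    def covers(self, chrom: str, start: int, end: int) -> bool:
        try:
            self.fetch(chrom, start, end)
            return True
        except KeyError:
            return False

    def window_containing(self, chrom: str, pos: int) -> GenomicInterval:
        for s, seq in self.windows.get(chrom, []):
            if s <= pos <= s + len(seq) - 1:
                return GenomicInterval(chrom, s, s + len(seq) - 1)
        raise KeyError(f"no reference window covering {chrom}:{pos}")


def read_fasta(path: str | Path) -> SparseReference:
    from Bio import SeqIO

    ref = SparseReference()
    for record in SeqIO.parse(str(path), "fasta"):
        m = _WINDOW_RE.match(record.id)
        if m:
            ref.add(m.group(1), int(m.group(2)), str(record.seq))
        else:
            ref.add(record.id, 1, str(record.seq))
    if not ref.windows:
        raise FormatError(f"{path}: no FASTA records")
    return ref


def write_fasta(ref: SparseReference, path: str | Path, width: int = 60) -> None:
    chunks: list[str] = []
    for chrom in sorted(ref.windows):
        for start, seq in ref.windows[chrom]:
            end = start + len(seq) - 1
            chunks.append(f">{chrom}:{start}-{end}")
            chunks.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VcfTable:
    """The slice of VCF content this pipeline uses.

    ``genotypes`` holds per-sample alternate-allele counts (0/1/2, -1 for
    missing), shape (n_variants, n_samples); empty array when the file has no
    samples.
    """

    variants: list[Variant]
    info: list[dict]
    samples: list[str]
    genotypes: np.ndarray

    def alt_carriers(self, i: int) -> list[str]:
        return [
            s
            for j, s in enumerate(self.samples)
            if self.genotypes[i, j] > 0
        ]


_INFO_FIELDS = [
    ("CLASS", "String", "Predicted consequence class"),
    ("HGVSC", "String", "Coding-DNA HGVS description"),
    ("NOVEL_CODONS", "Integer", "Novel codons before premature stop (frameshift)"),
    ("TRUNCATING", "Flag", "Most-severe consequence is protein-truncating"),
    ("GENE", "String", "Gene of the most severe consequence"),
]


def _build_header(
    contigs: dict[str, int], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name, vtype, desc in _INFO_FIELDS:
        number = 0 if vtype == "Flag" else 1
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    contigs: dict[str, int],
    info: Optional[Sequence[dict]] = None,
    samples: Sequence[str] = (),
    genotypes: Optional[np.ndarray] = None,
) -> None:
    """Write an uncompressed VCF 4.x file.

    Records must be coordinate-sorted per the contig order in ``contigs``.
    """
    header = _build_header(contigs, samples)
    order = {c: k for k, c in enumerate(contigs)}
    idx = sorted(
        range(len(variants)), key=lambda i: (order[variants[i].chrom], variants[i].pos)
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in idx:
            v = variants[i]
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.id,
            )
            if info is not None:
                for key, val in info[i].items():
                    if val is None or val is False:
                        continue
                    rec.info[key] = val
            if samples:
                assert genotypes is not None
                for j, s in enumerate(samples):
                    g = int(genotypes[i, j])
                    if g < 0:
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = (1, 1) if g == 2 else (0, 1) if g == 1 else (0, 0)
            out.write(rec)


def read_vcf(path: str | Path) -> VcfTable:
    variants: list[Variant] = []
    info: list[dict] = []
    gts: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            variants.append(
                Variant(rec.chrom, rec.pos, rec.ref, rec.alts[0], rec.id)
            )
            rec_info = {}
            for key in ("CLASS", "HGVSC", "NOVEL_CODONS", "GENE"):
                if key in rec.info:
                    rec_info[key] = rec.info[key]
            rec_info["TRUNCATING"] = "TRUNCATING" in rec.info
            info.append(rec_info)
            if samples:
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or gt[0] is None:
                        row.append(-1)
                    else:
                        row.append(int(sum(1 for a in gt if a == 1)))
                gts.append(row)
    genotypes = (
        np.array(gts, dtype=np.int8)
        if gts
        else np.zeros((len(variants), len(samples)), dtype=np.int8)
    )
    return VcfTable(variants, info, samples, genotypes)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

DEPTH_COLUMNS = ["chrom", "pos", "reads", "consensus_score"]


def write_depth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=DEPTH_COLUMNS)


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: depth table lacks columns {missing}")
    return df
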