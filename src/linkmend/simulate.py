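"""Synthetic study cohorts with known truth.

This module is the no-download test bed for the whole pipeline: it generates
a family segregating a dominant protein-truncating allele with reduced
penetrance, chip-style SNP genotypes produced by gene drop with Haldane
recombination, a proband variant list containing the causal variant plus
catalog-known, control-shared, private-benign and private-truncating decoy
variants, transcript models with a sparse reference sequence, and per-base
depth profiles.  Every variant carries a truth category so downstream filter
stages can be audited exactly.

Scale defaults mimic the study design they stand in for: 22 autosomes at
human-like lengths, a dominant model with penetrance 0.8, eight control
genomes, and 109 private truncating variants (19 stop gains, 90 frameshifting
indels) of which exactly one - an 11 bp frameshifting deletion - is causal
and lies inside the planted linkage region.  Chip marker density is reduced
to desk scale (see docs/methods.md).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .disease import DiseaseModel
from .intervals import GenomicInterval
from .io import SparseReference
from .linkage import haldane_theta
from .markers import GeneticMap, GenotypeMatrix
from .pedigree import Affection, Individual, Pedigree, Sex
from .transcripts import STOP_CODONS, TranscriptModel, validate_transcript
from .variants import Variant, left_align


def rng_for(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible random stream derived from one master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Pedigree fixtures
# ---------------------------------------------------------------------------

def _ind(iid, fa, mo, sex, aff):
    return Individual(
        iid,
        fa,
        mo,
        Sex.MALE if sex == "M" else Sex.FEMALE,
        Affection.AFFECTED if aff else Affection.UNAFFECTED,
        genotyped=True,
    )


def make_pedigree_fixture(template: str, seed: int = 0) -> Pedigree:
    """Canonical family fixtures.

    ``pedigree1_like``: four generations, 12 genotyped members, 7 affected /
    5 unaffected, dominant transmission through four meiotic branches.
    ``pedigree2_like``: three generations, 10 genotyped members, 3 affected /
    7 unaffected (two obligate-carrier branches through unaffected parents).
    ``nuclear(n)``: two founders and n children.  The multi-generation
    fixtures are stand-ins matching the published member/affected counts, not
    tracings of any real family's drawn structure.
    """
    if template == "pedigree1_like":
        rows = [
            _ind("I-1", None, None, "M", True),
            _ind("I-2", None, None, "F", False),
            _ind("II-1", "I-1", "I-2", "M", True),
            _ind("II-2", None, None, "F", False),
            _ind("II-3", "I-1", "I-2", "F", True),
            _ind("II-4", None, None, "M", False),
            _ind("III-1", "II-1", "II-2", "M", True),
            _ind("III-2", None, None, "F", False),
            _ind("III-3", "II-4", "II-3", "F", True),
            _ind("III-4", None, None, "M", False),
            _ind("IV-1", "III-1", "III-2", "F", True),
            _ind("IV-2", "III-4", "III-3", "M", True),
        ]
        return Pedigree(rows, family_id="PED1")
    if template == "pedigree2_like":
        rows = [
            _ind("I-1", None, None, "M", True),
            _ind("I-2", None, None, "F", False),
            _ind("II-1", None, None, "M", False),
            _ind("II-2", "I-1", "I-2", "F", False),
            _ind("II-3", None, None, "M", False),
            _ind("II-4", "I-1", "I-2", "F", False),
            _ind("III-1", "II-1", "II-2", "M", True),
            _ind("III-2", "II-1", "II-2", "F", False),
            _ind("III-3", "II-3", "II-4", "F", True),
            _ind("III-4", "II-3", "II-4", "M", False),
        ]
        return Pedigree(rows, family_id="PED2")
    if template.startswith("nuclear(") and template.endswith(")"):
        n = int(template[len("nuclear(") : -1])
        rows = [
            _ind("FA", None, None, "M", False),
            _ind("MO", None, None, "F", False),
        ]
        rows += [_ind(f"C{k + 1}", "FA", "MO", "M" if k % 2 == 0 else "F", False) for k in range(n)]
        return Pedigree(rows, family_id="NUC")
    raise ValueError(f"unknown pedigree template {template!r}")


# ---------------------------------------------------------------------------
# Genome layout and chip markers
# ---------------------------------------------------------------------------

_AUTOSOME_MB = [
    248, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133,
    114, 107, 102, 90, 83, 80, 59, 64, 47, 51,
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths; genetic length is cm_per_mb x physical."""

    chrom_lengths: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i + 1}", mb * 1_000_000) for i, mb in enumerate(_AUTOSOME_MB)
    )
    cm_per_mb: float = 1.2

    def cm_at(self, bp: int) -> float:
        return bp / 1e6 * self.cm_per_mb

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chrom_lengths)

    def length_of(self, chrom: str) -> int:
        for c, l in self.chrom_lengths:
            if c == chrom:
                return l
        raise KeyError(chrom)


def simulate_chip(
    genome: GenomeLayout,
    markers_per_cm: float,
    seed: int,
    maf_range: tuple[float, float] = (0.2, 0.5),
) -> tuple[GeneticMap, np.ndarray]:
    """Evenly spaced chip markers with common-SNP allele frequencies.

    Returns the genetic map and, per marker, the population frequency of
    allele 1 (the chip ascertains common SNPs, hence the MAF floor).
    """
    rng = rng_for(seed, "chip")
    ids: list[str] = []
    chroms: list[str] = []
    bp: list[int] = []
    cm: list[float] = []
    for chrom, length in genome.chrom_lengths:
        n = max(2, int(round(genome.cm_at(length) * markers_per_cm)))
        positions = np.linspace(1e5, length - 1e5, n).astype(np.int64)
        for k, pos in enumerate(positions):
            ids.append(f"{chrom}_snp{k + 1}")
            chroms.append(chrom)
            bp.append(int(pos))
            cm.append(genome.cm_at(int(pos)))
    freqs = rng.uniform(*maf_range, size=len(ids))
    # allele 1 is the ascertained minor allele on either side of 0.5 at random
    flip = rng.random(len(ids)) < 0.5
    freqs = np.where(flip, 1.0 - freqs, freqs)
    return GeneticMap(ids, chroms, np.array(bp), np.array(cm)), freqs


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

@dataclass
class CausalDescent:
    """Descent of the planted allele: where it sits and who inherited it."""

    chrom: str
    cm: float
    bp: int
    founder_id: str
    founder_slot_is_paternal: bool
    meiosis_bits: dict[str, tuple[int, int]]  # non-founder id -> (paternal, maternal)
    carrier_ids: set[str] = field(default_factory=set)


@dataclass
class DropResult:
    genotypes: GenotypeMatrix
    # phased truth, kept for audits: allele and descent per individual/marker
    paternal: np.ndarray  # (n_markers, n_ind) alleles in {1,2}
    maternal: np.ndarray


def _meiosis_bit_chains(
    n_markers: int,
    thetas: np.ndarray,
    n_meioses: int,
    rng: np.random.Generator,
    anchor_index: Optional[int] = None,
    anchor_bits: Optional[np.ndarray] = None,
    anchor_thetas: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Haldane bit chains (n_markers, n_meioses); optionally conditioned on
    known bits at an anchor locus between markers anchor_index-1 and
    anchor_index (walking outward with the anchor-to-marker thetas)."""
    bits = np.empty((n_markers, n_meioses), dtype=np.int8)
    if anchor_index is None:
        bits[0] = rng.integers(0, 2, size=n_meioses)
        for k in range(1, n_markers):
            flip = rng.random(n_meioses) < thetas[k - 1]
            bits[k] = bits[k - 1] ^ flip
        return bits
    assert anchor_bits is not None and anchor_thetas is not None
    th_left, th_right = anchor_thetas
    right = anchor_index
    if right < n_markers:
        flip = rng.random(n_meioses) < th_right
        bits[right] = anchor_bits ^ flip
        for k in range(right + 1, n_markers):
            flip = rng.random(n_meioses) < thetas[k - 1]
            bits[k] = bits[k - 1] ^ flip
    left = anchor_index - 1
    if left >= 0:
        flip = rng.random(n_meioses) < th_left
        bits[left] = anchor_bits ^ flip
        for k in range(left - 1, -1, -1):
            flip = rng.random(n_meioses) < thetas[k]
            bits[k] = bits[k + 1] ^ flip
    return bits


def gene_drop(
    pedigree: Pedigree,
    gmap: GeneticMap,
    founder_allele_freqs: np.ndarray,
    seed: int,
    condition_on: Optional[CausalDescent] = None,
) -> DropResult:
    """Drop founder haplotypes through the pedigree with Haldane crossovers.

    Founder haplotype alleles are drawn per marker from
    ``founder_allele_freqs`` (frequency of allele 1); transmissions follow
    Mendelian segregation, with the meiosis indicator process a Markov chain
    along each chromosome (no interference).  If ``condition_on`` carries the
    descent bits of a planted causal locus, the chains on its chromosome are
    conditioned to pass through those bits at the causal position, so nearby
    markers co-segregate with carrier status.
    """
    if len(gmap) == 0:
        raise ValueError("empty genetic map")
    freqs = np.asarray(founder_allele_freqs, dtype=float)
    if freqs.shape != (len(gmap),):
        raise ValueError("founder_allele_freqs must have one frequency per marker")
    if np.any(freqs <= 0) or np.any(freqs > 1):
        raise ValueError("founder allele frequencies must lie in (0, 1]")

    rng = rng_for(seed, "gene_drop")
    order = pedigree.topological_order()
    ids = [i.id for i in order]
    pos = {iid: k for k, iid in enumerate(ids)}
    nonfounders = [i for i in order if not i.is_founder]
    n_m = len(gmap)

    pat = np.empty((n_m, len(ids)), dtype=np.int8)
    mat = np.empty((n_m, len(ids)), dtype=np.int8)
    for ind in order:
        if ind.is_founder:
            k = pos[ind.id]
            pat[:, k] = np.where(rng.random(n_m) < freqs, 1, 2)
            mat[:, k] = np.where(rng.random(n_m) < freqs, 1, 2)

    # meiosis bit chains per chromosome
    n_mei = 2 * len(nonfounders)
    bits = np.empty((n_m, n_mei), dtype=np.int8)
    for chrom in gmap.chromosomes:
        cidx = gmap.indices_for(chrom)
        cm = gmap.cm[cidx]
        thetas = np.array(
            [haldane_theta(cm[k + 1] - cm[k]) for k in range(len(cidx) - 1)]
        )
        if condition_on is not None and condition_on.chrom == chrom:
            anchor_cm = condition_on.cm
            anchor_index = int(np.searchsorted(cm, anchor_cm))
            anchor_bits = np.empty(n_mei, dtype=np.int8)
            for j, nf in enumerate(nonfounders):
                bp_bit, bm_bit = condition_on.meiosis_bits[nf.id]
                anchor_bits[2 * j] = bp_bit
                anchor_bits[2 * j + 1] = bm_bit
            th_left = (
                haldane_theta(anchor_cm - cm[anchor_index - 1])
                if anchor_index > 0
                else 0.0
            )
            th_right = (
                haldane_theta(cm[anchor_index] - anchor_cm)
                if anchor_index < len(cidx)
                else 0.0
            )
            bits[cidx] = _meiosis_bit_chains(
                len(cidx), thetas, n_mei, rng, anchor_index, anchor_bits,
                (th_left, th_right),
            )
        else:
            bits[cidx] = _meiosis_bit_chains(len(cidx), thetas, n_mei, rng)

    for j, nf in enumerate(nonfounders):
        k = pos[nf.id]
        fa, mo = pos[nf.father_id], pos[nf.mother_id]
        bp_bit = bits[:, 2 * j]
        bm_bit = bits[:, 2 * j + 1]
        pat[:, k] = np.where(bp_bit == 0, pat[:, fa], mat[:, fa])
        mat[:, k] = np.where(bm_bit == 0, pat[:, mo], mat[:, mo])

    alleles = np.stack([pat, mat], axis=2)
    # hide genotypes of non-genotyped members
    for k, iid in enumerate(ids):
        if not pedigree[iid].genotyped:
            alleles[:, k, :] = 0
    return DropResult(GenotypeMatrix(ids, alleles), pat, mat)


def mendelian_audit(pedigree: Pedigree, genotypes: GenotypeMatrix) -> np.ndarray:
    """Indices of markers where some child's genotype cannot come from its
    typed parents (missing data is always compatible)."""
    pos = {s: j for j, s in enumerate(genotypes.sample_ids)}
    bad = np.zeros(genotypes.n_markers, dtype=bool)
    A = genotypes.alleles
    for ind in pedigree.nonfounders:
        if ind.id not in pos:
            continue
        c = A[:, pos[ind.id], :]
        fa = A[:, pos[ind.father_id], :] if ind.father_id in pos else None
        mo = A[:, pos[ind.mother_id], :] if ind.mother_id in pos else None

        def from_parent(allele, parent):
            if parent is None:
                return np.ones(A.shape[0], dtype=bool)
            untyped = parent[:, 0] == 0
            return untyped | (allele == parent[:, 0]) | (allele == parent[:, 1])

        c_missing = c[:, 0] == 0
        ok = (from_parent(c[:, 0], fa) & from_parent(c[:, 1], mo)) | (
            from_parent(c[:, 1], fa) & from_parent(c[:, 0], mo)
        )
        bad |= ~(ok | c_missing)
    return np.flatnonzero(bad)


# ---------------------------------------------------------------------------
# Planting the causal variant
# ---------------------------------------------------------------------------

class AscertainmentError(RuntimeError):
    pass


@dataclass
class PlantResult:
    descent: CausalDescent
    phenotypes: dict[str, Affection]
    carrier_ids: set[str]
    nonpenetrant_ids: set[str]
    phenocopy_ids: set[str]


def plant_causal_variant(
    pedigree: Pedigree,
    gmap: GeneticMap,
    region: GenomicInterval,
    model: DiseaseModel,
    seed: int,
    causal_bp: Optional[int] = None,
    min_affected: Optional[int] = None,
    genome: Optional[GenomeLayout] = None,
    max_tries: int = 100_000,
) -> PlantResult:
    """Introduce one copy of the disease allele through a single founder and
    segregate it to the pedigree, then draw phenotypes under the penetrance
    model (carriers affected with probability f1, non-carriers with f0).

    With ``min_affected`` set, descent and phenotypes are rejection-sampled
    until at least that many members are affected - the ascertainment step
    that makes the synthetic family resemble a clinically collected,
    multiply-affected pedigree.  Leave it ``None`` for unbiased sampling
    (penetrance calibration checks rely on that).
    """
    cidx = gmap.indices_for(region.chrom)
    if cidx.size == 0:
        raise ValueError(f"region chromosome {region.chrom} is not on the map")
    chrom_bp = gmap.bp[cidx]
    if region.end < chrom_bp[0] or region.start > chrom_bp[-1]:
        raise ValueError("planted region lies outside the mapped marker span")

    rng = rng_for(seed, "plant")
    if causal_bp is None:
        causal_bp = int(rng.integers(region.start, region.end + 1))
    cm = (
        genome.cm_at(causal_bp)
        if genome is not None
        else float(np.interp(causal_bp, gmap.bp[cidx], gmap.cm[cidx]))
    )

    founders = pedigree.founders
    affected_founders = [f for f in founders if f.affection is Affection.AFFECTED]
    founder = affected_founders[0] if affected_founders else founders[0]
    order = pedigree.topological_order()
    nonfounders = [i for i in order if not i.is_founder]

    for _ in range(max_tries):
        slot_paternal = bool(rng.integers(0, 2))
        bit_draw = rng.integers(0, 2, size=2 * len(nonfounders))
        meiosis_bits = {
            nf.id: (int(bit_draw[2 * j]), int(bit_draw[2 * j + 1]))
            for j, nf in enumerate(nonfounders)
        }
        # resolve carrier status: track which founder slot each allele copies
        slot_of: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {}
        for ind in order:
            if ind.is_founder:
                slot_of[ind.id] = ((ind.id, 0), (ind.id, 1))
            else:
                bp_bit, bm_bit = meiosis_bits[ind.id]
                slot_of[ind.id] = (
                    slot_of[ind.father_id][bp_bit],
                    slot_of[ind.mother_id][bm_bit],
                )
        causal_slot = (founder.id, 0 if slot_paternal else 1)
        carriers = {
            iid for iid, slots in slot_of.items() if causal_slot in slots
        }
        phenotypes: dict[str, Affection] = {}
        phenocopies: set[str] = set()
        for ind in order:
            f = model.f1 if ind.id in carriers else model.f0
            affected = bool(rng.random() < f)
            phenotypes[ind.id] = (
                Affection.AFFECTED if affected else Affection.UNAFFECTED
            )
            if affected and ind.id not in carriers:
                phenocopies.add(ind.id)
        n_aff = sum(1 for a in phenotypes.values() if a is Affection.AFFECTED)
        if min_affected is None or n_aff >= min_affected:
            nonpen = {
                iid
                for iid in carriers
                if phenotypes[iid] is Affection.UNAFFECTED
            }
            descent = CausalDescent(
                region.chrom, cm, causal_bp, founder.id, slot_paternal,
                meiosis_bits, carriers,
            )
            return PlantResult(descent, phenotypes, carriers, nonpen, phenocopies)
    raise AscertainmentError(
        f"could not ascertain >= {min_affected} affected in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Transcript simulation
# ---------------------------------------------------------------------------

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_REVCOMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_transcripts(
    n_genes: int,
    genome: GenomeLayout,
    seed: int,
    codon_range: tuple[int, int] = (150, 400),
    flank: int = 300,
) -> tuple[list[TranscriptModel], SparseReference]:
    """Random multi-exon genes on both strands with valid ORFs.

    Genes are spread over chromosomes proportionally to physical length; the
    returned reference carries sequence only in a window around each gene.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng_for(seed, "transcripts")
    lengths = np.array([l for _, l in genome.chrom_lengths], dtype=float)
    probs = lengths / lengths.sum()
    ref = SparseReference()
    transcripts: list[TranscriptModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    g = 0
    while g < n_genes:
        ci = int(rng.choice(len(lengths), p=probs))
        chrom, clen = genome.chrom_lengths[ci]
        n_codons = int(rng.integers(*codon_range))
        cds_len = 3 * (n_codons + 2)  # + start and stop codons
        n_exons = int(rng.integers(2, 6))
        # split CDS into exon chunks of >= 30 bp
        cuts = sorted(rng.choice(np.arange(30, cds_len - 30, 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        chunk_lens = np.diff([0] + list(cuts) + [cds_len])
        if np.any(chunk_lens < 30):
            continue
        introns = rng.integers(60, 500, size=n_exons - 1)
        utr5, utr3 = 12, 12
        genomic_len = cds_len + int(introns.sum()) + utr5 + utr3
        start = int(rng.integers(flank + 1, clen - genomic_len - flank))
        span = (start - flank, start + genomic_len + flank)
        clashes = any(
            not (span[1] < s or e < span[0]) for s, e in occupied.get(chrom, [])
        )
        if clashes:
            continue
        strand = "+" if rng.random() < 0.5 else "-"

        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        cds_seq = (
            "ATG"
            + "".join(_SENSE_CODONS[i] for i in codon_idx)
            + sorted(STOP_CODONS)[int(rng.integers(0, 3))]
        )
        offsets = np.cumsum([0] + list(chunk_lens))
        window_seq = list(_random_seq(rng, genomic_len + 2 * flank))
        w0 = start - flank  # genomic position of window_seq[0]

        # Lay exons left-to-right genomically.  On the plus strand the e-th
        # genomic exon carries the e-th transcript chunk and the 5' UTR sits
        # in the leftmost exon; on the minus strand the transcript runs
        # right-to-left, so the leftmost exon carries the LAST chunk
        # (reverse-complemented) plus the 3' UTR.
        exons_g: list[tuple[int, int]] = []
        cds_g: list[tuple[int, int]] = []
        cursor = start
        for e in range(n_exons):
            chunk_i = e if strand == "+" else n_exons - 1 - e
            chunk = cds_seq[offsets[chunk_i] : offsets[chunk_i + 1]]
            left_utr = utr5 if (strand == "+" and e == 0) else (
                utr3 if (strand == "-" and e == 0) else 0
            )
            right_utr = utr3 if (strand == "+" and e == n_exons - 1) else (
                utr5 if (strand == "-" and e == n_exons - 1) else 0
            )
            exon_start = cursor
            cds_start = exon_start + left_utr
            cds_end = cds_start + len(chunk) - 1
            exon_end = cds_end + right_utr
            exons_g.append((exon_start, exon_end))
            cds_g.append((cds_start, cds_end))
            gseq = chunk if strand == "+" else _revcomp(chunk)
            window_seq[cds_start - w0 : cds_end - w0 + 1] = list(gseq)
            cursor = exon_end + 1 + (int(introns[e]) if e < n_exons - 1 else 0)

        gene_id = f"G{g + 1:04d}"
        t = TranscriptModel(
            gene_id,
            f"{gene_id}T1",
            chrom,
            strand,
            [GenomicInterval(chrom, s, e) for s, e in exons_g],
            [GenomicInterval(chrom, s, e) for s, e in cds_g],
        )
        ref.add(chrom, w0, "".join(window_seq))
        occupied.setdefault(chrom, []).append(span)
        validate_transcript(t, ref)
        transcripts.append(t)
        g += 1

    transcripts.sort(key=lambda t: (t.chrom, t.span.start))
    return transcripts, ref


# ---------------------------------------------------------------------------
# Variant-set simulation
# ---------------------------------------------------------------------------

CATEGORY_IN_CATALOG = "in_catalog"
CATEGORY_IN_CONTROLS = "in_controls"
CATEGORY_PRIVATE_BENIGN = "private_benign"
CATEGORY_CAUSAL = "private_truncating_causal"
CATEGORY_DECOY = "private_truncating_noncausal"


@dataclass(frozen=True)
class VariantCounts:
    """Composition of the proband variant list (and companion sets)."""

    n_catalog: int = 1000  # proband variants also present in the catalog
    n_catalog_extra: int = 1000  # catalog-only records (never in the proband)
    n_control_shared: int = 500  # proband variants carried by >= 1 control
    n_private_benign: int = 300
    n_stop_gained: int = 19
    n_frameshift: int = 90  # includes the one causal frameshifting deletion
    n_controls: int = 8

    def __post_init__(self) -> None:
        for name in (
            "n_catalog", "n_catalog_extra", "n_control_shared",
            "n_private_benign", "n_stop_gained",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frameshift < 1:
            raise ValueError("n_frameshift must be >= 1 (the causal deletion)")


@dataclass
class VariantSets:
    proband: list[Variant]
    catalog: list[Variant]
    controls: list[list[Variant]]
    categories: dict[tuple[str, int, str, str], str]  # normalized key -> label
    causal: Variant
    causal_gene: str


class _PositionLedger:
    """Keeps engineered variants from colliding or abutting."""

    def __init__(self) -> None:
        self.used: set[tuple[str, int]] = set()

    def claim(self, chrom: str, start: int, end: int, pad: int = 2) -> bool:
        span = [(chrom, p) for p in range(start - pad, end + pad + 1)]
        if any(s in self.used for s in span):
            return False
        self.used.update(span)
        return True


def _weighted_window(rng, ref: SparseReference) -> tuple[str, int, str]:
    flat = [
        (chrom, start, seq)
        for chrom, wins in sorted(ref.windows.items())
        for start, seq in wins
    ]
    weights = np.array([len(seq) for _, _, seq in flat], dtype=float)
    i = int(rng.choice(len(flat), p=weights / weights.sum()))
    return flat[i]


def _random_snv(
    rng,
    ref: SparseReference,
    ledger: _PositionLedger,
    transcripts: Sequence[TranscriptModel],
    forbid_truncating: bool = True,
    max_tries: int = 1000,
) -> Variant:
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for _ in range(max_tries):
        chrom, start, seq = _weighted_window(rng, ref)
        off = int(rng.integers(5, len(seq) - 5))
        pos = start + off
        refb = seq[off]
        altb = "ACGT"[int(rng.integers(0, 4))]
        if altb == refb:
            continue
        if forbid_truncating and _snv_makes_stop(
            chrom, pos, altb, by_chrom.get(chrom, ()), ref
        ):
            continue
        if not ledger.claim(chrom, pos, pos):
            continue
        return Variant(chrom, pos, refb, altb)
    raise RuntimeError("could not place a random SNV (windows exhausted?)")


def _snv_makes_stop(chrom, pos, alt_genomic, transcripts, ref) -> bool:
    from Bio.Seq import Seq

    for t in transcripts:
        cpos = t.genomic_to_cds(pos)
        if cpos is None:
            continue
        alt_t = alt_genomic if t.strand == "+" else str(Seq(alt_genomic).complement())
        cds = t.spliced_cds(ref)
        ci = (cpos - 1) // 3
        codon = list(cds[ci * 3 : ci * 3 + 3])
        codon[(cpos - 1) % 3] = alt_t
        if "".join(codon) in STOP_CODONS:
            return True
    return False


def make_stop_gain(
    rng, gene: TranscriptModel, ref: SparseReference, ledger: _PositionLedger,
    max_tries: int = 200,
) -> Variant:
    """An SNV engineered to convert an internal codon to a stop codon."""
    from Bio.Seq import Seq

    cds = gene.spliced_cds(ref)
    n_codons = len(cds) // 3
    for _ in range(max_tries):
        ci = int(rng.integers(1, n_codons - 1))
        codon = cds[ci * 3 : ci * 3 + 3]
        cands = [
            (w, stop[w])
            for w in range(3)
            for stop in STOP_CODONS
            if sum(a != b for a, b in zip(codon, stop)) == 1 and codon[w] != stop[w]
        ]
        if not cands:
            continue
        w, newb = cands[int(rng.integers(0, len(cands)))]
        cpos = ci * 3 + w + 1
        gpos = gene.cds_to_genomic(cpos)
        if gene.strand == "+":
            refb, altb = codon[w], newb
        else:
            refb = str(Seq(codon[w]).complement())
            altb = str(Seq(newb).complement())
        if not ledger.claim(gene.chrom, gpos, gpos):
            continue
        return Variant(gene.chrom, gpos, refb, altb)
    raise RuntimeError(f"no stop-gain site found in {gene.gene_id}")


def make_frameshift_indel(
    rng,
    gene: TranscriptModel,
    ref: SparseReference,
    ledger: _PositionLedger,
    del_len: Optional[int] = None,
    max_tries: int = 200,
) -> Variant:
    """A left-anchored CDS indel whose length is not divisible by 3."""
    for _ in range(max_tries):
        if del_len is not None:
            length, is_del = del_len, True
        else:
            length = int(rng.choice([1, 2, 4]))
            is_del = bool(rng.random() < 0.75)
            if not is_del:
                length = int(rng.choice([1, 2]))
        segs = [s for s in gene.cds if s.length >= length + 12]
        if not segs:
            continue
        seg = segs[int(rng.integers(0, len(segs)))]
        start = int(rng.integers(seg.start + 5, seg.end - length - 5))
        anchor = start - 1
        if is_del:
            refseq = ref.fetch(gene.chrom, anchor, start + length - 1)
            variant = Variant(gene.chrom, anchor, refseq, refseq[0])
            lo, hi = anchor, start + length - 1
        else:
            base = ref.fetch(gene.chrom, start, start)
            ins = _random_seq(rng, length)
            variant = Variant(gene.chrom, start, base, base + ins)
            lo, hi = start, start
        # the whole deleted run must stay inside this CDS segment
        if is_del and (start < seg.start or start + length - 1 > seg.end):
            continue
        if not ledger.claim(gene.chrom, lo, hi):
            continue
        return variant
    raise RuntimeError(f"no indel site found in {gene.gene_id}")


def make_causal_deletion(
    rng, gene: TranscriptModel, ref: SparseReference, ledger: _PositionLedger
) -> Variant:
    """The planted causal event: an 11 bp frameshifting CDS deletion."""
    return make_frameshift_indel(rng, gene, ref, ledger, del_len=11)


def simulate_variant_sets(
    transcripts: Sequence[TranscriptModel],
    reference: SparseReference,
    planted_region: GenomicInterval,
    causal: Variant,
    causal_gene: str,
    counts: VariantCounts,
    seed: int,
) -> VariantSets:
    """Proband, catalog and control variant sets with truth labels.

    The proband list holds the causal deletion plus four decoy strata:
    catalog-known SNVs, control-shared SNVs, private benign SNVs and private
    truncating decoys (stop gains + frameshifting indels).  All truncating
    decoys are placed in genes *outside* the planted region, so that region
    holds exactly one private truncating variant - the causal one.  Truth
    labels are keyed by normalized (left-aligned) variant identity.
    """
    rng = rng_for(seed, "variant_sets")
    ledger = _PositionLedger()
    ledger.claim(causal.chrom, causal.pos, causal.end)

    genes_outside = [
        t
        for t in transcripts
        if not planted_region.overlaps(t.span)
    ]
    if counts.n_stop_gained + counts.n_frameshift - 1 > 0 and not genes_outside:
        raise ValueError("no genes outside the planted region to host decoys")

    proband: list[Variant] = [causal]
    categories: dict[tuple[str, int, str, str], str] = {
        left_align(causal, reference).key: CATEGORY_CAUSAL
    }

    def add(v: Variant, label: str) -> None:
        proband.append(v)
        categories[left_align(v, reference).key] = label

    for _ in range(counts.n_stop_gained):
        g = genes_outside[int(rng.integers(0, len(genes_outside)))]
        add(make_stop_gain(rng, g, reference, ledger), CATEGORY_DECOY)
    for _ in range(counts.n_frameshift - 1):
        g = genes_outside[int(rng.integers(0, len(genes_outside)))]
        add(make_frameshift_indel(rng, g, reference, ledger), CATEGORY_DECOY)

    for _ in range(counts.n_private_benign):
        add(_random_snv(rng, reference, ledger, transcripts), CATEGORY_PRIVATE_BENIGN)

    catalog: list[Variant] = []
    for _ in range(counts.n_catalog):
        v = _random_snv(rng, reference, ledger, transcripts)
        add(v, CATEGORY_IN_CATALOG)
        catalog.append(v)
    for _ in range(counts.n_catalog_extra):
        catalog.append(_random_snv(rng, reference, ledger, transcripts))

    controls: list[list[Variant]] = [[] for _ in range(counts.n_controls)]
    for _ in range(counts.n_control_shared):
        v = _random_snv(rng, reference, ledger, transcripts)
        add(v, CATEGORY_IN_CONTROLS)
        n_carriers = 1 + int(rng.binomial(counts.n_controls - 1, 0.25))
        for j in rng.choice(counts.n_controls, size=n_carriers, replace=False):
            controls[int(j)].append(v)

    proband.sort()
    catalog.sort()
    for c in controls:
        c.sort()
    return VariantSets(proband, catalog, controls, categories, causal, causal_gene)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

def simulate_depth_profile(
    region: GenomicInterval,
    mean_depth: float = 31.8,
    seed: int = 0,
    unmappable_fraction: float = 0.022,
    score_zero_fraction: float = 0.0,
):
    """Per-base Poisson read depths over a region.

    A fraction of bases is unmappable (zero reads, emulating assembly gaps
    and repeats); consensus scores are positive wherever at least one read
    landed, unless ``score_zero_fraction`` marks some covered bases as
    low-confidence (score 0), which exercises the score clause of the
    covered-base rule.
    """
    import pandas as pd

    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = rng_for(seed, "depth")
    n = region.length
    reads = rng.poisson(mean_depth, size=n)
    reads[rng.random(n) < unmappable_fraction] = 0
    score = rng.integers(1, 61, size=n)
    score[rng.random(n) < score_zero_fraction] = 0
    score[reads == 0] = 0
    return pd.DataFrame(
        {
            "chrom": region.chrom,
            "pos": np.arange(region.start, region.end + 1),
            "reads": reads,
            "consensus_score": score,
        }
    )


# ---------------------------------------------------------------------------
# Truth record and the one-stop cohort builder
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of a synthetic cohort, consumed by audits and tests."""

    causal_variant: Variant
    causal_gene: str
    planted_region: GenomicInterval
    carrier_ids: set[str]
    nonpenetrant_ids: set[str]
    phenotypes: dict[str, str]  # id -> affected/unaffected
    categories: dict[tuple[str, int, str, str], str]

    def __post_init__(self) -> None:
        if not self.planted_region.contains(
            self.causal_variant.chrom, self.causal_variant.pos
        ):
            raise ValueError("causal variant must lie inside the planted region")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_variant": list(self.causal_variant.key),
            "causal_gene": self.causal_gene,
            "planted_region": [
                self.planted_region.chrom,
                self.planted_region.start,
                self.planted_region.end,
            ],
            "carrier_ids": sorted(self.carrier_ids),
            "nonpenetrant_ids": sorted(self.nonpenetrant_ids),
            "phenotypes": self.phenotypes,
            "categories": {
                f"{c}:{p}:{r}:{a}": lab
                for (c, p, r, a), lab in sorted(self.categories.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        c, p, r, a = d["causal_variant"]
        cats = {}
        for key, lab in d["categories"].items():
            chrom, pos, ref, alt = key.rsplit(":", 3)
            cats[(chrom, int(pos), ref, alt)] = lab
        return cls(
            Variant(c, int(p), r, a),
            d["causal_gene"],
            GenomicInterval(*d["planted_region"][:1], *map(int, d["planted_region"][1:])),
            set(d["carrier_ids"]),
            set(d["nonpenetrant_ids"]),
            d["phenotypes"],
            cats,
        )


@dataclass(frozen=True)
class CohortConfig:
    template: str = "pedigree1_like"
    genome: GenomeLayout = GenomeLayout()
    markers_per_cm: float = 40.0
    n_genes: int = 280
    region_mb: float = 10.0
    model: DiseaseModel = DiseaseModel()
    counts: VariantCounts = VariantCounts()
    min_affected: Optional[int] = 7
    mean_depth: float = 31.8
    depth_bases: int = 100_000


@dataclass
class SyntheticCohort:
    config: CohortConfig
    seed: int
    pedigree: Pedigree  # affection statuses re-drawn under the disease model
    gmap: GeneticMap
    founder_freqs: np.ndarray
    genotypes: GenotypeMatrix
    transcripts: list[TranscriptModel]
    reference: SparseReference
    plant: PlantResult
    variant_sets: VariantSets
    truth: TruthRecord
    depth: "object"  # pandas DataFrame


def build_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic study: family, genotypes, variants, truth."""
    base = make_pedigree_fixture(config.template, seed)
    gmap, freqs = simulate_chip(config.genome, config.markers_per_cm, seed)
    transcripts, reference = simulate_transcripts(config.n_genes, config.genome, seed)

    rng = rng_for(seed, "region")
    causal_gene = transcripts[int(rng.integers(0, len(transcripts)))]
    half = int(config.region_mb * 1e6 / 2)
    mid = (causal_gene.span.start + causal_gene.span.end) // 2
    clen = config.genome.length_of(causal_gene.chrom)
    start = max(1, mid - half)
    end = min(clen, mid + half)
    planted_region = GenomicInterval(causal_gene.chrom, start, end)

    ledger = _PositionLedger()
    causal = make_causal_deletion(rng, causal_gene, reference, ledger)

    plant = plant_causal_variant(
        base,
        gmap,
        planted_region,
        config.model,
        seed,
        causal_bp=causal.pos,
        min_affected=config.min_affected,
        genome=config.genome,
    )
    pedigree = base.with_affection(plant.phenotypes)
    drop = gene_drop(pedigree, gmap, freqs, seed, condition_on=plant.descent)

    vsets = simulate_variant_sets(
        transcripts,
        reference,
        planted_region,
        causal,
        causal_gene.gene_id,
        config.counts,
        seed,
    )

    truth = TruthRecord(
        causal_variant=causal,
        causal_gene=causal_gene.gene_id,
        planted_region=planted_region,
        carrier_ids=set(plant.carrier_ids),
        nonpenetrant_ids=set(plant.nonpenetrant_ids),
        phenotypes={
            iid: aff.value for iid, aff in plant.phenotypes.items()
        },
        categories=dict(vsets.categories),
    )

    depth_region = GenomicInterval(
        planted_region.chrom,
        planted_region.start,
        min(planted_region.end, planted_region.start + config.depth_bases - 1),
    )
    depth = simulate_depth_profile(depth_region, config.mean_depth, seed)

    return SyntheticCohort(
        config, seed, pedigree, gmap, freqs, drop.genotypes, transcripts,
        reference, plant, vsets, truth, depth,
    )


# ---------------------------------------------------------------------------
# Engineered demonstration fixtures (synthetic stand-ins)
# ---------------------------------------------------------------------------

def make_truncation_demo(seed: int = 0):
    """Synthetic single-gene fixture for the frameshift stop scan.

    The 200-codon CDS is engineered so that deleting coding bases 514-524
    (an 11 bp frameshifting deletion, ``c.514_524del11``) shifts the frame
    into 12 novel codons followed by a premature stop - the geometry of the
    frameshift followed in the motivating study, on a constructed sequence
    (the real transcript is not bundled).

    Returns (transcript, reference, genomic_variant, hgvs_change).
    """
    from .hgvs import ChangeKind, HgvsCodingChange

    rng = rng_for(seed, "truncation_demo")
    n_codons = 200
    for _ in range(10_000):
        codons = ["ATG"] + [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        seq = list("".join(codons))
        # shifted frame after the deletion: 12 sense codons then TAA,
        # occupying original coding positions 525..563 (0-based 524..562)
        shifted = [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=12)
        ]
        seq[524:560] = list("".join(shifted))
        seq[560:563] = list("TAA")
        cds = "".join(seq)
        frame_codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(c in STOP_CODONS for c in frame_codons[:-1]):
            continue
        if frame_codons[-1] not in STOP_CODONS:
            continue
        break
    else:  # pragma: no cover - the search space is dense in valid fixtures
        raise RuntimeError("could not engineer the truncation demo CDS")

    chrom, gene_start, utr = "chr12", 111_000_001, 12
    cds_start = gene_start + utr
    cds_end = cds_start + len(cds) - 1
    exon = GenomicInterval(chrom, gene_start, cds_end + utr)
    t = TranscriptModel(
        "DEMO_FS",
        "DEMO_FS_T1",
        chrom,
        "+",
        [exon],
        [GenomicInterval(chrom, cds_start, cds_end)],
    )
    ref = SparseReference()
    window = (
        _random_seq(rng, utr) + cds + _random_seq(rng, utr)
    )
    ref.add(chrom, gene_start, window)
    validate_transcript(t, ref)

    change = HgvsCodingChange(ChangeKind.DELETION, 514, 524)
    # left-anchored genomic deletion: anchor at coding base 513
    anchor = t.cds_to_genomic(513)
    refseq = ref.fetch(chrom, anchor, anchor + 11)
    variant = Variant(chrom, anchor, refseq, refseq[0])
    return t, ref, variant, change


def make_nonsense_demo(seed: int = 0):
    """Synthetic fixture for a nonsense mutation that destroys an RsaI site.

    Codon 137 is fixed to GTA and codon 138 to CGA, so the reference carries
    the RsaI recognition site GTAC spanning the codon boundary; the C>T
    substitution at coding position 412 converts CGA to the stop codon TGA
    and abolishes the site (the p.R138X geometry, on a constructed sequence).

    Returns (transcript, reference, genomic_variant).
    """
    rng = rng_for(seed, "nonsense_demo")
    n_codons = 180
    for _ in range(10_000):
        codons = ["ATG"] + [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        codons[136] = "GTA"  # codon 137
        codons[137] = "CGA"  # codon 138, C at coding position 412
        cds = "".join(codons)
        frame_codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(c in STOP_CODONS for c in frame_codons[:-1]):
            continue
        break
    else:  # pragma: no cover
        raise RuntimeError("could not engineer the nonsense demo CDS")

    chrom, gene_start, utr = "chr12", 111_375_001, 12
    cds_start = gene_start + utr
    cds_end = cds_start + len(cds) - 1
    t = TranscriptModel(
        "DEMO_STOP",
        "DEMO_STOP_T1",
        chrom,
        "+",
        [GenomicInterval(chrom, gene_start, cds_end + utr)],
        [GenomicInterval(chrom, cds_start, cds_end)],
    )
    ref = SparseReference()
    ref.add(chrom, gene_start, _random_seq(rng, utr) + cds + _random_seq(rng, utr))
    validate_transcript(t, ref)
    gpos = t.cds_to_genomic(412)
    variant = Variant(chrom, gpos, "C", "T")
    return t, ref, variant
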