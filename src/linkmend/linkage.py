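"""Parametric multipoint linkage on small pedigrees.

The engine is an inheritance-vector hidden-Markov model in the Lander–Green
style: the hidden state at each marker is the vector of meiosis indicators
(one bit per parent-to-child transmission, recording which grandparental
allele was passed), transitions between adjacent markers flip each bit
independently with the Haldane recombination fraction, marker data enter
through a founder-allele-graph emission, and the disease phenotypes enter
through a penetrance-weighted sum over founder disease-allele configurations
under a diallelic disease model (q, f0, f1, f2).

The parametric LOD at marker x is

    LOD(x) = log10  P(markers, phenotypes | disease locus at x)
                    -------------------------------------------
                    P(markers) . P(phenotypes)

evaluated at marker positions only.  Untyped individuals are summed over
implicitly (their genotypes never constrain the founder graph).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import disease_emission, marker_emission
from .disease import DiseaseModel
from .intervals import GenomicInterval
from .markers import GeneticMap, GenotypeMatrix
from .pedigree import Affection, Pedigree

logger = logging.getLogger(__name__)

MAX_STATE_BITS = 24  # refuse pedigrees needing more than 2^24 inheritance vectors

LOD_FLOOR = -20.0  # reported LOD is clamped here; keeps curves finite


class LinkageError(ValueError):
    pass


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for a genetic distance in cM (no interference)."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def haldane_cm(theta: float) -> float:
    return -50.0 * math.log(1.0 - 2.0 * theta)


# ---------------------------------------------------------------------------
# Pedigree indexing and inheritance-vector machinery
# ---------------------------------------------------------------------------

@dataclass
class PedigreeIndex:
    """Bit/slot bookkeeping for the inheritance-vector state space."""

    pedigree: Pedigree
    ids: list[str]  # topological order, founders not necessarily first
    founder_slot: dict[str, int]  # founder id -> first of its two slots
    bit_of: dict[str, int]  # non-founder id -> first of its two meiosis bits
    n_bits: int
    n_slots: int

    @classmethod
    def build(cls, pedigree: Pedigree) -> "PedigreeIndex":
        order = pedigree.topological_order()
        ids = [i.id for i in order]
        founder_slot: dict[str, int] = {}
        bit_of: dict[str, int] = {}
        s = b = 0
        for ind in order:
            if ind.is_founder:
                founder_slot[ind.id] = s
                s += 2
            else:
                bit_of[ind.id] = b
                b += 2
        if b > MAX_STATE_BITS:
            raise LinkageError(
                f"pedigree needs 2^{b} inheritance vectors; guard is 2^{MAX_STATE_BITS}"
            )
        return cls(pedigree, ids, founder_slot, bit_of, b, s)

    @property
    def n_vectors(self) -> int:
        return 1 << self.n_bits

    def slot_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(V, n_ind) founder-slot of each individual's paternal/maternal allele."""
        V = self.n_vectors
        n = len(self.ids)
        pos = {iid: k for k, iid in enumerate(self.ids)}
        slots_p = np.empty((V, n), dtype=np.int16)
        slots_m = np.empty((V, n), dtype=np.int16)
        v = np.arange(V, dtype=np.int64)
        for k, iid in enumerate(self.ids):
            ind = self.pedigree[iid]
            if ind.is_founder:
                slots_p[:, k] = self.founder_slot[iid]
                slots_m[:, k] = self.founder_slot[iid] + 1
            else:
                b = self.bit_of[iid]
                fa, mo = pos[ind.father_id], pos[ind.mother_id]
                bit_p = (v >> b) & 1
                bit_m = (v >> (b + 1)) & 1
                slots_p[:, k] = np.where(
                    bit_p == 0, slots_p[:, fa], slots_m[:, fa]
                )
                slots_m[:, k] = np.where(
                    bit_m == 0, slots_p[:, mo], slots_m[:, mo]
                )
        return slots_p, slots_m


def _transition(arr: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """One HMM step: each meiosis bit flips independently with prob theta."""
    if theta == 0.0 or n_bits == 0:
        return arr
    a = arr.reshape((2,) * n_bits)
    for axis in range(n_bits):
        a = (1.0 - theta) * a + theta * np.flip(a, axis=axis)
    return a.reshape(arr.shape)


def _pheno_codes(pedigree: Pedigree, ids: Sequence[str]) -> np.ndarray:
    code = {Affection.UNAFFECTED: 0, Affection.AFFECTED: 1, Affection.UNKNOWN: -1}
    return np.array([code[pedigree[i].affection] for i in ids], dtype=np.int8)


def _genotype_codes(
    alleles_row: np.ndarray, sample_pos: dict[str, int], ids: Sequence[str]
) -> np.ndarray:
    """Map one marker's allele pairs to codes: -1 missing, 0=11, 1=het, 2=22."""
    out = np.full(len(ids), -1, dtype=np.int8)
    for k, iid in enumerate(ids):
        j = sample_pos.get(iid)
        if j is None:
            continue
        a, b = alleles_row[j]
        if a == 0:
            continue
        out[k] = (a - 1) + (b - 1)
    return out


# ---------------------------------------------------------------------------
# SNP selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSelectionRule:
    """Keep markers heterozygous in >= min_het_individuals, then retain a
    fixed fraction thinned evenly along the genetic map."""

    min_het_individuals: int = 4
    target_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in (0, 1]")
        if self.min_het_individuals < 0:
            raise ValueError("min_het_individuals must be >= 0")


def select_linkage_snps(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    rule: SnpSelectionRule = SnpSelectionRule(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Indices of retained markers (sorted, in map order).

    Eligibility is the heterozygosity rule; the retained count is
    round(target_fraction x eligible), spread evenly in genetic position per
    chromosome.  Selection is deterministic; ``seed`` is accepted for
    interface symmetry with the simulation stages but unused.
    """
    if genotypes.n_markers != len(gmap):
        raise LinkageError("genotype matrix and map have different marker counts")
    eligible = np.flatnonzero(genotypes.het_counts() >= rule.min_het_individuals)
    if eligible.size == 0:
        logger.warning("no marker satisfies the heterozygosity rule")
        return eligible
    n_keep = int(round(rule.target_fraction * eligible.size))
    n_keep = max(n_keep, 0)
    if n_keep == 0:
        return np.empty(0, dtype=np.int64)
    chrom_arr = np.asarray(gmap.chroms, dtype=object)[eligible]
    kept: list[int] = []
    chroms = list(dict.fromkeys(gmap.chroms))
    # allocate per chromosome proportionally to its eligible markers
    sizes = np.array([(chrom_arr == c).sum() for c in chroms], dtype=float)
    alloc = np.floor(n_keep * sizes / sizes.sum()).astype(int)
    remainder = n_keep - alloc.sum()
    for i in np.argsort(-(n_keep * sizes / sizes.sum() - alloc))[:remainder]:
        alloc[i] += 1
    for c, k in zip(chroms, alloc):
        idx = eligible[chrom_arr == c]
        if k <= 0 or idx.size == 0:
            continue
        if k >= idx.size:
            kept.extend(idx.tolist())
            continue
        cm = gmap.cm[idx]
        targets = np.linspace(cm[0], cm[-1], k)
        chosen = sorted(set(int(idx[np.argmin(np.abs(cm - t))]) for t in targets))
        # top up if nearest-position picks collided
        pool = [int(i) for i in idx if int(i) not in set(chosen)]
        chosen.extend(pool[: k - len(chosen)])
        kept.extend(sorted(chosen))
    return np.array(sorted(kept), dtype=np.int64)


# ---------------------------------------------------------------------------
# Multipoint LOD
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    marker_ids: list[str]
    chroms: list[str]
    bp: np.ndarray
    cm: np.ndarray
    lod: np.ndarray
    model: DiseaseModel
    dropped_markers: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "bp": self.bp,
                "cM": self.cm,
                "marker": self.marker_ids,
                "lod": self.lod,
            }
        )


def estimate_allele_freqs(
    genotypes: GenotypeMatrix, pseudocount: float = 1.0
) -> np.ndarray:
    """Frequency of allele 1 per marker from genotyped pedigree members.

    A symmetric pseudocount keeps frequencies off the boundary when a marker
    happens to be monomorphic among the typed members.
    """
    n1 = (genotypes.alleles == 1).sum(axis=(1, 2))
    n2 = (genotypes.alleles == 2).sum(axis=(1, 2))
    return (n1 + pseudocount) / (n1 + n2 + 2.0 * pseudocount)


def compute_multipoint_lod(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    model: DiseaseModel = DiseaseModel(),
    allele_freqs: Optional[np.ndarray] = None,
) -> LodCurve:
    """Parametric multipoint LOD at every marker of ``gmap``.

    Markers whose genotypes are Mendelian-inconsistent with the pedigree are
    dropped (logged and listed on the returned curve) and contribute nothing.
    """
    if genotypes.n_markers != len(gmap):
        raise LinkageError("genotype matrix and map have different marker counts")
    idx = PedigreeIndex.build(pedigree)
    slots_p, slots_m = idx.slot_arrays()
    V = idx.n_vectors
    sample_pos = {
        s: j for j, s in enumerate(genotypes.sample_ids) if s in pedigree
    }
    # untyped-in-pedigree or ungenotyped individuals simply contribute no data
    for iid in list(sample_pos):
        if not pedigree[iid].genotyped:
            del sample_pos[iid]

    phenos = _pheno_codes(pedigree, idx.ids)
    e_dis = np.empty(V)
    disease_emission(
        slots_p,
        slots_m,
        phenos,
        np.array(model.penetrance),
        model.q,
        idx.n_slots,
        e_dis,
    )
    p_phi = e_dis.mean()
    if p_phi == 0.0:
        raise LinkageError("phenotypes have zero probability under the disease model")

    if allele_freqs is None:
        allele_freqs = estimate_allele_freqs(genotypes)

    lod = np.zeros(len(gmap))
    dropped: list[str] = []

    for chrom in gmap.chromosomes:
        cidx = gmap.indices_for(chrom)
        emissions: list[np.ndarray] = []
        keep: list[int] = []
        for m in cidx:
            gcodes = _genotype_codes(genotypes.alleles[m], sample_pos, idx.ids)
            out = np.empty(V)
            marker_emission(slots_p, slots_m, gcodes, float(allele_freqs[m]), out)
            total = out.sum()
            if total == 0.0:
                mid = gmap.marker_ids[m]
                logger.warning("dropping Mendelian-inconsistent marker %s", mid)
                dropped.append(mid)
                lod[m] = 0.0
                continue
            emissions.append(out)
            keep.append(int(m))
        if not keep:
            continue
        cm = gmap.cm[keep]
        thetas = [haldane_theta(cm[k + 1] - cm[k]) for k in range(len(keep) - 1)]
        n = len(keep)
        # scaled forward (includes own emission) and backward (excludes it)
        fwd = np.empty((n, V))
        bwd = np.empty((n, V))
        a = emissions[0] / V
        fwd[0] = a / a.sum()
        for k in range(1, n):
            a = _transition(fwd[k - 1], thetas[k - 1], idx.n_bits) * emissions[k]
            fwd[k] = a / a.sum()
        b = np.full(V, 1.0 / V)
        bwd[n - 1] = b
        for k in range(n - 2, -1, -1):
            b = _transition(bwd[k + 1] * emissions[k + 1], thetas[k], idx.n_bits)
            bwd[k] = b / b.sum()
        for k, m in enumerate(keep):
            gamma = fwd[k] * bwd[k]
            gamma /= gamma.sum()
            ratio = float(gamma @ e_dis) / p_phi
            lod[m] = max(math.log10(ratio), LOD_FLOOR) if ratio > 0 else LOD_FLOOR

    return LodCurve(
        list(gmap.marker_ids),
        list(gmap.chroms),
        gmap.bp.copy(),
        gmap.cm.copy(),
        lod,
        model,
        dropped,
    )


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    interval: GenomicInterval
    peak_lod: float
    n_markers: int
    n_tolerated_nonpenetrant: int = 0
    nonpenetrant_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chrom": self.interval.chrom,
            "start": self.interval.start,
            "end": self.interval.end,
            "peak_lod": self.peak_lod,
            "n_markers": self.n_markers,
            "n_tolerated_nonpenetrant": self.n_tolerated_nonpenetrant,
            "nonpenetrant_ids": self.nonpenetrant_ids,
        }


def call_candidate_regions(
    curve: LodCurve,
    threshold: float = 1.0,
    merge_gap_markers: int = 0,
    extend_to_flanking: bool = True,
) -> list[CandidateRegion]:
    """Maximal runs of markers with LOD >= threshold (ties included).

    Runs on the same chromosome separated by at most ``merge_gap_markers``
    sub-threshold markers are merged.  With ``extend_to_flanking`` (the
    default) the region interval runs from the sub-threshold marker just
    before the first qualifying marker to the one just after the last - the
    support-interval convention, appropriate when markers are sparse because
    the locus is not excluded anywhere short of the flanking markers.  Set it
    False to span only the qualifying markers themselves.
    """
    if not math.isfinite(threshold):
        raise LinkageError("threshold must be finite")
    regions: list[CandidateRegion] = []
    chrom_arr = np.asarray(curve.chroms, dtype=object)
    for chrom in dict.fromkeys(curve.chroms):
        cidx = np.flatnonzero(chrom_arr == chrom)
        qual = curve.lod[cidx] >= threshold
        runs: list[list[int]] = []
        current: list[int] = []
        gap = 0
        for k, q in enumerate(qual):
            if q:
                current.append(k)
                gap = 0
            elif current:
                gap += 1
                if gap > merge_gap_markers:
                    runs.append(current)
                    current = []
                    gap = 0
        if current:
            runs.append(current)
        for run in runs:
            lo, hi = run[0], run[-1]
            if extend_to_flanking:
                lo = max(lo - 1, 0)
                hi = min(hi + 1, len(cidx) - 1)
            first, last = cidx[lo], cidx[hi]
            span = cidx[run[0] : run[-1] + 1]
            regions.append(
                CandidateRegion(
                    GenomicInterval(chrom, int(curve.bp[first]), int(curve.bp[last])),
                    peak_lod=float(curve.lod[span].max()),
                    n_markers=int(span.size),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# Affected-sharing scan (IBS-based, non-penetrance tolerant)
# ---------------------------------------------------------------------------

def marker_sharing(
    aff_genotypes: np.ndarray, max_exceptions: int
) -> tuple[bool, int, list[int]]:
    """Can all affecteds share one allele identical by state at this marker?

    ``aff_genotypes``: (n_affected, 2) allele codes, 0 = missing.  Returns
    (compatible, shared allele or 0, indices of affecteds used as exceptions).
    """
    best_allele, best_exc = 0, None
    for allele in (1, 2):
        exc = [
            i
            for i in range(aff_genotypes.shape[0])
            if aff_genotypes[i, 0] != 0 and allele not in aff_genotypes[i]
        ]
        if best_exc is None or len(exc) < len(best_exc):
            best_allele, best_exc = allele, exc
    assert best_exc is not None
    return len(best_exc) <= max_exceptions, best_allele, best_exc


def affected_sharing_scan(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    max_exceptions: int = 1,
) -> list[CandidateRegion]:
    """Runs of markers where genotyped affecteds can share an IBS allele.

    A simplified reimplementation of the pediSNP/SNPduo idea: per marker the
    scan asks whether a single allele can be carried by every genotyped
    affected, tolerating up to ``max_exceptions`` affecteds (candidate
    misclassifications); unaffected individuals carrying the shared allele at
    every typed marker of a run are reported as candidate non-penetrants.
    """
    aff_ids = [i.id for i in pedigree.affected if i.genotyped]
    if len(aff_ids) < 2:
        raise LinkageError("sharing scan needs >= 2 genotyped affected individuals")
    unaff_ids = [i.id for i in pedigree.unaffected if i.genotyped]
    sample_pos = {s: j for j, s in enumerate(genotypes.sample_ids)}
    aff_j = [sample_pos[i] for i in aff_ids if i in sample_pos]
    unaff_j = [sample_pos[i] for i in unaff_ids if i in sample_pos]

    regions: list[CandidateRegion] = []
    chrom_arr = np.asarray(gmap.chroms, dtype=object)
    for chrom in gmap.chromosomes:
        cidx = np.flatnonzero(chrom_arr == chrom)
        flags = []
        for m in cidx:
            ok, allele, exc = marker_sharing(
                genotypes.alleles[m][aff_j], max_exceptions
            )
            flags.append((ok, allele, exc))
        k = 0
        while k < len(cidx):
            if not flags[k][0]:
                k += 1
                continue
            j = k
            while j + 1 < len(cidx) and flags[j + 1][0]:
                j += 1
            run = list(range(k, j + 1))
            exc_ids = sorted(
                {aff_ids[e] for r in run for e in flags[r][2]}
            )
            nonpen = []
            for u, uj in zip(unaff_ids, unaff_j):
                carries = True
                for r in run:
                    g = genotypes.alleles[cidx[r]][uj]
                    if g[0] == 0:
                        continue
                    if flags[r][1] not in g:
                        carries = False
                        break
                if carries:
                    nonpen.append(u)
            regions.append(
                CandidateRegion(
                    GenomicInterval(
                        chrom, int(gmap.bp[cidx[k]]), int(gmap.bp[cidx[j]])
                    ),
                    peak_lod=float("nan"),
                    n_markers=len(run),
                    n_tolerated_nonpenetrant=len(exc_ids),
                    nonpenetrant_ids=nonpen,
                )
            )
            k = j + 1
    return regions
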