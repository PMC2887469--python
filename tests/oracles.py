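"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the pedigree
likelihood enumerates complete descent patterns and founder allele
configurations exhaustively; translation uses a hand-written codon table;
restriction sites come from Biopython's enzyme catalog.  They are only
feasible at tiny problem sizes, which is the point.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np

from linkmend.disease import DiseaseModel
from linkmend.pedigree import Affection, Pedigree

# ---------------------------------------------------------------------------
# Codon table (standard code), written out rather than imported
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate_oracle(seq: str) -> str:
    """Translate until the first stop (exclusive); '*' never appears."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def frameshift_scan_oracle(cds: str, mutated: str, first_affected: int) -> tuple[int, bool]:
    """Count novel codons before a stop after a frame-shifting change.

    ``first_affected`` is the 1-based CDS position of the first changed base.
    """
    ci = (first_affected - 1) // 3
    novel = 0
    for k in range(ci * 3, len(mutated) - 2, 3):
        if CODON_TABLE[mutated[k : k + 3]] == "*":
            return novel, True
        novel += 1
    return novel, False


# ---------------------------------------------------------------------------
# Exhaustive pedigree likelihood (Elston-Stewart-style enumeration)
# ---------------------------------------------------------------------------

def _haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


class PedigreeEnumerator:
    """Exhaustive sums over descent patterns and founder allele configs.

    Feasible only for pedigrees with <= ~3 non-founders and <= 3 markers.
    """

    def __init__(self, pedigree: Pedigree):
        self.pedigree = pedigree
        order = pedigree.topological_order()
        self.ids = [i.id for i in order]
        self.founders = [i.id for i in order if pedigree[i.id].is_founder]
        self.nonfounders = [i.id for i in order if not pedigree[i.id].is_founder]
        self.n_bits = 2 * len(self.nonfounders)
        self.n_slots = 2 * len(self.founders)
        self._slot_cache: dict[int, dict[str, tuple[int, int]]] = {}

    def slots_for(self, v: int) -> dict[str, tuple[int, int]]:
        if v in self._slot_cache:
            return self._slot_cache[v]
        slot_idx = {f: (2 * k, 2 * k + 1) for k, f in enumerate(self.founders)}
        slots: dict[str, tuple[int, int]] = dict(slot_idx)
        for j, nf in enumerate(self.nonfounders):
            ind = self.pedigree[nf]
            bp = (v >> (2 * j)) & 1
            bm = (v >> (2 * j + 1)) & 1
            slots[nf] = (slots[ind.father_id][bp], slots[ind.mother_id][bm])
        self._slot_cache[v] = slots
        return slots

    def marker_sum(self, v: int, gcodes: dict[str, int], p1: float) -> float:
        """Sum over founder allele configs consistent with observed genotypes.

        gcodes: individual id -> 0 (hom allele1), 1 (het), 2 (hom allele2);
        untyped individuals absent.
        """
        slots = self.slots_for(v)
        total = 0.0
        for cfg in itertools.product((0, 1), repeat=self.n_slots):
            ok = True
            for iid, g in gcodes.items():
                a = cfg[slots[iid][0]] + cfg[slots[iid][1]]
                if a != g:
                    ok = False
                    break
            if not ok:
                continue
            prob = 1.0
            for allele in cfg:
                prob *= p1 if allele == 0 else 1.0 - p1
            total += prob
        return total

    def pheno_sum(self, v: int, model: DiseaseModel) -> float:
        slots = self.slots_for(v)
        pen = model.penetrance
        total = 0.0
        for cfg in itertools.product((0, 1), repeat=self.n_slots):
            prob = 1.0
            for allele in cfg:
                prob *= model.q if allele == 1 else 1.0 - model.q
            for iid in self.ids:
                aff = self.pedigree[iid].affection
                if aff is Affection.UNKNOWN:
                    continue
                n = cfg[slots[iid][0]] + cfg[slots[iid][1]]
                f = pen[n]
                prob *= f if aff is Affection.AFFECTED else 1.0 - f
            total += prob
        return total


def oracle_multipoint_lod(
    pedigree: Pedigree,
    marker_gcodes: Sequence[dict[str, int]],
    marker_cm: Sequence[float],
    allele_freqs: Sequence[float],
    model: DiseaseModel,
) -> list[float]:
    """LOD at every marker by full joint enumeration of descent patterns."""
    enum = PedigreeEnumerator(pedigree)
    L = len(marker_gcodes)
    B = enum.n_bits
    V = 1 << B
    thetas = [_haldane(marker_cm[k + 1] - marker_cm[k]) for k in range(L - 1)]

    msum = [
        {v: enum.marker_sum(v, marker_gcodes[l], allele_freqs[l]) for v in range(V)}
        for l in range(L)
    ]
    psum = {v: enum.pheno_sum(v, model) for v in range(V)}
    p_phi = sum(psum.values()) / V

    # transition factor lookup by hamming distance
    def trans(theta: float, a: int, b: int) -> float:
        k = bin(a ^ b).count("1")
        return (theta**k) * ((1 - theta) ** (B - k))

    p_m = 0.0
    p_joint = [0.0] * L
    for pattern in itertools.product(range(V), repeat=L):
        prior = 1.0 / V
        for l in range(1, L):
            prior *= trans(thetas[l - 1], pattern[l - 1], pattern[l])
        like = prior
        for l in range(L):
            like *= msum[l][pattern[l]]
        p_m += like
        for x in range(L):
            p_joint[x] += like * psum[pattern[x]]

    return [math.log10(p_joint[x] / (p_m * p_phi)) for x in range(L)]


# ---------------------------------------------------------------------------
# Linear-scan region oracle
# ---------------------------------------------------------------------------

def region_scan_oracle(
    chroms: Sequence[str],
    bp: Sequence[int],
    lod: Sequence[float],
    threshold: float,
    merge_gap: int,
) -> list[tuple[str, int, int]]:
    """Independent region caller: literal linear scan with gap merging."""
    out: list[tuple[str, int, int]] = []
    i = 0
    n = len(lod)
    while i < n:
        if lod[i] < threshold:
            i += 1
            continue
        chrom = chroms[i]
        start = end = i
        j = i + 1
        gap = 0
        while j < n and chroms[j] == chrom:
            if lod[j] >= threshold:
                end = j
                gap = 0
            else:
                gap += 1
                if gap > merge_gap:
                    break
            j += 1
        out.append((chrom, bp[start], bp[end]))
        i = end + 1
    return out


# ---------------------------------------------------------------------------
# Restriction-site oracle (Biopython enzyme catalog)
# ---------------------------------------------------------------------------

def restriction_sites_oracle(sequence: str, enzyme_name: str) -> set[int]:
    """0-based start offsets of an enzyme's recognition footprint."""
    from Bio.Restriction import AllEnzymes
    from Bio.Seq import Seq

    enz = next(e for e in AllEnzymes if str(e) == enzyme_name)
    # Bio.Restriction.search returns 1-based cut positions; derive the
    # footprint start from the enzyme's cut offset within its site
    seq = Seq(sequence)
    sites = enz.search(seq)
    fst5 = enz.fst5  # cut position relative to site start
    return {p - 1 - fst5 for p in sites}
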