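"""Genetic map and SNP genotype containers, with PED/MAP I/O.

Genotypes are biallelic, coded per allele as 1/2 with 0 = missing, the most
widely parsed PED dialect (two allele columns per marker).  The genetic map
carries both physical (bp) and genetic (cM) marker positions; multipoint
transition probabilities use the cM coordinate through the Haldane map
function, region coordinates use bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class MapError(ValueError):
    pass


@dataclass
class GeneticMap:
    """Ordered marker positions: physical bp and genetic cM per chromosome."""

    marker_ids: list[str]
    chroms: list[str]
    bp: np.ndarray  # int64, 1-based
    cm: np.ndarray  # float64

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if not (len(self.chroms) == self.bp.size == self.cm.size == n):
            raise MapError("map columns have inconsistent lengths")
        if n == 0:
            raise MapError("empty genetic map")
        if len(set(self.marker_ids)) != n:
            raise MapError("duplicate marker ids in map")
        for chrom in dict.fromkeys(self.chroms):
            idx = self.indices_for(chrom)
            if np.any(np.diff(self.bp[idx]) <= 0):
                raise MapError(f"{chrom}: physical positions not strictly increasing")
            if np.any(np.diff(self.cm[idx]) < 0):
                raise MapError(f"{chrom}: genetic positions decrease along chromosome")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chroms))

    def indices_for(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chroms, dtype=object) == chrom)

    def subset(self, indices: Sequence[int]) -> "GeneticMap":
        idx = np.asarray(indices, dtype=np.int64)
        return GeneticMap(
            [self.marker_ids[i] for i in idx],
            [self.chroms[i] for i in idx],
            self.bp[idx],
            self.cm[idx],
        )


@dataclass
class GenotypeMatrix:
    """Biallelic calls for a set of individuals, aligned to a GeneticMap.

    ``alleles`` has shape (n_markers, n_individuals, 2) with values in
    {0, 1, 2}; 0 is missing.  Both alleles of an individual are missing or
    neither is.
    """

    sample_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (markers, individuals, 2)")
        if self.alleles.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match allele matrix")
        miss = self.alleles == 0
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing genotypes are not supported")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.alleles[:, self.sample_ids.index(sample_id), :]

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.alleles[np.asarray(indices)])

    def het_counts(self) -> np.ndarray:
        """Per marker, the number of individuals called heterozygous."""
        called = self.alleles[..., 0] != 0
        het = self.alleles[..., 0] != self.alleles[..., 1]
        return (called & het).sum(axis=1)


# ---------------------------------------------------------------------------
# MAP / PED-genotype I/O
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path: str | Path) -> None:
    """PLINK-style MAP: chrom, marker id, genetic position (cM), bp."""
    lines = [
        f"{gmap.chroms[i]}\t{gmap.marker_ids[i]}\t{gmap.cm[i]:.6f}\t{gmap.bp[i]}"
        for i in range(len(gmap))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_map(path: str | Path) -> GeneticMap:
    ids: list[str] = []
    chroms: list[str] = []
    bp: list[int] = []
    cm: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 4:
            raise MapError(f"line {lineno}: expected 4 MAP columns")
        chroms.append(fields[0])
        ids.append(fields[1])
        cm.append(float(fields[2]))
        bp.append(int(fields[3]))
    return GeneticMap(ids, chroms, np.array(bp), np.array(cm))


def write_genotypes_ped(
    path: str | Path,
    family_id: str,
    rows: Sequence[tuple[str, str, str, str, str]],
    genotypes: GenotypeMatrix,
) -> None:
    """Write a standard 6-column + two-alleles-per-marker PED file.

    ``rows`` supplies (individual, father, mother, sex_code, affection_code)
    in the same order as ``genotypes.sample_ids``.
    """
    if len(rows) != genotypes.n_samples:
        raise ValueError("rows and genotype columns differ in length")
    out = []
    for j, (iid, fid, mid, sex, aff) in enumerate(rows):
        geno = genotypes.alleles[:, j, :].reshape(-1)
        out.append(
            "\t".join([family_id, iid, fid, mid, sex, aff] + [str(a) for a in geno])
        )
    Path(path).write_text("\n".join(out) + "\n")


def read_genotypes_ped(path: str | Path, n_markers: int) -> tuple[list[str], GenotypeMatrix]:
    """Read genotype columns from a PED file; returns sample ids + matrix."""
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_markers:
            raise ValueError(
                f"line {lineno}: expected {6 + 2 * n_markers} columns, got {len(fields)}"
            )
        sample_ids.append(fields[1])
        geno = np.array(fields[6:], dtype=np.int8).reshape(n_markers, 2)
        cols.append(geno)
    alleles = np.stack(cols, axis=1)
    return sample_ids, GenotypeMatrix(sample_ids, alleles)
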