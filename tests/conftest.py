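import numpy as np
import pytest

from linkmend.disease import DiseaseModel
from linkmend.markers import GeneticMap, GenotypeMatrix
from linkmend.pedigree import Affection, Individual, Pedigree, Sex
from linkmend.simulate import (
    CohortConfig,
    GenomeLayout,
    VariantCounts,
    build_cohort,
    make_pedigree_fixture,
)


def individual(iid, fa, mo, sex, aff, genotyped=True):
    return Individual(
        iid,
        fa,
        mo,
        Sex.MALE if sex == "M" else Sex.FEMALE,
        {
            True: Affection.AFFECTED,
            False: Affection.UNAFFECTED,
            None: Affection.UNKNOWN,
        }[aff],
        genotyped,
    )


def genotype_matrix(pedigree, marker_dicts):
    """Build a GenotypeMatrix from per-marker {id: code} dicts.

    Codes: 0 = hom allele1, 1 = het, 2 = hom allele2; absent = missing.
    """
    ids = [i.id for i in pedigree.individuals]
    alleles = np.zeros((len(marker_dicts), len(ids), 2), dtype=np.int8)
    for m, gd in enumerate(marker_dicts):
        for j, iid in enumerate(ids):
            if iid in gd:
                g = gd[iid]
                alleles[m, j] = [1, 1] if g == 0 else ([1, 2] if g == 1 else [2, 2])
    return GenotypeMatrix(ids, alleles)


def uniform_map(n_markers, chrom="chr1", spacing_cm=10.0, start_bp=1_000_000):
    return GeneticMap(
        [f"m{k}" for k in range(n_markers)],
        [chrom] * n_markers,
        np.arange(n_markers) * 1_000_000 + start_bp,
        np.arange(n_markers) * spacing_cm,
    )


SMALL_GENOME = GenomeLayout(
    chrom_lengths=tuple((f"chr{i + 1}", 40_000_000) for i in range(4)),
    cm_per_mb=1.2,
)

SMALL_CONFIG = CohortConfig(
    genome=SMALL_GENOME,
    markers_per_cm=15.0,
    n_genes=30,
    region_mb=8.0,
    counts=VariantCounts(
        n_catalog=60,
        n_catalog_extra=60,
        n_control_shared=40,
        n_private_benign=40,
        n_stop_gained=6,
        n_frameshift=12,
    ),
)


@pytest.fixture(scope="session")
def small_cohort():
    """A down-scaled synthetic cohort shared by fast unit tests."""
    return build_cohort(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def pedigree1():
    return make_pedigree_fixture("pedigree1_like")


@pytest.fixture(scope="session")
def pedigree2():
    return make_pedigree_fixture("pedigree2_like")
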