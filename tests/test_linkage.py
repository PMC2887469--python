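"""Linkage engine tests: oracle equivalence, selection rules, region calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkmend.disease import DiseaseModel
from linkmend.linkage import (
    LinkageError,
    LodCurve,
    SnpSelectionRule,
    affected_sharing_scan,
    call_candidate_regions,
    compute_multipoint_lod,
    marker_sharing,
    select_linkage_snps,
)
from linkmend.markers import GeneticMap, GenotypeMatrix
from linkmend.pedigree import Affection, Pedigree
from linkmend.simulate import make_pedigree_fixture
from tests.conftest import genotype_matrix, individual, uniform_map
from tests.oracles import oracle_multipoint_lod

REDUCED = DiseaseModel(q=1e-4, f0=0.0, f1=0.8, f2=0.8)
FULL = DiseaseModel(q=1e-8, f0=0.0, f1=1.0, f2=1.0)


def lod_for(ped, gdicts, cms, freqs, model):
    gm = genotype_matrix(ped, gdicts)
    gmap = GeneticMap(
        [f"m{k}" for k in range(len(gdicts))],
        ["chr1"] * len(gdicts),
        np.arange(len(gdicts)) * 1_000_000 + 1_000_000,
        np.array(cms, dtype=float),
    )
    return compute_multipoint_lod(ped, gm, gmap, model, allele_freqs=np.array(freqs))


def nuclear_with(aff):
    ped = make_pedigree_fixture(f"nuclear({len(aff) - 2})")
    labels = {
        iid: (Affection.AFFECTED if a else Affection.UNAFFECTED)
        for iid, a in aff.items()
    }
    return ped.with_affection(labels)


def three_generation():
    rows = [
        individual("GF", None, None, "M", True),
        individual("GM", None, None, "F", False),
        individual("FA", "GF", "GM", "M", True),
        individual("MO", None, None, "F", False),
        individual("C1", "FA", "MO", "F", True),
    ]
    return Pedigree(rows)


def phase_known_family(n_children, n_affected):
    rows = [
        individual("GF", None, None, "M", True),
        individual("GM", None, None, "F", False),
        individual("FA", "GF", "GM", "M", True),
        individual("MO", None, None, "F", False),
    ]
    for k in range(1, n_children + 1):
        rows.append(individual(f"C{k}", "FA", "MO", "M", k <= n_affected))
    return Pedigree(rows)


class TestOracleEquivalence:
    """Multipoint LOD equals exhaustive descent/founder-config enumeration."""

    CASES = [
        # (pedigree builder, genotype dicts, cM positions, allele freqs, model)
        (
            lambda: nuclear_with({"FA": 1, "MO": 0, "C1": 1, "C2": 1, "C3": 0}),
            [
                {"FA": 1, "MO": 2, "C1": 1, "C2": 1, "C3": 2},
                {"FA": 1, "MO": 1, "C1": 1, "C2": 0, "C3": 2},
            ],
            [0.0, 10.0],
            [0.3, 0.5],
            REDUCED,
        ),
        (
            lambda: nuclear_with({"FA": 1, "MO": 0, "C1": 1, "C2": 1, "C3": 0}),
            [
                {"FA": 1, "MO": 2, "C1": 1, "C2": 1, "C3": 2},
                {"FA": 2, "C1": 1},
                {"FA": 1, "MO": 1, "C2": 0, "C3": 2},
            ],
            [0.0, 5.0, 30.0],
            [0.3, 0.7, 0.5],
            REDUCED,
        ),
        (
            three_generation,
            [
                {"GF": 1, "GM": 2, "FA": 1, "MO": 2, "C1": 1},
                {"GF": 0, "GM": 2, "FA": 1, "MO": 2, "C1": 1},
                {"GM": 1, "FA": 0, "C1": 0},
            ],
            [0.0, 2.0, 12.0],
            [0.4, 0.3, 0.6],
            REDUCED,
        ),
        (
            lambda: phase_known_family(4, 2),
            [{"GF": 0, "GM": 2, "FA": 1, "MO": 2, "C1": 1, "C2": 1, "C3": 2, "C4": 2}],
            [0.0],
            [0.4],
            FULL,
        ),
    ]

    @pytest.mark.parametrize("case", range(len(CASES)))
    def test_lod_matches_enumeration(self, case):
        build, gdicts, cms, freqs, model = self.CASES[case]
        ped = build()
        curve = lod_for(ped, gdicts, cms, freqs, model)
        oracle = oracle_multipoint_lod(ped, gdicts, cms, freqs, model)
        assert np.abs(curve.lod - np.array(oracle)).max() < 1e-6


class TestClosedFormLod:
    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_phase_known_cosegregation_gives_m_log10_2(self, m):
        """m informative meioses, phase known via grandparents, full
        penetrance: the co-segregating marker's LOD is m*log10(2)."""
        ped = phase_known_family(m, max(1, m - 2))
        g = {"GF": 0, "GM": 2, "FA": 1, "MO": 2}
        for k in range(1, m + 1):
            g[f"C{k}"] = 1 if k <= max(1, m - 2) else 2
        curve = lod_for(ped, [g], [0.0], [0.4], FULL)
        assert curve.lod[0] == pytest.approx(m * math.log10(2), abs=1e-6)

    def test_upper_bound_never_exceeded_nearby(self):
        """LOD <= m*log10(2) with m informative meioses, equality at co-seg."""
        m = 5
        ped = phase_known_family(m, 3)
        g = {"GF": 0, "GM": 2, "FA": 1, "MO": 2}
        for k in range(1, m + 1):
            g[f"C{k}"] = 1 if k <= 3 else 2
        partial = dict(g)
        partial.pop("C5")  # less data can only lower the bound
        curve = lod_for(ped, [g, partial], [0.0, 8.0], [0.4, 0.4], FULL)
        assert np.all(curve.lod <= m * math.log10(2) + 1e-9)

    def test_removing_genotypes_never_raises_cosegregating_lod(self):
        m = 4
        ped = phase_known_family(m, 2)
        g = {"GF": 0, "GM": 2, "FA": 1, "MO": 2, "C1": 1, "C2": 1, "C3": 2, "C4": 2}
        full = lod_for(ped, [g], [0.0], [0.4], FULL).lod[0]
        for drop in ("C1", "C4", "FA", "GF"):
            reduced_g = {k: v for k, v in g.items() if k != drop}
            reduced = lod_for(ped, [reduced_g], [0.0], [0.4], FULL).lod[0]
            assert abs(reduced) <= abs(full) + 1e-9

    def test_allele_relabeling_invariance(self):
        ped = nuclear_with({"FA": 1, "MO": 0, "C1": 1, "C2": 0})
        g = {"FA": 1, "MO": 2, "C1": 1, "C2": 2}
        swapped = {k: {0: 2, 1: 1, 2: 0}[v] for k, v in g.items()}
        a = lod_for(ped, [g], [0.0], [0.3], REDUCED).lod[0]
        b = lod_for(ped, [swapped], [0.0], [0.7], REDUCED).lod[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_missing_genotypes_give_zero_lod(self):
        ped = nuclear_with({"FA": 1, "MO": 0, "C1": 1, "C2": 0})
        curve = lod_for(ped, [{}, {}], [0.0, 10.0], [0.5, 0.5], REDUCED)
        assert np.allclose(curve.lod, 0.0)

    def test_mendelian_inconsistent_marker_dropped(self):
        ped = nuclear_with({"FA": 1, "MO": 0, "C1": 1, "C2": 0})
        # child hom 1/1 with both parents hom 2/2 is impossible
        bad = {"FA": 2, "MO": 2, "C1": 0}
        curve = lod_for(ped, [bad], [0.0], [0.5], REDUCED)
        assert curve.dropped_markers == ["m0"]
        assert curve.lod[0] == 0.0


class TestSnpSelection:
    def _geno(self, het_counts, n_ind=12):
        """One marker per requested het count."""
        alleles = np.ones((len(het_counts), n_ind, 2), dtype=np.int8)
        for m, h in enumerate(het_counts):
            for j in range(h):
                alleles[m, j] = [1, 2]
        return GenotypeMatrix([f"I{j}" for j in range(n_ind)], alleles)

    def test_heterozygosity_boundary(self):
        geno = self._geno([3, 4, 5])
        gmap = uniform_map(3)
        keep = select_linkage_snps(geno, gmap, SnpSelectionRule(4, 1.0))
        assert keep.tolist() == [1, 2]  # het-in-3 excluded, het-in-4 eligible

    def test_two_percent_of_ten_thousand_is_two_hundred(self):
        geno = self._geno([5] * 10_000)
        gmap = uniform_map(10_000, spacing_cm=0.35)
        keep = select_linkage_snps(geno, gmap, SnpSelectionRule(4, 0.02))
        assert keep.size == 200

    def test_no_eligible_marker_gives_empty_selection(self):
        geno = self._geno([0, 1])
        keep = select_linkage_snps(geno, uniform_map(2), SnpSelectionRule(4, 0.5))
        assert keep.size == 0

    def test_retained_markers_spread_over_chromosomes(self):
        alleles = np.ones((200, 12, 2), dtype=np.int8)
        alleles[:, :6] = [1, 2]
        geno = GenotypeMatrix([f"I{j}" for j in range(12)], alleles)
        gmap = GeneticMap(
            [f"m{k}" for k in range(200)],
            ["chr1"] * 100 + ["chr2"] * 100,
            np.tile(np.arange(100) * 1_000_000 + 1, 2),
            np.tile(np.arange(100) * 1.0, 2),
        )
        keep = select_linkage_snps(geno, gmap, SnpSelectionRule(4, 0.1))
        chroms = {gmap.chroms[i] for i in keep}
        assert chroms == {"chr1", "chr2"}
        assert keep.size == 20


def _curve(chroms, bp, lod):
    return LodCurve(
        [f"m{k}" for k in range(len(lod))],
        list(chroms),
        np.asarray(bp, dtype=np.int64),
        np.arange(len(lod), dtype=float),
        np.asarray(lod, dtype=float),
        REDUCED,
    )


class TestRegionCalling:
    def test_everywhere_negative_gives_no_regions(self):
        c = _curve(["chr1"] * 5, np.arange(5) * 10 + 10, [-1, -0.5, 0, -2, -1])
        assert call_candidate_regions(c, 1.0) == []

    def test_single_block_spans_qualifying_markers(self):
        c = _curve(["chr1"] * 5, [10, 20, 30, 40, 50], [0, 1.2, 1.5, 1.0, 0])
        [r] = call_candidate_regions(c, 1.0, extend_to_flanking=False)
        assert (r.interval.start, r.interval.end) == (20, 40)
        assert r.peak_lod == 1.5
        assert r.n_markers == 3

    def test_flanking_extension_reaches_neighbor_markers(self):
        c = _curve(["chr1"] * 5, [10, 20, 30, 40, 50], [0, 1.2, 1.5, 1.0, 0])
        [r] = call_candidate_regions(c, 1.0, extend_to_flanking=True)
        assert (r.interval.start, r.interval.end) == (10, 50)

    def test_threshold_tie_included(self):
        c = _curve(["chr1"] * 3, [10, 20, 30], [0.0, 1.8, 0.0])
        assert len(call_candidate_regions(c, 1.8)) == 1

    @given(
        lods=st.lists(
            st.floats(-3, 3, allow_nan=False), min_size=1, max_size=40
        ),
        threshold=st.floats(-1, 2.5),
        gap=st.integers(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_linear_scan_oracle(self, lods, threshold, gap):
        from tests.oracles import region_scan_oracle

        n = len(lods)
        chroms = ["chr1" if k < n // 2 else "chr2" for k in range(n)]
        bp = []
        counters = {}
        for c in chroms:
            counters[c] = counters.get(c, 0) + 1
            bp.append(counters[c] * 1000)
        c = _curve(chroms, bp, lods)
        got = [
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in call_candidate_regions(
                c, threshold, gap, extend_to_flanking=False
            )
        ]
        want = region_scan_oracle(chroms, bp, lods, threshold, gap)
        assert got == want


class TestSharingScan:
    def test_all_affected_het_share_allele(self, pedigree1):
        gdict = {
            i.id: (1 if i.affection is Affection.AFFECTED else 2)
            for i in pedigree1.individuals
        }
        gm = genotype_matrix(pedigree1, [gdict])
        regions = affected_sharing_scan(pedigree1, gm, uniform_map(1), 0)
        assert len(regions) == 1
        assert regions[0].n_tolerated_nonpenetrant == 0

    def test_single_exception_tolerated_and_reported(self, pedigree1):
        # affecteds hom for allele 1, unaffecteds hom for allele 2: the only
        # shareable allele is 1, and one affected is then made 2/2
        gdict = {
            i.id: (0 if i.affection is Affection.AFFECTED else 2)
            for i in pedigree1.individuals
        }
        gdict["IV-1"] = 2  # one affected without the shared allele
        gm = genotype_matrix(pedigree1, [gdict])
        assert affected_sharing_scan(pedigree1, gm, uniform_map(1), 0) == []
        [region] = affected_sharing_scan(pedigree1, gm, uniform_map(1), 1)
        assert region.n_tolerated_nonpenetrant == 1

    def test_unaffected_carrier_reported_as_nonpenetrant(self, pedigree1):
        gdict = {
            i.id: (1 if i.affection is Affection.AFFECTED else 2)
            for i in pedigree1.individuals
        }
        gdict["I-2"] = 1  # unaffected but carries the shared allele
        gm = genotype_matrix(pedigree1, [gdict])
        [region] = affected_sharing_scan(pedigree1, gm, uniform_map(1), 1)
        assert "I-2" in region.nonpenetrant_ids

    def test_fewer_than_two_affected_rejected(self):
        ped = nuclear_with({"FA": 1, "MO": 0, "C1": 0, "C2": 0})
        gm = genotype_matrix(ped, [{}])
        with pytest.raises(LinkageError):
            affected_sharing_scan(ped, gm, uniform_map(1))

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_marker_compatibility_matches_subset_oracle(self, data):
        n_aff = data.draw(st.integers(2, 6))
        genos = np.array(
            [
                data.draw(
                    st.sampled_from([(0, 0), (1, 1), (1, 2), (2, 2)])
                )
                for _ in range(n_aff)
            ],
            dtype=np.int8,
        )
        max_exc = data.draw(st.integers(0, 2))
        ok, allele, exc = marker_sharing(genos, max_exc)
        # oracle: exists an allele and an exception subset of size <= max_exc
        # such that every other typed affected carries the allele
        def oracle():
            idx = range(n_aff)
            for a in (1, 2):
                for k in range(max_exc + 1):
                    for sub in itertools.combinations(idx, k):
                        if all(
                            genos[i, 0] == 0 or a in genos[i] or i in sub
                            for i in idx
                        ):
                            return True
            return False

        assert ok == oracle()
        if ok:
            assert len(exc) <= max_exc
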