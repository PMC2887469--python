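"""Tests of the synthetic-cohort generator: gene drop, planting, variants."""

import numpy as np
import pytest

from linkmend.disease import DiseaseModel
from linkmend.intervals import GenomicInterval
from linkmend.linkage import haldane_theta
from linkmend.markers import GeneticMap
from linkmend.pedigree import Affection
from linkmend.simulate import (
    CATEGORY_CAUSAL,
    CATEGORY_DECOY,
    AscertainmentError,
    build_cohort,
    gene_drop,
    make_pedigree_fixture,
    mendelian_audit,
    plant_causal_variant,
    simulate_depth_profile,
    simulate_transcripts,
)
from linkmend.transcripts import validate_transcript
from linkmend.variants import left_align
from tests.conftest import SMALL_CONFIG, SMALL_GENOME, uniform_map
from tests.oracles import translate_oracle


class TestGeneDrop:
    def test_monomorphic_marker_all_homozygous(self, pedigree1):
        gmap = uniform_map(3)
        drop = gene_drop(pedigree1, gmap, np.array([1.0, 1.0, 1.0]), seed=3)
        assert (drop.genotypes.alleles == 1).all()

    def test_founder_allele_frequency_matches_binomial(self):
        ped = make_pedigree_fixture("nuclear(1)")
        gmap = uniform_map(2000, spacing_cm=0.05)
        freq = 0.3
        drop = gene_drop(ped, gmap, np.full(2000, freq), seed=4)
        founder_cols = [drop.genotypes.sample_ids.index(i) for i in ("FA", "MO")]
        alleles = drop.genotypes.alleles[:, founder_cols, :]
        n = alleles.size
        obs = (alleles == 1).mean()
        se = np.sqrt(freq * (1 - freq) / n)
        assert abs(obs - freq) < 3 * se

    def test_zero_distance_markers_never_recombine(self):
        """At theta = 0 (0 cM apart) no recombinant haplotypes over 10,000 meioses."""
        from linkmend.simulate import _meiosis_bit_chains, rng_for

        rng = rng_for(0, "theta0-check")
        bits = _meiosis_bit_chains(2, np.array([0.0]), 10_000, rng)
        assert (bits[0] == bits[1]).all()

    @pytest.mark.parametrize("d_cm", [5.0, 20.0, 50.0])
    def test_haldane_recombinant_fraction(self, d_cm):
        """Meiosis indicator flips between adjacent markers at Haldane theta(d)."""
        from linkmend.simulate import _meiosis_bit_chains, rng_for

        theta = haldane_theta(d_cm)
        rng = rng_for(int(d_cm), "theta-check")
        bits = _meiosis_bit_chains(2, np.array([theta]), 10_000, rng)
        obs = (bits[0] != bits[1]).mean()
        se = np.sqrt(theta * (1 - theta) / 10_000)
        assert abs(obs - theta) < 4 * se

    def test_gene_drop_is_mendelian_consistent(self, pedigree1):
        gmap = uniform_map(200, spacing_cm=1.0)
        rng = np.random.default_rng(9)
        freqs = rng.uniform(0.2, 0.8, 200)
        drop = gene_drop(pedigree1, gmap, freqs, seed=10)
        assert mendelian_audit(pedigree1, drop.genotypes).size == 0

    def test_empty_map_rejected(self, pedigree1):
        with pytest.raises(Exception):
            gene_drop(pedigree1, None, np.array([]), seed=0)


class TestPlanting:
    def _setup(self):
        ped = make_pedigree_fixture("pedigree1_like")
        gmap = uniform_map(40, spacing_cm=2.0)
        region = GenomicInterval("chr1", 5_000_000, 20_000_000)
        return ped, gmap, region

    def test_full_penetrance_affected_equals_carriers(self):
        ped, gmap, region = self._setup()
        model = DiseaseModel(q=1e-4, f0=0.0, f1=1.0, f2=1.0)
        plant = plant_causal_variant(ped, gmap, region, model, seed=1)
        affected = {
            iid for iid, a in plant.phenotypes.items() if a is Affection.AFFECTED
        }
        assert affected == plant.carrier_ids

    def test_zero_penetrance_no_affected_carriers(self):
        ped, gmap, region = self._setup()
        model = DiseaseModel(q=1e-4, f0=0.0, f1=1e-12, f2=1e-12)
        plant = plant_causal_variant(ped, gmap, region, model, seed=2)
        affected = {
            iid for iid, a in plant.phenotypes.items() if a is Affection.AFFECTED
        }
        assert not affected

    def test_penetrance_sampling_fraction(self):
        """Across many unascertained plantings, carriers are affected at f1.

        With f1 = 0.8, the affected fraction over ~10,000 carriers must sit
        within 3 standard errors of 0.8 (half-width 0.012).
        """
        ped, gmap, region = self._setup()
        model = DiseaseModel(q=1e-4, f0=0.0, f1=0.8, f2=0.8)
        carriers = affected = 0
        seed = 0
        while carriers < 10_000:
            plant = plant_causal_variant(
                ped, gmap, region, model, seed=seed, min_affected=None
            )
            carriers += len(plant.carrier_ids)
            affected += sum(
                1
                for iid in plant.carrier_ids
                if plant.phenotypes[iid] is Affection.AFFECTED
            )
            seed += 1
        frac = affected / carriers
        assert abs(frac - 0.8) < 0.012

    def test_ascertainment_reaches_requested_load(self):
        ped, gmap, region = self._setup()
        model = DiseaseModel()
        plant = plant_causal_variant(
            ped, gmap, region, model, seed=3, min_affected=7
        )
        n_aff = sum(
            1 for a in plant.phenotypes.values() if a is Affection.AFFECTED
        )
        assert n_aff >= 7
        # all affecteds are carriers (no phenocopies at f0 = 0)
        for iid, a in plant.phenotypes.items():
            if a is Affection.AFFECTED:
                assert iid in plant.carrier_ids

    def test_region_off_map_rejected(self):
        ped, gmap, _ = self._setup()
        with pytest.raises(ValueError):
            plant_causal_variant(
                ped, gmap, GenomicInterval("chr9", 1, 100), DiseaseModel(), seed=0
            )

    def test_impossible_ascertainment_raises(self):
        ped, gmap, region = self._setup()
        with pytest.raises(AscertainmentError):
            plant_causal_variant(
                ped, gmap, region, DiseaseModel(), seed=0,
                min_affected=13, max_tries=50,
            )


class TestTranscripts:
    def test_simulated_orfs_are_valid_and_translate(self):
        transcripts, ref = simulate_transcripts(12, SMALL_GENOME, seed=21)
        assert len(transcripts) == 12
        strands = {t.strand for t in transcripts}
        assert strands == {"+", "-"}
        for t in transcripts:
            assert len(t.exons) >= 2
            assert t.cds_length % 3 == 0
            validate_transcript(t, ref)  # ATG ... stop, no internal stop
            cds = t.spliced_cds(ref)
            protein = translate_oracle(cds)
            assert len(protein) == len(cds) // 3 - 1
            assert protein[0] == "M"

    def test_cds_coordinate_round_trip(self):
        transcripts, ref = simulate_transcripts(4, SMALL_GENOME, seed=22)
        for t in transcripts:
            for cpos in (1, 2, 3, t.cds_length // 2, t.cds_length):
                g = t.cds_to_genomic(cpos)
                assert t.genomic_to_cds(g) == cpos


class TestVariantSets:
    def test_truth_categories_partition_proband_set(self, small_cohort):
        vs = small_cohort.variant_sets
        ref = small_cohort.reference
        keys = {left_align(v, ref).key for v in vs.proband}
        assert keys == set(vs.categories)
        counts = small_cohort.config.counts
        expected = (
            1
            + counts.n_stop_gained
            + counts.n_frameshift
            - 1
            + counts.n_private_benign
            + counts.n_catalog
            + counts.n_control_shared
        )
        assert len(vs.proband) == expected

    def test_catalog_members_appear_in_proband_normalized(self, small_cohort):
        vs = small_cohort.variant_sets
        ref = small_cohort.reference
        proband_keys = {left_align(v, ref).key for v in vs.proband}
        n_shared = sum(
            1 for v in vs.catalog if left_align(v, ref).key in proband_keys
        )
        assert n_shared == small_cohort.config.counts.n_catalog

    def test_exactly_one_causal_inside_planted_region(self, small_cohort):
        vs = small_cohort.variant_sets
        truth = small_cohort.truth
        truncating_in_region = [
            key
            for key, label in vs.categories.items()
            if label in (CATEGORY_CAUSAL, CATEGORY_DECOY)
            and truth.planted_region.contains(key[0], key[1])
        ]
        assert truncating_in_region == [
            left_align(truth.causal_variant, small_cohort.reference).key
        ]

    def test_causal_is_eleven_bp_frameshift(self, small_cohort):
        causal = small_cohort.truth.causal_variant
        assert len(causal.ref) - len(causal.alt) == 11

    def test_default_truncating_total_is_109(self):
        from linkmend.simulate import VariantCounts

        c = VariantCounts()
        assert c.n_stop_gained + c.n_frameshift == 109
        assert c.n_stop_gained == 19


class TestDepth:
    def test_poisson_mean_within_one_percent(self):
        region = GenomicInterval("chr1", 1, 100_000)
        df = simulate_depth_profile(region, 31.8, seed=7, unmappable_fraction=0.0)
        assert abs(df["reads"].mean() - 31.8) / 31.8 < 0.01

    def test_poisson_variance_close_to_mean(self):
        region = GenomicInterval("chr1", 1, 100_000)
        df = simulate_depth_profile(region, 31.8, seed=8, unmappable_fraction=0.0)
        assert abs(df["reads"].var() / df["reads"].mean() - 1.0) < 0.05

    def test_vanishing_depth_leaves_bases_uncovered(self):
        from linkmend.validate import CoverageRule, coverage_assess

        region = GenomicInterval("chr1", 1, 20_000)
        df = simulate_depth_profile(region, 1e-4, seed=9)
        report = coverage_assess(df, CoverageRule())
        assert report.fraction_covered < 0.001

    def test_scores_positive_where_covered(self):
        region = GenomicInterval("chr1", 1, 50_000)
        df = simulate_depth_profile(region, 31.8, seed=10, score_zero_fraction=0.0)
        covered = df[df["reads"] >= 1]
        assert (covered["consensus_score"] > 0).all()


class TestCohort:
    def test_affecteds_are_carriers_and_load_meets_ascertainment(self, small_cohort):
        truth = small_cohort.truth
        ped = small_cohort.pedigree
        affected = {i.id for i in ped.affected}
        assert affected <= truth.carrier_ids
        assert len(affected) >= small_cohort.config.min_affected

    def test_cohort_genotypes_pass_mendelian_audit(self, small_cohort):
        assert (
            mendelian_audit(small_cohort.pedigree, small_cohort.genotypes).size == 0
        )

    def test_conditional_drop_anchors_descent_at_causal_locus(self):
        """A marker colocated with the planted locus (theta = 0) must be
        transmitted exactly along the planted descent bits."""
        ped = make_pedigree_fixture("nuclear(4)")
        causal_bp = 10_000_000
        gmap = GeneticMap(
            ["m0", "m1"],
            ["chr1", "chr1"],
            np.array([causal_bp, 20_000_000]),
            np.array([12.0, 24.0]),
        )
        region = GenomicInterval("chr1", causal_bp, causal_bp)
        plant = plant_causal_variant(
            ped, gmap, region, DiseaseModel(), seed=5, causal_bp=causal_bp
        )
        drop = gene_drop(
            ped, gmap, np.full(2, 0.5), seed=5, condition_on=plant.descent
        )
        ids = drop.genotypes.sample_ids
        fa, mo = ids.index("FA"), ids.index("MO")
        for child, (bp_bit, bm_bit) in plant.descent.meiosis_bits.items():
            c = ids.index(child)
            want_p = drop.paternal[0, fa] if bp_bit == 0 else drop.maternal[0, fa]
            want_m = drop.paternal[0, mo] if bm_bit == 0 else drop.maternal[0, mo]
            assert drop.paternal[0, c] == want_p
            assert drop.maternal[0, c] == want_m
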