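"""Segregation, RFLP, control-screen and coverage tests."""

import numpy as np
import pandas as pd
import pytest

from linkmend.annotate import Annotator
from linkmend.disease import DiseaseModel
from linkmend.intervals import GenomicInterval
from linkmend.markers import GeneticMap
from linkmend.pedigree import Affection
from linkmend.simulate import (
    make_nonsense_demo,
    make_pedigree_fixture,
    plant_causal_variant,
    simulate_depth_profile,
)
from linkmend.validate import (
    CARRIER,
    ENZYME_LIBRARY,
    MISSING,
    NON_CARRIER,
    CoverageRule,
    RestrictionEnzyme,
    ValidationError,
    control_cohort_screen,
    cosegregation_test,
    coverage_assess,
    find_sites,
    restriction_site_diff,
)
from linkmend.variants import Variant
from tests.conftest import uniform_map
from tests.oracles import restriction_sites_oracle


class TestCosegregation:
    def test_nonpenetrant_carriers_reported_not_incompatible(self, pedigree2):
        calls = {i.id: NON_CARRIER for i in pedigree2.individuals}
        for iid in ("I-1", "II-2", "II-4", "III-1", "III-3"):
            calls[iid] = CARRIER
        verdict = cosegregation_test(pedigree2, calls)
        assert verdict.compatible
        assert verdict.nonpenetrant_carriers == ["II-2", "II-4"]
        assert verdict.incompatible_individuals == []

    def test_affected_noncarrier_is_incompatible(self, pedigree1):
        calls = {
            i.id: (CARRIER if i.affection is Affection.AFFECTED else NON_CARRIER)
            for i in pedigree1.individuals
        }
        calls["IV-1"] = NON_CARRIER  # affected without the variant
        verdict = cosegregation_test(pedigree1, calls)
        assert not verdict.compatible
        assert "IV-1" in verdict.incompatible_individuals

    def test_allow_phenocopies_tolerates_affected_noncarrier(self, pedigree1):
        calls = {
            i.id: (CARRIER if i.affection is Affection.AFFECTED else NON_CARRIER)
            for i in pedigree1.individuals
        }
        calls["IV-1"] = NON_CARRIER
        assert cosegregation_test(pedigree1, calls, allow_phenocopies=True).compatible

    def test_carrier_with_both_parents_noncarrier_violates_transmission(
        self, pedigree1
    ):
        calls = {i.id: NON_CARRIER for i in pedigree1.individuals}
        calls["IV-1"] = CARRIER  # both parents called non-carrier
        verdict = cosegregation_test(
            pedigree1.with_affection(
                {i.id: Affection.UNAFFECTED for i in pedigree1.individuals}
            ),
            calls,
        )
        assert "IV-1" in verdict.incompatible_individuals

    def test_untyped_parent_allows_obligate_path(self, pedigree1):
        calls = {i.id: NON_CARRIER for i in pedigree1.individuals}
        calls["IV-1"] = CARRIER
        calls["III-1"] = MISSING
        ped = pedigree1.with_affection(
            {"IV-1": Affection.AFFECTED}
            | {
                i.id: Affection.UNAFFECTED
                for i in pedigree1.individuals
                if i.id != "IV-1"
            }
        )
        assert cosegregation_test(ped, calls).compatible

    def test_unknown_individual_rejected(self, pedigree1):
        with pytest.raises(ValidationError):
            cosegregation_test(pedigree1, {"GHOST": CARRIER})

    def test_verdict_invariant_to_member_order(self, pedigree2):
        calls = {i.id: NON_CARRIER for i in pedigree2.individuals}
        for iid in ("I-1", "II-2", "III-1"):
            calls[iid] = CARRIER
        from linkmend.pedigree import Pedigree

        reordered = Pedigree(
            list(reversed(pedigree2.individuals)), pedigree2.family_id
        )
        a = cosegregation_test(pedigree2, calls)
        b = cosegregation_test(reordered, calls)
        assert (a.compatible, a.nonpenetrant_carriers, a.incompatible_individuals) == (
            b.compatible, b.nonpenetrant_carriers, b.incompatible_individuals
        )

    def test_truth_audit_over_many_plantings(self, pedigree1):
        """Carrier truth from the generator is always compatible and its
        non-penetrant carriers are recovered exactly."""
        gmap = uniform_map(30, spacing_cm=3.0)
        region = GenomicInterval("chr1", 2_000_000, 25_000_000)
        model = DiseaseModel()
        for seed in range(100):
            plant = plant_causal_variant(
                pedigree1, gmap, region, model, seed=seed, min_affected=None
            )
            ped = pedigree1.with_affection(plant.phenotypes)
            calls = {
                i.id: (CARRIER if i.id in plant.carrier_ids else NON_CARRIER)
                for i in ped.individuals
            }
            verdict = cosegregation_test(ped, calls)
            assert verdict.compatible
            assert set(verdict.nonpenetrant_carriers) == plant.nonpenetrant_ids


class TestRestriction:
    def test_rsai_site_lost_by_c_to_t(self):
        # offsets:  0123456789
        window = "AAGTACCTTAGG"  # GTAC footprint at offset 2, its C at offset 5
        v = Variant("chr9", 1006, "C", "T")  # 4th base of the GTAC site
        [diff] = restriction_site_diff(window, 1001, v, [ENZYME_LIBRARY["RsaI"]])
        assert diff.lost == [2]
        assert diff.gained == []

    def test_variant_outside_all_sites_changes_nothing(self):
        window = "AAGTACCTTAGG"
        v = Variant("chr9", 1010, "A", "C")
        [diff] = restriction_site_diff(window, 1001, v, [ENZYME_LIBRARY["RsaI"]])
        assert diff.lost == [] and diff.gained == []

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            restriction_site_diff(
                "AAGTACC", 1001, Variant("chr9", 1003, "C", "T"), [ENZYME_LIBRARY["RsaI"]]
            )

    def test_nonsense_demo_abolishes_rsai(self):
        t, ref, v = make_nonsense_demo()
        window = ref.window_containing(v.chrom, v.pos)
        seq = ref.fetch(v.chrom, window.start, window.end)
        [diff] = restriction_site_diff(seq, window.start, v, [ENZYME_LIBRARY["RsaI"]])
        assert len(diff.lost) >= 1 and (v.pos - window.start - 3) in diff.lost

    @pytest.mark.parametrize("enzyme", ["RsaI", "EcoRI", "AluI", "TaqI"])
    def test_site_scan_matches_biopython_catalog(self, enzyme):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
            got = {p for p, _ in find_sites(seq, ENZYME_LIBRARY[enzyme])}
            assert got == restriction_sites_oracle(seq, enzyme)

    def test_palindromic_enzymes_symmetric_between_strands(self):
        rng = np.random.default_rng(19)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        for enz in ENZYME_LIBRARY.values():
            if not enz.is_palindromic:
                continue
            hits = find_sites(seq, enz)
            plus = {p for p, s in hits if s == "+"}
            minus = {p for p, s in hits if s == "-"}
            assert plus == minus

    def test_apply_then_revert_restores_sites(self):
        window = "AAGTACCTTAGGGTAC"
        mutated = window[:5] + "T" + window[6:]  # destroy the first GTAC
        inverse = Variant("chr9", 1006, "T", "C")
        before = {p for p, _ in find_sites(window, ENZYME_LIBRARY["RsaI"])}
        [diff_back] = restriction_site_diff(
            mutated, 1001, inverse, [ENZYME_LIBRARY["RsaI"]]
        )
        restored = {
            p for p, _ in find_sites(window, ENZYME_LIBRARY["RsaI"])
        }
        assert restored == before
        assert diff_back.gained == [2]

    def test_short_recognition_rejected(self):
        with pytest.raises(ValidationError):
            RestrictionEnzyme("Bad", "GTA")


class TestControlScreen:
    def test_clean_469_controls_count_zero(self):
        t, ref, v = make_nonsense_demo()
        ann = Annotator([t], ref)
        region = t.span
        rng = np.random.default_rng(23)
        controls = []
        for _ in range(469):
            person = []
            if rng.random() < 0.3:  # some controls carry a benign SNV
                cpos = int(rng.integers(4, 100))
                gpos = t.cds_to_genomic(cpos)
                refb = ref.fetch(t.chrom, gpos, gpos)
                altb = {"A": "G", "G": "A", "C": "A", "T": "C"}[refb]
                cand = Variant(t.chrom, gpos, refb, altb)
                if not ann.most_severe(cand).truncating:
                    person.append((cand, 1))
            controls.append(person)
        assert control_cohort_screen(controls, region, ann) == 0

    def test_single_planted_stop_counts_one(self):
        t, ref, v = make_nonsense_demo()
        ann = Annotator([t], ref)
        controls = [[] for _ in range(10)]
        controls[4] = [(v, 1)]
        assert control_cohort_screen(controls, t.span, ann) == 1

    def test_region_without_transcripts_rejected(self):
        t, ref, _ = make_nonsense_demo()
        ann = Annotator([t], ref)
        with pytest.raises(ValidationError):
            control_cohort_screen([], GenomicInterval("chr1", 1, 10), ann)


class TestCoverage:
    def _profile(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "reads", "consensus_score"]
        )

    def test_covered_base_rule_boundaries(self):
        df = self._profile(
            [
                ("chr1", 1, 5, 1),  # covered: exactly 5 reads, positive score
                ("chr1", 2, 4, 50),  # not covered: 4 reads
                ("chr1", 3, 5, 0),  # not covered: score not > 0
                ("chr1", 4, 100, 1),  # covered
            ]
        )
        report = coverage_assess(df, CoverageRule())
        assert report.fraction_covered == pytest.approx(0.5)

    def test_fraction_matches_counting_oracle_on_poisson_profile(self):
        region = GenomicInterval("chr1", 1, 100_000)
        df = simulate_depth_profile(region, 31.8, seed=3)
        rule = CoverageRule()
        report = coverage_assess(df, rule)
        oracle = sum(
            1
            for r, s in zip(df["reads"], df["consensus_score"])
            if r >= rule.min_reads and s > rule.min_consensus_score
        ) / len(df)
        assert report.fraction_covered == pytest.approx(oracle)

    def test_monotone_in_min_reads_and_cutoff(self):
        region = GenomicInterval("chr1", 1, 30_000)
        df = simulate_depth_profile(region, 20.0, seed=4)
        fracs = [
            coverage_assess(df, CoverageRule(min_reads=k)).fraction_covered
            for k in (1, 5, 10, 20)
        ]
        assert fracs == sorted(fracs, reverse=True)
        sub = [
            coverage_assess(df, regions=[region], depth_cutoff=k).per_region[
                f"{region.chrom}:{region.start}-{region.end}"
            ]
            for k in (0, 10, 25)
        ]
        assert sub == sorted(sub, reverse=True)

    def test_depth_cutoff_is_exclusive(self):
        df = self._profile([("chr1", 1, 10, 5), ("chr1", 2, 11, 5)])
        region = GenomicInterval("chr1", 1, 2)
        report = coverage_assess(df, regions=[region], depth_cutoff=10)
        assert report.per_region["chr1:1-2"] == pytest.approx(0.5)

    def test_unsorted_profile_rejected(self):
        df = self._profile([("chr1", 5, 1, 1), ("chr1", 3, 1, 1)])
        with pytest.raises(ValidationError):
            coverage_assess(df)
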