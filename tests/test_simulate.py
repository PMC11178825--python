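import math

import numpy as np
import pytest

from bequant.offtarget import count_mismatches
from bequant.simulate import (BackgroundModel, EditingProfile, make_target_site,
                              make_toy_genome, plant_candidate_sites,
                              simulate_amplicon_reads, simulate_plant_cohort)
from bequant.sites import locate_protospacer, revcomp
from bequant.variants import call_zygosity


class TestMakeTargetSite:
    def test_deterministic_and_unique_protospacer(self):
        a = make_target_site(seed=1)
        b = make_target_site(seed=1)
        assert a.amplicon == b.amplicon and len(a.amplicon) == 250
        assert locate_protospacer(a.amplicon, a.protospacer) == (a.offset, a.strand)

    def test_different_seeds_differ(self):
        assert make_target_site(seed=1).amplicon != make_target_site(seed=2).amplicon

    def test_minimum_length_accounting(self):
        site = make_target_site(seed=3, amplicon_length=40)
        assert len(site.amplicon) == 40
        lo, hi = site.footprint
        assert hi - lo == 23 and 0 <= lo and hi <= 40

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            make_target_site(seed=1, amplicon_length=39)


class TestEditingProfile:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            EditingProfile(c_to_t={21: 0.1})
        with pytest.raises(ValueError):
            EditingProfile(c_to_t={5: 1.5})

    def test_rejects_summed_conversions_above_one(self):
        with pytest.raises(ValueError):
            EditingProfile(c_to_t={5: 0.7}, c_to_g={5: 0.5})

    def test_rejects_probability_on_wrong_base(self, hand_site):
        # position 1 of the hand protospacer is G, not C
        profile = EditingProfile(c_to_t={1: 0.5})
        with pytest.raises(ValueError, match="carries G"):
            profile.validate_for(hand_site)


class TestSimulateAmpliconReads:
    def test_all_zero_profile_reads_identical(self, hand_site):
        reads, _, truth = simulate_amplicon_reads(hand_site, EditingProfile(), 50, seed=4)
        assert all(r == hand_site.amplicon for r in reads)
        assert all(t.outcome == "WT" for t in truth.reads)

    def test_certain_conversion_applied_everywhere(self, hand_site):
        profile = EditingProfile(c_to_t={5: 1.0})
        reads, _, truth = simulate_amplicon_reads(hand_site, profile, 30, seed=5)
        idx = hand_site.amplicon_index(5)
        expected = hand_site.amplicon[:idx] + "T" + hand_site.amplicon[idx + 1:]
        assert all(r == expected for r in reads)
        assert all(t.outcome == "C_TO_T" and t.conversions == [(5, "C>T")]
                   for t in truth.reads)

    def test_minus_strand_conversion_lands_as_complement(self, hand_site_minus):
        profile = EditingProfile(c_to_t={5: 1.0})
        reads, _, _ = simulate_amplicon_reads(hand_site_minus, profile, 5, seed=6)
        idx = hand_site_minus.amplicon_index(5)
        assert hand_site_minus.amplicon[idx] == "G"  # complement of the C
        assert all(r[idx] == "A" for r in reads)  # C>T reads as G>A on the amplicon

    def test_rate_within_binomial_error(self, hand_site):
        profile = EditingProfile(c_to_t={5: 0.5})
        n = 10000
        reads, _, _ = simulate_amplicon_reads(hand_site, profile, n, seed=7)
        idx = hand_site.amplicon_index(5)
        frac = sum(r[idx] == "T" for r in reads) / n
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / n)

    def test_linked_conversions_cooccur(self, hand_site):
        profile = EditingProfile(c_to_t={4: 0.4, 5: 0.4}, a_to_g={6: 0.4},
                                 cooccurrence="linked")
        _, _, truth = simulate_amplicon_reads(hand_site, profile, 2000, seed=8)
        for t in truth.reads:
            # equal probabilities under the comonotone coupling: all or none
            assert len(t.conversions) in (0, 3)

    def test_determinism(self, hand_site):
        profile = EditingProfile(c_to_t={5: 0.3}, indel_rate=0.02, seq_error_rate=0.01)
        a = simulate_amplicon_reads(hand_site, profile, 200, seed=9)
        b = simulate_amplicon_reads(hand_site, profile, 200, seed=9)
        assert a[0] == b[0]
        assert a[2].to_json() == b[2].to_json()

    def test_indel_reads_change_length(self, hand_site):
        profile = EditingProfile(indel_rate=1.0)
        reads, _, truth = simulate_amplicon_reads(hand_site, profile, 40, seed=10)
        assert all(t.outcome == "INDEL" for t in truth.reads)
        assert all(len(r) != len(hand_site.amplicon) for r in reads)
        assert all(1 <= abs(len(r) - len(hand_site.amplicon)) <= 5 for r in reads)


class TestToyGenome:
    def test_shape_and_determinism(self):
        g = make_toy_genome(2, 50000, seed=7)
        assert sorted(g) == ["chr1", "chr2"]
        assert all(len(seq) == 50000 for seq in g.values())
        assert g == make_toy_genome(2, 50000, seed=7)

    def test_base_composition_uniform(self):
        seq = make_toy_genome(1, 50000, seed=11)["chr1"]
        n = len(seq)
        tol = 3 * math.sqrt(0.25 * 0.75 / n)
        for base in "ACGT":
            assert abs(seq.count(base) / n - 0.25) <= tol

    def test_rejects_short_chromosomes(self):
        with pytest.raises(ValueError):
            make_toy_genome(1, 999, seed=1)


PROTO = "GATCCATAGCTGACGTACGT"


class TestPlantCandidateSites:
    def test_exact_plus_strand_plant(self):
        genome = make_toy_genome(1, 5000, seed=1)
        mutated, reg = plant_candidate_sites(genome, PROTO, [("chr1", 100, "+", 0)],
                                             seed=2)
        assert mutated["chr1"][100:120] == PROTO
        assert reg[0].mismatch_count == 0

    def test_minus_strand_plant_is_revcomp(self):
        genome = make_toy_genome(1, 5000, seed=1)
        mutated, reg = plant_candidate_sites(genome, PROTO, [("chr1", 100, "-", 0)],
                                             seed=2)
        assert mutated["chr1"][100:120] == revcomp(PROTO)
        # PAM sits 5' of the block in genome coordinates
        assert revcomp(mutated["chr1"][97:100]) == reg[0].pam

    @pytest.mark.parametrize("n_mm", [1, 2, 3, 4])
    def test_hamming_distance_exact(self, n_mm):
        genome = make_toy_genome(1, 5000, seed=3)
        mutated, reg = plant_candidate_sites(genome, PROTO,
                                             [("chr1", 400, "+", n_mm)], seed=4)
        assert count_mismatches(mutated["chr1"][400:420], PROTO) == n_mm
        assert reg[0].mismatch_count == n_mm

    def test_overlap_rejected(self):
        genome = make_toy_genome(1, 5000, seed=5)
        with pytest.raises(ValueError, match="overlaps"):
            plant_candidate_sites(genome, PROTO,
                                  [("chr1", 100, "+", 0), ("chr1", 110, "+", 1)],
                                  seed=6)

    def test_out_of_bounds_rejected(self):
        genome = make_toy_genome(1, 5000, seed=5)
        with pytest.raises(ValueError, match="bounds"):
            plant_candidate_sites(genome, PROTO, [("chr1", 4990, "+", 0)], seed=6)


class TestSimulatePlantCohort:
    @pytest.fixture()
    def planted_genome(self):
        genome = make_toy_genome(1, 8000, seed=20)
        return plant_candidate_sites(
            genome, PROTO, [("chr1", 100, "+", 0), ("chr1", 300, "-", 0)], seed=21)

    def test_single_planted_edit_only(self, planted_genome):
        genome, reg = planted_genome
        bg = BackgroundModel(mean_snvs=0, mean_indels=0)
        plants, truth = simulate_plant_cohort(genome, reg[:1], [("C>T", 0.9)],
                                              bg, 1, seed=22)
        assert len(plants[0].snvs) == 1 and not plants[0].indels
        rec = plants[0].snvs[0]
        assert (rec.ref, rec.alt, rec.allele_frequency) == ("C", "T", 0.9)

    def test_minus_strand_edit_recorded_as_complement(self, planted_genome):
        genome, reg = planted_genome
        bg = BackgroundModel(mean_snvs=0, mean_indels=0)
        plants, truth = simulate_plant_cohort(genome, reg[1:], [("C>T", 0.8)],
                                              bg, 1, seed=23)
        rec = plants[0].snvs[0]
        assert (rec.ref, rec.alt) == ("G", "A")
        assert truth.variants[0].conversion == "C>T"
        assert truth.variants[0].snv_class == "C>T"

    def test_background_counts_in_poisson_band(self, planted_genome):
        genome, reg = planted_genome
        from scipy.stats import poisson
        mean = 200
        bg = BackgroundModel(mean_snvs=mean, mean_indels=0)
        plants, _ = simulate_plant_cohort(genome, [], [], bg, 10, seed=24)
        lo, hi = poisson.ppf(0.005, mean), poisson.ppf(0.995, mean)
        for plant in plants:
            assert lo <= len(plant.snvs) <= hi

    def test_truth_zygosity_matches_af(self, planted_genome):
        genome, reg = planted_genome
        bg = BackgroundModel(mean_snvs=50, mean_indels=5)
        _, truth = simulate_plant_cohort(genome, reg, [("C>T", 0.9), ("A>G", 0.5)],
                                         bg, 2, seed=25)
        for v in truth.variants:
            assert v.zygosity == call_zygosity(v.allele_frequency)

    def test_truth_round_trips_through_json(self, planted_genome):
        genome, reg = planted_genome
        bg = BackgroundModel(mean_snvs=10, mean_indels=2)
        plants, truth = simulate_plant_cohort(genome, reg[:1], [("C>T", 0.9)],
                                              bg, 1, seed=26)
        import json
        data = json.loads(truth.to_json())
        assert data["samples"] == [p.sample_id for p in plants]
        assert len(data["variants"]) == len(plants[0].snvs)
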