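import math

import pytest

from bequant.offtarget import CandidateSite
from bequant.variants import (PlantVariantSet, SNVRecord, call_zygosity,
                              classify_snv_type, germline_fraction,
                              intersect_callsets, motif_context,
                              on_target_genotype_matrix, per_plant_counts)


def snv(chrom="chr1", pos=100, ref="C", alt="T", af=0.5, sample="p1", mol="DNA"):
    return SNVRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, allele_frequency=af,
                     sample_id=sample, molecule=mol)


class TestClassifySnvType:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", "C>T"), ("G", "A", "C>T"), ("A", "C", "T>G"),
        ("A", "G", "T>C"), ("T", "C", "T>C"), ("G", "C", "C>G"),
    ])
    def test_pyrimidine_anchoring(self, ref, alt, expected):
        assert classify_snv_type(ref, alt) == expected

    def test_complement_invariance(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_snv_type(ref, alt) == \
                    classify_snv_type(comp[ref], comp[alt])

    def test_identical_bases_raise(self):
        with pytest.raises(ValueError):
            classify_snv_type("C", "C")


class TestCallZygosity:
    @pytest.mark.parametrize("af,expected", [
        (0.85, "homozygous"), (0.50, "heterozygous"),
        (0.70, "heterozygous"),  # strict inequality at the upper cutoff
        (0.30, "subclonal"),  # strict inequality at the lower cutoff
        (0.300001, "heterozygous"), (0.700001, "homozygous"),
        (0.05, "subclonal"), (1.0, "homozygous"),
    ])
    def test_thresholds(self, af, expected):
        assert call_zygosity(af) == expected

    @pytest.mark.parametrize("af", [0.0, -0.1, 1.1])
    def test_out_of_range_raises(self, af):
        with pytest.raises(ValueError):
            call_zygosity(af)


class TestIntersectCallsets:
    def test_three_way_intersection(self):
        a, b, c, d = (snv(pos=p) for p in (1, 2, 3, 4))
        result = intersect_callsets([[a, b, c], [b, c, d], [b, c]])
        assert [r.pos for r in result] == [2, 3]

    def test_identical_callsets(self):
        cs = [snv(pos=1), snv(pos=2)]
        assert intersect_callsets([cs, list(cs)]) == cs

    def test_disjoint_callsets_empty(self):
        assert intersect_callsets([[snv(pos=1)], [snv(pos=2)]]) == []

    def test_af_taken_from_first_callset(self):
        first = snv(pos=1, af=0.2)
        second = snv(pos=1, af=0.9)
        assert intersect_callsets([[first], [second]])[0].allele_frequency == 0.2

    def test_commutative_over_key_sets(self):
        a = [snv(pos=1), snv(pos=2)]
        b = [snv(pos=2), snv(pos=3)]
        keys = lambda recs: {r.key for r in recs}
        assert keys(intersect_callsets([a, b])) == keys(intersect_callsets([b, a]))


class TestPerPlantCounts:
    def test_empty_plant_all_zero(self):
        table, _ = per_plant_counts([PlantVariantSet(sample_id="p1")])
        row = table.loc["p1"]
        assert row.n_snvs == 0 and row.n_indels == 0 and row[2:].sum() == 0

    def test_classification_then_count(self):
        plant = PlantVariantSet(sample_id="p1", snvs=[
            snv(pos=1, ref="C", alt="T"), snv(pos=2, ref="G", alt="A"),
            snv(pos=3, ref="A", alt="G")])
        table, chrom_table = per_plant_counts([plant])
        row = table.loc["p1"]
        assert row["C>T"] == 2 and row["T>C"] == 1 and row.n_snvs == 3
        assert chrom_table.loc["p1", "chr1"] == 3

    def test_class_partition_and_strand_collapse(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        snvs = [snv(pos=i, ref=r, alt=a, af=0.4)
                for i, (r, a) in enumerate(
                    [("C", "T"), ("G", "A"), ("A", "C"), ("T", "G"), ("C", "G")], 1)]
        flipped = [snv(pos=s.pos, ref=comp[s.ref], alt=comp[s.alt], af=0.4)
                   for s in snvs]
        t1, _ = per_plant_counts([PlantVariantSet(sample_id="p", snvs=snvs)])
        t2, _ = per_plant_counts([PlantVariantSet(sample_id="p", snvs=flipped)])
        assert t1.loc["p"].iloc[2:].sum() == t1.loc["p"].n_snvs  # partition
        assert (t1.loc["p"] == t2.loc["p"]).all()  # strand collapse


class TestGermlineFraction:
    def test_hand_count(self):
        plant = PlantVariantSet(sample_id="p1", snvs=[
            snv(pos=i, af=af) for i, af in enumerate([0.1, 0.5, 0.8, 0.9], 1)])
        assert germline_fraction(plant) == pytest.approx(0.75)

    def test_all_subclonal_zero(self):
        plant = PlantVariantSet(sample_id="p1",
                                snvs=[snv(pos=i, af=0.1) for i in range(1, 4)])
        assert germline_fraction(plant) == 0

    def test_all_homozygous_one(self):
        plant = PlantVariantSet(sample_id="p1",
                                snvs=[snv(pos=i, af=0.9) for i in range(1, 4)])
        assert germline_fraction(plant) == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            germline_fraction(PlantVariantSet(sample_id="p1"))


SITE = CandidateSite(chrom="chr1", start=99, end=119, strand="+",
                     sequence="C" * 20, mismatch_count=0, pam="AGG",
                     source_grna="site01")


class TestGenotypeMatrix:
    def plant(self, name, af):
        return PlantVariantSet(sample_id=name,
                               snvs=[snv(pos=105, af=af, sample=name)])

    def test_af_rule(self):
        plants = [self.plant("hi", 0.9), self.plant("mid", 0.4),
                  self.plant("lo", 0.1), PlantVariantSet(sample_id="none")]
        matrix = on_target_genotype_matrix(plants, [SITE], "C>T")
        assert matrix.loc["hi", "site01"] == "biallelic"
        assert matrix.loc["mid", "site01"] == "edited"
        assert matrix.loc["lo", "site01"] == "unedited"
        assert matrix.loc["none", "site01"] == "unedited"

    def test_wrong_conversion_ignored(self):
        plant = PlantVariantSet(sample_id="p",
                                snvs=[snv(pos=105, ref="C", alt="A", af=0.9)])
        matrix = on_target_genotype_matrix([plant], [SITE], "C>T")
        assert matrix.loc["p", "site01"] == "unedited"

    def test_minus_strand_site_resolved(self):
        minus = CandidateSite(chrom="chr1", start=99, end=119, strand="-",
                              sequence="C" * 20, mismatch_count=0, pam="AGG",
                              source_grna="s")
        plant = PlantVariantSet(sample_id="p",
                                snvs=[snv(pos=105, ref="G", alt="A", af=0.9)])
        matrix = on_target_genotype_matrix([plant], [minus], "C>T")
        assert matrix.loc["p", "s"] == "biallelic"


class TestMotifContext:
    def test_fully_conserved_context(self):
        genome = {"chr1": "ATCGATCGATCG"}  # TCG at indices 1..3 (0-based)
        snvs = [snv(pos=3, ref="C", alt="T"), snv(pos=7, ref="C", alt="T")]
        m = motif_context(snvs, genome)
        assert m.information.tolist() == pytest.approx([2.0, 2.0, 2.0])
        assert m.frequencies.loc[2, "C"] == 1.0

    def test_uniform_position_zero_bits(self):
        genome = {"chr1": "ACAA" "CCAG" "GCAC" "TCAT"}  # X C A blocks
        snvs = [snv(pos=p, ref="C", alt="T") for p in (2, 6, 10, 14)]
        m = motif_context(snvs, genome)
        assert m.information[1] == pytest.approx(0.0)
        assert m.information[2] == pytest.approx(2.0)

    def test_half_half_one_bit(self):
        genome = {"chr1": "ACGG" "TCGG"}
        snvs = [snv(pos=2, ref="C", alt="T"), snv(pos=6, ref="C", alt="T")]
        m = motif_context(snvs, genome)
        assert m.information[1] == pytest.approx(1.0)

    def test_purine_anchored_call_reverse_complemented(self):
        # G>A at pos 5 of AATTGAACC -> revcomp of "TGA" context = "TCA"
        genome = {"chr1": "AATTGAACC"}
        m = motif_context([snv(pos=5, ref="G", alt="A")], genome)
        assert m.frequencies.loc[2, "C"] == 1.0
        assert m.frequencies.loc[1, "T"] == 1.0
        assert m.frequencies.loc[3, "A"] == 1.0

    def test_edge_snv_skipped_and_counted(self):
        genome = {"chr1": "CGATT"}
        m = motif_context([snv(pos=1, ref="C", alt="T"),
                           snv(pos=3, ref="A", alt="G")], genome)
        assert m.n_used == 1 and m.n_skipped == 1

    def test_rna_mode_records_behave_identically(self):
        genome = {"chr1": "ATCGATCG"}
        dna = motif_context([snv(pos=3, ref="C", alt="T", mol="DNA")], genome)
        rna = motif_context([snv(pos=3, ref="C", alt="T", mol="RNA")], genome)
        assert dna.frequencies.equals(rna.frequencies)
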