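"""Recessive-model filtering chain and consequence classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tiny_transcript
from oracles import consequence_by_retranslation
from rohvar.genotype_model import MISSING
from rohvar.roh import ROHRegion
from rohvar.variant_filter import (
    FilterError,
    SampleRoles,
    VariantRecord,
    classify_consequence,
    exclude_known,
    intersect_roh,
    qc_filter,
    recessive_segregation_filter,
)

ROLES = SampleRoles(
    cases=frozenset({"a1", "a2"}),
    obligate_carriers=frozenset({"p1", "p2"}),
    controls=frozenset({"c1", "c2", "c3"}),
)
SAMPLES = ["a1", "a2", "p1", "p2", "c1", "c2", "c3"]


def var(genos, pos=100, chrom="1", ref="A", alt="G"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=dict(zip(SAMPLES, genos))
    )


class TestQcFilter:
    def test_call_rate_threshold_strict(self):
        # 1/7 called -> 0.14 removed; 2/7 -> 0.29 kept (threshold 0.2 strict)
        low = var([2] + [MISSING] * 6)
        ok = var([2, 1] + [MISSING] * 5)
        assert qc_filter([low, ok]) == [ok]
        # exactly at the boundary: call rate 0.2 with 1/5 samples is removed
        five = VariantRecord("1", 5, "A", "G", {f"s{i}": (1 if i == 0 else MISSING) for i in range(5)})
        assert qc_filter([five]) == []

    def test_maf_threshold_strict(self):
        rare = var([1, 0, 0, 0, 0, 0, 0])     # maf 1/14 = 0.071 kept
        very_rare = VariantRecord("1", 6, "A", "G", {f"s{i}": (1 if i == 0 else 0) for i in range(10)})
        assert very_rare.maf == pytest.approx(0.05)  # exactly 0.05: removed
        assert qc_filter([rare, very_rare]) == [rare]

    def test_perfect_variant_kept(self):
        v = var([2, 2, 1, 1, 0, 0, 0])
        assert v.call_rate == 1.0 and v.maf == pytest.approx(6 / 14)
        assert qc_filter([v]) == [v]


class TestRecessiveFilter:
    def test_textbook_segregation_kept(self):
        assert recessive_segregation_filter([var([2, 2, 1, 1, 0, 1, 0])], ROLES)

    def test_carrier_missing_tolerated_case_missing_not(self):
        assert recessive_segregation_filter([var([2, 2, MISSING, 1, 0, 0, 0])], ROLES)
        assert not recessive_segregation_filter([var([2, MISSING, 1, 1, 0, 0, 0])], ROLES)

    @pytest.mark.parametrize(
        "genos",
        [
            [2, 1, 1, 1, 0, 0, 0],  # case het
            [2, 2, 0, 1, 0, 0, 0],  # carrier hom-ref
            [2, 2, 2, 1, 0, 0, 0],  # carrier hom-alt
            [2, 2, 1, 1, 0, 0, 2],  # control hom-alt
        ],
    )
    def test_violations_removed(self, genos):
        assert recessive_segregation_filter([var(genos)], ROLES) == []

    def test_empty_case_set_errors(self):
        empty = SampleRoles(frozenset(), frozenset({"p1"}), frozenset({"c1"}))
        with pytest.raises(FilterError):
            recessive_segregation_filter([var([0] * 7)], empty)

    def test_adding_controls_never_adds_survivors(self):
        vs = [var([2, 2, 1, 1, 0, 1, 0]), var([2, 2, 1, MISSING, 0, 0, 0], pos=200)]
        before = {v.pos for v in recessive_segregation_filter(vs, ROLES)}
        bigger = SampleRoles(ROLES.cases, ROLES.obligate_carriers, ROLES.controls | {"c4"})
        vs4 = [
            VariantRecord(v.chrom, v.pos, v.ref, v.alt, {**v.genotypes, "c4": 2})
            for v in vs
        ]
        after = {v.pos for v in recessive_segregation_filter(vs4, bigger)}
        assert after <= before

    @settings(max_examples=100, deadline=None)
    @given(genos=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=7, max_size=7))
    def test_qc_and_segregation_commute(self, genos):
        vs = [var(genos)]
        ab = recessive_segregation_filter(qc_filter(vs), ROLES)
        ba = qc_filter(recessive_segregation_filter(vs, ROLES))
        assert ab == ba


class TestRohIntersection:
    REGIONS = [ROHRegion(chrom="2", start_bp=1000, end_bp=2000, n_candidate_snps=5)]

    def test_inside_kept_boundaries_half_open(self):
        inside = var([0] * 7, pos=1500, chrom="2")
        at_start = var([0] * 7, pos=1001, chrom="2")   # 0-based 1000 == start
        at_end = var([0] * 7, pos=2001, chrom="2")     # 0-based 2000 == end -> out
        other_chrom = var([0] * 7, pos=1500, chrom="3")
        kept = intersect_roh([inside, at_start, at_end, other_chrom], self.REGIONS)
        assert kept == [inside, at_start]


class TestConsequenceClassifier:
    def test_donor_plus_five_is_splice_region(self, designated, genome):
        donor_g = designated.exons[8][1] + 4
        v = VariantRecord("2", donor_g + 1, genome["2"][donor_g], "A", {})
        assert classify_consequence(v, [designated], genome=genome) == "splice_region"

    def test_donor_plus_one_is_splice_donor(self, designated, genome):
        donor_g = designated.exons[8][1]
        v = VariantRecord("2", donor_g + 1, genome["2"][donor_g], "A", {})
        assert classify_consequence(v, [designated], genome=genome) == "splice_donor"

    def test_deep_intron_and_intergenic(self, designated, genome):
        mid_intron = (designated.exons[0][1] + designated.exons[1][0]) // 2
        v = VariantRecord("2", mid_intron + 1, genome["2"][mid_intron], "A", {})
        assert classify_consequence(v, [designated], genome=genome) == "intronic"
        far = VariantRecord("2", 5, genome["2"][4], "A" if genome["2"][4] != "A" else "C", {})
        assert classify_consequence(far, [designated], genome=genome) == "intergenic"

    def test_ref_mismatch_errors_with_position(self, designated, genome):
        donor_g = designated.exons[8][1] + 4
        wrong = "C" if genome["2"][donor_g] != "C" else "T"
        v = VariantRecord("2", donor_g + 1, wrong, "A", {})
        with pytest.raises(FilterError, match=str(donor_g + 1)):
            classify_consequence(v, [designated], genome=genome)

    def test_toy_codon_gag_to_aag_is_missense(self):
        # tiny gene: c.16-18 is GAC; use its own codons: c.4-6 AAA -> AGA etc.
        tr = make_tiny_transcript("+")
        # codon 2 AAA (Lys); change c.4 A>G -> GAA? no: build GAG->AAG analogue
        # c.13-15 TTT(F): c.13 T>C -> CTT(L) missense
        g = tr.t_to_g(12)
        v = VariantRecord("9", g + 1, "T", "C", {})
        assert classify_consequence(v, [tr]) == "missense"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exonic_snvs_match_retranslation_oracle(self, strand):
        """Every CDS SNV of the tiny gene agrees with mutate-and-retranslate.

        Positions inside a splice-region window assert the window label
        instead (unless the substitution gains a stop, which outranks it).
        """
        tr = make_tiny_transcript(strand)
        windows = set()
        offs = tr.exon_t_offsets()
        for i, l in enumerate(tr.exon_lengths[:-1]):
            windows |= set(range(offs[i] + l - 3, offs[i] + l))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for tpos in range(tr.cds_start, tr.cds_end):
            t_ref = tr.seq[tpos]
            for t_alt in "ACGT":
                if t_alt == t_ref:
                    continue
                g = tr.t_to_g(tpos)
                ref = t_ref if strand == "+" else comp[t_ref]
                alt = t_alt if strand == "+" else comp[t_alt]
                v = VariantRecord(tr.chrom, g + 1, ref, alt, {})
                got = classify_consequence(v, [tr])
                expected = consequence_by_retranslation(tr, tpos, t_alt)
                if tpos in windows and expected != "stop_gained":
                    assert got == "splice_region", (tpos, t_alt)
                else:
                    assert got == expected, (tpos, t_alt, got, expected)


class TestKnownExclusion:
    def test_fifteen_of_sixteen_known_leaves_one(self):
        vs = [var([2] * 7, pos=100 + i) for i in range(16)]
        known = {v.key for v in vs[:15]}
        assert exclude_known(vs, known) == [vs[15]]

    def test_empty_known_set_is_identity(self):
        vs = [var([0] * 7, pos=1), var([1] * 7, pos=2)]
        assert exclude_known(vs, set()) == vs

    def test_all_known_leaves_nothing(self):
        vs = [var([0] * 7, pos=1)]
        assert exclude_known(vs, {vs[0].key}) == []
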