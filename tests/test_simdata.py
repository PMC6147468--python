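"""Synthetic study generator: pedigree, array, transcriptome, exome, pileups."""

import numpy as np
import pandas as pd
import pytest

from rohvar.config import ConfigError, SimConfig
from rohvar.genotype_model import MISSING
from rohvar.simdata import (
    DESIGNATED_TRANSCRIPT,
    DONOR_EXON_INDEX,
    known_variant_keys,
    make_toy_transcriptome,
    simulate_exome_variants,
    simulate_genotype_array,
    simulate_pedigree,
    simulate_pileups,
)
from rohvar.variant_filter import matches_recessive_pattern, recessive_segregation_filter


class TestPedigree:
    def test_zero_generations_gives_founders_only(self):
        ped = simulate_pedigree(SimConfig(seed=3, n_generations=0))
        assert all(i.sire is None and i.dam is None for i in ped)
        assert len(ped.individuals) == 6

    def test_same_seed_reproduces_pedigree(self):
        a = simulate_pedigree(SimConfig(seed=11))
        b = simulate_pedigree(SimConfig(seed=11))
        assert a.individuals == b.individuals

    def test_structure_matches_study_design(self, pedigree):
        cases = pedigree.cases()
        assert len(cases) >= 2
        carriers = {i.id for i in pedigree.obligate_carriers()}
        for case in cases:
            assert {case.sire, case.dam} <= carriers
            assert case.causal_gt == 2
        assert len(pedigree.controls()) == 3
        # affected individuals never reproduce
        parents = {i.sire for i in pedigree} | {i.dam for i in pedigree}
        assert not any(pedigree.by_id(p).causal_gt == 2 for p in parents if p)

    def test_carrier_cross_offspring_ratio(self):
        """Gene-dropping through a carrier x carrier cross is Binomial(1/4)."""
        from rohvar.simdata import _drop_child, _rng

        rng = _rng(SimConfig(seed=5), 17)
        n = 10_000
        affected = sum(_drop_child(rng, 1, 1) == 2 for _ in range(n))
        sd = (n * 0.25 * 0.75) ** 0.5
        assert abs(affected - n * 0.25) < 3 * sd

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="n_founders"):
            SimConfig(seed=1, n_founders=1)
        with pytest.raises(ConfigError, match="causal_region"):
            SimConfig(seed=1, causal_region=("2", 0, 10**9))
        with pytest.raises(ConfigError, match="base_error_rate"):
            SimConfig(seed=1, base_error_rate=0.5)


class TestGenotypeArray:
    def test_cases_share_homozygous_haplotype_in_region(self, genotype_array, pedigree, sim_config):
        chrom, start, end = sim_config.causal_region
        t = genotype_array.markers.table
        idx = ((t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] < end)).to_numpy()
        cases = [i.id for i in pedigree.cases()]
        g = genotype_array.rows(cases)[:, idx]
        known = (g != MISSING).all(axis=0)
        assert np.isin(g[:, known], (0, 2)).all()
        assert (g[:, known] == g[0, known]).all()

    def test_founder_heterozygosity_matches_hardy_weinberg(self):
        cfg = SimConfig(seed=9, n_generations=0, n_markers=50_000, missing_rate=0.0,
                        founder_allele_freq=0.3, causal_region=("2", 1_000_000, 1_050_000))
        ped = simulate_pedigree(cfg)
        arr = simulate_genotype_array(ped, cfg)
        t = arr.markers.table
        outside = ~((t["chrom"] == "2") & (t["pos"] >= 1_000_000) & (t["pos"] < 1_050_000))
        het = (arr.geno[:, outside.to_numpy()] == 1).mean()
        expect = 2 * 0.3 * 0.7
        n = arr.geno[:, outside.to_numpy()].size
        sd = (expect * (1 - expect) / n) ** 0.5
        assert abs(het - expect) < 3 * sd

    def test_zero_missing_rate_means_no_missing_codes(self, pedigree):
        cfg = SimConfig(seed=1, missing_rate=0.0)
        arr = simulate_genotype_array(pedigree, cfg)
        assert not (arr.geno == MISSING).any()

    def test_mendelian_consistency(self, genotype_array, pedigree):
        """Child genotypes are reachable from parents at every marker."""
        compatible = {
            (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
            (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
        }
        idx = {s: i for i, s in enumerate(genotype_array.samples)}
        for ind in pedigree:
            if ind.sire is None:
                continue
            trio = genotype_array.geno[[idx[ind.id], idx[ind.sire], idx[ind.dam]]]
            ok = (trio != MISSING).all(axis=0)
            child, sire, dam = trio[:, ok]
            for c, s, d in zip(child, sire, dam):
                key = (min(s, d), max(s, d))
                assert c in compatible[key], (ind.id, s, d, c)

    def test_determinism(self, pedigree, sim_config):
        a = simulate_genotype_array(pedigree, sim_config)
        b = simulate_genotype_array(pedigree, sim_config)
        assert np.array_equal(a.geno, b.geno)


class TestToyTranscriptome:
    def test_every_intron_is_gt_ag(self, genome, transcripts):
        for tr in transcripts:
            exons = sorted(tr.exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                intron = genome[tr.chrom][e1:s2]
                if tr.strand == "-":
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    intron = "".join(comp[b] for b in reversed(intron))
                assert intron.startswith("GT") and intron.endswith("AG"), tr.id

    def test_canonical_cds_has_no_internal_stop(self, transcripts):
        for tr in transcripts:
            tr.validate_coding()

    def test_cryptic_gt_sits_exactly_fifty_nt_before_exon_nine_end(self, designated):
        off0 = designated.exon_t_offsets()[DONOR_EXON_INDEX]
        exon = designated.seq[off0 : off0 + designated.exon_lengths[DONOR_EXON_INDEX]]
        assert exon[-50:-48] == "GT"

    def test_configurable_cryptic_offset(self):
        cfg = SimConfig(seed=2, cryptic_offset=37)
        _, trs = make_toy_transcriptome(cfg)
        des = next(t for t in trs if t.id == DESIGNATED_TRANSCRIPT)
        off0 = des.exon_t_offsets()[DONOR_EXON_INDEX]
        exon = des.seq[off0 : off0 + des.exon_lengths[DONOR_EXON_INDEX]]
        assert exon[-37:-35] == "GT"
        assert "GT" not in exon[-35:]


class TestExomeVariants:
    def test_causal_genotypes_equal_pedigree_states(self, exome_variants, pedigree):
        causal = next(v for v in exome_variants if v.vid == "causal")
        for sample, gt in causal.genotypes.items():
            assert gt == pedigree.by_id(sample).causal_gt

    def test_exactly_sixteen_pass_recessive_filter(self, exome_variants, pedigree):
        """causal + 15 decoys and nothing else satisfy the recessive pattern."""
        roles = pedigree.exome_roles()
        passing = recessive_segregation_filter(list(exome_variants), roles)
        assert len(passing) == 16
        assert {v.vid for v in passing} == {"causal"} | {f"known{i}" for i in range(1, 16)}
        assert len(known_variant_keys(exome_variants)) == 15

    def test_decoys_live_inside_causal_region(self, exome_variants, sim_config):
        chrom, start, end = sim_config.causal_region
        for v in exome_variants:
            if v.vid.startswith("known") or v.vid == "causal":
                assert v.chrom == chrom and start <= v.pos - 1 < end

    def test_zero_transcripts_errors(self, pedigree, sim_config, genome):
        with pytest.raises(ConfigError):
            simulate_exome_variants(pedigree, [], sim_config, genome)

    def test_background_rejection_is_pattern_exact(self, exome_variants, pedigree):
        roles = pedigree.exome_roles()
        for v in exome_variants:
            if not (v.vid == "causal" or v.vid.startswith("known")):
                assert not matches_recessive_pattern(v.genotypes, roles)


class TestPileups:
    def test_missing_truth_gives_zero_depth(self, exome_variants, sim_config):
        pu = simulate_pileups(list(exome_variants), sim_config)
        truth = {(v.chrom, v.pos): v.genotypes for v in exome_variants}
        for r in pu.itertuples(index=False):
            if truth[(r.chrom, r.pos)][r.sample] == MISSING:
                assert r.ref_count == 0 and r.alt_count == 0

    def test_pooled_error_rate_matches_binomial(self):
        """Hom-ref truth at eps=0.01: pooled alt fraction within 3 sigma."""
        from rohvar.variant_filter import VariantRecord

        cfg = SimConfig(seed=21, pileup_depth_mean=50.0, base_error_rate=0.01)
        variants = [
            VariantRecord("1", i + 1, "A", "G", {f"s{j}": 0 for j in range(10)})
            for i in range(250)
        ]
        pu = simulate_pileups(variants, cfg)
        total = (pu["ref_count"] + pu["alt_count"]).sum()
        alt = pu["alt_count"].sum()
        assert total > 100_000
        sd = (total * 0.01 * 0.99) ** 0.5
        assert abs(alt - total * 0.01) < 3 * sd

    def test_fixed_seed_reproduces_pileups(self, exome_variants, sim_config):
        a = simulate_pileups(list(exome_variants), sim_config)
        b = simulate_pileups(list(exome_variants), sim_config)
        pd.testing.assert_frame_equal(a, b)
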