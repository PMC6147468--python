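"""Candidate-locus selection, region merging, and priority scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import rle_regions
from rohvar.config import ROHParams
from rohvar.genotype_model import MISSING
from rohvar.roh import (
    GenotypeMatrix,
    MarkerMap,
    ROHError,
    ROHRegion,
    map_case_regions,
    merge_candidate_regions,
    prioritize_regions,
    select_candidate_loci,
)


def matrix(geno_rows, samples=None, chroms=None, positions=None):
    geno = np.array(geno_rows, dtype=np.int8)
    n = geno.shape[1]
    samples = samples or [f"s{i}" for i in range(geno.shape[0])]
    chroms = chroms or ["1"] * n
    positions = positions or [1000 * (i + 1) for i in range(n)]
    mmap = MarkerMap(
        pd.DataFrame({"chrom": chroms, "pos": positions, "id": [f"m{i}" for i in range(n)]})
    )
    return GenotypeMatrix(samples=tuple(samples), markers=mmap, geno=geno)


class TestCandidateSelection:
    def test_selection_rules(self):
        # columns: monomorphic / missing / shared-case-hom / discordant-hom / case-het
        m = matrix(
            [
                [0, 2, 2, 2, 1],
                [0, 2, 2, 0, 1],
                [0, MISSING, 1, 1, 0],
                [0, 1, 1, 0, 2],
                [0, 0, 0, 1, 0],
            ],
            samples=["case1", "case2", "x", "y", "z"],
        )
        mask = select_candidate_loci(m, ["case1", "case2"])
        assert mask.tolist() == [False, False, True, False, False]
        relaxed = select_candidate_loci(m, ["case1", "case2"], allow_discordant_hom=True)
        assert relaxed.tolist() == [False, False, True, True, False]

    def test_unknown_case_id_errors(self):
        with pytest.raises(ROHError):
            select_candidate_loci(matrix([[0, 1], [1, 0]]), ["nope"])
        with pytest.raises(ROHError):
            select_candidate_loci(matrix([[0, 1], [1, 0]]), [])


class TestMerging:
    def test_all_false_mask_gives_no_regions(self):
        m = matrix([[0, 1, 2]])
        assert merge_candidate_regions(np.zeros(3, bool), m.markers) == []

    def test_run_decomposition(self):
        m = matrix([[0, 0, 0, 0]])
        regions = merge_candidate_regions(np.array([True, True, False, True]), m.markers)
        assert [(r.start_bp, r.end_bp, r.n_candidate_snps) for r in regions] == [
            (1000, 2001, 2),
            (4000, 4001, 1),
        ]

    def test_chromosome_change_breaks_runs(self):
        m = matrix([[0] * 4], chroms=["1", "1", "2", "2"], positions=[10, 20, 10, 20])
        regions = merge_candidate_regions(np.ones(4, bool), m.markers)
        assert [(r.chrom, r.n_candidate_snps) for r in regions] == [("1", 2), ("2", 2)]

    @settings(max_examples=200, deadline=None)
    @given(mask=st.lists(st.booleans(), min_size=1, max_size=40), split=st.integers(0, 40))
    def test_matches_rle_oracle(self, mask, split):
        n = len(mask)
        chroms = ["1" if i < split else "2" for i in range(n)]
        positions = [100 * (i + 1) for i in range(n)]
        m = matrix([[0] * n], chroms=chroms, positions=positions)
        got = merge_candidate_regions(np.array(mask), m.markers)
        expected = rle_regions(mask, chroms, positions)
        assert [(r.chrom, r.start_bp, r.end_bp, r.n_candidate_snps) for r in got] == expected


class TestPriority:
    def region(self, chrom, start, end, idx):
        return ROHRegion(
            chrom=chrom, start_bp=start, end_bp=end,
            n_candidate_snps=len(idx), marker_index=tuple(idx),
        )

    def test_all_het_carriers_single_region_scores_one(self):
        m = matrix([[1, 1, 1], [1, 1, 1]], samples=["c1", "c2"])
        regions = [self.region("1", 1000, 3001, [0, 1, 2])]
        scored = prioritize_regions(
            regions, m, ["c1", "c2"], ROHParams(min_consecutive_snps=1, min_priority=0.1)
        )
        assert scored[0].carrier_maf == pytest.approx(0.5)
        assert scored[0].priority == pytest.approx(1.0)

    def test_two_region_formula(self):
        # region A: carriers het everywhere (MAF .5), 1000 kb; B: MAF .2, 500 kb
        geno = [[1, 1, 1, 1, 0], [1, 1, 1, 0, 1]]  # per-SNP MAF: .5 x3 then .25, .25
        m = matrix(
            geno,
            samples=["c1", "c2"],
            chroms=["1"] * 3 + ["2"] * 2,
            positions=[0, 500_000, 1_000_000, 0, 500_000],
        )
        regions = [
            self.region("1", 0, 1_000_000, [0, 1, 2]),
            self.region("2", 0, 500_000, [3, 4]),
        ]
        scored = prioritize_regions(
            regions, m, ["c1", "c2"], ROHParams(min_consecutive_snps=1, min_priority=0.01)
        )
        by_chrom = {r.chrom: r for r in scored}
        assert by_chrom["1"].priority == pytest.approx(2 * 0.5 * 1.0)
        assert by_chrom["2"].priority == pytest.approx(2 * 0.25 * 0.5)

    def test_snp_count_threshold_is_strict(self):
        m = matrix([[1] * 201, [1] * 201], samples=["c1", "c2"])
        base = [self.region("1", 1000, 201_001, list(range(201)))]
        kept_200 = prioritize_regions(base, m, ["c1"], ROHParams(min_consecutive_snps=201))
        assert kept_200 == []  # 201 SNPs is not > 201
        kept_201 = prioritize_regions(base, m, ["c1"], ROHParams(min_consecutive_snps=200))
        assert len(kept_201) == 1  # 201 SNPs is > 200

    def test_priority_threshold_is_strict(self):
        m = matrix([[1, 1, 0], [1, 1, 0]], samples=["c1", "c2"])
        # single region, carriers het at every SNP -> priority exactly 1.0
        region = [self.region("1", 0, 2001, [0, 1])]
        assert prioritize_regions(region, m, ["c1", "c2"], ROHParams(1, min_priority=1.0)) == []
        assert len(prioritize_regions(region, m, ["c1", "c2"], ROHParams(1, 0.999))) == 1

    def test_scale_invariance(self):
        geno = [[1, 1, 0, 1], [1, 0, 1, 1]]
        for scale in (1, 17):
            m = matrix(geno, samples=["c1", "c2"], positions=[scale * p for p in (10, 20, 30, 40)])
            regions = [
                self.region("1", 10 * scale, 20 * scale + 1, [0, 1]),
                self.region("1", 30 * scale, 40 * scale + 1, [2, 3]),
            ]
            scored = prioritize_regions(regions, m, ["c1", "c2"], ROHParams(1, 0.001))
            if scale == 1:
                baseline = [r.priority for r in scored]
            else:
                rescaled = [r.priority for r in scored]
        assert rescaled == pytest.approx(baseline, rel=1e-9)

    def test_empty_carrier_set_errors(self):
        m = matrix([[1, 1]])
        with pytest.raises(ROHError):
            prioritize_regions([self.region("1", 0, 10, [0])], m, [])


class TestPipelineMapping:
    def test_reported_regions_are_case_homozygous_disjoint_sorted(
        self, genotype_array, pedigree
    ):
        cases, carriers, members = pedigree.array_cohort()
        sub = GenotypeMatrix(
            samples=tuple(members),
            markers=genotype_array.markers,
            geno=genotype_array.rows(members),
        )
        regions = map_case_regions(sub, cases, carriers)
        assert regions, "expected the implanted region to be recovered"
        for r in regions:
            assert 0.0 <= r.priority <= 1.0
            assert 0.0 <= r.carrier_maf <= 0.5
        spans = sorted((r.chrom, r.start_bp, r.end_bp) for r in regions)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2  # disjoint
        # post-hoc: inside a reported span every analyzed (fully genotyped,
        # polymorphic) marker carries the same homozygous genotype in all cases
        from rohvar.roh import analyzed_loci_mask

        case_geno = sub.rows(cases)
        chroms = sub.markers.table["chrom"].to_numpy()
        pos = sub.markers.table["pos"].to_numpy()
        analyzed = analyzed_loci_mask(sub)
        for r in regions:
            inside = (chroms == r.chrom) & (pos >= r.start_bp) & (pos < r.end_bp) & analyzed
            g = case_geno[:, inside]
            assert np.isin(g, (0, 2)).all()
            assert (g == g[0, :]).all()
        # the implanted region is the top hit
        top = regions[0]
        assert top.chrom == "2" and top.start_bp >= 990_000 and top.end_bp <= 1_360_001
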