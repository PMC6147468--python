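"""Case-shared runs of homozygosity and region prioritisation.

Candidate loci are array markers that are polymorphic in the study cohort,
fully genotyped, and homozygous for the same allele in every case;
consecutive candidates are merged into regions; regions are ranked by

    priority_r = 2 * MAF_r * length_r / max(length_r*)

where MAF_r is the carrier minor-allele frequency within region r (mean of
per-SNP carrier MAFs over the region's candidate loci by default), length_r
is the region span in kb, and the maximum runs over all scored regions.
Under autozygosity around a recessive causal allele, obligate carriers are
heterozygous across the shared haplotype, pushing MAF_r toward its 0.5
ceiling, so long carrier-polymorphic case-homozygous regions rank first.
Regions are retained when priority > min_priority and the candidate-run
length exceeds min_consecutive_snps (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ROHParams
from .genotype_model import MISSING

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "ROHRegion",
    "select_candidate_loci",
    "analyzed_loci_mask",
    "merge_candidate_regions",
    "prioritize_regions",
    "map_case_regions",
]


class ROHError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP marker map: (chrom, pos_bp, marker_id) per marker."""

    table: pd.DataFrame  # columns: chrom (str), pos (int, 0-based), id (str)

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "id"}
        if not need <= set(self.table.columns):
            raise ROHError(f"marker map needs columns {sorted(need)}")
        if self.table["id"].duplicated().any():
            raise ROHError("duplicate marker ids")
        for _, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ROHError("marker positions must strictly increase within chromosome")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask, bool)].reset_index(drop=True))


@dataclass(frozen=True)
class GenotypeMatrix:
    """samples x ordered markers, codes {0,1,2,-9}."""

    samples: tuple[str, ...]
    markers: MarkerMap
    geno: np.ndarray  # shape (n_samples, n_markers), int8

    def __post_init__(self) -> None:
        if self.geno.shape != (len(self.samples), len(self.markers)):
            raise ROHError("genotype matrix shape does not match samples x markers")
        valid = np.isin(self.geno, (0, 1, 2, MISSING))
        if not valid.all():
            raise ROHError("genotype codes must be in {0, 1, 2, -9}")

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ROHError(f"unknown sample ids: {missing}")
        return self.geno[[index[s] for s in ids], :]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, bool)
        return GenotypeMatrix(self.samples, self.markers.subset(mask), self.geno[:, mask])


@dataclass(frozen=True)
class ROHRegion:
    """A merged run of candidate loci; scoring fields filled by prioritisation."""

    chrom: str
    start_bp: int
    end_bp: int
    n_candidate_snps: int
    marker_index: tuple[int, ...] = ()   # indices into the map used for merging
    carrier_maf: Optional[float] = None
    priority: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ROHError("region end must exceed start")
        if self.n_candidate_snps < 1:
            raise ROHError("region must contain at least one candidate SNP")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def select_candidate_loci(
    genotypes: GenotypeMatrix,
    case_ids: Sequence[str],
    allow_discordant_hom: bool = False,
) -> np.ndarray:
    """Boolean mask of candidate loci.

    A locus qualifies iff it is (i) polymorphic across the whole cohort,
    (ii) free of missing genotypes in every sample, and (iii) homozygous in
    every case for one shared allele (identity-by-descent rationale;
    ``allow_discordant_hom`` relaxes to any-homozygous per case).
    """
    if len(case_ids) == 0:
        raise ROHError("case_ids must be non-empty")
    cases = genotypes.rows(case_ids)
    g = genotypes.geno
    no_missing = ~(g == MISSING).any(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    known = 2 * (g != MISSING).sum(axis=0)
    polymorphic = (alt > 0) & (alt < known)   # both alleles observed
    hom = np.isin(cases, (0, 2)).all(axis=0)
    if allow_discordant_hom:
        shared = hom
    else:
        shared = hom & np.all(cases == cases[0, :], axis=0)
    return no_missing & polymorphic & shared


def analyzed_loci_mask(genotypes: GenotypeMatrix) -> np.ndarray:
    """Loci retained in the analysis: polymorphic and without missing data."""
    g = genotypes.geno
    no_missing = ~(g == MISSING).any(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    known = 2 * (g != MISSING).sum(axis=0)
    polymorphic = (alt > 0) & (alt < known)
    return no_missing & polymorphic


def merge_candidate_regions(mask: np.ndarray, marker_map: MarkerMap) -> list[ROHRegion]:
    """Merge maximal runs of consecutive candidate markers within chromosomes.

    Pure run-length decomposition over the supplied mask: any False entry
    (and any chromosome change) breaks a run. Region spans cover the first
    to last candidate position of the run, half-open.
    """
    mask = np.asarray(mask, bool)
    if len(mask) != len(marker_map):
        raise ROHError("mask length does not match marker map")
    chroms = marker_map.table["chrom"].to_numpy()
    pos = marker_map.table["pos"].to_numpy()
    regions: list[ROHRegion] = []
    start = None
    for i in range(len(mask) + 1):
        boundary = (
            i == len(mask)
            or not mask[i]
            or (start is not None and chroms[i] != chroms[start])
        )
        if start is not None and boundary:
            idx = tuple(range(start, i))
            regions.append(
                ROHRegion(
                    chrom=str(chroms[start]),
                    start_bp=int(pos[start]),
                    end_bp=int(pos[i - 1]) + 1,
                    n_candidate_snps=len(idx),
                    marker_index=idx,
                )
            )
            start = None
        if i < len(mask) and mask[i] and start is None:
            start = i
    return regions


def _per_snp_carrier_maf(carrier_geno: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP among carriers, ignoring missing calls."""
    known = carrier_geno != MISSING
    alt = np.where(known, carrier_geno, 0).sum(axis=0)
    denom = 2 * known.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def prioritize_regions(
    regions: Sequence[ROHRegion],
    genotypes: GenotypeMatrix,
    carrier_ids: Sequence[str],
    params: ROHParams = ROHParams(),
    pooled_maf: bool = False,
) -> list[ROHRegion]:
    """Score, filter, and sort merged regions.

    MAF_r is by default the mean over the region's candidate SNPs of the
    per-SNP carrier minor-allele frequency; ``pooled_maf`` switches to a
    single frequency from pooled allele counts over the region. The length
    term is the candidate-SNP span in kb normalised by the longest scored
    region, so 0 <= priority <= 1, the normalisation cancels any global
    rescaling of positions, and exactly one scored region attains ratio 1.
    """
    if len(carrier_ids) == 0:
        raise ROHError("carrier set must be non-empty")
    if not regions:
        return []
    carrier_geno = genotypes.rows(carrier_ids)
    max_len = max(r.length_kb for r in regions)
    scored: list[ROHRegion] = []
    for r in regions:
        idx = np.array(r.marker_index, dtype=int)
        sub = carrier_geno[:, idx]
        if pooled_maf:
            known = sub != MISSING
            alt = int(np.where(known, sub, 0).sum())
            denom = int(2 * known.sum())
            f = alt / denom if denom else float("nan")
            maf = min(f, 1.0 - f)
        else:
            maf = float(np.nanmean(_per_snp_carrier_maf(sub)))
        priority = 2.0 * maf * r.length_kb / max_len
        scored.append(replace(r, carrier_maf=maf, priority=priority))
    kept = [
        r
        for r in scored
        if r.priority > params.min_priority
        and r.n_candidate_snps > params.min_consecutive_snps
    ]
    kept.sort(key=lambda r: (-r.priority, r.chrom, r.start_bp))
    return kept


def map_case_regions(
    genotypes: GenotypeMatrix,
    case_ids: Sequence[str],
    carrier_ids: Sequence[str],
    params: ROHParams = ROHParams(),
    allow_discordant_hom: bool = False,
    pooled_maf: bool = False,
) -> list[ROHRegion]:
    """Full mapping pass: excise removed loci, merge candidate runs, prioritise.

    Loci dropped from the analysis (missing data or monomorphic) are excised
    from the map before merging, so they thin candidate runs without
    breaking them; only analyzed non-candidate loci interrupt a run.
    """
    keep = analyzed_loci_mask(genotypes)
    sub = genotypes.subset_markers(keep)
    mask = select_candidate_loci(sub, case_ids, allow_discordant_hom=allow_discordant_hom)
    regions = merge_candidate_regions(mask, sub.markers)
    return prioritize_regions(regions, sub, carrier_ids, params=params, pooled_maf=pooled_maf)
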