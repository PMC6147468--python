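"""End-to-end discovery pipeline: simulate -> call -> map -> filter -> annotate.

``run_all`` reproduces, on one synthetic study, the complete computational
chain that isolates a recessive splice variant: Bayesian genotype calling
from read pileups, case-homozygosity region mapping with the priority
score, recessive-model variant filtering intersected with those regions,
known-variant exclusion, splice-consequence prediction for the surviving
candidate, and a small case-control exact association. All randomness flows
from the single config seed, so a fixed seed reproduces the report
byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as rio
from .cohort import GenotypeCounts, fisher_exact_association
from .config import ConfigError, RunConfig
from .genotype_model import MISSING, ReadPileup, call_genotype, genotype_posterior
from .roh import GenotypeMatrix
from .simdata import (
    known_variant_keys,
    make_toy_transcriptome,
    simulate_exome_variants,
    simulate_genotype_array,
    simulate_pedigree,
    simulate_pileups,
)
from .splice import TranscriptModel, map_g_to_c, scan_cryptic_donors, splice_consequence
from .variant_filter import VariantRecord, discover_candidates

log = logging.getLogger("rohvar")

__all__ = ["run_all", "call_variants_from_pileups", "annotate_candidate"]


def call_variants_from_pileups(
    variants: Sequence[VariantRecord],
    pileups: pd.DataFrame,
    error_rate: float,
    min_reads: int = 2,
) -> tuple[list[VariantRecord], dict[tuple[str, int], float]]:
    """Re-genotype every variant site from its pileups.

    Returns the called records plus a per-site QUAL (phred-scaled mean
    posterior of the called genotypes, capped at 99).
    """
    indexed = {
        (r.sample, r.chrom, int(r.pos)): (int(r.ref_count), int(r.alt_count))
        for r in pileups.itertuples(index=False)
    }
    called, quals = [], {}
    for v in variants:
        geno, posts = {}, []
        for s in v.genotypes:
            ref_n, alt_n = indexed.get((s, v.chrom, v.pos), (0, 0))
            post = genotype_posterior(ReadPileup(ref_n, alt_n, error_rate))
            call = call_genotype(post, min_reads=min_reads)
            if call is None:
                geno[s] = MISSING
            else:
                geno[s] = {"hom_ref": 0, "het": 1, "hom_alt": 2}[call]
                posts.append(post.posterior[call])
        called.append(replace(v, genotypes=geno))
        if posts:
            err = max(1.0 - min(posts), 1e-10)
            quals[(v.chrom, v.pos)] = round(min(-10.0 * math.log10(err), 99.0), 2)
    return called, quals


def annotate_candidate(
    variant: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    window: int = 60,
) -> Optional[dict]:
    """Splice annotation for a candidate near a donor site.

    Locates the transcript and exon whose donor region covers the variant,
    scans the exon for cryptic donors, and predicts the consequence of the
    top-ranked cryptic site. Returns None when the variant is not
    donor-proximal.
    """
    gpos = variant.pos - 1
    for tr in transcripts:
        if tr.chrom != variant.chrom:
            continue
        for i, (s, e) in enumerate(tr.exons[:-1]):
            if tr.strand == "+":
                donor_zone = range(e, e + 8)
                hit = gpos in donor_zone
            else:
                donor_zone = range(s - 8, s)
                hit = gpos in donor_zone
            if not hit:
                continue
            hgvs = map_g_to_c(gpos, tr, ref=variant.ref, alt=variant.alt)
            scan = scan_cryptic_donors(tr, i, min(window, tr.exon_lengths[i]), genome=genome)
            result = {
                "transcript": tr.id,
                "exon_index": i,
                "hgvs_c": str(hgvs),
                "hgvs_g": f"chr{tr.chrom} g.{variant.pos}{variant.ref}>{variant.alt}",
                "cryptic_candidates": scan[:5],
            }
            if scan:
                offset = scan[0][0]
                cons = splice_consequence(tr, offset, i)
                result["consequence"] = {
                    "deleted_bp": cons.deleted_bp,
                    "frameshift": cons.frameshift,
                    "ptc_transcript_pos": cons.ptc_transcript_pos,
                    "normal_protein_aa": cons.normal_protein_aa,
                    "aberrant_protein_aa": cons.aberrant_protein_aa,
                    "aberrant_tail_aa": cons.aberrant_tail_aa,
                    "nmd_candidate": cons.nmd_candidate,
                }
            return result
    return None


def _subset_samples(matrix: GenotypeMatrix, ids: Sequence[str]) -> GenotypeMatrix:
    return GenotypeMatrix(
        samples=tuple(ids), markers=matrix.markers, geno=matrix.rows(ids)
    )


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full synthetic discovery pipeline; return the report dict."""
    out = Path(config.out_dir)
    if write_outputs:
        if not out.parent.exists():
            raise ConfigError(f"RunConfig.out_dir: parent directory {out.parent} does not exist")
        out.mkdir(parents=True, exist_ok=True)
    sim = config.sim

    log.info("simulating pedigree (seed=%d)", sim.seed)
    pedigree = simulate_pedigree(sim)
    genome, transcripts = make_toy_transcriptome(sim)
    array = simulate_genotype_array(pedigree, sim)
    variants = simulate_exome_variants(pedigree, transcripts, sim, genome)
    known = known_variant_keys(variants)
    pileups = simulate_pileups(variants, sim)

    log.info("calling genotypes at %d sites", len(variants))
    called, quals = call_variants_from_pileups(
        variants, pileups, error_rate=config.error_rate, min_reads=config.min_reads
    )

    roles = pedigree.exome_roles()
    case_ids, carrier_ids, array_members = pedigree.array_cohort()
    array_cohort = _subset_samples(array, array_members)

    report_obj = discover_candidates(
        called,
        array_cohort,
        roles,
        case_ids,
        carrier_ids,
        transcripts,
        known,
        genome=genome,
        roh_params=config.roh,
        min_call_rate=config.min_call_rate,
        min_maf=config.min_maf,
    )
    log.info("stage counts: %s", report_obj.stage_counts)

    annotations = []
    for cand in report_obj.candidates:
        ann = annotate_candidate(cand, transcripts, genome, window=config.donor_scan_window)
        if ann is not None:
            annotations.append(ann)

    # within-cohort exact association of the top candidate (cases vs controls)
    association = None
    if report_obj.candidates:
        top = report_obj.candidates[0]

        def counts(ids):
            vals = [top.genotypes.get(s, MISSING) for s in sorted(ids)]
            return GenotypeCounts(
                n_hom_ref=sum(v == 0 for v in vals),
                n_het=sum(v == 1 for v in vals),
                n_hom_alt=sum(v == 2 for v in vals),
            )

        case_c, ctrl_c = counts(roles.cases), counts(roles.controls)
        try:
            p, odds = fisher_exact_association(case_c, ctrl_c, mode="allelic")
            association = {
                "mode": "allelic",
                "p_value": p,
                "odds_ratio": "inf" if math.isinf(odds) else odds,
            }
        except Exception as exc:
            association = {"mode": "allelic", "error": str(exc)}

    report = {
        "seed": sim.seed,
        "parameters": {
            "min_call_rate": config.min_call_rate,
            "min_maf": config.min_maf,
            "min_reads": config.min_reads,
            "error_rate": config.error_rate,
            "roh_min_snps": config.roh.min_consecutive_snps,
            "roh_min_priority": config.roh.min_priority,
        },
        "cohorts": {
            "exome_cases": sorted(roles.cases),
            "exome_carriers": sorted(roles.obligate_carriers),
            "exome_controls": sorted(roles.controls),
            "array_samples": list(array_members),
        },
        "stage_counts": report_obj.stage_counts,
        "regions": [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps": r.n_candidate_snps,
                "carrier_maf": round(r.carrier_maf, 6),
                "priority": round(r.priority, 6),
            }
            for r in report_obj.regions
        ],
        "candidates": [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "id": v.vid,
                "consequence": v.consequence,
            }
            for v in report_obj.candidates
        ],
        "splice_annotations": annotations,
        "association": association,
        "warnings": report_obj.warnings,
    }

    if write_outputs:
        contigs = {c: len(s) for c, s in genome.items()}
        rio.write_fasta(out / "genome.fa", genome)
        rio.write_gff3(out / "genes.gff3", transcripts)
        rio.write_fam(out / "pedigree.fam.tsv", pedigree)
        rio.write_ped_map(out / "array", array_cohort, pedigree)
        rio.write_genotype_tsv(out / "array.tsv", array_cohort)
        pu = pileups.merge(
            pd.DataFrame([(v.chrom, v.pos, v.ref, v.alt) for v in variants],
                         columns=["chrom", "pos", "ref", "alt"]).drop_duplicates(),
            on=["chrom", "pos"],
        )
        pu.to_csv(out / "pileups.tsv", sep="\t", index=False)
        rio.write_vcf(out / "truth.vcf", variants, contigs=contigs)
        rio.write_vcf(out / "calls.vcf", called, contigs=contigs, quals=quals)
        rio.write_known_tsv(out / "known.tsv", known)
        rio.write_bed(out / "regions.bed", report_obj.regions)
        rio.write_regions_tsv(out / "regions.tsv", report_obj.regions)
        pd.DataFrame(report["candidates"]).to_csv(out / "candidates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"stage": k, "n": v} for k, v in report_obj.stage_counts.items()]
        ).to_csv(out / "stage_counts.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
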