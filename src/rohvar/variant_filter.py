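"""Recessive-model exome variant filtering.

The discovery chain mirrors how a recessive Mendelian variant is isolated in
a small family study: quality filters on call rate and minor-allele
frequency, a strict segregation filter (cases homozygous-alt, obligate
carriers heterozygous or missing, controls anything but homozygous-alt),
intersection with case-shared runs of homozygosity, a functional-consequence
triage, and exclusion of variants already catalogued in the breed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import ROHParams
from .genotype_model import MISSING
from .roh import GenotypeMatrix, ROHRegion, map_case_regions
from .splice import TranscriptModel

__all__ = [
    "VariantRecord",
    "SampleRoles",
    "CandidateReport",
    "qc_filter",
    "recessive_segregation_filter",
    "intersect_roh",
    "classify_consequence",
    "exclude_known",
    "discover_candidates",
]

#: consequence precedence, most severe first
CONSEQUENCE_ORDER = (
    "splice_donor",
    "stop_gained",
    "splice_region",
    "missense",
    "synonymous",
    "other",
    "intronic",
    "intergenic",
)
#: classes carried forward as disease-candidate material
CANDIDATE_CLASSES = frozenset({"splice_donor", "stop_gained", "splice_region", "missense"})

_CODON_TABLE = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-sample genotype codes.

    ``pos`` is 1-based as printed in VCF; conversions to the package's
    0-based internal convention happen where coordinates are compared.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, int]
    vid: str = "."
    consequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FilterError(f"{self.vid}: VCF positions are 1-based")
        bad = {g for g in self.genotypes.values() if g not in (0, 1, 2, MISSING)}
        if bad:
            raise FilterError(f"{self.vid}: invalid genotype codes {sorted(bad)}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def call_rate(self) -> float:
        vals = list(self.genotypes.values())
        if not vals:
            return 0.0
        return sum(v != MISSING for v in vals) / len(vals)

    @property
    def maf(self) -> float:
        known = [v for v in self.genotypes.values() if v != MISSING]
        if not known:
            return 0.0
        f = sum(known) / (2 * len(known))
        return min(f, 1.0 - f)


@dataclass(frozen=True)
class SampleRoles:
    """Study roles within the sequenced cohort (pairwise disjoint)."""

    cases: frozenset[str]
    obligate_carriers: frozenset[str]
    controls: frozenset[str]

    def __post_init__(self) -> None:
        groups = [set(self.cases), set(self.obligate_carriers), set(self.controls)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise FilterError(f"sample role overlap: {sorted(overlap)}")


def qc_filter(
    variants: Iterable[VariantRecord],
    min_call_rate: float = 0.2,
    min_maf: float = 0.05,
) -> list[VariantRecord]:
    """Keep variants with call rate and MAF strictly above the thresholds."""
    return [v for v in variants if v.call_rate > min_call_rate and v.maf > min_maf]


def matches_recessive_pattern(genotypes: Mapping[str, int], roles: SampleRoles) -> bool:
    """Case hom-alt / carrier het-or-missing / control non-hom-alt-or-missing."""
    for s in roles.cases:
        if genotypes.get(s, MISSING) != 2:
            return False
    for s in roles.obligate_carriers:
        if genotypes.get(s, MISSING) not in (1, MISSING):
            return False
    for s in roles.controls:
        if genotypes.get(s, MISSING) not in (0, 1, MISSING):
            return False
    return True


def recessive_segregation_filter(
    variants: Iterable[VariantRecord], roles: SampleRoles
) -> list[VariantRecord]:
    """Keep variants segregating under a fully penetrant recessive model.

    Missing genotypes are tolerated in carriers and controls but not in
    cases: a case without a confirmed homozygous-alt call cannot support
    the variant.
    """
    if not roles.cases:
        raise FilterError("recessive filtering requires a non-empty case set")
    return [v for v in variants if matches_recessive_pattern(v.genotypes, roles)]


def intersect_roh(
    variants: Iterable[VariantRecord], regions: Sequence[ROHRegion]
) -> list[VariantRecord]:
    """Keep variants inside a [start_bp, end_bp) region (0-based half-open)."""
    kept = []
    for v in variants:
        p0 = v.pos - 1
        if any(r.chrom == v.chrom and r.start_bp <= p0 < r.end_bp for r in regions):
            kept.append(v)
    return kept


def _exonic_class(
    variant: VariantRecord, transcript: TranscriptModel, tpos: int
) -> str:
    strand = transcript.strand
    t_ref = variant.ref if strand == "+" else variant.ref.translate(_COMPLEMENT)
    t_alt = variant.alt if strand == "+" else variant.alt.translate(_COMPLEMENT)
    if transcript.seq[tpos] != t_ref:
        raise FilterError(
            f"{variant.chrom}:{variant.pos}: ref allele {variant.ref!r} disagrees "
            f"with transcript {transcript.id} sequence"
        )
    labels = []
    # donor-proximal exonic bases (last 3 nt of any exon with a downstream intron)
    offs = transcript.exon_t_offsets()
    for i, (off, l) in enumerate(zip(offs, transcript.exon_lengths)):
        if i < len(transcript.exons) - 1 and off + l - 3 <= tpos < off + l:
            labels.append("splice_region")
            break
    if transcript.cds_start <= tpos < transcript.cds_end:
        cpos = tpos - transcript.cds_start
        codon_i, within = divmod(cpos, 3)
        codon = transcript.cds[codon_i * 3 : codon_i * 3 + 3]
        mutated = codon[:within] + t_alt + codon[within + 1 :]
        old_aa, new_aa = _translate_codon(codon), _translate_codon(mutated)
        if old_aa == new_aa:
            labels.append("synonymous")
        elif new_aa == "*":
            labels.append("stop_gained")
        elif old_aa == "*":
            labels.append("other")  # stop-lost: outside the modelled classes
        else:
            labels.append("missense")
    else:
        labels.append("other")  # UTR
    return min(labels, key=CONSEQUENCE_ORDER.index)


def _intronic_class(transcript: TranscriptModel, gpos: int) -> Optional[str]:
    for i in range(len(transcript.exons) - 1):
        up_s, up_e = transcript.exons[i]
        dn_s, dn_e = transcript.exons[i + 1]
        if transcript.strand == "+":
            lo, hi = up_e, dn_s
            d_donor = gpos - up_e + 1
            d_acceptor = dn_s - gpos
        else:
            lo, hi = dn_e, up_s
            d_donor = up_s - gpos
            d_acceptor = gpos - dn_e + 1
        if not lo <= gpos < hi:
            continue
        if d_donor in (1, 2):
            return "splice_donor"
        if 3 <= d_donor <= 8 or 3 <= d_acceptor <= 8:
            return "splice_region"
        return "intronic"
    return None


def classify_consequence(
    variant: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    genome: Optional[Mapping[str, str]] = None,
) -> str:
    """Most severe consequence of an SNV across the supplied transcripts.

    Precedence: splice_donor > stop_gained > splice_region > missense >
    synonymous > other > intronic > intergenic. Splice-donor means intronic
    +1/+2 past an exon 3' end; splice-region covers the exonic last 3 nt of
    a junctioned exon and intronic +3..+8 / -8..-3; coding classes come from
    codon substitution. The ref allele is checked against the transcript
    (exonic) or genome (intronic) sequence and a disagreement is an error.
    """
    gpos = variant.pos - 1
    labels = []
    for tr in transcripts:
        if tr.chrom != variant.chrom:
            continue
        lo, hi = tr.gene_span
        if not lo <= gpos < hi:
            continue
        tpos = tr.g_to_t(gpos)
        if tpos is not None:
            labels.append(_exonic_class(variant, tr, tpos))
        else:
            if genome is not None and variant.chrom in genome:
                base = genome[variant.chrom][gpos].upper()
                if base != variant.ref:
                    raise FilterError(
                        f"{variant.chrom}:{variant.pos}: ref allele {variant.ref!r} "
                        f"disagrees with genome sequence {base!r}"
                    )
            label = _intronic_class(tr, gpos)
            if label is not None:
                labels.append(label)
    if not labels:
        return "intergenic"
    return min(labels, key=CONSEQUENCE_ORDER.index)


def exclude_known(
    variants: Iterable[VariantRecord],
    known: Iterable[tuple[str, int, str, str]],
) -> list[VariantRecord]:
    """Remove variants whose (chrom, pos, ref, alt) is in the known set."""
    known = set(known)
    return [v for v in variants if v.key not in known]


@dataclass
class CandidateReport:
    stage_counts: dict[str, int] = field(default_factory=dict)
    regions: list[ROHRegion] = field(default_factory=list)
    candidates: list[VariantRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def discover_candidates(
    variants: Sequence[VariantRecord],
    array_genotypes: GenotypeMatrix,
    roles: SampleRoles,
    array_case_ids: Sequence[str],
    array_carrier_ids: Sequence[str],
    transcripts: Sequence[TranscriptModel],
    known: Iterable[tuple[str, int, str, str]],
    genome: Optional[Mapping[str, str]] = None,
    roh_params: ROHParams = ROHParams(),
    min_call_rate: float = 0.2,
    min_maf: float = 0.05,
) -> CandidateReport:
    """Run the full filtering chain and report per-stage survivor counts.

    Stages: qc -> recessive segregation -> ROH mapping/intersection ->
    consequence triage (candidate classes only) -> known-variant exclusion.
    Each stage is a pure subset operation, so counts are non-increasing.
    """
    report = CandidateReport()
    report.stage_counts["input"] = len(variants)

    def stage(name, fn, vs):
        try:
            out = fn(vs)
        except Exception as exc:  # annotate with the failing stage
            raise FilterError(f"stage {name!r} failed: {exc}") from exc
        report.stage_counts[name] = len(out)
        return out

    vs = stage("qc", lambda v: qc_filter(v, min_call_rate, min_maf), list(variants))
    vs = stage("recessive", lambda v: recessive_segregation_filter(v, roles), vs)
    try:
        regions = map_case_regions(
            array_genotypes, array_case_ids, array_carrier_ids, params=roh_params
        )
    except Exception as exc:
        raise FilterError(f"stage 'roh' failed: {exc}") from exc
    report.regions = regions
    report.stage_counts["roh_regions"] = len(regions)
    vs = stage("roh_intersect", lambda v: intersect_roh(v, regions), vs)

    def annotate(v: Sequence[VariantRecord]) -> list[VariantRecord]:
        out = []
        for var in v:
            term = classify_consequence(var, transcripts, genome=genome)
            if term in CANDIDATE_CLASSES:
                out.append(replace(var, consequence=term))
        return out

    vs = stage("consequence", annotate, vs)
    vs = stage("known_exclusion", lambda v: exclude_known(v, known), vs)
    report.candidates = sorted(vs, key=lambda v: (v.chrom, v.pos))
    if not report.candidates:
        report.warnings.append(
            "no candidate variants remain after known-variant exclusion"
        )
    return report
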