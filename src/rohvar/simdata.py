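"""Synthetic study generator: pedigree, SNP array, transcriptome, exome, pileups.

Emulates the design of a recessive-disease mapping study in a closed breed:
a lethal recessive allele descends from one shared carrier ancestor through
two related lineages; a final carrier x carrier mating produces affected
homozygotes whose parents are obligate carriers; unrelated controls are
added for sequencing. The SNP array carries an implanted autozygous region:
every causal-allele copy travels with the ancestor's marker haplotype across
the configured region, so cases are homozygous for one shared haplotype
there and obligate carriers are heterozygous for it.

The toy transcriptome contains one designated splice-reporter gene, a
*synthetic* stand-in for the canine INPP5E transcript: 10 exons, a 613-aa
canonical protein whose exon 9 ends at coding position 1572, a strong native
donor (GTAAGT) whose +5 base is the causal G>A target, and an exonic cryptic
GT placed ``cryptic_offset`` nt upstream of the exon 9 donor. With the
default offset of 50 the coding sequence is additionally engineered so that
cryptic-donor use yields a 594-aa frameshift protein whose last 85 residues
are aberrant - the consequence geometry of a donor-site ciliopathy variant -
while remaining an ordinary random coding sequence everywhere else.

All outputs are deterministic functions of ``SimConfig.seed``; each
component draws from its own seed stream so the pieces can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .genotype_model import MISSING
from .roh import GenotypeMatrix, MarkerMap
from .splice import TranscriptModel
from .variant_filter import SampleRoles, VariantRecord, matches_recessive_pattern

__all__ = [
    "Individual",
    "Pedigree",
    "simulate_pedigree",
    "simulate_genotype_array",
    "make_toy_transcriptome",
    "simulate_exome_variants",
    "simulate_pileups",
    "known_variant_keys",
    "DESIGNATED_TRANSCRIPT",
    "DONOR_EXON_INDEX",
]

#: transcript id of the designated splice-reporter gene (synthetic stand-in)
DESIGNATED_TRANSCRIPT = "INPP5E_like.t1"
#: 0-based index of the exon whose donor the causal variant disrupts (exon 9)
DONOR_EXON_INDEX = 8

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_AA = {}


def _aa(codon: str) -> str:
    if not _AA:
        from Bio.Data.CodonTable import standard_dna_table

        _AA.update(standard_dna_table.forward_table)
        for s in standard_dna_table.stop_codons:
            _AA[s] = "*"
    return _AA[codon]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per simulator component."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            return c


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    id: str
    sire: Optional[str]
    dam: Optional[str]
    sex: str               # 'M' / 'F'
    role: str              # case / obligate_carrier / control / unknown
    causal_gt: int         # copies of the causal allele (0/1/2)
    generation: int


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            for p in (ind.sire, ind.dam):
                if p is not None and p not in seen:
                    raise ConfigError(f"pedigree: parent {p} of {ind.id} not defined earlier")
            if (ind.sire is None) != (ind.dam is None):
                raise ConfigError(f"pedigree: {ind.id} has exactly one parent")
            seen.add(ind.id)

    def __iter__(self):
        return iter(self.individuals)

    def by_id(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.id == iid:
                return ind
        raise KeyError(iid)

    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    def with_role(self, role: str) -> list[Individual]:
        return [i for i in self.individuals if i.role == role]

    def cases(self) -> list[Individual]:
        return self.with_role("case")

    def obligate_carriers(self) -> list[Individual]:
        return self.with_role("obligate_carrier")

    def controls(self) -> list[Individual]:
        return self.with_role("control")

    def exome_roles(self, n_cases: int = 2) -> SampleRoles:
        """Sequenced subset mirroring the study: 2 cases, 2 carriers, controls."""
        cases = [i.id for i in self.cases()][:n_cases]
        carriers = [i.id for i in self.obligate_carriers()][:2]
        controls = [i.id for i in self.controls()]
        if len(cases) < n_cases or len(carriers) < 2 or not controls:
            raise ConfigError("pedigree lacks the case/carrier/control structure for an exome cohort")
        return SampleRoles(
            cases=frozenset(cases),
            obligate_carriers=frozenset(carriers),
            controls=frozenset(controls),
        )

    def array_cohort(self) -> tuple[list[str], list[str], list[str]]:
        """(case ids, carrier ids, all genotyped ids) for the SNP array.

        Mirrors the array design of two affected, one unaffected full
        sibling, and four close relatives (the obligate-carrier parents and
        their own parents where present).
        """
        cases = [i.id for i in self.cases()][:2]
        if len(cases) < 2:
            raise ConfigError("array cohort needs at least two cases")
        carriers = [i.id for i in self.obligate_carriers()][:2]
        case0 = self.by_id(cases[0])
        sibs = [
            i.id
            for i in self.individuals
            if i.role != "case"
            and i.sire == case0.sire
            and i.dam == case0.dam
            and i.sire is not None
        ]
        relatives = list(carriers)
        for cid in carriers:
            parent = self.by_id(cid)
            for p in (parent.sire, parent.dam):
                if p is not None and p not in relatives and len(relatives) < 4:
                    # prefer the carrier grandparent lineage
                    if self.by_id(p).causal_gt >= 1:
                        relatives.append(p)
        for cid in carriers:
            parent = self.by_id(cid)
            for p in (parent.sire, parent.dam):
                if p is not None and p not in relatives and len(relatives) < 4:
                    relatives.append(p)
        members = cases + sibs[:1] + relatives
        return cases, carriers, members


def _drop_child(rng: np.random.Generator, sire_gt: int, dam_gt: int) -> int:
    def transmit(gt: int) -> int:
        if gt == 0:
            return 0
        if gt == 2:
            return 1
        return int(rng.integers(0, 2))

    return transmit(sire_gt) + transmit(dam_gt)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Build a multi-generation pedigree segregating a recessive lethal allele.

    One founder is the shared carrier ancestor; two carrier lineages descend
    from it and meet in a final carrier x carrier mating whose litter is
    conditioned (by litter resampling, the in-silico analogue of family
    ascertainment) to contain at least two affected homozygotes. Affected
    individuals never reproduce. With ``n_generations == 0`` only founders
    are returned.
    """
    rng = _rng(config, 0)
    inds: list[Individual] = []

    def add(iid, sire, dam, sex, gt, gen, role="unknown"):
        ind = Individual(iid, sire, dam, sex, role, gt, gen)
        inds.append(ind)
        return ind

    for i in range(config.n_founders):
        add(f"F{i + 1}", None, None, "M" if i % 2 == 0 else "F", 1 if i == 0 else 0, 0)
    if config.n_generations == 0:
        return Pedigree(inds)

    def litter(sire: Individual, dam: Individual, gen: int, need, tries: int = 1000):
        """Gene-drop a litter, resampling until ``need(children_gts)`` holds."""
        for _ in range(tries):
            gts = [_drop_child(rng, sire.causal_gt, dam.causal_gt) for _ in range(config.litter_size)]
            if need(gts):
                sexes = ["M" if rng.integers(0, 2) else "F" for _ in gts]
                return gts, sexes
        raise ConfigError("pedigree: litter resampling did not satisfy the design")

    counter = [0]

    def fresh_spouse(sex: str, gen: int) -> Individual:
        counter[0] += 1
        return add(f"S{gen}_{counter[0]}", None, None, sex, 0, gen)

    # generation 1: ancestor x co-founder, need two carriers to head the lineages
    ancestor, cofounder = inds[0], inds[1]
    gts, sexes = litter(ancestor, cofounder, 1, lambda g: sum(x == 1 for x in g) >= 2)
    gen1 = [
        add(f"G1_{j + 1}", ancestor.id, cofounder.id, sexes[j], gts[j], 1)
        for j in range(len(gts))
    ]
    carriers1 = [c for c in gen1 if c.causal_gt == 1]
    head_a, head_b = carriers1[0], carriers1[1]
    head_a.sex, head_b.sex = "M", "F"

    # intermediate generations: each lineage head mates an unrelated spouse
    for gen in range(2, config.n_generations):
        new_heads = []
        for head in (head_a, head_b):
            spouse = fresh_spouse("F" if head.sex == "M" else "M", gen)
            sire, dam = (head, spouse) if head.sex == "M" else (spouse, head)
            gts, sexes = litter(sire, dam, gen, lambda g: any(x == 1 for x in g))
            kids = [
                add(f"G{gen}_{len(inds)}", sire.id, dam.id, sexes[j], gts[j], gen)
                for j in range(len(gts))
            ]
            new_heads.append(next(k for k in kids if k.causal_gt == 1))
        head_a, head_b = new_heads
        head_a.sex, head_b.sex = "M", "F"

    if config.n_generations >= 2:
        # final carrier x carrier mating; ascertainment: >= 2 affected pups
        gen = config.n_generations
        sire, dam = head_a, head_b
        gts, sexes = litter(sire, dam, gen, lambda g: sum(x == 2 for x in g) >= 2)
        for j in range(len(gts)):
            role = "case" if gts[j] == 2 else "unknown"
            add(f"G{gen}_{len(inds)}", sire.id, dam.id, sexes[j], gts[j], gen, role)
        sire.role = dam.role = "obligate_carrier"

    for i in range(config.n_controls):
        add(f"C{i + 1}", None, None, "M" if i % 2 == 0 else "F", 0, config.n_generations, "control")
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# SNP array
# ---------------------------------------------------------------------------


def marker_map(config: SimConfig) -> MarkerMap:
    rows = []
    m = config.markers_per_chromosome()
    for chrom in config.chromosome_names():
        for j in range(m):
            pos = (j + 1) * config.marker_spacing_bp
            rows.append((chrom, pos, f"chr{chrom}_snp{j + 1}"))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id"]))


def simulate_genotype_array(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop marker haplotypes through the pedigree and implant autozygosity.

    Founder haplotypes are i.i.d. Bernoulli(founder_allele_freq) per marker;
    transmission recombines between adjacent markers with probability
    ``recomb_rate``. Afterwards every causal-allele copy is overwritten with
    the ancestor's haplotype across the causal region, guaranteeing that all
    cases are homozygous and allele-identical there. Missing genotypes are
    injected at ``missing_rate``.
    """
    rng = _rng(config, 1)
    mmap = marker_map(config)
    chroms = mmap.table["chrom"].to_numpy()
    pos = mmap.table["pos"].to_numpy()
    n = len(mmap)
    region_chrom, region_start, region_end = config.causal_region
    region_idx = np.where(
        (chroms == region_chrom) & (pos >= region_start) & (pos < region_end)
    )[0]
    if region_idx.size == 0:
        raise ConfigError("SimConfig.causal_region: region contains no simulated markers")

    new_chrom = np.concatenate(([True], chroms[1:] != chroms[:-1]))
    haplotypes: dict[str, np.ndarray] = {}  # id -> (2, n) uint8
    causal_gt = {ind.id: ind.causal_gt for ind in pedigree}
    ancestor_hap: Optional[np.ndarray] = None

    def transmit(parent: np.ndarray) -> np.ndarray:
        switch = rng.random(n) < config.recomb_rate
        switch |= new_chrom & (rng.random(n) < 0.5)
        which = np.cumsum(switch) % 2
        return parent[which, np.arange(n)]

    # Invariant: every haplotype slot that carries the causal allele (the
    # first `causal_gt` slots of an individual) holds the ancestor haplotype
    # across the region. A gamete transmitting the causal allele therefore
    # copies its parent's slot-0 region segment, which keeps transmission
    # Mendelian marker by marker while implanting shared autozygosity.
    for ind in pedigree:
        if ind.sire is None:
            haps = (rng.random((2, n)) < config.founder_allele_freq).astype(np.uint8)
            if ind.causal_gt >= 1 and ancestor_hap is None:
                ancestor_hap = haps[0, region_idx].copy()
            for c in range(ind.causal_gt):
                haps[c, region_idx] = ancestor_hap
        else:
            gametes = {
                "sire": transmit(haplotypes[ind.sire]),
                "dam": transmit(haplotypes[ind.dam]),
            }
            carrying: list[str] = []
            if ind.causal_gt == 2:
                carrying = ["sire", "dam"]
            elif ind.causal_gt == 1:
                options = [p for p in ("sire", "dam") if causal_gt[getattr(ind, p)] >= 1]
                carrying = [options[int(rng.integers(0, len(options)))]]
            for p in carrying:
                gametes[p][region_idx] = ancestor_hap
            order = carrying + [p for p in ("sire", "dam") if p not in carrying]
            haps = np.stack([gametes[p] for p in order])
        haplotypes[ind.id] = haps

    samples = tuple(pedigree.ids())
    geno = np.stack([haplotypes[s].sum(axis=0) for s in samples]).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING
    return GenotypeMatrix(samples=samples, markers=mmap, geno=geno)


# ---------------------------------------------------------------------------
# toy transcriptome
# ---------------------------------------------------------------------------

# designated-gene geometry (coding positions are 1-based HGVS c.)
_N_AA = 613                      # canonical protein length
_CDS_LEN = (_N_AA + 1) * 3       # 1842 nt including the stop codon
_EXON9_CEND = 1572               # exon 9 ends at c.1572
_EXON_CODING = (90, 187, 187, 187, 187, 187, 188, 188, 171, 270)
_UTR5, _UTR3 = 60, 120
_DEFAULT_OFFSET = 50             # cryptic donor 50 nt upstream of the exon 9 end
_MATCH_PREFIX = 509              # engineered canonical/aberrant identity prefix
_ABERRANT_AA = 594               # engineered aberrant protein length
_SCRUB_WINDOW = 60               # GT-free window at the exon 9 3' end

assert sum(_EXON_CODING) == _CDS_LEN and sum(_EXON_CODING[:9]) == _EXON9_CEND


def _draw_codon(rng, *, prev: str, not_aa: Optional[str] = None, no_gt: bool = False) -> str:
    for _ in range(10_000):
        c = _random_codon(rng)
        if not_aa is not None and _aa(c) == not_aa:
            continue
        if no_gt and "GT" in prev[-1:] + c:
            continue
        return c
    raise ConfigError("codon engineering failed to satisfy constraints")


def _engineer_frameshift_cds(rng: np.random.Generator) -> str:
    """Random 1842-nt CDS engineered for the default cryptic-donor geometry.

    Deleting the terminal 50 nt of exon 9 (coding 1523-1572) from the mRNA
    must give a 594-aa protein identical to the canonical 613-aa protein for
    its first 509 residues and aberrant for the last 85; the deleted segment
    begins with the cryptic GT, and the last 60 nt of exon 9 contain no
    other GT dinucleotide. Achieved by fixing the handful of constrained
    positions and drawing everything else as random non-stop codons.
    """
    nt = [""] * (_CDS_LEN + 1)  # 1-based

    def put(start: int, s: str) -> None:
        for k, ch in enumerate(s):
            nt[start + k] = ch

    put(1, "ATG")
    # free prefix codons 2..507; scrub GT inside the window tail (c.1513-1521)
    for c in range(2, 508):
        start = 3 * c - 2
        prev = nt[start - 1]
        codon = _draw_codon(rng, prev=prev, no_gt=start >= _EXON9_CEND - _SCRUB_WINDOW - 2)
        put(start, codon)
    put(1522, "CGT")      # codon 508; the GT at c.1523-1524 is the cryptic donor
    put(1525, "AAA")      # codon 509
    put(1573, "GCA")      # codon 525: frameshifted codon 508 reads CGC (Arg, matches)
    put(1576, "AA")       # frameshifted codon 509 reads AAA (Lys, matches)

    # frameshifted codons 510..594 (canonical nt 1578..1832), then the PTC
    shifted: dict[int, str] = {}
    for k in range(510, 595):
        start = 3 * k + 48
        prev2 = "AA" if k == 510 else shifted[k - 1][1:]
        if 526 <= k:
            canon_k = (
                "AA" + shifted[510][0]
                if k == 526
                else shifted[k - 17][1:] + shifted[k - 16][0]
            )
            avoid = _aa(canon_k)
        elif k == 525:
            avoid = "A"
        else:
            avoid = None
        for _ in range(10_000):
            cand = _random_codon(rng)
            if avoid is not None and _aa(cand) == avoid:
                continue
            if prev2 + cand[0] in _STOPS:
                continue
            break
        else:
            raise ConfigError("frameshift engineering failed")
        shifted[k] = cand
        put(start, cand)
    put(3 * 595 + 48, "TAA")  # aberrant-frame PTC at codon 595 (nt 1833-1835)
    nt[1836] = "ACGT"[int(rng.integers(0, 4))]
    # codon 613: C-terminus must differ from the aberrant protein's last
    # residue so the engineered tail is not shortened by a chance match
    put(1837, _draw_codon(rng, prev=nt[1836], not_aa=_aa(shifted[594])))
    put(1840, "TAA")                            # canonical stop

    # deleted-region codons 510..524: mismatch the shifted frame, stay GT-free
    for k in range(510, 525):
        start = 3 * k - 2
        codon = _draw_codon(rng, prev=nt[start - 1], not_aa=_aa(shifted[k]), no_gt=True)
        put(start, codon)

    cds = "".join(nt[1:])
    _verify_engineered(cds)
    return cds


def _translate_to_stop(seq: str) -> str:
    prot = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            return "".join(prot)
        prot.append(_aa(codon))
    raise ConfigError("no stop codon found")


def _verify_engineered(cds: str) -> None:
    assert len(cds) == _CDS_LEN
    canonical = _translate_to_stop(cds)
    assert len(canonical) == _N_AA, len(canonical)
    aberrant_seq = cds[: _EXON9_CEND - _DEFAULT_OFFSET] + cds[_EXON9_CEND:]
    aberrant = _translate_to_stop(aberrant_seq)
    assert len(aberrant) == _ABERRANT_AA, len(aberrant)
    match = 0
    for a, b in zip(aberrant, canonical):
        if a != b:
            break
        match += 1
    assert match == _MATCH_PREFIX, match
    assert aberrant[-1] != canonical[-1]  # no chance C-terminal suffix match
    window = cds[_EXON9_CEND - _SCRUB_WINDOW : _EXON9_CEND]
    gt_at = [i for i in range(len(window) - 1) if window[i : i + 2] == "GT"]
    assert gt_at == [_SCRUB_WINDOW - _DEFAULT_OFFSET], gt_at


def _generic_reporter_cds(rng: np.random.Generator, offset: int) -> str:
    """Reporter CDS with a cryptic GT at an arbitrary offset (no tail engineering).

    The scrub window at the exon 9 3' end is drawn from a T-free alphabet
    (codons over {A,C,G} can neither be stops nor contain GT), then the
    single cryptic GT is planted at the requested offset.
    """
    no_t = "ACG"
    win_lo = _EXON9_CEND - _SCRUB_WINDOW  # 1-based coding position of window start - 1
    codons = ["ATG"]
    for c in range(2, _N_AA + 1):
        start = 3 * c - 2
        if start + 2 >= win_lo and start <= _EXON9_CEND:
            codons.append("".join(no_t[int(rng.integers(0, 3))] for _ in range(3)))
        else:
            codons.append(_random_codon(rng))
    codons.append("TAA")
    cds = list("".join(codons))
    j = _EXON9_CEND - offset  # 0-based index of the planted G
    cds[j], cds[j + 1] = "G", "T"
    if (j + 1) % 3 == 0:
        cds[j + 2] = "C"  # T starts a codon: force TC?, never a stop
    out = "".join(cds)
    if len(_translate_to_stop(out)) != _N_AA:
        raise ConfigError("generic reporter CDS construction failed")
    return out


@dataclass
class _GenePlan:
    tid: str
    chrom: str
    start: int
    strand: str
    exon_pieces: list[str]      # transcript order
    intron_pieces: list[str]
    cds_start: int              # transcript coords
    cds_end: int


def _plan_to_transcript(plan: _GenePlan) -> tuple[TranscriptModel, str]:
    """Materialise a gene plan into a TranscriptModel and its genomic sequence."""
    pre = []
    exon_pre: list[tuple[int, int]] = []
    cursor = 0
    for i, ex in enumerate(plan.exon_pieces):
        exon_pre.append((cursor, cursor + len(ex)))
        pre.append(ex)
        cursor += len(ex)
        if i < len(plan.intron_pieces):
            pre.append(plan.intron_pieces[i])
            cursor += len(plan.intron_pieces[i])
    pre_seq = "".join(pre)
    if plan.strand == "+":
        exons = tuple((plan.start + s, plan.start + e) for s, e in exon_pre)
        gseq = pre_seq
    else:
        L = len(pre_seq)
        exons = tuple((plan.start + L - e, plan.start + L - s) for s, e in exon_pre)
        comp = str.maketrans("ACGT", "TGCA")
        gseq = pre_seq.translate(comp)[::-1]
    tr = TranscriptModel(
        id=plan.tid,
        chrom=plan.chrom,
        strand=plan.strand,
        exons=exons,
        cds_start=plan.cds_start,
        cds_end=plan.cds_end,
        seq="".join(plan.exon_pieces),
    )
    tr.validate_coding()
    return tr, gseq


def _designated_gene_plan(rng: np.random.Generator, config: SimConfig, chrom: str, start: int) -> _GenePlan:
    offset = config.cryptic_offset
    if offset >= _EXON_CODING[8]:
        raise ConfigError("SimConfig.cryptic_offset: must be smaller than the reporter exon length")
    cds = (
        _engineer_frameshift_cds(rng)
        if offset == _DEFAULT_OFFSET
        else _generic_reporter_cds(rng, offset)
    )
    pieces, acc = [], 0
    for i, l in enumerate(_EXON_CODING):
        chunk = cds[acc : acc + l]
        acc += l
        if i == 0:
            chunk = _random_seq(rng, _UTR5) + chunk
        if i == len(_EXON_CODING) - 1:
            chunk = chunk + _random_seq(rng, _UTR3)
        pieces.append(chunk)
    introns = []
    for i in range(len(_EXON_CODING) - 1):
        body = _random_seq(rng, int(rng.integers(250, 450)))
        head = "GTAAGT" if i == DONOR_EXON_INDEX else "GT" + _random_seq(rng, 4)
        introns.append(head + body + "AG")
    return _GenePlan(
        tid=DESIGNATED_TRANSCRIPT,
        chrom=chrom,
        start=start,
        strand="+",
        exon_pieces=pieces,
        intron_pieces=introns,
        cds_start=_UTR5,
        cds_end=_UTR5 + _CDS_LEN,
    )


def _background_gene_plan(
    rng: np.random.Generator, tid: str, chrom: str, start: int, strand: str
) -> _GenePlan:
    n_exons = int(rng.integers(3, 6))
    coding = [int(rng.integers(30, 60)) * 3 for _ in range(n_exons)]
    n_codons = sum(coding) // 3
    cds = "ATG" + "".join(_random_codon(rng) for _ in range(n_codons - 2)) + "TAA"
    pieces, acc = [], 0
    for i, l in enumerate(coding):
        chunk = cds[acc : acc + l]
        acc += l
        if i == 0:
            chunk = _random_seq(rng, 30) + chunk
        if i == n_exons - 1:
            chunk = chunk + _random_seq(rng, 30)
        pieces.append(chunk)
    introns = [
        "GT" + _random_seq(rng, 4) + _random_seq(rng, int(rng.integers(150, 400))) + "AG"
        for _ in range(n_exons - 1)
    ]
    return _GenePlan(
        tid=tid,
        chrom=chrom,
        start=start,
        strand=strand,
        exon_pieces=pieces,
        intron_pieces=introns,
        cds_start=30,
        cds_end=30 + sum(coding),
    )


def make_toy_transcriptome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome plus gene models; the designated reporter sits in the causal region.

    Returns ``(genome, transcripts)`` where ``genome`` maps chromosome name
    to sequence. ``n_region_genes`` genes (including the reporter) are laid
    out inside the causal region so that recessive decoy variants have host
    genes; the remaining genes are spread over all chromosomes. Every intron
    starts GT and ends AG and every CDS is ATG..stop with no internal stop.
    """
    rng = _rng(config, 2)
    L = config.chromosome_length()
    genome = {c: bytearray(_random_seq(rng, L), "ascii") for c in config.chromosome_names()}
    region_chrom, region_start, region_end = config.causal_region

    plans: list[_GenePlan] = []
    slot = (region_end - region_start) // config.n_region_genes
    designated_slot = config.n_region_genes // 2
    gene_no = 0
    for k in range(config.n_region_genes):
        start = region_start + k * slot + 500
        if k == designated_slot:
            plans.append(_designated_gene_plan(rng, config, region_chrom, start))
        else:
            gene_no += 1
            plans.append(
                _background_gene_plan(rng, f"GENE{gene_no}.t1", region_chrom, start, "+")
            )
    n_background = config.n_genes - config.n_region_genes
    cursors = {c: 20_000 for c in config.chromosome_names()}
    chrom_cycle = config.chromosome_names()
    for k in range(n_background):
        chrom = chrom_cycle[k % len(chrom_cycle)]
        start = cursors[chrom]
        if chrom == region_chrom and region_start - 20_000 <= start < region_end + 5_000:
            start = region_end + 5_000
        gene_no += 1
        strand = "-" if gene_no % 5 == 0 else "+"
        plans.append(_background_gene_plan(rng, f"GENE{gene_no}.t1", chrom, start, strand))
        gene_len = sum(len(p) for p in plans[-1].exon_pieces) + sum(
            len(p) for p in plans[-1].intron_pieces
        )
        cursors[chrom] = start + gene_len + 15_000

    transcripts = []
    for plan in plans:
        tr, gseq = _plan_to_transcript(plan)
        lo, hi = tr.gene_span
        if hi > L:
            raise ConfigError("gene placement exceeds chromosome length")
        genome[plan.chrom][lo:hi] = gseq.encode()
        transcripts.append(tr)
    return {c: bytes(b).decode() for c, b in genome.items()}, transcripts


# ---------------------------------------------------------------------------
# exome variants
# ---------------------------------------------------------------------------


def _hwe_genotypes(rng: np.random.Generator, samples: Sequence[str], q: float) -> dict[str, int]:
    return {
        s: int((rng.random() < q) + (rng.random() < q))
        for s in samples
    }


def simulate_exome_variants(
    pedigree: Pedigree,
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
    genome: dict[str, str],
) -> list[VariantRecord]:
    """Variant table for the sequenced cohort: causal + decoys + background.

    Exactly one causal splice-donor-region variant (the +5 G>A of the
    reporter's exon 9 donor) carries the pedigree's causal-allele genotypes;
    ``n_decoy_recessive`` decoys inside the causal region share that
    genotype vector (they ride the same autozygous haplotype) and are
    flagged as previously known via their ids; background variants draw
    Hardy-Weinberg genotypes and are redrawn whenever they would satisfy the
    recessive segregation pattern, so the number of recessive-compatible
    variants is exactly 1 + n_decoy_recessive by construction.
    """
    if not transcripts:
        raise ConfigError("simulate_exome_variants: zero transcripts supplied")
    from .variant_filter import classify_consequence

    rng = _rng(config, 3)
    roles = pedigree.exome_roles()
    samples = sorted(roles.cases) + sorted(roles.obligate_carriers) + sorted(roles.controls)
    causal_vector = {s: pedigree.by_id(s).causal_gt for s in samples}

    designated = next(t for t in transcripts if t.id == DESIGNATED_TRANSCRIPT)
    donor_exon_end = designated.exons[DONOR_EXON_INDEX][1]
    causal_gpos = donor_exon_end + 4  # donor +5, 0-based
    region_chrom, region_start, region_end = config.causal_region
    ref = genome[designated.chrom][causal_gpos]
    variants = [
        VariantRecord(
            chrom=designated.chrom,
            pos=causal_gpos + 1,
            ref=ref,
            alt="A" if ref != "A" else "G",
            genotypes=dict(causal_vector),
            vid="causal",
        )
    ]
    used = {(designated.chrom, causal_gpos)}

    region_transcripts = [
        t
        for t in transcripts
        if t.chrom == region_chrom and region_start <= t.gene_span[0] < region_end
    ]
    n_missense = config.n_decoy_recessive - config.n_decoy_recessive // 2
    wanted = ["missense"] * n_missense + ["splice_region"] * (config.n_decoy_recessive // 2)
    for i, target in enumerate(wanted):
        host = region_transcripts[i % len(region_transcripts)]
        for _ in range(10_000):
            lo, hi = host.gene_span
            gpos = int(rng.integers(lo, hi))
            if (host.chrom, gpos) in used:
                continue
            ref = genome[host.chrom][gpos]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            probe = VariantRecord(
                chrom=host.chrom, pos=gpos + 1, ref=ref, alt=alt,
                genotypes=dict(causal_vector), vid=f"known{i + 1}",
            )
            try:
                term = classify_consequence(probe, [host], genome=genome)
            except Exception:
                continue
            if term == target:
                used.add((host.chrom, gpos))
                variants.append(probe)
                break
        else:
            raise ConfigError(f"could not place a {target} decoy variant")

    n_background = config.n_exome_variants - len(variants)
    for i in range(n_background):
        for _ in range(10_000):
            host = transcripts[int(rng.integers(0, len(transcripts)))]
            lo, hi = host.gene_span
            gpos = int(rng.integers(lo, hi))
            if (host.chrom, gpos) in used:
                continue
            ref = genome[host.chrom][gpos]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            break
        else:
            raise ConfigError("could not place a background variant")
        used.add((host.chrom, gpos))
        kind = rng.random()
        for _ in range(10_000):
            if kind < 0.10:
                geno = _hwe_genotypes(rng, samples, float(rng.uniform(0.001, 0.04)))
            elif kind < 0.15:
                geno = _hwe_genotypes(rng, samples, float(rng.uniform(0.05, 0.45)))
                for s in samples:
                    if rng.random() < 0.8:
                        geno[s] = MISSING
            else:
                geno = _hwe_genotypes(rng, samples, float(rng.uniform(0.05, 0.45)))
            if not matches_recessive_pattern(geno, roles):
                break
        else:
            raise ConfigError("could not draw non-recessive background genotypes")
        variants.append(
            VariantRecord(
                chrom=host.chrom, pos=gpos + 1, ref=ref, alt=alt,
                genotypes=geno, vid=f"var{i + 1}",
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def known_variant_keys(variants: Sequence[VariantRecord]) -> set[tuple[str, int, str, str]]:
    """Keys of the internally flagged previously-known decoys."""
    return {v.key for v in variants if v.vid.startswith("known")}


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def simulate_pileups(variants: Sequence[VariantRecord], config: SimConfig) -> pd.DataFrame:
    """Read pileups per (sample, site) from Poisson depth and symmetric error.

    True genotype 0/1/2 gives per-read alternate probability eps, 0.5,
    1 - eps; a missing true genotype is modelled as capture dropout (depth
    0). Columns: sample, chrom, pos (1-based), ref_count, alt_count.
    """
    rng = _rng(config, 4)
    eps = config.base_error_rate
    p_alt = {0: eps, 1: 0.5, 2: 1.0 - eps}
    rows = []
    for v in variants:
        for s in sorted(v.genotypes):
            gt = v.genotypes[s]
            if gt == MISSING:
                depth = 0
            else:
                depth = int(rng.poisson(config.pileup_depth_mean))
            alt = int(rng.binomial(depth, p_alt[gt])) if depth else 0
            rows.append((s, v.chrom, v.pos, depth - alt, alt))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref_count", "alt_count"])
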