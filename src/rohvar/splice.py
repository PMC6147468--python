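"""Transcript models and splice-consequence prediction.

The central object is :class:`TranscriptModel`, an exon/CDS description of a
protein-coding transcript on either strand. On top of it this module provides

* genomic <-> HGVS c. coordinate mapping (``map_g_to_c`` / ``map_c_to_g``),
* a cryptic splice-donor scan over the 3' end of an exon, scored by IUPAC
  consensus match to the canonical donor 9-mer MAG|GTRAGT,
* :func:`splice_consequence`, which removes the terminal nucleotides of an
  exon from the spliced mRNA (the effect of cryptic-donor activation),
  re-translates, and reports frameshift/premature-stop geometry, and
* a global pairwise transcript alignment used to localise the deleted block.

A weakened native donor typically hands splicing to the strongest nearby
exonic GT; the deletion it causes is ``offset`` nt, so a frameshift arises
whenever ``offset % 3 != 0`` and usually terminates translation early.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "HgvsC",
    "SpliceConsequence",
    "map_g_to_c",
    "map_c_to_g",
    "scan_cryptic_donors",
    "splice_consequence",
    "align_transcripts",
]

_STOPS = {"TAA", "TAG", "TGA"}

# IUPAC donor consensus, positions -3..-1 (exonic) and +1..+6 (intronic).
_DONOR_CONSENSUS = "MAGGTRAGT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "N": "ACGT",
}


class SpliceError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced protein-coding transcript.

    ``exons`` are genomic 0-based half-open intervals given in 5'->3'
    transcript order (for minus-strand transcripts genomic coordinates
    therefore descend). ``seq`` is the spliced transcript sequence on the
    coding strand; ``cds_start``/``cds_end`` delimit the CDS (ATG..stop,
    stop included) in transcript coordinates, 0-based half-open.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SpliceError(f"{self.id}: strand must be '+' or '-'")
        lens = [e - s for s, e in self.exons]
        if any(l <= 0 for l in lens):
            raise SpliceError(f"{self.id}: empty exon interval")
        if sum(lens) != len(self.seq):
            raise SpliceError(f"{self.id}: exon lengths do not match spliced sequence")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise SpliceError(f"{self.id}: exons are not in transcript order")
        if not 0 <= self.cds_start < self.cds_end <= len(self.seq):
            raise SpliceError(f"{self.id}: CDS outside transcript")

    # -- derived ----------------------------------------------------------

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def cds(self) -> str:
        return self.seq[self.cds_start : self.cds_end]

    @property
    def protein(self) -> str:
        """Canonical protein, stop codon stripped."""
        aa = str(Seq(self.cds).translate())
        return aa[:-1] if aa.endswith("*") else aa

    @property
    def gene_span(self) -> tuple[int, int]:
        """Genomic [start, end) covered by the transcript."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def validate_coding(self) -> None:
        cds = self.cds
        if len(cds) % 3:
            raise SpliceError(f"{self.id}: CDS length not divisible by 3")
        if not cds.startswith("ATG"):
            raise SpliceError(f"{self.id}: CDS does not begin with ATG")
        if cds[-3:] not in _STOPS:
            raise SpliceError(f"{self.id}: CDS does not end at a stop codon")
        internal = str(Seq(cds[:-3]).translate())
        if "*" in internal:
            raise SpliceError(f"{self.id}: internal stop codon in CDS")

    # -- coordinate helpers -----------------------------------------------

    def exon_t_offsets(self) -> list[int]:
        """Transcript coordinate of the first base of each exon."""
        offs, acc = [], 0
        for l in self.exon_lengths:
            offs.append(acc)
            acc += l
        return offs

    def g_to_t(self, gpos: int) -> Optional[int]:
        """Genomic position -> transcript position, or None if intronic/outside."""
        for (s, e), off in zip(self.exons, self.exon_t_offsets()):
            if s <= gpos < e:
                within = gpos - s if self.strand == "+" else e - 1 - gpos
                return off + within
        return None

    def t_to_g(self, tpos: int) -> int:
        if not 0 <= tpos < len(self.seq):
            raise SpliceError(f"{self.id}: transcript position {tpos} out of range")
        for (s, e), off, l in zip(self.exons, self.exon_t_offsets(), self.exon_lengths):
            if off <= tpos < off + l:
                within = tpos - off
                return s + within if self.strand == "+" else e - 1 - within
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class HgvsC:
    """HGVS coding-DNA coordinate: position + signed intronic offset.

    ``pos`` follows HGVS conventions: 1..n within the CDS, negative for the
    5' UTR, and ``utr3`` marks ``*n`` positions past the stop codon.
    ``offset`` is 0 for exonic positions, +n downstream of a donor, -n
    upstream of an acceptor.
    """

    pos: int
    offset: int = 0
    ref: str = ""
    alt: str = ""
    utr3: bool = False

    def __str__(self) -> str:
        base = f"*{self.pos}" if self.utr3 else str(self.pos)
        if self.offset:
            base += f"{self.offset:+d}"
        if self.ref and self.alt:
            return f"c.{base}{self.ref}>{self.alt}"
        return f"c.{base}"


def _t_to_c(transcript: TranscriptModel, tpos: int) -> tuple[int, bool]:
    """Transcript coordinate -> HGVS coding position (pos, utr3 flag)."""
    if tpos < transcript.cds_start:
        return tpos - transcript.cds_start, False       # negative: 5' UTR
    if tpos < transcript.cds_end:
        return tpos - transcript.cds_start + 1, False
    return tpos - transcript.cds_end + 1, True


def _c_to_t(transcript: TranscriptModel, pos: int, utr3: bool) -> int:
    if utr3:
        return transcript.cds_end + pos - 1
    if pos < 0:
        return transcript.cds_start + pos
    if pos == 0:
        raise SpliceError("HGVS c. position 0 does not exist")
    return transcript.cds_start + pos - 1


def map_g_to_c(gpos: int, transcript: TranscriptModel, ref: str = "", alt: str = "") -> HgvsC:
    """Map a genomic position (0-based) to an HGVS c. coordinate.

    Intronic positions are expressed relative to the nearest exon boundary:
    the 5' half of an intron is donor-anchored (``+n``), the 3' half
    acceptor-anchored (``-n``); the exact middle base goes to the donor side.
    """
    lo, hi = transcript.gene_span
    if not lo <= gpos < hi:
        raise SpliceError(f"{transcript.id}: genomic position {gpos} outside gene span [{lo},{hi})")
    tpos = transcript.g_to_t(gpos)
    if tpos is not None:
        pos, utr3 = _t_to_c(transcript, tpos)
        return HgvsC(pos=pos, offset=0, ref=ref, alt=alt, utr3=utr3)

    # intronic: find flanking exons in transcript order
    for i in range(len(transcript.exons) - 1):
        up_s, up_e = transcript.exons[i]
        dn_s, dn_e = transcript.exons[i + 1]
        if transcript.strand == "+":
            intron = (up_e, dn_s)
            in_intron = intron[0] <= gpos < intron[1]
            d_donor = gpos - up_e + 1
            d_acceptor = dn_s - gpos
        else:
            intron = (dn_e, up_s)
            in_intron = intron[0] <= gpos < intron[1]
            d_donor = up_s - 1 - gpos + 1
            d_acceptor = gpos - dn_e + 1
        if not in_intron:
            continue
        offs = transcript.exon_t_offsets()
        if d_donor <= d_acceptor:
            t_anchor = offs[i] + transcript.exon_lengths[i] - 1
            pos, utr3 = _t_to_c(transcript, t_anchor)
            return HgvsC(pos=pos, offset=d_donor, ref=ref, alt=alt, utr3=utr3)
        t_anchor = offs[i + 1]
        pos, utr3 = _t_to_c(transcript, t_anchor)
        return HgvsC(pos=pos, offset=-d_acceptor, ref=ref, alt=alt, utr3=utr3)
    raise SpliceError(f"{transcript.id}: position {gpos} in gene span but not locatable")


def map_c_to_g(hgvs: HgvsC, transcript: TranscriptModel) -> int:
    """Inverse of :func:`map_g_to_c` (returns a 0-based genomic position)."""
    t_anchor = _c_to_t(transcript, hgvs.pos, hgvs.utr3)
    g_anchor = transcript.t_to_g(t_anchor)
    if hgvs.offset == 0:
        return g_anchor
    step = 1 if transcript.strand == "+" else -1
    return g_anchor + step * hgvs.offset


# -- cryptic donor scan ----------------------------------------------------


def _donor_score(context: str) -> int:
    """Matches of a 9-mer (junction -3..+6) against MAG|GTRAGT."""
    if len(context) != 9:
        raise SpliceError("donor context must be 9 nt")
    return sum(base in _IUPAC[cons] for base, cons in zip(context, _DONOR_CONSENSUS))


def scan_cryptic_donors(
    transcript: TranscriptModel,
    disrupted_donor: int,
    window_nt: int,
    genome: Optional[dict[str, str]] = None,
) -> list[tuple[int, int]]:
    """Rank exonic GT dinucleotides near an exon's 3' end as cryptic donors.

    ``disrupted_donor`` is the 0-based index of the exon whose native donor
    is disabled. Candidates are GT dinucleotides whose use would delete the
    terminal ``offset`` nt of the exon, for offsets 1..window_nt; each is
    scored by consensus match of the 9-mer spanning the putative junction.
    Returns ``(offset_from_exon_3prime_end, score)`` sorted by descending
    score, ties broken by the smaller offset (least sequence lost).

    The +1..+6 context of candidates close to the exon end can extend past
    the exon; those bases are taken from ``genome`` when provided and
    otherwise padded with N (scored permissively).
    """
    if not 0 <= disrupted_donor < len(transcript.exons):
        raise SpliceError(f"exon index {disrupted_donor} out of range")
    exon_len = transcript.exon_lengths[disrupted_donor]
    if window_nt > exon_len:
        raise SpliceError("window_nt exceeds exon length")
    off0 = transcript.exon_t_offsets()[disrupted_donor]
    exon_seq = transcript.seq[off0 : off0 + exon_len]

    def downstream(j: int, n: int) -> str:
        """n bases following exon position j (0-based, from exon or genome)."""
        chunk = exon_seq[j : j + n]
        if len(chunk) == n:
            return chunk
        missing = n - len(chunk)
        if genome is not None:
            g_last = transcript.t_to_g(off0 + exon_len - 1)
            chrom = genome[transcript.chrom]
            if transcript.strand == "+":
                extra = chrom[g_last + 1 : g_last + 1 + missing]
            else:
                extra = str(Seq(chrom[g_last - missing : g_last]).reverse_complement())
            return chunk + extra.upper().ljust(missing, "N")
        return chunk + "N" * missing

    candidates = []
    for offset in range(1, window_nt + 1):
        j = exon_len - offset            # junction after exon position j (0-based count)
        if exon_seq[j : j + 2] != "GT":
            continue
        upstream = ("N" * 3 + exon_seq[:j])[-3:] if j < 3 else exon_seq[j - 3 : j]
        context = upstream + downstream(j, 6)
        candidates.append((offset, _donor_score(context)))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    return candidates


# -- frameshift consequence ------------------------------------------------


@dataclass(frozen=True)
class SpliceConsequence:
    """Summary of an aberrant transcript produced by cryptic-donor use."""

    deleted_bp: int
    frameshift: bool
    ptc_transcript_pos: Optional[int]   # 1-based start of the stop codon in the aberrant mRNA
    normal_protein_aa: int
    aberrant_protein_aa: int
    aberrant_tail_aa: int
    nmd_candidate: bool                 # heuristic PTC>50-nt-upstream-of-last-junction flag

    def __post_init__(self) -> None:
        if self.aberrant_tail_aa > self.aberrant_protein_aa:
            raise SpliceError("aberrant tail cannot exceed aberrant protein length")


def splice_consequence(
    transcript: TranscriptModel,
    cryptic_offset: int,
    exon_index: int,
) -> SpliceConsequence:
    """Predict the protein outcome of deleting an exon's terminal nucleotides.

    The aberrant mRNA is the canonical spliced mRNA minus the terminal
    ``cryptic_offset`` nt of exon ``exon_index``; translation starts from the
    canonical ATG and runs to the first stop (scanning past the canonical
    stop into the 3' UTR if the frame requires). The aberrant tail counts
    the novel residues: both proteins are anchored at the start codon, the
    longest common prefix and (disjoint) longest common suffix are removed,
    and the tail is what remains of the aberrant protein. A frameshift tail
    is therefore the run of aberrant residues up to the premature stop,
    while a clean in-frame deletion leaves no tail.
    """
    if not 0 <= exon_index < len(transcript.exons):
        raise SpliceError(f"exon index {exon_index} out of range")
    exon_len = transcript.exon_lengths[exon_index]
    if not 1 <= cryptic_offset < exon_len:
        raise SpliceError(
            f"cryptic_offset must lie in [1, {exon_len - 1}] for exon {exon_index}"
        )
    off0 = transcript.exon_t_offsets()[exon_index]
    del_start = off0 + exon_len - cryptic_offset
    del_end = off0 + exon_len
    aberrant = transcript.seq[:del_start] + transcript.seq[del_end:]
    assert len(aberrant) == len(transcript.seq) - cryptic_offset

    if del_end <= transcript.cds_start:
        raise SpliceError("deletion lies entirely in the 5' UTR; no coding consequence")
    cds_start = transcript.cds_start
    if del_start < cds_start:
        raise SpliceError("deletion overlaps the start codon")

    if not aberrant[cds_start : cds_start + 3] == "ATG":
        raise SpliceError(f"{transcript.id}: no ATG at canonical start in aberrant mRNA")
    # translate to first stop
    prot = []
    stop_t = None
    for i in range(cds_start, len(aberrant) - 2, 3):
        codon = aberrant[i : i + 3]
        if codon in _STOPS:
            stop_t = i
            break
        prot.append(str(Seq(codon).translate()))
    if stop_t is None:
        raise SpliceError(f"{transcript.id}: no in-frame stop codon found in aberrant mRNA")
    aberrant_prot = "".join(prot)

    canonical_prot = transcript.protein
    frameshift = cryptic_offset % 3 != 0
    canonical_stop_t = transcript.cds_end - 3
    deleted_coding = min(del_end, transcript.cds_end) - max(del_start, cds_start)
    ptc: Optional[int]
    if not frameshift and stop_t == canonical_stop_t - deleted_coding:
        ptc = None                       # canonical stop still used
    else:
        ptc = stop_t + 1                 # 1-based in the aberrant mRNA

    prefix = 0
    for a, b in zip(aberrant_prot, canonical_prot):
        if a != b:
            break
        prefix += 1
    suffix = 0
    max_suffix = min(len(aberrant_prot), len(canonical_prot)) - prefix
    while suffix < max_suffix and aberrant_prot[-1 - suffix] == canonical_prot[-1 - suffix]:
        suffix += 1
    tail = len(aberrant_prot) - prefix - suffix

    # NMD heuristic: PTC more than 50 nt upstream of the last exon junction.
    junctions = []
    acc = 0
    lens = list(transcript.exon_lengths)
    lens[exon_index] -= cryptic_offset
    for l in lens[:-1]:
        acc += l
        junctions.append(acc)
    nmd = bool(junctions) and ptc is not None and (junctions[-1] - (stop_t + 2)) > 50

    return SpliceConsequence(
        deleted_bp=cryptic_offset,
        frameshift=frameshift,
        ptc_transcript_pos=ptc,
        normal_protein_aa=len(canonical_prot),
        aberrant_protein_aa=len(aberrant_prot),
        aberrant_tail_aa=tail,
        nmd_candidate=nmd,
    )


# -- transcript alignment --------------------------------------------------


def align_transcripts(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Globally align two nucleotide sequences; return gap blocks in seq_b.

    Needleman-Wunsch with match +1, mismatch -1 and affine gap penalties
    (open -10, extend -0.5, the weighting of the standard pairwise
    alignment web tools): affine costs keep a deletion in one contiguous
    block instead of fragmenting it for chance flank matches. Returns
    maximal runs where ``seq_b`` is gapped relative to ``seq_a``, as
    ``(position_in_seq_a, length)`` with 0-based positions; e.g. a normal
    transcript aligned against its deletion-bearing counterpart yields one
    block per deleted segment.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise SpliceError(f"{name} is empty")
        if set(s.upper()) - set("ACGTN"):
            raise SpliceError(f"{name} contains non-nucleotide symbols")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    blocks: list[tuple[int, int]] = []
    # aligned blocks of the target (seq_a): gaps in seq_b are the a-intervals
    # between consecutive aligned blocks where the query does not advance.
    a_blocks = aln.aligned[0]
    b_blocks = aln.aligned[1]
    for (a_prev, b_prev), (a_next, b_next) in zip(
        zip(a_blocks[:-1], b_blocks[:-1]), zip(a_blocks[1:], b_blocks[1:])
    ):
        a_gap = a_next[0] - a_prev[1]
        b_gap = b_next[0] - b_prev[1]
        if a_gap > 0 and b_gap == 0:
            blocks.append((int(a_prev[1]), int(a_gap)))
    # leading/trailing unaligned target stretches count as gaps in seq_b
    if len(a_blocks):
        if a_blocks[0][0] > 0 and b_blocks[0][0] == 0:
            blocks.insert(0, (0, int(a_blocks[0][0])))
        if a_blocks[-1][1] < len(seq_a) and b_blocks[-1][1] == len(seq_b):
            blocks.append((int(a_blocks[-1][1]), int(len(seq_a) - a_blocks[-1][1])))
    return blocks
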