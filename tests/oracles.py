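"""Independent reference implementations used to check the package.

Everything here is deliberately written from first principles (exact
rational arithmetic, run-length scans, a literal codon table) so the
oracles share no code path with the implementations they verify.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import groupby
from math import comb

GENOTYPES = ("hom_ref", "het", "hom_alt")

# literal standard codon table (independent of Biopython)
_T = "TTTF TTCF TTAL TTGL CTTL CTCL CTAL CTGL ATTI ATCI ATAI ATGM GTTV GTCV GTAV GTGV " \
    "TCTS TCCS TCAS TCGS CCTP CCCP CCAP CCGP ACTT ACCT ACAT ACGT GCTA GCCA GCAA GCGA " \
    "TATY TACY TAA* TAG* CATH CACH CAAQ CAGQ AATN AACN AAAK AAGK GATD GACD GAAE GAGE " \
    "TGTC TGCC TGA* TGGW CGTR CGCR CGAR CGGR AGTS AGCS AGAR AGGR GGTG GGCG GGAG GGGG"
CODON_TABLE = {chunk[:3]: chunk[3] for chunk in _T.split()}


def translate(cds: str) -> str:
    """Translate to the first stop; '*' never included."""
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def bayes_posterior_exact(
    ref_count: int, alt_count: int, error_rate: float, prior: dict[str, float]
) -> dict[str, Fraction]:
    """Exact-rational genotype posterior by direct enumeration."""
    e = Fraction(error_rate)  # exact value of the float
    n = ref_count + alt_count
    p_alt = {"hom_ref": e, "het": Fraction(1, 2), "hom_alt": 1 - e}
    weight = {}
    for g in GENOTYPES:
        p = p_alt[g]
        lik = comb(n, alt_count) * p**alt_count * (1 - p) ** ref_count
        weight[g] = Fraction(prior[g]) * lik
    z = sum(weight.values())
    return {g: weight[g] / z for g in GENOTYPES}


def fisher_two_sided_exact(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), comb(n, col1))

    p_obs = pmf(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)


def rle_regions(mask, chroms, positions):
    """Run-length decomposition of a candidate mask, independent of numpy."""
    runs = []
    items = list(zip(chroms, positions, mask))
    i = 0
    for (chrom, flag), group in groupby(enumerate(items), key=lambda t: (t[1][0], t[1][2])):
        group = list(group)
        if flag:
            first, last = group[0][0], group[-1][0]
            runs.append(
                (chrom, items[first][1], items[last][1] + 1, last - first + 1)
            )
    return runs


def consequence_by_retranslation(transcript, tpos: int, t_alt: str) -> str:
    """Coding-class oracle: mutate the spliced CDS, retranslate, compare.

    Applies to CDS positions only; returns synonymous / missense /
    stop_gained / other(stop-lost) without any splice-window logic.
    """
    cds = transcript.cds
    cpos = tpos - transcript.cds_start
    mutated = cds[:cpos] + t_alt + cds[cpos + 1 :]
    codon_i = cpos // 3
    old = CODON_TABLE[cds[codon_i * 3 : codon_i * 3 + 3]]
    new = CODON_TABLE[mutated[codon_i * 3 : codon_i * 3 + 3]]
    if old == new:
        return "synonymous"
    if new == "*":
        return "stop_gained"
    if old == "*":
        return "other"
    return "missense"


def donor_score_bruteforce(context: str) -> int:
    """Per-position consensus match count against MAG|GTRAGT."""
    allowed = ["AC", "A", "G", "G", "T", "AG", "A", "G", "T"]
    return sum(base in ok for base, ok in zip(context, allowed))
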