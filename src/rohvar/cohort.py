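"""Cohort genotype counting, carrier frequency, and exact association.

Validation of a candidate recessive variant in a breed cohort: count
genotypes, estimate the carrier (heterozygote) frequency, and test
case-control association with a two-sided Fisher exact test computed by
hypergeometric enumeration, either on allele counts (allelic mode) or on
homozygous-alt versus other genotypes (genotypic-recessive mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal

from scipy.stats import hypergeom

__all__ = [
    "GenotypeCounts",
    "carrier_frequency",
    "fisher_exact_2x2",
    "fisher_exact_association",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise CohortError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def alt_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_alt

    @property
    def ref_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_ref


def carrier_frequency(counts: GenotypeCounts, decimals: int = 1) -> tuple[float, float]:
    """Heterozygote fraction and its display percentage.

    Returns ``(fraction, percent)`` where the percentage is rounded half-up
    to ``decimals`` places (banker's rounding would misprint borderline
    frequencies such as 29/483 = 6.004% -> 6.0%).
    """
    if counts.total == 0:
        raise CohortError("cannot compute a carrier frequency from zero genotypes")
    frac = counts.n_het / counts.total
    percent = float(
        Decimal(frac * 100).quantize(Decimal(f"1.{'0' * decimals}"), rounding=ROUND_HALF_UP)
    )
    return frac, percent


def fisher_exact_2x2(table: list[list[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact p and odds ratio for a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (standard two-sided definition, with a small relative tolerance against
    floating-point ties). The odds ratio is ``inf`` when only the
    denominator holds a zero cell.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise CohortError("table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise CohortError("all-zero table")
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise CohortError("table has a zero row or column margin")

    rv = hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = rv.pmf(a)
    cutoff = p_obs * (1.0 + 1e-7)
    p = float(sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= cutoff))
    p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return p, odds


def fisher_exact_association(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    mode: Literal["allelic", "genotypic_recessive"] = "allelic",
) -> tuple[float, float]:
    """Case-control Fisher exact association for a biallelic variant.

    ``allelic`` tests the 2x2 allele-count table (alt vs ref alleles);
    ``genotypic_recessive`` tests homozygous-alt versus all other genotypes.
    Returns ``(p_value, odds_ratio)`` with ``inf`` odds for a denominator
    zero cell.
    """
    if mode == "allelic":
        table = [
            [case_counts.alt_alleles, case_counts.ref_alleles],
            [control_counts.alt_alleles, control_counts.ref_alleles],
        ]
    elif mode == "genotypic_recessive":
        table = [
            [case_counts.n_hom_alt, case_counts.total - case_counts.n_hom_alt],
            [control_counts.n_hom_alt, control_counts.total - control_counts.n_hom_alt],
        ]
    else:
        raise CohortError(f"unknown association mode {mode!r}")
    return fisher_exact_2x2(table)
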